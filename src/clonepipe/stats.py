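"""Assumption-gated group tests, effect sizes, FDR, and multi-family GLMs.

The univariate workflow mirrors common practice in mosaic-tissue studies:
parametric assumptions are screened per comparison with a Shapiro–Wilk
normality test on each group and a Fligner–Killeen homogeneity-of-variance
test across groups (both at α = 0.05); comparisons that pass route to a
Welch t-test with an unpooled standardized mean difference (Cohen's d /
Hedges' g), and ones that fail route to a Mann–Whitney U test (Wilcoxon
signed-rank if paired) with Cliff's δ.  p-values across a family of
comparisons are adjusted with the Benjamini–Hochberg step-up FDR procedure.

The regression layer fits linear, logistic (binary or (success, failure)
counts), Poisson and negative-binomial models by maximum likelihood,
reports Wald inference, Cox–Snell / Nagelkerke / McFadden pseudo-R², and
model diagnostics (variance inflation factors, Durbin–Watson,
non-constant-variance score test), selects among candidate predictor sets
by AIC, and produces delta-method effects profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.stattools import durbin_watson

__all__ = [
    "TestResult",
    "ModelFit",
    "two_group_test",
    "multi_group_test",
    "cliffs_delta",
    "cohens_d_unpooled",
    "hedges_g_unpooled",
    "glass_delta",
    "effect_size",
    "adjust_p",
    "fit_glm",
    "pseudo_r2",
    "diagnostics",
    "select_model_aic",
    "effects_profile",
    "transform",
    "correlate",
]

ALPHA_GATE = 0.05


# ---------------------------------------------------------------------------
# effect sizes

def cliffs_delta(x: Sequence[float], y: Sequence[float]) -> float:
    """Cliff's δ = (#(xᵢ > yⱼ) − #(xᵢ < yⱼ)) / (nₓ·n_y) ∈ [−1, 1].

    Computed through the Mann–Whitney U identity δ = 2U/(nₓ n_y) − 1 with
    midranks, which handles ties and avoids the O(n²) pair enumeration.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")
    ranks = sps.rankdata(np.concatenate([x, y]))
    u = ranks[: x.size].sum() - x.size * (x.size + 1) / 2  # U for x over y
    return float(2.0 * u / (x.size * y.size) - 1.0)


def cohens_d_unpooled(x: Sequence[float], y: Sequence[float]) -> float:
    """Unpooled Cohen's d: (x̄ − ȳ) / √((s²ₓ + s²_y)/2), sample variances.

    Zero variance in both groups with equal means is defined as d = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per group")
    denom = np.sqrt((x.var(ddof=1) + y.var(ddof=1)) / 2.0)
    diff = x.mean() - y.mean()
    if denom == 0:
        return 0.0 if diff == 0 else np.sign(diff) * np.inf
    return float(diff / denom)


def hedges_g_unpooled(x: Sequence[float], y: Sequence[float]) -> float:
    """Hedges' g: small-sample corrected d, g = d·(1 − 3/(4(nₓ+n_y) − 9))."""
    n = len(x) + len(y)
    return cohens_d_unpooled(x, y) * (1.0 - 3.0 / (4.0 * n - 9.0))


def glass_delta(x: Sequence[float], y: Sequence[float]) -> float:
    """Glass's Δ: (x̄ − ȳ) / s_y (control-group standardizer)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sd = y.std(ddof=1)
    if sd == 0:
        raise ValueError("control group has zero variance")
    return float((x.mean() - y.mean()) / sd)


_EFFECTS = {
    "cliffs_delta": cliffs_delta,
    "cohens_d_unpooled": cohens_d_unpooled,
    "hedges_g_unpooled": hedges_g_unpooled,
    "glass_delta": glass_delta,
}


def effect_size(x, y, kind: str = "cliffs_delta") -> float:
    if kind not in _EFFECTS:
        raise ValueError(f"unknown effect size {kind!r}; choose from {sorted(_EFFECTS)}")
    return _EFFECTS[kind](x, y)


# ---------------------------------------------------------------------------
# group tests

@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    effect_size: tuple[str, float] | None = None
    assumption_report: dict = field(default_factory=dict)
    adjusted_p: float | None = None
    note: str = ""


def _assumption_gate(groups: list[np.ndarray]) -> tuple[bool, dict, str]:
    """Shapiro–Wilk per group + Fligner–Killeen across; True = parametric ok."""
    report: dict = {"shapiro_p": [], "fligner_p": None}
    note = ""
    ok = True
    for g in groups:
        if len(g) < 3 or np.ptp(g) == 0:
            report["shapiro_p"].append(np.nan)
            ok = False
            note = "group too small or constant for Shapiro-Wilk; using nonparametric test"
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = float(sps.shapiro(g).pvalue)
        report["shapiro_p"].append(p)
        if p < ALPHA_GATE:
            ok = False
    try:
        fp = float(sps.fligner(*groups).pvalue)
    except ValueError:
        fp = np.nan
        ok = False
    report["fligner_p"] = fp
    if np.isfinite(fp) and fp < ALPHA_GATE:
        ok = False
    return ok, report, note


def two_group_test(
    x: Sequence[float],
    y: Sequence[float],
    paired: bool = False,
    auto: bool = True,
    test: str | None = None,
) -> TestResult:
    """Two-sample comparison with automatic parametric/nonparametric routing.

    With ``auto`` (default) the assumption gate decides: all Shapiro–Wilk
    p-values and the Fligner–Killeen p above 0.05 route to a two-sided Welch
    t-test with Hedges' g; any failure routes to a two-sided Mann–Whitney U
    (or Wilcoxon signed-rank when ``paired``) with Cliff's δ.  With
    ``auto=False`` the caller names the test: one of ``t``, ``mannwhitney``,
    ``wilcoxon``, ``paired_t``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("need at least 3 observations per group")
    if paired and x.size != y.size:
        raise ValueError("paired samples must have equal length")

    report: dict = {}
    note = ""
    if auto:
        ok, report, note = _assumption_gate([x, y])
        test = ("paired_t" if paired else "t") if ok else ("wilcoxon" if paired else "mannwhitney")
    elif test is None:
        raise ValueError("auto=False requires an explicit test name")

    if test == "t":
        res = sps.ttest_ind(x, y, equal_var=False)
        eff = ("hedges_g_unpooled", hedges_g_unpooled(x, y))
        name = "welch_t"
    elif test == "paired_t":
        res = sps.ttest_rel(x, y)
        eff = ("hedges_g_unpooled", hedges_g_unpooled(x, y))
        name = "paired_t"
    elif test == "mannwhitney":
        res = sps.mannwhitneyu(x, y, alternative="two-sided")
        eff = ("cliffs_delta", cliffs_delta(x, y))
        name = "mann_whitney_u"
    elif test == "wilcoxon":
        d = x - y
        if np.all(d == 0):
            res = type("R", (), {"statistic": 0.0, "pvalue": 1.0})
        else:
            res = sps.wilcoxon(x, y, alternative="two-sided")
        eff = ("cliffs_delta", cliffs_delta(x, y))
        name = "wilcoxon_signed_rank"
    else:
        raise ValueError(f"unknown test {test!r}")
    return TestResult(
        test_name=name,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        effect_size=eff,
        assumption_report=report,
        note=note,
    )


def multi_group_test(
    groups: Sequence[Sequence[float]] | np.ndarray,
    auto: bool = True,
    contingency: bool = False,
) -> TestResult:
    """k-group comparison: ANOVA vs Kruskal–Wallis by the assumption gate.

    With ``contingency=True`` the input is a 2D count table routed to
    Fisher's exact test (2×2) or a chi-square test otherwise.
    """
    if contingency:
        table = np.asarray(groups, dtype=int)
        if table.shape == (2, 2):
            res = sps.fisher_exact(table)
            return TestResult("fisher_exact", float(res[0]), float(res[1]))
        chi2, p, _, _ = sps.chi2_contingency(table)
        return TestResult("chi_square", float(chi2), float(p))
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size < 3 for g in gs):
        raise ValueError("need at least 2 groups of at least 3 observations")
    if auto:
        ok, report, note = _assumption_gate(gs)
    else:
        ok, report, note = True, {}, ""
    if ok:
        res = sps.f_oneway(*gs)
        return TestResult("anova", float(res.statistic), float(res.pvalue), assumption_report=report)
    res = sps.kruskal(*gs)
    return TestResult(
        "kruskal_wallis", float(res.statistic), float(res.pvalue),
        assumption_report=report, note=note,
    )


# ---------------------------------------------------------------------------
# multiple testing

def adjust_p(p_values: Sequence[float], method: str = "fdr") -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment (``method='none'`` passes through).

    qᵢ = min over j ≥ i (in ascending-p order) of min(1, pⱼ·n/j), returned in
    the original order; adjusted values never fall below the raw ones.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if method in (None, "none"):
        return p.copy()
    if method not in ("fdr", "bh", "fdr_bh"):
        raise ValueError(f"unknown adjustment method {method!r}")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    # clamp float round-off so adjusted >= raw holds exactly, then cap at 1
    q = np.minimum(np.maximum(q, p[order]), 1.0)
    out = np.empty(n)
    out[order] = q
    return out


# ---------------------------------------------------------------------------
# GLMs

_FAMILIES = ("linear", "logistic", "poisson", "negative_binomial")


@dataclass
class ModelFit:
    """A fitted regression with likelihoods, Wald inference and extras."""

    family: str
    response: str | tuple[str, str]
    predictors: list[str]
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame
    llf: float
    llnull: float
    nobs: int
    aic: float
    pseudo_r2: dict[str, float]
    odds_ratios: pd.Series | None = None
    scale: float = 1.0
    nb_alpha: float | None = None
    converged: bool = True
    separation_flag: bool = False
    _result: object = None
    _data_means: pd.Series | None = None

    @property
    def k_params(self) -> int:
        k = len(self.params)
        if self.family == "linear":
            k += 1  # σ²
        if self.family == "negative_binomial":
            k += 1  # dispersion
        return k


def pseudo_r2(llf: float, llnull: float, n: int) -> dict[str, float]:
    """Cox–Snell, Nagelkerke and McFadden pseudo-R² from two log-likelihoods.

    cox_snell = 1 − exp(2(LL₀ − LL)/n); nagelkerke rescales it by its
    maximum 1 − exp(2·LL₀/n); mcfadden = 1 − LL/LL₀.
    """
    cs = 1.0 - np.exp(2.0 * (llnull - llf) / n)
    denom = 1.0 - np.exp(2.0 * llnull / n)
    nag = cs / denom if denom > 0 else 0.0
    mcf = 1.0 - llf / llnull if llnull != 0 else 0.0
    # clip tiny negative round-off
    return {
        "cox_snell": float(max(cs, 0.0)),
        "nagelkerke": float(min(max(nag, 0.0), 1.0)),
        "mcfadden": float(max(mcf, 0.0)),
    }


def _design(table: pd.DataFrame, predictors: Sequence[str]) -> pd.DataFrame:
    missing = [p for p in predictors if p not in table.columns]
    if missing:
        raise ValueError(f"predictors not in table: {missing}")
    X = table[list(predictors)].astype(float)
    if not np.all(np.isfinite(X.to_numpy())):
        raise ValueError("non-finite values in predictors")
    X = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name an aliased column for the error message
        aliased = []
        cols = X.columns.tolist()
        for j in range(1, X.shape[1]):
            sub = X.iloc[:, [c for c in range(X.shape[1]) if c != j]]
            if np.linalg.matrix_rank(sub.to_numpy()) == rank:
                aliased.append(cols[j])
        raise ValueError(f"rank-deficient design; aliased column(s): {aliased or cols}")
    return X


def _endog(table: pd.DataFrame, response, family: str) -> np.ndarray:
    if isinstance(response, (tuple, list)):
        if family != "logistic":
            raise ValueError("(success, failure) counts response requires the logistic family")
        endog = table[list(response)].to_numpy(dtype=float)
        if (endog < 0).any():
            raise ValueError("counts must be non-negative")
        return endog
    y = table[response].to_numpy(dtype=float)
    if family == "logistic" and not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("binary logistic response must be 0/1")
    if family in ("poisson", "negative_binomial"):
        if (y < 0).any() or not np.allclose(y, np.round(y)):
            raise ValueError(f"{family} response must be non-negative integers")
    return y


def fit_glm(
    table: pd.DataFrame,
    response: str | tuple[str, str],
    predictors: Sequence[str],
    family: str = "linear",
) -> ModelFit:
    """Maximum-likelihood fit of one of four regression families.

    ``family`` ∈ {linear, logistic, poisson, negative_binomial}.  The
    logistic family accepts either a 0/1 response column or a
    ``(success_col, failure_col)`` pair of count columns (binomial counts);
    the two parameterizations of the same data give identical coefficients.
    The negative-binomial dispersion is estimated by maximum likelihood.
    Requires at least 10 rows per predictor.  Perfect separation in the
    logistic family is flagged (``separation_flag``) rather than silently
    returning diverging estimates.
    """
    if family not in _FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {_FAMILIES}")
    predictors = list(predictors)
    X = _design(table, predictors)
    y = _endog(table, response, family)
    # for a (success, failure) counts response the information unit is the
    # trial, not the table row
    n_eff = int(y.sum()) if y.ndim == 2 else len(table)
    if n_eff < 10 * max(len(predictors), 1):
        raise ValueError(
            f"need at least {10 * max(len(predictors), 1)} observations "
            f"for {len(predictors)} predictor(s); got {n_eff}"
        )
    X0 = X[["const"]]

    separation = False
    nb_alpha = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if family == "linear":
            res = sm.OLS(y, X).fit()
            res0 = sm.OLS(y, X0).fit()
        elif family == "logistic":
            try:
                res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
                mu = np.asarray(res.fittedvalues)
                if np.any(mu < 1e-10) or np.any(mu > 1 - 1e-10):
                    separation = True
            except Exception:
                res = sm.GLM(y, X, family=sm.families.Binomial()).fit_regularized(alpha=1e-4, L1_wt=0.0)
                separation = True
            res0 = sm.GLM(y, X0, family=sm.families.Binomial()).fit()
        elif family == "poisson":
            res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
            res0 = sm.GLM(y, X0, family=sm.families.Poisson()).fit()
        else:  # negative binomial, ML dispersion
            dm = sm.NegativeBinomial(y, X)
            res = dm.fit(disp=False, maxiter=200)
            nb_alpha = float(res.params[-1])
            res0 = sm.NegativeBinomial(y, X0).fit(disp=False, maxiter=200)

    if family == "negative_binomial":
        params = pd.Series(res.params[:-1], index=X.columns)
        bse = pd.Series(res.bse[:-1], index=X.columns)
        pvals = pd.Series(res.pvalues[:-1], index=X.columns)
        ci = pd.DataFrame(res.conf_int()[:-1], index=X.columns, columns=[0, 1])
    else:
        params = pd.Series(np.asarray(res.params), index=X.columns)
        bse = pd.Series(np.asarray(getattr(res, "bse", np.full(len(params), np.nan))), index=X.columns)
        pvals = pd.Series(np.asarray(getattr(res, "pvalues", np.full(len(params), np.nan))), index=X.columns)
        try:
            ci = pd.DataFrame(np.asarray(res.conf_int()), index=X.columns, columns=[0, 1])
        except Exception:
            ci = pd.DataFrame(np.nan, index=X.columns, columns=[0, 1])

    llf = float(res.llf)
    llnull = float(res0.llf)
    n = n_eff
    k = len(params) + (1 if family == "linear" else 0) + (1 if family == "negative_binomial" else 0)
    aic = 2 * k - 2 * llf
    fit = ModelFit(
        family=family,
        response=response if not isinstance(response, list) else tuple(response),
        predictors=predictors,
        params=params,
        bse=bse,
        pvalues=pvals,
        conf_int=ci,
        llf=llf,
        llnull=llnull,
        nobs=n,
        aic=float(aic),
        pseudo_r2=pseudo_r2(llf, llnull, n),
        odds_ratios=np.exp(params) if family == "logistic" else None,
        scale=float(getattr(res, "scale", 1.0)),
        nb_alpha=nb_alpha,
        converged=bool(getattr(res, "converged", True)) if hasattr(res, "converged") else True,
        separation_flag=separation,
        _result=res,
        _data_means=table[predictors].astype(float).mean() if predictors else None,
    )
    return fit


# ---------------------------------------------------------------------------
# diagnostics

def variance_inflation(table: pd.DataFrame, predictors: Sequence[str]) -> pd.Series:
    """VIFⱼ = 1/(1 − R²ⱼ) from regressing predictor j on the others.

    Exact collinearity reports inf for the offending predictors.
    """
    predictors = list(predictors)
    if len(predictors) < 2:
        raise ValueError("VIF needs at least 2 predictors")
    X = table[predictors].astype(float).to_numpy()
    out = {}
    for j, name in enumerate(predictors):
        yj = X[:, j]
        others = np.column_stack([np.ones(len(X)), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        if ss_tot == 0:
            out[name] = np.inf
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def ncv_score_test(fit: ModelFit) -> tuple[float, float]:
    """Non-constant-variance score test for a linear fit (χ²₁).

    Regresses the normalized squared residuals on the fitted values; the
    score statistic is half the model sum of squares of that auxiliary
    regression.
    """
    if fit.family != "linear":
        raise ValueError("ncv score test applies to the linear family only")
    res = fit._result
    e = np.asarray(res.resid)
    sigma2 = float(e @ e) / len(e)
    u = e**2 / sigma2
    f = np.asarray(res.fittedvalues)
    Z = np.column_stack([np.ones(len(f)), f])
    g, *_ = np.linalg.lstsq(Z, u, rcond=None)
    u_hat = Z @ g
    stat = float(((u_hat - u.mean()) ** 2).sum()) / 2.0
    p = float(sps.chi2.sf(stat, df=1))
    return stat, p


def diagnostics(fit: ModelFit, table: pd.DataFrame) -> dict:
    """VIFs, Durbin–Watson on row-ordered residuals, and (linear) ncv test.

    Flags any predictor with VIF ≥ 5 under ``high_vif``.
    """
    report: dict = {}
    if len(fit.predictors) >= 2:
        vif = variance_inflation(table, fit.predictors)
        report["vif"] = vif
        report["high_vif"] = vif[vif >= 5].index.tolist()
    else:
        report["vif"] = None
        report["high_vif"] = []
    res = fit._result
    resid = np.asarray(res.resid if hasattr(res, "resid") else res.resid_response)
    report["durbin_watson"] = float(durbin_watson(resid))
    if fit.family == "linear":
        stat, p = ncv_score_test(fit)
        report["ncv_statistic"], report["ncv_p"] = stat, p
    return report


def select_model_aic(
    candidates: Sequence[Sequence[str]],
    table: pd.DataFrame,
    response,
    family: str = "linear",
    vif_screen: bool = True,
) -> ModelFit:
    """Fit every candidate predictor set; return the lowest-AIC fit.

    Candidates with any VIF ≥ 5 are screened out first (multi-predictor sets
    only).  Ties break toward fewer parameters.  Raises if no candidate can
    be fitted.
    """
    if not candidates:
        raise ValueError("need at least one candidate predictor set")
    fits: list[ModelFit] = []
    for preds in candidates:
        preds = list(preds)
        try:
            if vif_screen and len(preds) >= 2:
                vif = variance_inflation(table, preds)
                if (vif >= 5).any():
                    continue
            fits.append(fit_glm(table, response, preds, family))
        except Exception:
            continue
    if not fits:
        raise RuntimeError("no candidate model could be fitted (or all failed the VIF screen)")
    fits.sort(key=lambda f: (f.aic, f.k_params))
    return fits[0]


# ---------------------------------------------------------------------------
# effects profiles

def _link_inverse(family: str):
    if family == "linear":
        return lambda eta: eta
    if family == "logistic":
        return lambda eta: 1.0 / (1.0 + np.exp(-eta))
    return np.exp  # poisson / negative binomial (log link)


def effects_profile(
    fit: ModelFit,
    predictor: str,
    grid: Sequence[float] | None = None,
    n_points: int = 50,
    observed_range: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Predicted response over one predictor, others held at sample means.

    The 95% band comes from the delta method on the linear predictor
    (η ± 1.96·se(η)) transformed through the inverse link, so it respects
    the response scale.  Grid points outside the observed predictor range
    are allowed but flagged in the ``extrapolated`` column.
    """
    if predictor not in fit.predictors:
        raise ValueError(f"{predictor!r} is not in the fitted model")
    means = fit._data_means
    if grid is None:
        lo, hi = observed_range if observed_range else (None, None)
        if lo is None:
            # fall back to ±2 sd around the mean
            lo, hi = means[predictor] - 2, means[predictor] + 2
        grid = np.linspace(lo, hi, n_points)
    grid = np.asarray(grid, dtype=float)

    cols = fit.params.index.tolist()
    X = np.tile([means.get(c, 1.0) if c != "const" else 1.0 for c in cols], (len(grid), 1))
    j = cols.index(predictor)
    X[:, j] = grid

    beta = fit.params.to_numpy()
    res = fit._result
    try:
        cov = np.asarray(res.cov_params())
        if fit.family == "negative_binomial":
            cov = cov[: len(beta), : len(beta)]
    except Exception:
        cov = np.diag(fit.bse.to_numpy() ** 2)
    eta = X @ beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", X, cov, X))
    inv = _link_inverse(fit.family)
    lo_obs, hi_obs = (grid.min(), grid.max()) if observed_range is None else observed_range
    return pd.DataFrame(
        {
            "grid": grid,
            "response": inv(eta),
            "lower": inv(eta - 1.96 * se),
            "upper": inv(eta + 1.96 * se),
            "extrapolated": (grid < lo_obs) | (grid > hi_obs),
        }
    )


# ---------------------------------------------------------------------------
# misc

def transform(column: Sequence[float], kind: str) -> np.ndarray:
    """Elementwise column transform: log, log1p, sqrt or zscore."""
    x = np.asarray(column, dtype=float)
    if kind == "log":
        bad = np.nonzero(x <= 0)[0]
        if bad.size:
            raise ValueError(f"log requires positive values; offending rows: {bad[:10].tolist()}")
        return np.log(x)
    if kind == "log1p":
        if (x < -1).any():
            raise ValueError("log1p requires values > -1")
        return np.log1p(x)
    if kind == "sqrt":
        if (x < 0).any():
            raise ValueError("sqrt requires non-negative values")
        return np.sqrt(x)
    if kind == "zscore":
        sd = x.std(ddof=1)
        if sd == 0:
            raise ValueError("zscore undefined for a constant column")
        return (x - x.mean()) / sd
    raise ValueError(f"unknown transform {kind!r}")


def correlate(x: Sequence[float], y: Sequence[float], method: str = "pearson") -> tuple[float, float]:
    """Correlation coefficient and two-sided p (pearson/spearman/kendall)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length samples of at least 3")
    if method == "pearson":
        r = sps.pearsonr(x, y)
    elif method == "spearman":
        r = sps.spearmanr(x, y)
    elif method == "kendall":
        r = sps.kendalltau(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(r.statistic), float(r.pvalue)
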