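import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst
from scipy import stats as sps

from clonepipe import stats as st


def cliffs_delta_enumeration(x, y):
    """O(n^2) pair-enumeration oracle."""
    gt = sum(1 for a in x for b in y if a > b)
    lt = sum(1 for a in x for b in y if a < b)
    return (gt - lt) / (len(x) * len(y))


class TestEffectSizes:
    def test_cliffs_delta_textbook_example(self):
        # 9 pairs: 1 with x>y, 6 with x<y
        assert st.cliffs_delta([1, 2, 3], [2, 3, 4]) == pytest.approx(-5 / 9, abs=1e-12)

    @pytest.mark.parametrize("seed", range(30))
    def test_cliffs_delta_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 8, rng.integers(2, 20)).astype(float)  # ties likely
        y = rng.normal(0, 2, rng.integers(2, 20))
        assert st.cliffs_delta(x, y) == pytest.approx(cliffs_delta_enumeration(x, y), abs=1e-12)

    def test_cliffs_delta_bounds_and_antisymmetry(self, rng):
        x = rng.normal(2, 1, 15)
        y = rng.normal(0, 1, 12)
        d = st.cliffs_delta(x, y)
        assert -1 <= d <= 1
        assert st.cliffs_delta(y, x) == pytest.approx(-d, abs=1e-12)
        assert st.cliffs_delta([5, 6], [1, 2]) == 1.0

    def test_cohens_d_shift_by_one_sd(self, rng):
        y = rng.normal(0, 1, 200)
        x = y + y.std(ddof=1)  # same sample variance, mean shifted by 1 sd
        assert st.cohens_d_unpooled(x, y) == pytest.approx(1.0, abs=1e-12)

    def test_hedges_correction_factor(self, rng):
        x = rng.normal(1, 1, 10)
        y = rng.normal(0, 1, 8)
        d = st.cohens_d_unpooled(x, y)
        assert st.hedges_g_unpooled(x, y) == pytest.approx(d * (1 - 3 / (4 * 18 - 9)))

    def test_zero_variance_equal_means_gives_zero(self):
        assert st.cohens_d_unpooled([2, 2, 2], [2, 2, 2]) == 0.0

    def test_glass_delta_uses_control_sd(self):
        y = [0.0, 2.0, 4.0]  # sd = 2
        assert st.glass_delta([3.0, 5.0], y) == pytest.approx((4 - 2) / 2)


class TestGroupTests:
    def test_identical_samples_mwu_p_one_delta_zero(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        r = st.two_group_test(x, list(x), auto=False, test="mannwhitney")
        assert r.p_value == pytest.approx(1.0)
        assert r.effect_size == ("cliffs_delta", 0.0)

    def test_gate_routes_normal_data_to_welch_t(self, rng):
        x = rng.normal(0, 1, 40)
        y = rng.normal(0.3, 1, 40)
        r = st.two_group_test(x, y)
        assert r.assumption_report["fligner_p"] > 0.05
        assert all(p > 0.05 for p in r.assumption_report["shapiro_p"])
        assert r.test_name == "welch_t"
        assert r.effect_size[0] == "hedges_g_unpooled"

    def test_gate_routes_skewed_data_to_mannwhitney(self, rng):
        x = rng.lognormal(0, 1.5, 60)
        y = rng.lognormal(0.5, 1.5, 60)
        r = st.two_group_test(x, y)
        assert r.test_name == "mann_whitney_u"
        assert r.effect_size[0] == "cliffs_delta"

    def test_paired_violation_routes_to_wilcoxon(self, rng):
        x = rng.lognormal(0, 2, 30)
        y = x * rng.lognormal(0.2, 1.5, 30)
        r = st.two_group_test(x, y, paired=True)
        assert r.test_name == "wilcoxon_signed_rank"

    def test_tiny_group_falls_back_with_note(self):
        r = st.two_group_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert r.test_name == "mann_whitney_u"
        assert "nonparametric" in r.note

    def test_multi_group_identical_high_p(self):
        g = [1.0, 2.0, 3.0, 4.0, 5.0]
        r = st.multi_group_test([g, g, g])
        assert r.p_value > 0.9

    def test_fisher_exact_routing_matches_hypergeometric_tail(self):
        table = [[10, 0], [0, 10]]
        r = st.multi_group_test(table, contingency=True)
        _, p_oracle = sps.fisher_exact(np.asarray(table))
        assert r.test_name == "fisher_exact"
        assert r.p_value == pytest.approx(p_oracle)
        # two-sided tail of the hypergeometric: both extreme tables
        from math import comb

        assert r.p_value == pytest.approx(2 / comb(20, 10), rel=1e-9)


class TestAdjustP:
    def test_single_p_unchanged(self):
        assert st.adjust_p([0.03]).tolist() == [0.03]

    def test_hand_computed_step_up(self):
        out = st.adjust_p([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_order_preserved_and_bounded(self, rng):
        for _ in range(20):
            p = rng.random(rng.integers(1, 30))
            q = st.adjust_p(p)
            assert np.all(q >= p) and np.all(q <= 1)
            assert np.all(np.argsort(q, kind="stable")[np.argsort(np.argsort(p))] >= 0)
            # raw order implies adjusted order
            i, j = np.argsort(p)[:2] if len(p) > 1 else (0, 0)
            assert q[i] <= q[j] + 1e-15

    def test_matches_statsmodels_reference(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(25)
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(st.adjust_p(p), q_ref, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            st.adjust_p([0.5, 1.5])

    @settings(derandomize=True, deadline=None, max_examples=60)
    @given(hst.lists(hst.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_property_adjusted_dominates_raw_and_capped(self, p):
        q = st.adjust_p(p)
        assert np.all(q >= np.asarray(p)) and np.all(q <= 1.0)


@settings(derandomize=True, deadline=None, max_examples=60)
@given(
    hst.lists(hst.integers(min_value=-50, max_value=50), min_size=1, max_size=25),
    hst.lists(hst.integers(min_value=-50, max_value=50), min_size=1, max_size=25),
)
def test_property_cliffs_delta_bounded_and_antisymmetric(xs, ys):
    d = st.cliffs_delta(xs, ys)
    assert -1.0 <= d <= 1.0
    assert st.cliffs_delta(ys, xs) == pytest.approx(-d, abs=1e-12)


class TestGLM:
    def test_intercept_only_logistic_balanced(self):
        tab = pd.DataFrame({"y": [0] * 5 + [1] * 5})
        fit = st.fit_glm(tab, "y", [], family="logistic")
        assert fit.params["const"] == pytest.approx(0.0, abs=1e-8)
        assert fit.pseudo_r2["nagelkerke"] == pytest.approx(0.0, abs=1e-10)
        assert fit.pseudo_r2["cox_snell"] == pytest.approx(0.0, abs=1e-10)

    def test_noiseless_linear_recovers_beta_exactly(self):
        from clonepipe.synth import make_regression_table

        tab, gt = make_regression_table([2.0, -1.5, 0.5], "linear", 200, seed=5, noise_sigma=0.0)
        fit = st.fit_glm(tab, "y", ["x1", "x2"], family="linear")
        np.testing.assert_allclose(fit.params.to_numpy(), [2.0, -1.5, 0.5], atol=1e-10)

    def test_logistic_recovery_within_wald_ci(self):
        from clonepipe.synth import make_regression_table

        tab, _ = make_regression_table([-4.0, 0.8], "logistic", 5000, seed=11)
        fit = st.fit_glm(tab, "y", ["x1"], family="logistic")
        lo, hi = fit.conf_int.loc["x1"]
        assert lo < 0.8 < hi
        assert fit.odds_ratios["x1"] == pytest.approx(np.exp(fit.params["x1"]))

    def test_poisson_and_negative_binomial(self):
        from clonepipe.synth import make_regression_table

        tab, _ = make_regression_table([np.log(5.0)], "poisson", 2000, seed=3)
        fit = st.fit_glm(tab, "y", [], family="poisson")
        assert fit.params["const"] == pytest.approx(np.log(tab.y.mean()))
        tab, _ = make_regression_table([1.0, 0.3], "negative_binomial", 2000, seed=4, nb_dispersion=2.0)
        assert tab.y.var() / tab.y.mean() > 1  # overdispersed by construction
        fit = st.fit_glm(tab, "y", ["x1"], family="negative_binomial")
        assert fit.nb_alpha is not None and fit.nb_alpha > 0.5
        assert abs(fit.params["x1"] - 0.3) < 0.15

    def test_binomial_counts_equal_expanded_binary(self):
        rng = np.random.default_rng(8)
        discs = pd.DataFrame(
            {
                "x1": rng.normal(size=12),
                "x2": rng.normal(size=12),
                "dead": rng.integers(1, 15, 12),
                "alive": rng.integers(20, 80, 12),
            }
        )
        fit_counts = st.fit_glm(discs, ("dead", "alive"), ["x1", "x2"], family="logistic")
        rows = []
        for _, r in discs.iterrows():
            rows += [{"x1": r.x1, "x2": r.x2, "y": 1}] * int(r.dead)
            rows += [{"x1": r.x1, "x2": r.x2, "y": 0}] * int(r.alive)
        fit_binary = st.fit_glm(pd.DataFrame(rows), "y", ["x1", "x2"], family="logistic")
        np.testing.assert_allclose(
            fit_counts.params.to_numpy(), fit_binary.params.to_numpy(), atol=1e-8
        )

    def test_pseudo_r2_closed_form_perfect_fit(self):
        n = 10
        r2 = st.pseudo_r2(llf=0.0, llnull=n * np.log(0.5), n=n)
        assert r2["nagelkerke"] == pytest.approx(1.0)
        assert r2["cox_snell"] == pytest.approx(0.75)
        assert r2["mcfadden"] == pytest.approx(1.0)

    def test_pseudo_r2_ordering(self, rng):
        from clonepipe.synth import make_regression_table

        tab, _ = make_regression_table([-1.0, 1.0], "logistic", 500, seed=2)
        fit = st.fit_glm(tab, "y", ["x1"], family="logistic")
        r2 = fit.pseudo_r2
        assert 0 <= r2["cox_snell"] <= r2["nagelkerke"] <= 1

    def test_perfect_separation_is_flagged(self):
        tab = pd.DataFrame({"x1": np.r_[np.zeros(10), np.ones(10)], "y": np.r_[np.zeros(10), np.ones(10)]})
        fit = st.fit_glm(tab, "y", ["x1"], family="logistic")
        assert fit.separation_flag

    def test_rank_deficient_design_names_column(self):
        rng = np.random.default_rng(1)
        tab = pd.DataFrame({"x1": rng.normal(size=30)})
        tab["x2"] = 2 * tab.x1
        tab["y"] = rng.normal(size=30)
        with pytest.raises(ValueError, match="x"):
            st.fit_glm(tab, "y", ["x1", "x2"], family="linear")

    def test_too_few_observations_rejected(self):
        rng = np.random.default_rng(0)
        tab = pd.DataFrame({"x1": rng.normal(size=15), "x2": rng.normal(size=15)})
        tab["y"] = rng.normal(size=15)
        with pytest.raises(ValueError, match="observations"):
            st.fit_glm(tab, "y", ["x1", "x2"], family="linear")


class TestDiagnostics:
    def test_orthogonal_predictors_have_unit_vif(self):
        n = 64
        tab = pd.DataFrame({"x1": np.tile([1.0, -1.0], n // 2), "x2": np.repeat([1.0, -1.0], n // 2)})
        vif = st.variance_inflation(tab, ["x1", "x2"])
        np.testing.assert_allclose(vif.to_numpy(), [1.0, 1.0], atol=1e-12)

    def test_correlated_predictors_match_auxiliary_regression_oracle(self, rng):
        from statsmodels.stats.outliers_influence import variance_inflation_factor
        import statsmodels.api as sm

        x1 = rng.normal(size=500)
        x2 = 0.8 * x1 + np.sqrt(1 - 0.64) * rng.normal(size=500)
        tab = pd.DataFrame({"x1": x1, "x2": x2})
        vif = st.variance_inflation(tab, ["x1", "x2"])
        X = sm.add_constant(tab[["x1", "x2"]]).to_numpy()
        for j, name in enumerate(["x1", "x2"], start=1):
            assert vif[name] == pytest.approx(variance_inflation_factor(X, j), rel=1e-9)
        # population value 1/(1-0.64) = 2.777...; wide tolerance for sampling
        assert vif["x1"] == pytest.approx(1 / (1 - 0.64), rel=0.2)

    def test_exact_collinearity_reports_inf(self):
        tab = pd.DataFrame({"x1": np.arange(30.0)})
        tab["x2"] = 3 * tab.x1 + 1
        vif = st.variance_inflation(tab, ["x1", "x2"])
        assert np.isinf(vif).all()

    def test_durbin_watson_near_two_for_independent_residuals(self):
        rng = np.random.default_rng(1)
        tab = pd.DataFrame({"x1": rng.normal(size=2000), "x2": rng.normal(size=2000)})
        tab["y"] = tab.x1 + rng.normal(size=2000)
        fit = st.fit_glm(tab, "y", ["x1", "x2"], family="linear")
        rep = st.diagnostics(fit, tab)
        assert abs(rep["durbin_watson"] - 2.0) < 0.15
        assert rep["high_vif"] == []
        assert 0 <= rep["ncv_p"] <= 1

    def test_ncv_flags_heteroscedastic_residuals(self, rng):
        x = rng.uniform(1, 10, 1500)
        y = 2 * x + rng.normal(0, x, 1500)  # variance grows with x
        tab = pd.DataFrame({"x1": x, "x2": rng.normal(size=1500), "y": y})
        fit = st.fit_glm(tab, "y", ["x1", "x2"], family="linear")
        rep = st.diagnostics(fit, tab)
        assert rep["ncv_p"] < 0.01


class TestModelSelection:
    def test_single_candidate_returned(self, rng):
        tab = pd.DataFrame({"x1": rng.normal(size=100)})
        tab["y"] = 1 + 2 * tab.x1 + rng.normal(size=100)
        best = st.select_model_aic([["x1"]], tab, "y", family="linear")
        assert best.predictors == ["x1"]

    def test_true_covariate_beats_null_on_signal(self, rng):
        tab = pd.DataFrame({"x1": rng.normal(size=400)})
        tab["y"] = 1 + 2 * tab.x1 + rng.normal(size=400)
        best = st.select_model_aic([[], ["x1"]], tab, "y", family="linear")
        assert best.predictors == ["x1"]

    def test_noise_covariate_usually_loses(self):
        wins = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            tab = pd.DataFrame({"x1": r.normal(size=300), "noise": r.normal(size=300)})
            tab["y"] = 1 + 2 * tab.x1 + r.normal(size=300)
            best = st.select_model_aic([["x1"], ["x1", "noise"]], tab, "y", family="linear")
            wins += best.predictors == ["x1"]
        assert wins >= 14  # AIC keeps pure noise out in a clear majority of runs

    def test_collinear_candidate_screened_out(self, rng):
        tab = pd.DataFrame({"x1": rng.normal(size=200)})
        tab["x2"] = tab.x1 * 0.999 + rng.normal(0, 0.01, 200)
        tab["y"] = tab.x1 + rng.normal(size=200)
        best = st.select_model_aic([["x1"], ["x1", "x2"]], tab, "y", family="linear")
        assert best.predictors == ["x1"]


class TestProfilesAndMisc:
    def test_profile_at_mean_equals_all_means_prediction(self, rng):
        from clonepipe.synth import make_regression_table

        tab, _ = make_regression_table([-1.0, -0.5, 0.7], "logistic", 800, seed=6)
        fit = st.fit_glm(tab, "y", ["x1", "x2"], family="logistic")
        mu = tab[["x1", "x2"]].mean()
        prof = st.effects_profile(fit, "x1", grid=[mu["x1"]])
        eta = fit.params["const"] + fit.params["x1"] * mu["x1"] + fit.params["x2"] * mu["x2"]
        assert prof.response.iloc[0] == pytest.approx(1 / (1 + np.exp(-eta)))
        assert prof.lower.iloc[0] < prof.response.iloc[0] < prof.upper.iloc[0]

    def test_negative_slope_gives_decreasing_profile(self, rng):
        from clonepipe.synth import make_regression_table

        tab, _ = make_regression_table([-1.0, -0.5], "logistic", 800, seed=6)
        fit = st.fit_glm(tab, "y", ["x1"], family="logistic")
        assert fit.params["x1"] < 0
        prof = st.effects_profile(fit, "x1", grid=np.linspace(-2, 2, 25))
        assert np.all(np.diff(prof.response.to_numpy()) < 0)

    def test_extrapolation_flagged(self, rng):
        from clonepipe.synth import make_regression_table

        tab, _ = make_regression_table([0.0, 1.0], "linear", 100, seed=1)
        fit = st.fit_glm(tab, "y", ["x1"], family="linear")
        prof = st.effects_profile(fit, "x1", grid=[0.0, 99.0], observed_range=(-3, 3))
        assert prof.extrapolated.tolist() == [False, True]

    def test_transforms(self):
        np.testing.assert_allclose(st.transform([np.e], "log"), [1.0])
        np.testing.assert_allclose(st.transform([4.0], "sqrt"), [2.0])
        z = st.transform([1.0, 2.0, 3.0], "zscore")
        np.testing.assert_allclose(st.transform(z, "zscore"), z, atol=1e-12)
        with pytest.raises(ValueError, match="rows"):
            st.transform([1.0, -2.0], "log")

    def test_correlations(self, rng):
        x = rng.normal(size=50)
        for m in ("pearson", "spearman", "kendall"):
            r, _ = st.correlate(x, x, m)
            assert r == pytest.approx(1.0)
            r, _ = st.correlate(x, -x, m)
            assert r == pytest.approx(-1.0)
        x = rng.normal(size=10_000)
        y = rng.normal(size=10_000)
        r, p = st.correlate(x, y, "pearson")
        assert abs(r) < 0.1
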