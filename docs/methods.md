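# Methods

This note documents the models, conventions and numerical choices behind
clonepipe, and what its synthetic validation does and does not demonstrate.

## Image model and coordinates

A stack is a `(z, y, x, channel)` array with square lateral pixels
(`xy` µm/px) and an independent axial step (`z` µm/plane); typical inputs
are 8-bit confocal acquisitions at 512×512 or 1024×1024 per plane with 1 µm
Z-steps. Voxel indices are 0-based; physical coordinates are voxel-centre
positions, `x = column·xy`, `z = plane·z`. Integer images are promoted to
float for measurement; raw intensities are never rescaled.

Channel *roles* (`genotype_*`, `nuclear`, `foci`, `aux_*`) decouple biology
from channel order. On-disk axis order is read from TIFF metadata and can
be overridden with an explicit axes string; bare arrays fall back to the
ImageJ hyperstack convention.

## Per-plane segmentation

* **Genotype markers** — Gaussian smoothing (σ in px, default 1) →
  Otsu or fixed threshold → morphological closing → hole filling. Masks
  for multiple genotypes are made pairwise disjoint by clipping later
  classes against earlier ones (sorted role order). A constant plane under
  auto-threshold yields an empty mask with a warning, not an error, so
  batches survive blank planes at stack ends. Any learned classifier can
  replace the built-in method through the `PixelClassifier` contract (a
  callable from one full plane to an integer class mask).
* **Nuclei** — smooth → threshold → marker-controlled watershed on the
  Euclidean distance transform. One marker per distance-maximum plateau;
  plateaus closer than `peak_min_distance` px merge. A component whose
  maximum is suppressed by a taller neighbour inside the peak footprint is
  rescued as its own label rather than dropped. Labels are area-filtered to
  `[min_nuc_px, max_nuc_px]`.
* **Foci** — an alternating intensity/size filter: thresholds ascend
  (quantiles of the plane or absolute values); each pass keeps, from within
  the previous pass's survivors, the 8-connected components of the
  thresholded image with area in `[min_size_px, max_size_px]`. Defaults:
  two passes at quantiles (0.95, 0.99), sizes 4–400 px. The pass count,
  thresholds and bounds are declared package conventions, exposed in
  config; the procedure is idempotent on its own output and monotone in
  `min_size_px`.

In-plane connectivity is 8-connected throughout (4-connected available in
the code paths that take a structure element).

## 3D assembly

Two linking mechanisms, matched to object geometry:

* **Patches** (large, irregular): 2D components on adjacent planes are
  joined when their pixel overlap is ≥ `min_overlap_px` (default 1;
  an overlap *fraction* of the smaller component is also available). A
  patch is a connected component of the resulting component-adjacency
  graph, so a clone that splits into two children or two clones that merge
  remain one object. This equals 3D connected components under "8-connected
  in-plane + face-adjacent in Z", which is how the brute-force oracle
  verifies it. Patch ids are assigned in descending volume order with
  deterministic tie-breaks.
* **Cells and foci** (compact): greedy nearest-centroid matching between
  adjacent planes within `max_drift_um` (default 2 µm), candidate pairs
  taken in ascending distance with label-id tie-breaks, no endpoint claimed
  twice. Greedy rather than globally optimal assignment: deterministic,
  O(n log n), and at wing-disc nuclear densities contention between
  candidates is rare. Foci are first split per plane by watershed on the
  distance transform with h-maxima markers (dynamic depth `h`, default
  1 px), then chained with the same rule.

**Border/centre partition.** Within each patch, per plane, the Euclidean
distance transform against the patch complement defines centre = distance
> `width_um`, border = remainder; default width 8 µm, the conventional
"two cell diameters" lateral neighbourhood in a columnar epithelium. The
partition is deliberately 2D — the border relation is lateral, and axial
anisotropy would distort a 3D shell. Note the two distance conventions in
the package: the *partition* measures distance to the nearest non-patch
pixel (an interior pixel adjacent to background is at distance 1), while
the per-cell `dist_border_um` measures distance to the nearest pixel of
the patch's own boundary shell (a boundary pixel is at distance 0). Each
matches the natural reading of its use; they differ by about one pixel.

**Cell annotation.** A cell's genotype is the genotype mask containing a
majority (≥ 50%) of its nuclear voxels; cells with no majority inside the
analysis territory are assigned the implicit unmarked "winner" class, and
cells outside it are "none" and excluded from patch statistics. Region
(border/centre) is sampled at the cell's centroid voxel.

**Apoptosis calls.** Every 3D focus is assigned to exactly one cell —
the cell whose nucleus contains the focus centroid, else the nearest cell
centroid (ties to the smaller id). A cell is apoptotic iff an assigned
focus centroid lies in its nucleus or its assigned foci overlap ≥
`overlap_frac` (default 0.3) of its nuclear voxels. Single assignment
guarantees one focus cannot flag two cells. The 0.3 default is a package
convention: large enough to ignore incidental spillover from a
neighbouring dying cell, small enough that a focus covering a third of a
nucleus counts.

**Analysis territory ("pouch").** A user ROI mask when supplied; otherwise
a tissue mask from the nuclear channel (heavy smoothing → threshold → hole
filling → largest 3D component). "Death density" is emitted in all three
senses used in this field — area coverage of the reporter, focus count per
µm³, and percent apoptotic cells — since different figures of merit use
different ones.

## Statistics layer

Univariate comparisons are gated: Shapiro–Wilk per group and
Fligner–Killeen across groups, both at α = 0.05; all pass → two-sided
Welch *t* with Hedges' g; any failure → Mann–Whitney U (Wilcoxon
signed-rank if paired) with Cliff's δ. Welch rather than Student is the
default because variance homogeneity is already a separate gate and Welch
is the safer parametric choice; groups too small for Shapiro–Wilk fall to
the nonparametric branch with a note. "Unpooled" Cohen's d is
(x̄−ȳ)/√((s²ₓ+s²ᵧ)/2) with sample variances; Hedges' g applies the
small-sample factor 1 − 3/(4n−9); Glass's Δ is available behind a flag.
Cliff's δ is computed through the Mann–Whitney U identity with midranks
(ties handled exactly); an O(n²) enumeration oracle checks it in the
tests. FDR adjustment is Benjamini–Hochberg step-up, clamped so adjusted ≥
raw holds exactly in floating point.

Regression families: linear (OLS), logistic (binary 0/1 or
(success, failure) counts — the two parameterizations give identical
coefficients, an identity the tests assert to 1e-8), Poisson, and
negative binomial with ML-estimated dispersion. Fits are maximum
likelihood via iteratively reweighted least squares (statsmodels is the
fit engine); inference is Wald. Pseudo-R²: Cox–Snell
1 − exp(2(LL₀−LL)/n), Nagelkerke (Cox–Snell rescaled by its maximum),
McFadden 1 − LL/LL₀; for a counts response, n is the number of trials,
not rows. AIC is 2k − 2LL with k counting the error variance (linear) and
dispersion (NB). Diagnostics: VIF from auxiliary regressions (flagged at
≥ 5, the conventional collinearity screen), Durbin–Watson on row-ordered
residuals (callers doing spatial/temporal diagnostics must sort first),
and a non-constant-variance score test (squared normalized residuals
regressed on fitted values, χ²₁) for the linear family. Model selection
fits each candidate predictor set passing the VIF screen and keeps the
lowest AIC, ties to fewer parameters. Effects profiles hold all other
predictors at their sample means and propagate a 95% delta-method band
through the link; grid points outside the observed range are flagged as
extrapolation. Perfect separation in logistic fits is flagged, never
silently returned.

## Synthetic data

**Semi-synthetic stacks** draw planes at random (seeded) from a library of
analytically specified layouts — crisp rectangles (clone marker), disks on
a coarse grid (nuclei, spacing ≥ 24 px so Z-links are unambiguous), small
disks (foci) — with no blur or noise. Ground truth (patch count and volume,
border/centre areas per 3D component, cell and focus counts via the same
declared adjacency/tracking rules, coverage fractions) is computed from the
analytic masks by the generator's own small implementations (BFS union-find
over the voxel graph, greedy point matching), never by the pipeline under
test. Because the images are exactly segmentable with fixed thresholds and
no smoothing, any measurement error is a bookkeeping defect; the validation
asserts counts exactly and continuous quantities within 1%.

**Wing-disc phantoms** render an elliptical tissue (semi-axes 240×210 µm at
1 µm/px, 10 planes), ~110 small loser patches (radius 6–16 µm; real loser
clones are thin and irregular, so most loser cells sit within two cell
diameters of a border) plus 6 large ones (28–40 µm) contributing deep
centre territory, and ~6300 grid-packed nuclei (radius 1.4 µm, spacing
5 µm, each spanning 3–5 planes with sub-pixel centroid jitter so tracking
is genuinely exercised). Each loser nucleus is apoptotic with
P = logistic(β₀ + β₁·d), d its true in-plane distance to the patch
border, defaults β₀ = −4.5, β₁ = −0.25 µm⁻¹; winners die at a constant
baseline of 0.3%. These defaults place ~2000 loser cells per disc and a
low-percent apoptotic fraction, the regime of the assays this pipeline
targets; they are fixture choices, not measured biology. One two-plane
focus is rendered per apoptotic nucleus; planes get Gaussian blur
(σ 0.6 px) and read noise (σ 3 intensity units) over a background of 8.
The phantom deliberately omits real-image difficulties: no depth-dependent
attenuation, no full 3D PSF, no intensity inhomogeneity, no segmentation-
confusing debris. Passing phantom tests therefore demonstrates correct
geometry, linking, calling and regression plumbing under mild noise — not
robustness to difficult real acquisitions, where thresholds and the
classifier seam are the tuning points.

**Regression tables** draw covariates i.i.d. standard normal and responses
from the stated family (NB via a gamma–Poisson mixture, variance
μ + α·μ²); truth records β and the seed. Every generator is a pure
function of (spec, seed).

## Determinism and problem sizes

Same inputs + config + seed ⇒ byte-identical CSVs: tables are sorted by
image id, floats serialized at round-trip precision, label ids and colours
derived deterministically (colour = hash of label id). The validation
suite uses 5 semi-synthetic stacks, 100 random 32×32×16 volumes for the
topology oracle, 1000 random sample pairs for the effect-size oracle, 100
simulated datasets (n = 5000) for Wald-CI coverage, and 10 phantoms for
the end-to-end border-death reproduction; these sizes give stable
pass/fail behaviour at desk scale while keeping a full run in minutes.

## Known limitations

* Z-linking only; no time-lapse tracking.
* Centroid tracking is greedy; pathological nuclear densities (spacing
  comparable to drift) could mis-chain — the global-assignment alternative
  was rejected as unnecessary at the densities this targets.
* The border/centre partition and border distances are 2D in-plane by
  design; strongly non-columnar tissues would need a 3D notion.
* The built-in segmentation is threshold-based; images that need learned
  classification should attach a classifier through the plug-in contract.
* Pseudo-R² definitions for counts responses follow the trials convention
  above; other software may report row-based values.
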