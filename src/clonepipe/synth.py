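"""Synthetic stacks with exhaustive ground truth.

Three generators make every other module testable without any downloaded
data:

* :func:`make_semisynthetic_stack` — noise-free stacks assembled by randomly
  drawing planes from a library of analytically specified plane layouts
  (crisp rectangles/disks).  Ground truth for all 3D quantities is computed
  from the analytic masks by this module's own small implementations of the
  declared adjacency rules (voxel union-find, greedy centroid matching),
  never by calling the pipeline under test.
* :func:`make_disc_phantom` — a wing-disc-like phantom: elliptical tissue,
  marked loser patches, packed nuclei spanning several planes, and one
  death focus per apoptotic nucleus, where each loser nucleus dies with
  probability ``logistic(β₀ + β₁ · distance_to_patch_border_um)``.  Blur and
  read noise make this the robustness testbed.
* :func:`make_regression_table` — tabular datasets with known coefficients
  for the four regression families.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .io import ImageStack

__all__ = [
    "Shape",
    "PlaneSpec",
    "GroundTruth",
    "PhantomSpec",
    "default_plane_library",
    "make_semisynthetic_stack",
    "make_disc_phantom",
    "make_regression_table",
    "semisynthetic_config",
    "phantom_config",
]


# ---------------------------------------------------------------------------
# analytic plane specs

@dataclass(frozen=True)
class Shape:
    """One analytic shape on one channel: an axis-aligned ``rect`` (y0, x0,
    h, w) or a ``disk`` (cy, cx, r), drawn at a given intensity."""

    channel: str            # role name: genotype_*, nuclear, foci
    kind: str               # rect | disk
    params: tuple
    intensity: int = 200

    def render(self, out: np.ndarray) -> None:
        if self.kind == "rect":
            y0, x0, h, w = self.params
            out[y0 : y0 + h, x0 : x0 + w] = self.intensity
        elif self.kind == "disk":
            cy, cx, r = self.params
            yy, xx = np.ogrid[: out.shape[0], : out.shape[1]]
            out[(yy - cy) ** 2 + (xx - cx) ** 2 <= r * r] = self.intensity
        else:
            raise ValueError(f"unknown shape kind {self.kind!r}")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=np.uint8)
        self.render(out)
        return out > 0

    def centre(self) -> tuple[float, float]:
        if self.kind == "disk":
            return float(self.params[0]), float(self.params[1])
        y0, x0, h, w = self.params
        return y0 + (h - 1) / 2.0, x0 + (w - 1) / 2.0


@dataclass(frozen=True)
class PlaneSpec:
    """A full analytic layout of one plane."""

    shapes: tuple[Shape, ...]
    plane_shape: tuple[int, int] = (128, 128)

    def channel_mask(self, role: str) -> np.ndarray:
        out = np.zeros(self.plane_shape, dtype=bool)
        for s in self.shapes:
            if s.channel == role:
                out |= s.mask(self.plane_shape)
        return out

    def centroids(self, role: str) -> list[tuple[float, float]]:
        return [s.centre() for s in self.shapes if s.channel == role]


@dataclass
class GroundTruth:
    """Known quantities of a generated stack (analytic, pipeline-free)."""

    seed: int
    n_patches: int = 0
    patch_volume_um3: float = 0.0
    border_area_um2: float = 0.0
    centre_area_um2: float = 0.0
    n_cells: int = 0
    n_foci: int = 0
    foci_coverage: float = 0.0
    border_width_um: float = 8.0
    masks: dict = field(default_factory=dict)           # role -> (z, y, x) bool
    cell_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    beta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "seed": self.seed,
                    "n_patches": self.n_patches,
                    "patch_volume_um3": self.patch_volume_um3,
                    "border_area_um2": self.border_area_um2,
                    "centre_area_um2": self.centre_area_um2,
                    "n_cells": self.n_cells,
                    "n_foci": self.n_foci,
                    "foci_coverage": self.foci_coverage,
                    "border_width_um": self.border_width_um,
                }
            ]
        )


# --- independent truth machinery (not the pipeline's code) -----------------

def label_3d_components(masks: np.ndarray) -> tuple[np.ndarray, int]:
    """Brute-force labeling: 8-connected in-plane + face-adjacent in Z.

    Plain BFS over the voxel graph; this is the oracle the patch linker is
    checked against (the adjacency equals per-plane 8-connected components
    joined by any vertical pixel overlap).
    """
    masks = np.asarray(masks, dtype=bool)
    labels = np.zeros(masks.shape, dtype=np.int32)
    nz, ny, nx = masks.shape
    count = 0
    nbrs = [(0, dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
    nbrs += [(1, 0, 0), (-1, 0, 0)]
    stack = []
    for z in range(nz):
        rs, cs = np.nonzero(masks[z])
        for r, c in zip(rs, cs):
            if labels[z, r, c]:
                continue
            count += 1
            stack.append((z, r, c))
            labels[z, r, c] = count
            while stack:
                zz, rr, cc = stack.pop()
                for dz, dy, dx in nbrs:
                    z2, r2, c2 = zz + dz, rr + dy, cc + dx
                    if 0 <= z2 < nz and 0 <= r2 < ny and 0 <= c2 < nx:
                        if masks[z2, r2, c2] and not labels[z2, r2, c2]:
                            labels[z2, r2, c2] = count
                            stack.append((z2, r2, c2))
    return labels, count


def count_3d_components(masks: np.ndarray) -> int:
    return label_3d_components(masks)[1]


def _truth_chain_count(
    per_plane_points: list[list[tuple[float, float]]],
    max_drift_px: float,
) -> int:
    """Count 3D objects under greedy nearest-centroid Z-linking of points."""
    n_chains = 0
    open_chains: list[tuple[float, float]] = []
    for pts in per_plane_points:
        pts = list(pts)
        # candidate links (distance, open_idx, new_idx), greedy ascending
        cands = []
        for i, p in enumerate(open_chains):
            for j, q in enumerate(pts):
                d = float(np.hypot(p[0] - q[0], p[1] - q[1]))
                if d <= max_drift_px:
                    cands.append((d, i, j))
        cands.sort()
        used_open, used_new = set(), set()
        nxt: dict[int, int] = {}
        for d, i, j in cands:
            if i in used_open or j in used_new:
                continue
            used_open.add(i)
            used_new.add(j)
            nxt[i] = j
        n_chains += len(pts) - len(used_new)  # unmatched points start new chains
        open_chains = [pts[j] for j in range(len(pts))]
    return n_chains


def _border_centre_truth(mask2d: np.ndarray, width_px: float) -> tuple[int, int]:
    """Per-plane border/centre pixel counts: centre = EDT-to-complement > width."""
    if not mask2d.any():
        return 0, 0
    dist = ndi.distance_transform_edt(mask2d)
    centre = int((dist > width_px).sum())
    return int(mask2d.sum()) - centre, centre


# ---------------------------------------------------------------------------
# semi-synthetic stacks

def default_plane_library(
    rng: np.random.Generator,
    n_specs: int = 4,
    plane_shape: tuple[int, int] = (128, 128),
) -> list[PlaneSpec]:
    """A seeded library of analytically-known plane layouts.

    Each spec holds 1–2 rectangular loser patches, several well-separated
    nuclei (disks on a coarse position grid, so cross-spec Z-links are
    either exact-position matches or clearly out of tracking range) and a
    few foci, some inside patches.
    """
    ny, nx = plane_shape
    specs = []
    for _ in range(n_specs):
        shapes: list[Shape] = []
        # patches: rectangles away from the image edge
        for _ in range(int(rng.integers(1, 3))):
            h, w = int(rng.integers(24, 44)), int(rng.integers(24, 44))
            y0 = int(rng.integers(6, ny - h - 6))
            x0 = int(rng.integers(6, nx - w - 6))
            shapes.append(Shape("genotype_1", "rect", (y0, x0, h, w), 180))
        # nuclei on a coarse grid with ≥ 24 px spacing
        pts = []
        for gy in range(16, ny - 16, 24):
            for gx in range(16, nx - 16, 24):
                if rng.random() < 0.5:
                    pts.append((gy, gx))
        for cy, cx in pts:
            shapes.append(Shape("nuclear", "disk", (cy, cx, 5), 200))
        # foci: half sit on nuclei (apoptotic cells), half elsewhere
        for k, (cy, cx) in enumerate(pts):
            if k % 3 == 0:
                shapes.append(Shape("foci", "disk", (cy, cx, 2), 230))
        specs.append(PlaneSpec(tuple(shapes), plane_shape))
    return specs


def make_semisynthetic_stack(
    plane_library: Sequence[PlaneSpec],
    n_planes: int,
    seed: int,
    voxel_size: tuple[float, float] = (1.0, 1.0),
    border_width_um: float = 8.0,
    max_drift_um: float = 2.0,
) -> tuple[ImageStack, GroundTruth]:
    """Randomly stack library planes; return the stack and its ground truth.

    The image is noise-free 8-bit with crisp shapes, so any disagreement
    between pipeline output and truth is a bookkeeping error, not an imaging
    ambiguity.
    """
    if not plane_library:
        raise ValueError("plane library is empty")
    rng = np.random.default_rng(seed)
    picks = [plane_library[int(i)] for i in rng.integers(0, len(plane_library), n_planes)]
    ny, nx = picks[0].plane_shape
    roles = ("genotype_1", "nuclear", "foci")
    vox = np.zeros((n_planes, ny, nx, 3), dtype=np.uint8)
    truth_masks = {r: np.zeros((n_planes, ny, nx), dtype=bool) for r in roles}
    for z, spec in enumerate(picks):
        if spec.plane_shape != (ny, nx):
            raise ValueError("all plane specs must share one plane shape")
        for ci, r in enumerate(roles):
            for s in spec.shapes:
                if s.channel == r:
                    s.render(vox[z, :, :, ci])
            truth_masks[r][z] = spec.channel_mask(r)

    xy, zstep = voxel_size
    gt = GroundTruth(seed=seed, border_width_um=border_width_um, masks=truth_masks)
    patch = truth_masks["genotype_1"]
    comp_labels, n_comp = label_3d_components(patch)
    gt.n_patches = n_comp
    gt.patch_volume_um3 = float(patch.sum()) * xy * xy * zstep
    # border/centre partitioned per 3D component, matching the declared
    # per-patch in-plane distance rule
    b_tot = c_tot = 0
    for comp in range(1, n_comp + 1):
        cmask = comp_labels == comp
        for z in range(n_planes):
            if cmask[z].any():
                b, c = _border_centre_truth(cmask[z], border_width_um / xy)
                b_tot += b
                c_tot += c
    gt.border_area_um2 = b_tot * xy * xy
    gt.centre_area_um2 = c_tot * xy * xy
    gt.n_cells = _truth_chain_count(
        [p.centroids("nuclear") for p in picks], max_drift_um / xy
    )
    gt.n_foci = _truth_chain_count(
        [p.centroids("foci") for p in picks], max_drift_um / xy
    )
    n_patch = int(patch.sum())
    gt.foci_coverage = (
        float((patch & truth_masks["foci"]).sum()) / n_patch if n_patch else 0.0
    )
    stack = ImageStack(
        voxels=vox,
        voxel_size=voxel_size,
        channel_roles={"genotype_1": 0, "nuclear": 1, "foci": 2},
        image_id=f"semisynthetic_{seed}",
    )
    return stack, gt


def semisynthetic_config(**overrides):
    """RunConfig tuned to the crisp, noise-free semi-synthetic images."""
    from .pipeline import RunConfig

    base = dict(
        channel_roles={"genotype_1": 0, "nuclear": 1, "foci": 2},
        voxel_size=(1.0, 1.0),
        genotype_smooth_sigma=0.0,
        genotype_threshold=100.0,
        genotype_closing_radius=0,
        nuclear_smooth_sigma=0.0,
        nuclear_threshold=100.0,
        min_nuc_px=6,
        peak_min_distance=5,
        foci_thresholds=(100.0,),
        foci_quantile=False,
        foci_min_size_px=1,
        foci_max_size_px=400,
        border_width_um=8.0,
        max_drift_um=2.0,
        foci_max_drift_um=2.0,
    )
    base.update(overrides)
    return RunConfig(**base)


# ---------------------------------------------------------------------------
# wing-disc phantoms

@dataclass
class PhantomSpec:
    """Parameters of the wing-disc phantom.

    Defaults emulate one competing disc imaged at low lateral zoom: an
    elliptical pouch holding a few thousand packed nuclei, roughly a
    quarter of its area covered by many small, partly merging loser patches
    (real loser clones are thin and irregular, so most loser cells sit
    within a couple of cell diameters of a border), and a border-death
    logistic model with β₀ = −4.5, β₁ = −0.25 µm⁻¹ on the distance (µm) of
    each loser nucleus from its patch border.  Winner cells die at a low
    constant baseline rate.
    """

    plane_shape: tuple[int, int] = (512, 512)
    n_planes: int = 10
    voxel_size: tuple[float, float] = (1.0, 1.0)
    tissue_axes_um: tuple[float, float] = (240.0, 210.0)   # ellipse semi-axes (x, y)
    n_patches: int = 110
    patch_radius_um: tuple[float, float] = (6.0, 16.0)     # uniform radius range
    n_large_patches: int = 6                               # deep-interior clones
    large_patch_radius_um: tuple[float, float] = (28.0, 40.0)
    nuclear_radius_um: float = 1.4
    nuclear_spacing_um: float = 5.0
    nuclear_z_span: tuple[int, int] = (3, 5)
    beta0: float = -4.5
    beta_border_dist: float = -0.25       # µm⁻¹
    winner_death_p: float = 0.003         # baseline epithelial apoptosis rate
    background_level: float = 8.0
    read_noise_sigma: float = 3.0
    blur_sigma_px: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.nuclear_radius_um, self.nuclear_spacing_um, *self.tissue_axes_um) <= 0:
            raise ValueError("physical phantom parameters must be positive")


def make_disc_phantom(spec: PhantomSpec) -> tuple[ImageStack, GroundTruth]:
    """Render a competing-disc phantom and its exhaustive truth table.

    Channels: 0 = loser patch marker, 1 = nuclear stain, 2 = death foci.
    Every nucleus, its genotype, its true border distance and its apoptotic
    flag are recorded in ``truth.cell_table``.
    """
    rng = np.random.default_rng(spec.seed)
    ny, nx = spec.plane_shape
    nz = spec.n_planes
    xy, zstep = spec.voxel_size

    cy0, cx0 = (ny - 1) / 2.0, (nx - 1) / 2.0
    ax_px, ay_px = spec.tissue_axes_um[0] / xy, spec.tissue_axes_um[1] / xy
    yy, xx = np.mgrid[:ny, :nx]
    tissue2d = ((xx - cx0) / ax_px) ** 2 + ((yy - cy0) / ay_px) ** 2 <= 1.0

    # loser patches: random disks inside the tissue (may merge); many small
    # ones (border-dominated, as real thin clones are) plus a few large ones
    # contributing deep centre territory
    patch2d = np.zeros((ny, nx), dtype=bool)
    radii = [spec.patch_radius_um] * spec.n_patches
    radii += [spec.large_patch_radius_um] * spec.n_large_patches
    for r_lo, r_hi in radii:
        r = rng.uniform(r_lo, r_hi) / xy
        theta = rng.uniform(0, 2 * np.pi)
        rho = np.sqrt(rng.uniform(0, 1))
        cx = cx0 + rho * np.cos(theta) * (ax_px - r)
        cy = cy0 + rho * np.sin(theta) * (ay_px - r)
        patch2d |= (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
    patch2d &= tissue2d

    # in-plane distance (µm) of patch pixels to the patch complement
    dist2d = ndi.distance_transform_edt(patch2d) * xy

    # nuclei: jittered grid packing inside the tissue
    sp = spec.nuclear_spacing_um / xy
    r_nuc = spec.nuclear_radius_um / xy
    centres = []
    gy = np.arange(sp, ny - sp, sp)
    gx = np.arange(sp, nx - sp, sp)
    for y0 in gy:
        for x0 in gx:
            cyp = y0 + rng.uniform(-1.0, 1.0)
            cxp = x0 + rng.uniform(-1.0, 1.0)
            ri, ci = int(round(cyp)), int(round(cxp))
            if 0 <= ri < ny and 0 <= ci < nx and tissue2d[ri, ci]:
                centres.append((cyp, cxp))
    if not centres:
        raise RuntimeError("nucleus packing failed; lower the packing density")

    z_lo, z_hi = spec.nuclear_z_span
    p_winner = spec.winner_death_p
    records = []
    nuc_stack = np.zeros((nz, ny, nx), dtype=np.uint8)
    foci_stack = np.zeros((nz, ny, nx), dtype=np.uint8)
    for cid, (cyp, cxp) in enumerate(centres, start=1):
        ri, ci = int(round(cyp)), int(round(cxp))
        is_loser = bool(patch2d[ri, ci])
        d_border = float(dist2d[ri, ci]) if is_loser else 0.0
        if is_loser:
            p_die = 1.0 / (1.0 + np.exp(-(spec.beta0 + spec.beta_border_dist * d_border)))
        else:
            p_die = p_winner
        apoptotic = bool(rng.random() < p_die)
        span = int(rng.integers(z_lo, z_hi + 1))
        z_start = int(rng.integers(0, max(nz - span, 0) + 1))
        for z in range(z_start, z_start + span):
            jy = cyp + rng.uniform(-0.5, 0.5)
            jx = cxp + rng.uniform(-0.5, 0.5)
            _draw_disk(nuc_stack[z], jy, jx, r_nuc, 150)
        if apoptotic:
            z_mid = z_start + span // 2
            for z in (z_mid, min(z_mid + 1, nz - 1)):
                _draw_disk(foci_stack[z], cyp, cxp, max(r_nuc * 0.9, 1.2), 230)
        records.append(
            {
                "cell_id": cid,
                "cy_px": cyp,
                "cx_px": cxp,
                "z_start": z_start,
                "z_span": span,
                "genotype": "loser" if is_loser else "winner",
                "dist_border_um": d_border,
                "p_death": p_die,
                "apoptotic": int(apoptotic),
            }
        )

    geno_stack = np.where(patch2d, 120.0, 0.0)[None].repeat(nz, axis=0)
    vox = np.zeros((nz, ny, nx, 3), dtype=np.uint8)
    for z in range(nz):
        for ci_, chan in enumerate((geno_stack[z], nuc_stack[z].astype(float), foci_stack[z].astype(float))):
            img = chan + spec.background_level
            if spec.blur_sigma_px > 0:
                img = ndi.gaussian_filter(img, spec.blur_sigma_px)
            img = img + rng.normal(0, spec.read_noise_sigma, size=img.shape)
            vox[z, :, :, ci_] = np.clip(img, 0, 255).astype(np.uint8)

    cell_table = pd.DataFrame(records)
    truth_masks = {
        "genotype_1": np.repeat(patch2d[None], nz, axis=0),
        "tissue": np.repeat(tissue2d[None], nz, axis=0),
    }
    losers = cell_table[cell_table.genotype == "loser"]
    gt = GroundTruth(
        seed=spec.seed,
        n_patches=count_3d_components(truth_masks["genotype_1"]),
        patch_volume_um3=float(patch2d.sum()) * nz * xy * xy * zstep,
        n_cells=len(cell_table),
        n_foci=int(cell_table.apoptotic.sum()),
        masks=truth_masks,
        cell_table=cell_table,
        beta={"beta0": spec.beta0, "beta_border_dist": spec.beta_border_dist},
    )
    stack = ImageStack(
        voxels=vox,
        voxel_size=spec.voxel_size,
        channel_roles={"genotype_1": 0, "nuclear": 1, "foci": 2},
        image_id=f"phantom_{spec.seed}",
    )
    return stack, gt


def _draw_disk(plane: np.ndarray, cy: float, cx: float, r: float, value: int) -> None:
    y0, y1 = max(int(cy - r) - 1, 0), min(int(cy + r) + 2, plane.shape[0])
    x0, x1 = max(int(cx - r) - 1, 0), min(int(cx + r) + 2, plane.shape[1])
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    sel = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
    sub = plane[y0:y1, x0:x1]
    sub[sel] = np.maximum(sub[sel], value)


def phantom_config(**overrides):
    """RunConfig tuned to the rendered phantom (fixed thresholds, noise-aware)."""
    from .pipeline import RunConfig

    base = dict(
        channel_roles={"genotype_1": 0, "nuclear": 1, "foci": 2},
        voxel_size=(1.0, 1.0),
        genotype_smooth_sigma=1.0,
        genotype_threshold=68.0,  # midpoint of background and marker levels: unbiased edges
        genotype_closing_radius=1,
        genotype_min_size_px=9,
        nuclear_smooth_sigma=0.5,
        nuclear_threshold=75.0,
        min_nuc_px=3,
        max_nuc_px=200,
        peak_min_distance=2,
        foci_thresholds=(60.0, 120.0),
        foci_quantile=False,
        foci_min_size_px=3,
        foci_max_size_px=120,
        border_width_um=8.0,
        max_drift_um=2.0,
        foci_max_drift_um=2.5,
        tissue_smooth_sigma=8.0,
        tissue_threshold=18.0,
    )
    base.update(overrides)
    return RunConfig(**base)


# ---------------------------------------------------------------------------
# regression tables

def make_regression_table(
    beta: Sequence[float],
    family: str,
    n: int,
    seed: int,
    covariate_sd: float = 1.0,
    noise_sigma: float = 1.0,
    nb_dispersion: float = 0.5,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a regression dataset with known coefficients.

    ``beta[0]`` is the intercept; each remaining coefficient gets one
    standard-normal covariate (scaled by ``covariate_sd``) named ``x1..xk``.
    Families: ``linear`` (Gaussian, sd ``noise_sigma``), ``logistic``
    (Bernoulli), ``poisson``, ``negative_binomial`` (gamma–Poisson mixture
    with variance μ + α·μ², α = ``nb_dispersion``).
    """
    if n < 50:
        raise ValueError("n must be at least 50")
    beta = np.asarray(beta, dtype=float)
    rng = np.random.default_rng(seed)
    k = len(beta) - 1
    X = rng.normal(0, covariate_sd, size=(n, k))
    eta = beta[0] + X @ beta[1:] if k else np.full(n, beta[0])
    if family == "linear":
        y = eta + rng.normal(0, noise_sigma, n)
    elif family == "logistic":
        y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    elif family == "poisson":
        y = rng.poisson(np.exp(eta))
    elif family == "negative_binomial":
        mu = np.exp(eta)
        shape = 1.0 / nb_dispersion
        lam = rng.gamma(shape, mu / shape)
        y = rng.poisson(lam)
    else:
        raise ValueError(f"unknown family {family!r}")
    table = pd.DataFrame(X, columns=[f"x{i + 1}" for i in range(k)])
    table["y"] = y
    gt = GroundTruth(seed=seed, beta={"beta": beta.tolist(), "family": family})
    return table, gt
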