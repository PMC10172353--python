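"""Batch orchestration: configuration and deterministic end-to-end runs.

``analyze_stack`` runs one image through segmentation → 3D topology →
measurements and returns the four result tables plus label volumes for QC;
``analyze_batch`` maps it over a directory of TIFFs, skipping (and logging)
failed images, and writes byte-stable CSVs sorted by image id.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage as ndi

from . import io as cio
from . import measure, segment, topology

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "StackResult", "analyze_stack", "analyze_batch", "stats_report"]


@dataclass
class RunConfig:
    """Declarative run configuration (YAML-loadable, unknown keys rejected).

    Physical defaults follow conventional confocal acquisition of imaginal
    discs: 1 µm Z-steps, 8-bit planes, and an 8 µm border width (roughly two
    cell diameters in a columnar epithelium).
    """

    channel_roles: dict[str, int] = field(default_factory=lambda: {"genotype_1": 0, "nuclear": 1, "foci": 2})
    voxel_size: tuple[float, float] = (0.38, 1.0)   # (xy µm/px, z µm/plane)
    axes: str | None = None                          # on-disk axis order override

    # segmentation
    genotype_smooth_sigma: float = 1.0
    genotype_threshold: float | None = None          # None = Otsu
    genotype_closing_radius: int = 1
    genotype_min_size_px: int = 0
    nuclear_smooth_sigma: float = 1.0
    nuclear_threshold: float | None = None
    min_nuc_px: int = 6
    max_nuc_px: int = 10_000
    peak_min_distance: int = 4
    foci_thresholds: tuple[float, ...] = (0.95, 0.99)
    foci_quantile: bool = True
    foci_min_size_px: int = 4
    foci_max_size_px: int = 400

    # 3D linking
    border_width_um: float = 8.0
    min_overlap_px: int = 1
    min_overlap_frac: float = 0.0
    max_drift_um: float = 2.0
    foci_max_drift_um: float = 2.0
    watershed_h: float = 1.0

    # measurement
    apoptosis_overlap_frac: float = 0.3
    loser_genotype: str = "genotype_1"
    winner_genotype: str = "winner"                  # implicit unmarked background class
    tissue_smooth_sigma: float = 4.0
    tissue_threshold: float | None = None

    # bookkeeping
    groups: dict[str, str] = field(default_factory=dict)  # image_id -> group
    stats: dict[str, Any] = field(default_factory=dict)   # declarative stats block
    seed: int = 0
    write_overlays: bool = False

    def __post_init__(self) -> None:
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 2 or min(self.voxel_size) <= 0:
            raise ValueError("voxel_size must be two positive numbers (xy_um, z_um)")
        if self.border_width_um <= 0:
            raise ValueError("border_width_um must be positive")
        if not 0 < self.apoptosis_overlap_frac <= 1:
            raise ValueError("apoptosis_overlap_frac must be in (0, 1]")
        self.foci_thresholds = tuple(self.foci_thresholds)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        valid = set(cls.__dataclass_fields__)
        unknown = set(d) - valid
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def genotype_params(self) -> segment.SegmentationParams:
        return segment.SegmentationParams(
            smooth_sigma=self.genotype_smooth_sigma,
            threshold=self.genotype_threshold,
            closing_radius=self.genotype_closing_radius,
            min_size_px=self.genotype_min_size_px,
        )

    def nuclei_params(self) -> segment.NucleiParams:
        return segment.NucleiParams(
            smooth_sigma=self.nuclear_smooth_sigma,
            threshold=self.nuclear_threshold,
            min_nuc_px=self.min_nuc_px,
            max_nuc_px=self.max_nuc_px,
            peak_min_distance=self.peak_min_distance,
        )

    def foci_schedule(self) -> segment.FociFilterSchedule:
        return segment.FociFilterSchedule(
            thresholds=self.foci_thresholds,
            quantile=self.foci_quantile,
            min_size_px=self.foci_min_size_px,
            max_size_px=self.foci_max_size_px,
        )


@dataclass
class StackResult:
    """Everything computed for one image."""

    image_id: str
    tables: cio.ResultTables
    patches: list[topology.Patch3D]
    cells: list[topology.Cell3D]
    foci: list[topology.Focus3D]
    nuclear_labels: np.ndarray
    foci_labels: np.ndarray
    genotype_masks: dict[str, np.ndarray]
    pouch_mask: np.ndarray


def _per_label_overlap(label_planes: np.ndarray, mask: np.ndarray) -> dict[tuple[int, int], float]:
    """(z, label) -> number of label pixels inside mask, vectorized per plane."""
    out: dict[tuple[int, int], float] = {}
    for z in range(label_planes.shape[0]):
        ids = np.unique(label_planes[z])
        ids = ids[ids > 0]
        if ids.size == 0:
            continue
        sums = ndi.sum_labels(mask[z].astype(float), label_planes[z], ids)
        for i, s in zip(ids, sums):
            out[(z, int(i))] = float(s)
    return out


def analyze_stack(
    stack: cio.ImageStack,
    config: RunConfig,
    group: str | None = None,
    roi_mask: np.ndarray | None = None,
) -> StackResult:
    """Run the full per-image analysis and assemble the result tables."""
    xy, zstep = stack.voxel_size
    nz = stack.n_planes
    group = group if group is not None else config.groups.get(stack.image_id, "")

    # --- per-plane segmentation -------------------------------------------
    geno_roles = stack.genotype_roles()
    geno_masks = {r: np.zeros((nz, *stack.plane_shape), dtype=bool) for r in geno_roles}
    nuclear_labels = np.zeros((nz, *stack.plane_shape), dtype=np.int32)
    foci_masks = np.zeros((nz, *stack.plane_shape), dtype=bool)
    gparams = config.genotype_params()
    nparams = config.nuclei_params()
    schedule = config.foci_schedule()
    for z in range(nz):
        plane = stack.plane(z)
        masks = segment.segment_genotypes(
            plane, {r: stack.channel_roles[r] for r in geno_roles}, params=gparams
        )
        for r in geno_roles:
            geno_masks[r][z] = masks[r]
        if "nuclear" in stack.channel_roles:
            nuclear_labels[z] = segment.segment_nuclei(
                plane, stack.channel_roles["nuclear"], params=nparams
            )
        if "foci" in stack.channel_roles:
            foci_masks[z] = segment.detect_foci_plane(
                plane[..., stack.channel_roles["foci"]], schedule
            )

    # --- pouch / analysis territory ---------------------------------------
    if roi_mask is not None:
        pouch = np.asarray(roi_mask, dtype=bool)
    elif "nuclear" in stack.channel_roles:
        pouch = measure.tissue_mask_from_nuclear(
            stack, config.tissue_smooth_sigma, config.tissue_threshold
        )
    else:
        pouch = np.ones((nz, *stack.plane_shape), dtype=bool)
    if not pouch.any():
        pouch = np.ones((nz, *stack.plane_shape), dtype=bool)
    pouch_volume = float(pouch.sum()) * stack.voxel_volume_um3
    pouch_centroid = topology.mask_centroid_um(pouch, stack.voxel_size)

    # --- 3D assembly -------------------------------------------------------
    patches: list[topology.Patch3D] = []
    offset = 0
    for r in geno_roles:
        ps = topology.link_patches(
            geno_masks[r], r, stack.voxel_size,
            min_overlap_px=config.min_overlap_px,
            min_overlap_frac=config.min_overlap_frac,
        )
        for p in ps:
            p.patch_id += offset
            b, c = topology.partition_border_centre(p.mask, config.border_width_um, stack.voxel_size)
            p.border_mask, p.centre_mask = b, c
        offset += len(ps)
        patches.extend(ps)

    cells = topology.track_cells(
        nuclear_labels, stack.voxel_size, config.max_drift_um, intensity_volumes=stack.voxels
    )
    foci, foci_labels = topology.assemble_foci(
        foci_masks, stack.voxel_size, config.foci_max_drift_um, config.watershed_h
    )

    # --- cell genotype / region / distances --------------------------------
    geno_border = {}
    geno_centre = {}
    for r in geno_roles:
        geno_border[r] = np.zeros_like(geno_masks[r])
        geno_centre[r] = np.zeros_like(geno_masks[r])
        for p in patches:
            if p.genotype == r:
                geno_border[r] |= p.border_mask
                geno_centre[r] |= p.centre_mask

    overlap_by_geno = {
        r: _per_label_overlap(nuclear_labels, geno_masks[r]) for r in geno_roles
    }
    # per-plane distance maps to the loser patch boundary (boundary-pixel rule)
    loser = config.loser_genotype
    dist_maps = None
    if loser in geno_masks:
        dist_maps = np.zeros((nz, *stack.plane_shape))
        for z in range(nz):
            plane_mask = geno_masks[loser][z]
            if plane_mask.any():
                boundary = plane_mask & ~ndi.binary_erosion(plane_mask)
                dist_maps[z] = ndi.distance_transform_edt(~boundary) * xy

    for c in cells:
        best_r, best_frac = "none", 0.0
        for r in geno_roles:
            ov = sum(overlap_by_geno[r].get((z, lab), 0.0) for z, lab in c.member_rois.items())
            frac = ov / c.voxel_count if c.voxel_count else 0.0
            if frac > best_frac:
                best_r, best_frac = r, frac
        in_pouch = _sample_mask(pouch, c.centroid_um, stack.voxel_size)
        if best_frac >= 0.5:
            c.genotype = best_r
        elif in_pouch:
            c.genotype = config.winner_genotype
        else:
            c.genotype = "none"
        c.dist_pouch_centre_um = float(
            np.linalg.norm(np.asarray(c.centroid_um) - np.asarray(pouch_centroid))
        )
        if c.genotype in geno_roles:
            zi, ri, ci_ = _voxel_index(c.centroid_um, stack.voxel_size, pouch.shape)
            if geno_border[c.genotype][zi, ri, ci_]:
                c.region = "border"
            elif geno_centre[c.genotype][zi, ri, ci_]:
                c.region = "centre"
            else:
                c.region = "none"
            if c.genotype == loser and dist_maps is not None:
                inside = geno_masks[loser][zi, ri, ci_]
                c.dist_border_um = float(dist_maps[zi, ri, ci_]) if inside else 0.0
                c.outside_patch = not bool(inside)

    measure.mark_cells_apoptotic(
        cells, foci, nuclear_labels, foci_labels, stack.voxel_size,
        overlap_frac=config.apoptosis_overlap_frac,
    )

    # --- focus region labels ------------------------------------------------
    for f in foci:
        zi, ri, ci_ = _voxel_index(f.centroid_um, stack.voxel_size, pouch.shape)
        f.genotype_region = "none"
        f.border_or_centre = "none"
        for r in geno_roles:
            if geno_masks[r][zi, ri, ci_]:
                f.genotype_region = r
                if geno_border[r][zi, ri, ci_]:
                    f.border_or_centre = "border"
                elif geno_centre[r][zi, ri, ci_]:
                    f.border_or_centre = "centre"
                break

    # --- tables -------------------------------------------------------------
    tables = _build_tables(
        stack, config, group, patches, cells, foci, foci_masks, pouch, pouch_volume
    )
    return StackResult(
        image_id=stack.image_id,
        tables=tables,
        patches=patches,
        cells=cells,
        foci=foci,
        nuclear_labels=nuclear_labels,
        foci_labels=foci_labels,
        genotype_masks=geno_masks,
        pouch_mask=pouch,
    )


def _voxel_index(point_um, voxel_size, shape):
    xy, zstep = voxel_size
    x, y, z = point_um
    zi = min(max(int(round(z / zstep)), 0), shape[0] - 1)
    ri = min(max(int(round(y / xy)), 0), shape[1] - 1)
    ci = min(max(int(round(x / xy)), 0), shape[2] - 1)
    return zi, ri, ci


def _sample_mask(mask, point_um, voxel_size) -> bool:
    zi, ri, ci = _voxel_index(point_um, voxel_size, mask.shape)
    return bool(mask[zi, ri, ci])


def _build_tables(stack, config, group, patches, cells, foci, foci_masks, pouch, pouch_volume):
    xy, zstep = stack.voxel_size
    area_px = xy * xy
    loser = config.loser_genotype
    image_id = stack.image_id

    per_patch_rows = []
    for p in patches:
        row = {
            "image_id": image_id,
            "patch_id": p.patch_id,
            "genotype": p.genotype,
            "volume_um3": p.volume_um3,
            "z_min": p.z_range[0],
            "z_max": p.z_range[1],
            "n_components_2d": p.n_components_2d,
            "border_area_um2": float(p.border_mask.sum()) * area_px,
            "centre_area_um2": float(p.centre_mask.sum()) * area_px,
            "border_foci_coverage": (
                measure.coverage_fraction(p.border_mask, foci_masks) if p.border_mask.any() else 0.0
            ),
            "centre_foci_coverage": (
                measure.coverage_fraction(p.centre_mask, foci_masks) if p.centre_mask.any() else 0.0
            ),
        }
        per_patch_rows.append(row)

    per_cell_rows = []
    n_ch = stack.n_channels
    for c in cells:
        row = {
            "image_id": image_id,
            "cell_id": c.cell_id,
            "genotype": c.genotype,
            "cx_um": c.centroid_um[0],
            "cy_um": c.centroid_um[1],
            "cz_um": c.centroid_um[2],
            "z_plane": c.z_plane,
            "region": c.region,
            "dist_border_um": c.dist_border_um,
            "dist_pouch_centre_um": c.dist_pouch_centre_um,
            "apoptotic": int(c.apoptotic),
        }
        for ch in range(n_ch):
            row[f"mean_intensity_c{ch}"] = c.intensities.get(ch, np.nan)
        per_cell_rows.append(row)

    per_focus_rows = [
        {
            "image_id": image_id,
            "focus_id": f.focus_id,
            "cx_um": f.centroid_um[0],
            "cy_um": f.centroid_um[1],
            "cz_um": f.centroid_um[2],
            "volume_um3": f.volume_um3,
            "genotype_region": f.genotype_region,
            "border_or_centre": f.border_or_centre,
            "nearest_cell_id": f.nearest_cell_id,
        }
        for f in foci
    ]

    loser_patches = [p for p in patches if p.genotype == loser]
    loser_mask = np.zeros(pouch.shape, dtype=bool)
    border_mask = np.zeros(pouch.shape, dtype=bool)
    centre_mask = np.zeros(pouch.shape, dtype=bool)
    for p in loser_patches:
        loser_mask |= p.mask
        border_mask |= p.border_mask
        centre_mask |= p.centre_mask
    loser_cells = [c for c in cells if c.genotype == loser]
    border_cells = [c for c in loser_cells if c.region == "border"]
    n_apo_border = sum(c.apoptotic for c in border_cells)

    per_image = {
        "image_id": image_id,
        "group": group,
        "n_patches": len(loser_patches),
        "loser_coverage_pct": measure.pouch_coverage(loser_mask, pouch) if pouch.any() else np.nan,
        "border_death_coverage_pct": (
            100.0 * measure.coverage_fraction(border_mask, foci_masks) if border_mask.any() else 0.0
        ),
        "centre_death_coverage_pct": (
            100.0 * measure.coverage_fraction(centre_mask, foci_masks) if centre_mask.any() else 0.0
        ),
        "n_cells": len(cells),
        "n_apoptotic_border": int(n_apo_border),
        "n_nonapoptotic_border": int(len(border_cells) - n_apo_border),
        "pouch_volume_um3": pouch_volume,
    }

    per_cell = pd.DataFrame(per_cell_rows)
    if not per_cell.empty:
        # disc-level regression covariates, constant within the image
        n_winner_apoptotic = sum(
            c.apoptotic for c in cells if c.genotype not in (loser, "none")
        )
        per_cell["pouch_volume_um3"] = pouch_volume
        per_cell["n_loser_cells"] = len(loser_cells)
        per_cell["n_winner_apoptotic"] = int(n_winner_apoptotic)
        per_cell["group"] = group

    return cio.ResultTables(
        per_image=pd.DataFrame([per_image]),
        per_patch=pd.DataFrame(per_patch_rows),
        per_cell=per_cell,
        per_focus=pd.DataFrame(per_focus_rows),
    )


def analyze_batch(
    input_dir: str | Path,
    config: RunConfig,
    out_dir: str | Path,
    write_overlays: bool | None = None,
) -> cio.ResultTables:
    """Analyse every TIFF in a directory; write merged CSVs and a run log.

    Images are independent: a failure is logged and skipped without aborting
    the batch.  Tables are sorted by image_id before writing, so the output
    bytes do not depend on directory iteration order.
    """
    input_dir = Path(input_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = sorted(p for p in input_dir.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
    if not paths:
        raise FileNotFoundError(f"no TIFF images found in {input_dir}")
    cfg_hash = config.config_hash()
    log_lines = [f"# clonepipe run  config_hash={cfg_hash}"]
    merged = {n: [] for n in ("per_image", "per_patch", "per_cell", "per_focus")}
    n_ok = 0
    for p in paths:
        t0 = time.perf_counter()
        try:
            stack = cio.read_stack(p, config.channel_roles, config.voxel_size, axes=config.axes)
            roi_path = input_dir / f"{p.stem}_roi.tif"
            roi = None
            if roi_path.is_file():
                roi = cio.read_stack(roi_path, {}, config.voxel_size, axes=config.axes).voxels[..., 0] > 0
            result = analyze_stack(stack, config, roi_mask=roi)
            for n in merged:
                merged[n].append(getattr(result.tables, n))
            if write_overlays if write_overlays is not None else config.write_overlays:
                cio.write_overlays(
                    stack, result.nuclear_labels, out_dir / "overlays",
                    apoptotic_ids=[c.cell_id for c in result.cells if c.apoptotic],
                    prefix=f"{stack.image_id}_cells",
                )
            n_ok += 1
            log_lines.append(
                f"ok {p.name} {time.perf_counter() - t0:.2f}s config_hash={cfg_hash}"
            )
        except Exception as exc:
            log_lines.append(f"FAILED {p.name}: {exc} config_hash={cfg_hash}")
            log.warning("image %s failed: %s", p.name, exc)
    if n_ok == 0:
        raise RuntimeError(f"no analysable images in {input_dir}")
    tables = cio.ResultTables(
        **{
            n: (
                pd.concat(v, ignore_index=True).sort_values(
                    ["image_id"] + [c for c in ("patch_id", "cell_id", "focus_id") if v and c in v[0].columns],
                    kind="stable",
                ).reset_index(drop=True)
                if v and any(len(t) for t in v)
                else pd.DataFrame()
            )
            for n, v in merged.items()
        }
    )
    tables.validate()
    cio.write_tables(tables, out_dir)
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    return tables


def stats_report(tables: cio.ResultTables, config: RunConfig, out_dir: str | Path) -> pd.DataFrame:
    """Execute the declarative stats block against the result tables.

    The block names a table, a value column, a grouping column, comparisons
    (pairs of group labels, or all-vs-reference), the adjustment method, and
    optional regressions.  Emits ``stats_report.csv`` (one row per
    comparison) and an effects-profile CSV per regression predictor.
    """
    from . import stats as st

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    block = config.stats or {}
    table_name = block.get("table", "per_image")
    tab: pd.DataFrame = getattr(tables, table_name)
    rows = []
    adjust = block.get("adjust", "fdr")
    for comp in block.get("comparisons", []):
        value, by = comp["value"], comp.get("by", "group")
        g1, g2 = comp["groups"]
        x = tab.loc[tab[by] == g1, value].to_numpy(dtype=float)
        y = tab.loc[tab[by] == g2, value].to_numpy(dtype=float)
        if len(x) < 3 or len(y) < 3:
            log.warning("comparison %s vs %s skipped: group too small", g1, g2)
            rows.append(
                {"value": value, "group_1": g1, "group_2": g2, "n_1": len(x), "n_2": len(y),
                 "test": "skipped (n < 3)", "statistic": np.nan, "p": np.nan,
                 "effect_size_name": "", "effect_size": np.nan}
            )
            continue
        r = st.two_group_test(x, y, paired=comp.get("paired", False))
        rows.append(
            {"value": value, "group_1": g1, "group_2": g2, "n_1": len(x), "n_2": len(y),
             "test": r.test_name, "statistic": r.statistic, "p": r.p_value,
             "effect_size_name": r.effect_size[0], "effect_size": r.effect_size[1]}
        )
    report = pd.DataFrame(rows)
    if len(report):
        ok = report["p"].notna()
        if adjust not in (None, "none") and ok.any():
            adj = np.full(len(report), np.nan)
            adj[ok.to_numpy()] = st.adjust_p(report.loc[ok, "p"].to_numpy(), adjust)
            report["adjusted_p"] = adj
    report.to_csv(out_dir / "stats_report.csv", index=False, lineterminator="\n")

    for reg in block.get("regressions", []):
        fam = reg.get("family", "logistic")
        fit = st.fit_glm(tab, reg["response"] if not isinstance(reg["response"], list) else tuple(reg["response"]),
                         reg["predictors"], family=fam)
        coef = pd.DataFrame(
            {"coef": fit.params, "se": fit.bse, "p": fit.pvalues}
        )
        coef.to_csv(out_dir / f"regression_{fam}_coefficients.csv", lineterminator="\n")
        for pred in reg.get("profiles", reg["predictors"]):
            col = tab[pred].astype(float)
            prof = st.effects_profile(
                fit, pred, grid=np.linspace(col.min(), col.max(), 50),
                observed_range=(col.min(), col.max()),
            )
            prof.to_csv(out_dir / f"profile_{pred}.csv", index=False, lineterminator="\n")
    return report
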