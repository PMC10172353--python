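"""Per-region and per-cell metrics: coverage, densities, apoptosis calls.

"Density of apoptosis" is used in three distinct senses across clonal
competition analyses, and all three are implemented and named separately:

* :func:`coverage_fraction` — area/volume fraction of a region positive for
  the death reporter;
* :func:`foci_density` — discrete puncta per µm³ of region;
* :func:`pct_cells_positive` — percentage of segmented cells in a region
  called apoptotic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .io import ImageStack
from .segment import FociFilterSchedule, detect_foci_plane
from .topology import Cell3D, Focus3D

__all__ = [
    "UndefinedMetricError",
    "coverage_fraction",
    "foci_density",
    "mark_cells_apoptotic",
    "pct_cells_positive",
    "pouch_coverage",
    "tissue_mask_from_nuclear",
    "speckle_stats",
    "build_cell_table",
]


class UndefinedMetricError(ValueError):
    """A metric was requested on an empty measurement territory."""


def coverage_fraction(region_mask: np.ndarray, foci_mask: np.ndarray) -> float:
    """Fraction of a region's voxels positive for the foci/reporter mask."""
    region_mask = np.asarray(region_mask, dtype=bool)
    n = int(region_mask.sum())
    if n == 0:
        raise UndefinedMetricError("coverage_fraction of an empty region is undefined")
    return float((region_mask & np.asarray(foci_mask, dtype=bool)).sum()) / n


def _point_to_voxel(point_um, voxel_size):
    xy, zstep = voxel_size
    x, y, z = point_um
    return int(round(z / zstep)), int(round(y / xy)), int(round(x / xy))


def foci_density(
    region_mask: np.ndarray,
    foci: list[Focus3D],
    voxel_size: tuple[float, float],
) -> float:
    """Number of foci whose centroid voxel lies in the region, per µm³.

    Membership is by voxel: a centroid on an edge voxel of the region counts.
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    n_vox = int(region_mask.sum())
    if n_vox == 0:
        raise UndefinedMetricError("foci_density of an empty region is undefined")
    xy, zstep = voxel_size
    count = 0
    for f in foci:
        zi, ri, ci = _point_to_voxel(f.centroid_um, voxel_size)
        if (
            0 <= zi < region_mask.shape[0]
            and 0 <= ri < region_mask.shape[1]
            and 0 <= ci < region_mask.shape[2]
            and region_mask[zi, ri, ci]
        ):
            count += 1
    return count / (n_vox * xy * xy * zstep)


def mark_cells_apoptotic(
    cells: list[Cell3D],
    foci: list[Focus3D],
    nuclear_labels: np.ndarray,
    foci_volume: np.ndarray,
    voxel_size: tuple[float, float],
    overlap_frac: float = 0.3,
) -> list[Cell3D]:
    """Set each cell's apoptotic flag from foci overlap (in place).

    Every focus is first assigned to exactly one cell: the cell whose
    nucleus contains the focus centroid if there is one, else the cell with
    the nearest centroid (ties go to the smaller cell id); the assignment is
    recorded in ``focus.nearest_cell_id``.  A cell is then apoptotic iff an
    assigned focus centroid lies within its nuclear voxels, or the fraction
    of its nuclear voxels overlapped by the voxels of its assigned foci is
    at least ``overlap_frac``.  Single-assignment guarantees one focus can
    flag at most one cell.

    ``nuclear_labels`` are the per-plane 2D nucleus labels each cell's
    ``member_rois`` refer to; ``foci_volume`` is the 3D focus-id label
    volume from :func:`clonepipe.topology.assemble_foci`.
    """
    if not 0 < overlap_frac <= 1:
        raise ValueError("overlap_frac must be in (0, 1]")
    foci_labels = np.asarray(foci_volume)
    nuclear_labels = np.asarray(nuclear_labels)
    for c in cells:
        c.apoptotic = 0
    if not cells:
        return cells

    # map (z, 2D nucleus label) -> cell id
    roi_to_cell: dict[tuple[int, int], int] = {}
    for c in cells:
        for z, lab in c.member_rois.items():
            roi_to_cell[(z, lab)] = c.cell_id

    # assign every focus to exactly one cell: containment first, then
    # nearest cell centroid (ties to the smaller cell id)
    cell_cents = np.array([c.centroid_um for c in cells])
    cell_ids = np.array([c.cell_id for c in cells], dtype=int)
    order = np.argsort(cell_ids)
    contained: set[int] = set()  # cell ids hit by an in-nucleus focus centroid
    focus_owner: dict[int, int] = {}
    for f in foci:
        zi, ri, ci = _point_to_voxel(f.centroid_um, voxel_size)
        owner = -1
        if (
            0 <= zi < nuclear_labels.shape[0]
            and 0 <= ri < nuclear_labels.shape[1]
            and 0 <= ci < nuclear_labels.shape[2]
        ):
            lab = int(nuclear_labels[zi, ri, ci])
            if lab > 0:
                owner = roi_to_cell.get((zi, lab), -1)
        if owner >= 0:
            contained.add(owner)
        else:
            d = np.linalg.norm(cell_cents - np.asarray(f.centroid_um), axis=1)
            owner = int(cell_ids[np.lexsort((cell_ids, d))[0]])
        f.nearest_cell_id = owner
        focus_owner[f.focus_id] = owner

    # voxel overlap between each nucleus and its *assigned* foci, via a
    # per-plane joint histogram of (nucleus label, owning cell of the focus)
    max_focus = int(foci_labels.max())
    owner_lut = np.zeros(max_focus + 1, dtype=np.int64)
    for fid, owner in focus_owner.items():
        if 0 < fid <= max_focus:
            owner_lut[fid] = max(owner, 0)
    overlap_by_cell: dict[tuple[int, int], int] = {}  # (z, nucleus label) -> px
    for z in range(nuclear_labels.shape[0]):
        nz = nuclear_labels[z]
        oz = owner_lut[foci_labels[z]] if max_focus else np.zeros_like(nz)
        sel = (nz > 0) & (oz > 0)
        if not sel.any():
            continue
        codes = nz[sel].astype(np.int64) * (oz.max() + 1) + oz[sel]
        uniq, counts = np.unique(codes, return_counts=True)
        base = int(oz.max() + 1)
        for code, cnt in zip(uniq, counts):
            lab, owner = divmod(int(code), base)
            cid = roi_to_cell.get((z, lab), -1)
            if cid == owner:  # only foci assigned to this very cell count
                overlap_by_cell[(z, lab)] = overlap_by_cell.get((z, lab), 0) + int(cnt)

    for c in cells:
        if c.cell_id in contained:
            c.apoptotic = 1
            continue
        overlap = sum(overlap_by_cell.get((z, lab), 0) for z, lab in c.member_rois.items())
        if c.voxel_count and overlap / c.voxel_count >= overlap_frac:
            c.apoptotic = 1
    return cells


def pct_cells_positive(cells: list[Cell3D]) -> float:
    """Percentage of the given cells flagged apoptotic."""
    if not cells:
        raise UndefinedMetricError("pct_cells_positive of zero cells is undefined")
    return 100.0 * sum(c.apoptotic for c in cells) / len(cells)


def tissue_mask_from_nuclear(
    stack: ImageStack,
    smooth_sigma: float = 4.0,
    threshold: float | None = None,
) -> np.ndarray:
    """Whole-tissue mask from the nuclear channel.

    Smoothed threshold (Otsu by default) per plane, holes filled, then the
    largest 3D connected component.  Used as the default pouch territory
    when no region-of-interest mask is supplied.
    """
    from skimage import filters

    nuc = stack.channel("nuclear").astype(float)
    mask = np.zeros(nuc.shape, dtype=bool)
    for z in range(nuc.shape[0]):
        img = ndi.gaussian_filter(nuc[z], smooth_sigma) if smooth_sigma > 0 else nuc[z]
        if threshold is not None:
            cut = threshold
        elif np.ptp(img) == 0:
            continue
        else:
            cut = filters.threshold_otsu(img)
        m = img >= cut
        if m.any():
            mask[z] = ndi.binary_fill_holes(m)
    if not mask.any():
        return mask
    labels, n = ndi.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    if n > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        mask = labels == int(np.argmax(counts))
    return mask


def pouch_coverage(genotype_mask: np.ndarray, pouch_mask: np.ndarray) -> float:
    """Percentage of the pouch (analysis territory) occupied by a genotype."""
    pouch_mask = np.asarray(pouch_mask, dtype=bool)
    n = int(pouch_mask.sum())
    if n == 0:
        raise UndefinedMetricError("pouch mask is empty")
    return 100.0 * int((np.asarray(genotype_mask, dtype=bool) & pouch_mask).sum()) / n


def speckle_stats(
    region_mask: np.ndarray,
    channel_planes: np.ndarray,
    detector: FociFilterSchedule | None = None,
    voxel_size: tuple[float, float] = (1.0, 1.0),
) -> tuple[int, float, float]:
    """Speckle (2D puncta) statistics within a region.

    Speckles are components found by the foci detector on each plane whose
    centroid lies inside the region.  Returns ``(count, mean_size_um2,
    density_per_um2)`` where density is count per region area (µm², summed
    over planes).  A blank channel reports ``(0, 0.0, 0.0)``.
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    n_vox = int(region_mask.sum())
    if n_vox == 0:
        raise UndefinedMetricError("speckle_stats of an empty region is undefined")
    xy = voxel_size[0]
    detector = detector or FociFilterSchedule()
    count = 0
    total_px = 0
    for z in range(channel_planes.shape[0]):
        mask = detect_foci_plane(channel_planes[z], detector)
        if not mask.any():
            continue
        labels, n = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
        ids = np.arange(1, n + 1)
        cents = ndi.center_of_mass(mask, labels, ids)
        areas = ndi.sum_labels(np.ones_like(mask, dtype=float), labels, ids)
        for (r, c), a in zip(np.atleast_2d(cents), areas):
            if region_mask[z, int(round(r)), int(round(c))]:
                count += 1
                total_px += int(a)
    mean_size = (total_px / count) * xy * xy if count else 0.0
    density = count / (n_vox * xy * xy)
    return count, mean_size, density


def build_cell_table(
    image_id: str,
    group: str,
    cells: list[Cell3D],
    loser_genotype: str,
    pouch_volume_um3: float,
) -> pd.DataFrame:
    """Regression-ready table: one row per loser-genotype cell.

    Disc-level covariates (pouch volume, total loser cell count, winner
    apoptotic count) are constant within the image; per-cell predictors are
    the Z-plane, the distance to the pouch centre and the distance to the
    loser patch border, with the apoptotic flag as the response.
    """
    if not cells:
        raise ValueError("no cells computed for this image; run tracking first")
    losers = [c for c in cells if c.genotype == loser_genotype]
    n_winner_apoptotic = sum(
        c.apoptotic for c in cells if c.genotype not in (loser_genotype, "none")
    )
    rows = []
    for c in losers:
        row = {
            "image_id": image_id,
            "group": group,
            "cell_id": c.cell_id,
            "apoptotic": int(c.apoptotic),
            "pouch_volume_um3": pouch_volume_um3,
            "n_loser_cells": len(losers),
            "n_winner_apoptotic": int(n_winner_apoptotic),
            "z_plane": c.z_plane,
            "dist_pouch_centre_um": c.dist_pouch_centre_um,
            "dist_border_um": c.dist_border_um,
        }
        rows.append(row)
    return pd.DataFrame(rows)
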