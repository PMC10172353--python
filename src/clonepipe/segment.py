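"""Per-plane pixel classification: genotype masks, nuclei labels, foci masks.

Each operation works on a single Z-plane; 3D assembly lives in
:mod:`clonepipe.topology`.  The built-in methods are deliberately simple
(smooth → threshold → morphology); anything fancier plugs in through the
:class:`PixelClassifier` contract, the seam where a learned pixel classifier
would attach.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Protocol, Sequence, runtime_checkable

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, morphology, segmentation

log = logging.getLogger(__name__)

__all__ = [
    "PixelClassifier",
    "FunctionClassifier",
    "FociFilterSchedule",
    "SegmentationParams",
    "NucleiParams",
    "segment_genotype",
    "segment_genotypes",
    "segment_nuclei",
    "detect_foci_plane",
]


@runtime_checkable
class PixelClassifier(Protocol):
    """Contract for pluggable per-plane pixel classifiers.

    ``classify`` receives one full plane, ``(y, x, channel)``, and returns an
    integer class mask of shape ``(y, x)`` with values in ``[0, len(classes))``;
    class 0 is background.
    """

    classes: Sequence[str]

    def classify(self, plane: np.ndarray) -> np.ndarray: ...


@dataclass
class FunctionClassifier:
    """Adapter wrapping a plain function as a :class:`PixelClassifier`."""

    classes: Sequence[str]
    fn: Callable[[np.ndarray], np.ndarray]

    def classify(self, plane: np.ndarray) -> np.ndarray:
        mask = np.asarray(self.fn(plane))
        if mask.shape != plane.shape[:2]:
            raise ValueError(f"classifier returned shape {mask.shape}, expected {plane.shape[:2]}")
        if mask.min() < 0 or mask.max() >= len(self.classes):
            raise ValueError("classifier emitted class ids outside [0, n_classes)")
        return mask.astype(np.int32)


@dataclass
class SegmentationParams:
    """Built-in genotype/marker segmentation knobs.

    ``threshold=None`` selects Otsu; a number fixes the cutoff (pixels with
    intensity >= threshold are positive).  ``smooth_sigma`` is in pixels;
    0 disables smoothing.
    """

    smooth_sigma: float = 1.0
    threshold: float | None = None
    closing_radius: int = 1
    fill_holes: bool = True
    min_size_px: int = 0


@dataclass
class NucleiParams:
    """Nuclear segmentation knobs (watershed on the distance transform)."""

    smooth_sigma: float = 1.0
    threshold: float | None = None
    min_nuc_px: int = 6
    max_nuc_px: int = 10_000
    peak_min_distance: int = 4


@dataclass
class FociFilterSchedule:
    """Alternating intensity/size filter schedule for punctate foci.

    ``thresholds`` is a strictly ascending list of cutoffs; with
    ``quantile=True`` (default) each value is an intensity quantile of the
    plane, else an absolute intensity.  After each thresholding pass the
    surviving connected components are size-filtered to
    ``[min_size_px, max_size_px]``; the next pass re-thresholds only inside
    the survivors.  The default two-pass (q = 0.95, 0.99) schedule keeps
    bright compact puncta and discards both large dim blobs and hot pixels.
    """

    thresholds: Sequence[float] = (0.95, 0.99)
    quantile: bool = True
    min_size_px: int = 4
    max_size_px: int = 400
    connectivity: int = 2  # scipy/skimage convention: 2 = 8-connected

    def __post_init__(self) -> None:
        th = list(self.thresholds)
        if not th or any(b <= a for a, b in zip(th, th[1:])):
            raise ValueError("thresholds must be a non-empty strictly ascending sequence")
        if not (0 < self.min_size_px <= self.max_size_px):
            raise ValueError("need 0 < min_size_px <= max_size_px")
        if self.quantile and (th[0] < 0 or th[-1] > 1):
            raise ValueError("quantile thresholds must lie in [0, 1]")


def _smooth(plane: np.ndarray, sigma: float) -> np.ndarray:
    plane = plane.astype(float, copy=False)
    return ndi.gaussian_filter(plane, sigma) if sigma > 0 else plane


def _auto_or_fixed_threshold(img: np.ndarray, threshold: float | None) -> float | None:
    """Resolve the cutoff; returns None when auto-threshold is degenerate."""
    if threshold is not None:
        return float(threshold)
    if np.ptp(img) == 0:
        return None
    return float(filters.threshold_otsu(img))


def segment_genotype(
    plane: np.ndarray,
    channel: int,
    params: SegmentationParams | None = None,
    classifier: PixelClassifier | None = None,
    class_id: int = 1,
) -> np.ndarray:
    """Binary mask of marker-positive pixels on one plane.

    Built-in method: Gaussian smoothing → Otsu or fixed threshold →
    morphological closing → hole filling.  When ``classifier`` is given it
    replaces the built-in method and the mask is ``classify(plane) == class_id``.

    A constant plane under auto-threshold yields an empty mask with a logged
    warning rather than an error, so batch runs survive blank planes.
    """
    params = params or SegmentationParams()
    if classifier is not None:
        return classifier.classify(plane) == class_id
    img = _smooth(plane[..., channel], params.smooth_sigma)
    cut = _auto_or_fixed_threshold(img, params.threshold)
    if cut is None:
        log.warning("constant plane under auto-threshold; returning empty genotype mask")
        return np.zeros(img.shape, dtype=bool)
    mask = img >= cut
    if params.closing_radius > 0 and mask.any():
        footprint = morphology.disk(params.closing_radius)
        mask = ndi.binary_erosion(ndi.binary_dilation(mask, footprint), footprint, border_value=1)
    if params.fill_holes and mask.any():
        mask = ndi.binary_fill_holes(mask)
    if params.min_size_px > 1 and mask.any():
        labels, n = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
        counts = np.bincount(labels.ravel())
        mask = (counts >= params.min_size_px)[labels] & mask
    return mask


def segment_genotypes(
    plane: np.ndarray,
    channels: dict[str, int],
    params: SegmentationParams | dict[str, SegmentationParams] | None = None,
    classifier: PixelClassifier | None = None,
) -> dict[str, np.ndarray]:
    """Masks for every genotype role on one plane, pairwise disjoint.

    Roles are processed in sorted order; each later mask is clipped against
    the union of earlier ones, so a pixel belongs to at most one genotype.
    """
    claimed = np.zeros(plane.shape[:2], dtype=bool)
    out: dict[str, np.ndarray] = {}
    for k, role in enumerate(sorted(channels)):
        p = params.get(role) if isinstance(params, dict) else params
        if classifier is not None:
            cls_id = list(classifier.classes).index(role) if role in classifier.classes else k + 1
            mask = segment_genotype(plane, channels[role], classifier=classifier, class_id=cls_id)
        else:
            mask = segment_genotype(plane, channels[role], params=p)
        mask = mask & ~claimed
        claimed |= mask
        out[role] = mask
    return out


def _plateau_markers(dt: np.ndarray, min_distance: int, mask: np.ndarray) -> np.ndarray:
    """Label one marker per regional-maximum plateau of the distance map."""
    if min_distance < 1:
        min_distance = 1
    foot = morphology.disk(min_distance)
    peaks = (dt == ndi.maximum_filter(dt, footprint=foot)) & mask
    markers, _ = ndi.label(peaks, structure=np.ones((3, 3), dtype=int))
    return markers


def segment_nuclei(
    plane: np.ndarray,
    channel: int,
    params: NucleiParams | None = None,
    classifier: PixelClassifier | None = None,
    class_id: int = 1,
) -> np.ndarray:
    """Integer label plane of individual nuclei.

    Built-in method: smooth → threshold → marker-controlled watershed on the
    Euclidean distance transform (one marker per distance-maximum plateau,
    plateaus closer than ``peak_min_distance`` px merge) → area filter
    ``[min_nuc_px, max_nuc_px]``.  Labels are compacted to 1..n within the
    plane.
    """
    params = params or NucleiParams()
    if classifier is not None:
        mask = classifier.classify(plane) == class_id
    else:
        img = _smooth(plane[..., channel], params.smooth_sigma)
        cut = _auto_or_fixed_threshold(img, params.threshold)
        if cut is None:
            return np.zeros(plane.shape[:2], dtype=np.int32)
        mask = img >= cut
    if not mask.any():
        return np.zeros(plane.shape[:2], dtype=np.int32)
    dt = ndi.distance_transform_edt(mask)
    markers = _plateau_markers(dt, params.peak_min_distance, mask)
    labels = segmentation.watershed(-dt, markers, mask=mask)
    # a component whose maximum was suppressed by a taller neighbour inside
    # the peak footprint has no marker; rescue it as its own label
    orphan = mask & (labels == 0)
    if orphan.any():
        extra, n_extra = ndi.label(orphan, structure=np.ones((3, 3), dtype=int))
        labels = labels + np.where(extra > 0, extra + labels.max(), 0)
    # area filter + compaction
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    keep = ids[(counts >= params.min_nuc_px) & (counts <= params.max_nuc_px)]
    remap = np.zeros(labels.max() + 1, dtype=np.int32)
    remap[keep] = np.arange(1, len(keep) + 1)
    return remap[labels]


def detect_foci_plane(plane_channel: np.ndarray, schedule: FociFilterSchedule | None = None) -> np.ndarray:
    """Binary foci mask from one channel plane via alternating filters.

    Passes run in ascending threshold order.  Pass *i* keeps, from within the
    survivors of pass *i−1*, the connected components of
    ``image > threshold_i`` whose area lies in ``[min_size_px, max_size_px]``.
    The returned mask is the union of the final pass's survivors.
    """
    schedule = schedule or FociFilterSchedule()
    img = np.asarray(plane_channel, dtype=float)
    structure = np.ones((3, 3), dtype=int) if schedule.connectivity == 2 else None
    survivors = np.ones(img.shape, dtype=bool)
    for th in schedule.thresholds:
        cut = float(np.quantile(img, th)) if schedule.quantile else float(th)
        candidate = survivors & (img > cut)
        if not candidate.any():
            return candidate
        labels, n = ndi.label(candidate, structure=structure)
        counts = np.bincount(labels.ravel())
        good = np.zeros(n + 1, dtype=bool)
        good[1:] = (counts[1:] >= schedule.min_size_px) & (counts[1:] <= schedule.max_size_px)
        survivors = good[labels]
    return survivors
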