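"""Reading multi-channel Z-stacks and writing result tables and QC overlays.

The on-disk unit is a TIFF (optionally OME/ImageJ hyperstack); the in-memory
unit is :class:`ImageStack`, a ``(z, y, x, channel)`` voxel array tagged with
physical voxel sizes and a mapping from biological channel roles (genotype
markers, nuclear stain, foci/reporter stain) to channel indices.

Result tables are plain CSVs; overlays are per-plane RGB PNGs meant purely
for visual QC and never read back by the pipeline.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageStack",
    "ResultTables",
    "read_stack",
    "write_stack",
    "write_tables",
    "write_overlays",
]

_VALID_ROLE_PREFIXES = ("genotype_", "aux_")
_VALID_ROLE_NAMES = ("nuclear", "foci")


class StackFormatError(ValueError):
    """The on-disk file cannot be interpreted as a Z-stack."""


class ConfigurationError(ValueError):
    """A channel-role map or axes declaration is inconsistent with the file."""


def _check_role(role: str) -> None:
    if role in _VALID_ROLE_NAMES or role.startswith(_VALID_ROLE_PREFIXES):
        return
    raise ConfigurationError(
        f"unknown channel role {role!r}; expected 'nuclear', 'foci', "
        f"'genotype_<name>' or 'aux_<name>'"
    )


@dataclass
class ImageStack:
    """A multi-channel 3D image with physical calibration.

    Parameters
    ----------
    voxels
        Intensity array indexed ``(z, y, x, channel)``.  Integer input is
        kept as stored; measurement code promotes to float as needed.
    voxel_size
        ``(xy_um, z_um)``: lateral pixel pitch in µm/px and axial step in
        µm/plane.  Lateral pixels are assumed square; Z may be anisotropic.
    channel_roles
        Maps role names (``genotype_*``, ``nuclear``, ``foci``, ``aux_*``)
        to channel indices.
    image_id
        Identifier carried into every output table row.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float]
    channel_roles: dict[str, int]
    image_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise StackFormatError(
                f"voxels must be (z, y, x, channel); got shape {self.voxels.shape}"
            )
        xy, z = self.voxel_size
        if xy <= 0 or z <= 0:
            raise ConfigurationError(f"voxel sizes must be positive, got {self.voxel_size}")
        self.voxel_size = (float(xy), float(z))
        n_ch = self.voxels.shape[3]
        seen: dict[int, str] = {}
        for role, idx in self.channel_roles.items():
            _check_role(role)
            if not 0 <= int(idx) < n_ch:
                raise ConfigurationError(
                    f"role {role!r} maps to channel {idx} but the stack has {n_ch} channel(s)"
                )
            if idx in seen:
                raise ConfigurationError(
                    f"channel {idx} claimed by both {seen[idx]!r} and {role!r}"
                )
            seen[int(idx)] = role

    @property
    def n_planes(self) -> int:
        return self.voxels.shape[0]

    @property
    def plane_shape(self) -> tuple[int, int]:
        return self.voxels.shape[1], self.voxels.shape[2]

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[3]

    @property
    def voxel_volume_um3(self) -> float:
        xy, z = self.voxel_size
        return xy * xy * z

    def channel(self, role: str) -> np.ndarray:
        """Return the ``(z, y, x)`` sub-volume for a named role."""
        if role not in self.channel_roles:
            raise ConfigurationError(f"role {role!r} not declared for image {self.image_id!r}")
        return self.voxels[..., self.channel_roles[role]]

    def plane(self, z: int) -> np.ndarray:
        """Return one ``(y, x, channel)`` plane."""
        return self.voxels[z]

    def genotype_roles(self) -> list[str]:
        return sorted(r for r in self.channel_roles if r.startswith("genotype_"))


@dataclass
class ResultTables:
    """The four CSV-bound result tables of one run (possibly many images)."""

    per_image: pd.DataFrame = field(default_factory=pd.DataFrame)
    per_patch: pd.DataFrame = field(default_factory=pd.DataFrame)
    per_cell: pd.DataFrame = field(default_factory=pd.DataFrame)
    per_focus: pd.DataFrame = field(default_factory=pd.DataFrame)

    def validate(self) -> None:
        """Check parent/child image_id referential integrity."""
        if self.per_image.empty:
            return
        ids = set(self.per_image["image_id"])
        for name in ("per_patch", "per_cell", "per_focus"):
            tab = getattr(self, name)
            if not tab.empty:
                orphans = set(tab["image_id"]) - ids
                if orphans:
                    raise ValueError(f"{name} rows reference unknown image_id(s): {sorted(orphans)}")


# ---------------------------------------------------------------------------
# reading / writing stacks

def _normalise_axes(arr: np.ndarray, axes: str) -> np.ndarray:
    """Reorder an on-disk array with tifffile-style ``axes`` into (Z, Y, X, C).

    Missing Z or C axes are inserted with extent 1; singleton T/S axes are
    squeezed out.
    """
    axes = axes.upper()
    if len(axes) != arr.ndim:
        raise StackFormatError(f"axes {axes!r} does not match array of ndim {arr.ndim}")
    # drop singleton axes we do not model (time, sample, ...)
    drop = tuple(i for i, ax in enumerate(axes) if ax not in "ZYXC")
    for i in drop:
        if arr.shape[i] != 1:
            raise StackFormatError(
                f"unsupported non-singleton axis {axes[i]!r} in axes {axes!r}"
            )
    if drop:
        arr = np.squeeze(arr, axis=drop)
    axes = "".join(ax for ax in axes if ax in "ZYXC")
    if "Y" not in axes or "X" not in axes:
        raise StackFormatError(f"axes {axes!r} lack Y/X")
    for missing in ("Z", "C"):
        if missing not in axes:
            arr = arr[np.newaxis]
            axes = missing + axes
    order = [axes.index(ax) for ax in "ZYXC"]
    return np.transpose(arr, order)


def read_stack(
    path: str | Path,
    channel_roles: Mapping[str, int],
    voxel_size: tuple[float, float],
    axes: str | None = None,
    image_id: str | None = None,
) -> ImageStack:
    """Read a TIFF Z-stack into an :class:`ImageStack`.

    ``axes`` names the on-disk axis order (e.g. ``"ZCYX"``); when omitted the
    order recorded in the file metadata is used, falling back to the ImageJ
    hyperstack convention for bare arrays (trailing ``(Y, X)``, channel before
    that if 3D+, Z outermost).
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"no such image file: {path}")
    try:
        with tifffile.TiffFile(str(path)) as tf:
            series = tf.series[0]
            arr = series.asarray()
            file_axes = series.axes
    except FileNotFoundError:
        raise
    except Exception as exc:  # corrupt / not a TIFF
        raise OSError(f"could not read TIFF {path}: {exc}") from exc
    if axes is None:
        if file_axes and len(file_axes) == arr.ndim and set(file_axes.upper()) <= set("TZCYXSQI"):
            axes = file_axes.upper().replace("S", "C").replace("Q", "Z").replace("I", "Z")
        else:
            axes = "ZCYX"[-arr.ndim:] if arr.ndim <= 4 else None
    if axes is None:
        raise StackFormatError(f"cannot infer axis order for {path} with shape {arr.shape}")
    vox = _normalise_axes(arr, axes)
    return ImageStack(
        voxels=vox,
        voxel_size=tuple(voxel_size),
        channel_roles=dict(channel_roles),
        image_id=image_id if image_id is not None else path.stem,
    )


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write an :class:`ImageStack` as a ZCYX TIFF (lossless for integer data)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.transpose(stack.voxels, (0, 3, 1, 2))  # ZCYX
    tifffile.imwrite(str(path), data, photometric="minisblack", metadata={"axes": "ZCYX"})
    return path


# ---------------------------------------------------------------------------
# tables

_TABLE_NAMES = ("per_image", "per_patch", "per_cell", "per_focus")

TABLE_SCHEMAS: dict[str, list[str]] = {
    "per_image": [
        "image_id", "group", "n_patches", "loser_coverage_pct",
        "border_death_coverage_pct", "centre_death_coverage_pct", "n_cells",
        "n_apoptotic_border", "n_nonapoptotic_border", "pouch_volume_um3",
    ],
    "per_patch": [
        "image_id", "patch_id", "genotype", "volume_um3", "z_min", "z_max",
        "n_components_2d", "border_area_um2", "centre_area_um2",
        "border_foci_coverage", "centre_foci_coverage",
    ],
    "per_cell": [
        "image_id", "cell_id", "genotype", "cx_um", "cy_um", "cz_um", "z_plane",
        "dist_border_um", "dist_pouch_centre_um", "apoptotic",
        # mean_intensity_c<k> columns are appended per channel
        "pouch_volume_um3", "n_loser_cells", "n_winner_apoptotic",
    ],
    "per_focus": [
        "image_id", "focus_id", "cx_um", "cy_um", "cz_um", "volume_um3",
        "genotype_region", "border_or_centre", "nearest_cell_id",
    ],
}


def write_tables(tables: ResultTables, out_dir: str | Path) -> list[Path]:
    """Write the four result tables as CSV; returns written paths.

    Floats are serialised with ``repr`` round-trip precision so a re-read
    reproduces integers exactly and floats to well under 1e-9.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for name in _TABLE_NAMES:
            tab: pd.DataFrame = getattr(tables, name)
            if tab.empty and not len(tab.columns):
                tab = pd.DataFrame(columns=TABLE_SCHEMAS[name])
            p = out_dir / f"{name}.csv"
            tab.to_csv(p, index=False, lineterminator="\n")
            paths.append(p)
    except PermissionError as exc:
        raise OSError(f"cannot write result tables under {out_dir}: {exc}") from exc
    return paths


def read_tables(in_dir: str | Path) -> ResultTables:
    """Read back tables written by :func:`write_tables`."""
    in_dir = Path(in_dir)
    out = {}
    for name in _TABLE_NAMES:
        p = in_dir / f"{name}.csv"
        out[name] = pd.read_csv(p) if p.is_file() else pd.DataFrame()
    return ResultTables(**out)


# ---------------------------------------------------------------------------
# overlays

def _label_colour(label: int) -> np.ndarray:
    """Deterministic, run-independent colour for a label id (hash of the id)."""
    digest = hashlib.sha256(str(int(label)).encode()).digest()
    rgb = np.frombuffer(digest[:3], dtype=np.uint8).astype(float)
    # keep colours bright enough to see on dark background
    return (64 + rgb * (191 / 255)).astype(np.uint8)


def write_overlays(
    stack: ImageStack,
    labels: np.ndarray,
    out_dir: str | Path,
    apoptotic_ids: Sequence[int] = (),
    prefix: str = "overlay",
) -> list[Path]:
    """Render per-plane QC overlays of a label volume on the image.

    Each label id gets a deterministic colour; labels whose id is listed in
    ``apoptotic_ids`` are drawn with a white rim so flagged (dying) cells
    stand out.  Output PNGs are byte-reproducible for identical inputs.
    """
    labels = np.asarray(labels)
    if labels.shape != stack.voxels.shape[:3]:
        raise ValueError(
            f"label volume shape {labels.shape} does not match stack {stack.voxels.shape[:3]}"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    apoptotic = set(int(i) for i in apoptotic_ids)

    # background: first genotype channel if present, else channel 0, scaled
    bg_role = (stack.genotype_roles() or [None])[0]
    bg = stack.channel(bg_role) if bg_role else stack.voxels[..., 0]
    bg = bg.astype(float)
    vmax = bg.max() or 1.0

    # colour table covering every label present
    ids = np.unique(labels)
    ids = ids[ids > 0]
    lut = np.zeros((int(ids.max()) + 1 if ids.size else 1, 3), dtype=np.uint8)
    for i in ids:
        lut[int(i)] = _label_colour(int(i))

    paths = []
    for z in range(stack.n_planes):
        grey = (bg[z] / vmax * 120).astype(np.uint8)
        rgb = np.stack([grey, grey, grey], axis=-1)
        lab = labels[z]
        fg = lab > 0
        if fg.any():
            rgb[fg] = lut[lab[fg]]
            if apoptotic:
                from scipy import ndimage as ndi

                for i in apoptotic:
                    m = lab == i
                    if m.any():
                        rim = m & ~ndi.binary_erosion(m)
                        rgb[rim] = (255, 255, 255)
        p = out_dir / f"{prefix}_z{z:03d}.png"
        iio.imwrite(p, rgb)
        paths.append(p)
    return paths
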