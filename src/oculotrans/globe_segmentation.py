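"""Globe segmentation and centroid extraction.

The globe is delineated by seeded region growing — a 3-D generalisation of a
tolerance-based "wand" selection: starting from a seed voxel in the bright
vitreous, all 6-connected voxels whose intensity lies within a fractional
tolerance of the seed intensity are collected, then the region is closed,
hole-filled (which absorbs the darker lens) and reduced to its largest
connected component.  The segmented set is therefore the globe *interior*
(vitreous + lens); an optional ``shell_mm`` dilation adds the dark scleral
shell for sensitivity analyses.

The eyeball position proxy is the binary centroid: the unweighted arithmetic
mean of the member voxel centres, converted to millimetres per axis by the
(anisotropic) voxel spacing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .volume_io import GlobeMask, Volume

__all__ = [
    "SeedSpec",
    "CentroidMM",
    "SegmentationError",
    "segment_globe",
    "auto_seed",
    "centroid_mm",
    "mask_volume_ml",
    "dice",
    "estimate_rotation_deg",
    "find_lens_pole",
]

_STRUCT6 = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


class SegmentationError(RuntimeError):
    """Region growing failed (leak, bad seed, or empty result)."""


@dataclass
class SeedSpec:
    """Seed voxel and fractional intensity tolerance for region growing."""

    index: tuple[int, int, int] | str = "auto"  # voxel index or "auto"
    tolerance: float = 0.25
    side: str = "left"  # used only to resolve an "auto" seed

    def __post_init__(self) -> None:
        if not (0.0 < self.tolerance < 1.0):
            raise ValueError(f"tolerance must lie in (0, 1), got {self.tolerance}")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")


@dataclass
class CentroidMM:
    """Arithmetic-mean position of a mask's voxels, in mm (patient frame)."""

    x: float
    y: float
    z: float
    side: str = ""
    gaze: str = ""
    source: str = ""

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @classmethod
    def from_array(cls, p: Sequence[float], **kw) -> "CentroidMM":
        x, y, z = (float(v) for v in p)
        return cls(x=x, y=y, z=z, **kw)


def auto_seed(volume: Volume, side: str) -> tuple[int, int, int]:
    """Pick a vitreous seed: brightest voxel of the mean-filtered half-grid.

    ``side`` selects the patient half (+x is patient left); the 5-voxel mean
    filter suppresses noise spikes and small bright fiducials.
    """
    smooth = ndimage.uniform_filter(np.asarray(volume.data, float), size=5, mode="nearest")
    nx = volume.shape[0]
    half = slice(nx // 2, nx) if side == "left" else slice(0, nx // 2)
    sub = smooth[half]
    idx = np.unravel_index(int(np.argmax(sub)), sub.shape)
    return (idx[0] + (nx // 2 if side == "left" else 0), int(idx[1]), int(idx[2]))


def segment_globe(
    volume: Volume,
    seed: SeedSpec | None = None,
    shell_mm: float = 0.0,
    min_volume_ml: float = 1.0,
) -> GlobeMask:
    """Segment one globe by seeded 3-D region growing.

    Raises :class:`SegmentationError` if the grown region touches the grid
    boundary (a leak into surrounding tissue) or ends up smaller than
    ``min_volume_ml`` (a misplaced seed).
    """
    seed = seed or SeedSpec()
    data = np.asarray(volume.data, float)
    if seed.index == "auto":
        idx = auto_seed(volume, seed.side)
    else:
        idx = tuple(int(v) for v in seed.index)  # type: ignore[arg-type]
        if len(idx) != 3 or any(i < 0 or i >= n for i, n in zip(idx, volume.shape)):
            raise SegmentationError(f"seed index {idx} outside grid {volume.shape}")
    seed_val = float(data[idx])
    bg = float(threshold_otsu(data)) if data.max() > data.min() else data.max()
    if seed_val <= bg:
        raise SegmentationError(f"seed intensity {seed_val:.3g} not above background ({bg:.3g})")

    band = np.abs(data - seed_val) <= seed.tolerance * abs(seed_val)
    labels, _ = ndimage.label(band, structure=_STRUCT6)
    region = labels == labels[idx]
    if labels[idx] == 0:
        raise SegmentationError("seed voxel not inside its own tolerance band")

    faces = (region[0].any() or region[-1].any() or region[:, 0].any() or region[:, -1].any()
             or region[:, :, 0].any() or region[:, :, -1].any())
    if faces:
        raise SegmentationError("region grew to the grid boundary (leak)")

    region = ndimage.binary_closing(region, structure=_STRUCT6, iterations=1)
    region = ndimage.binary_fill_holes(region, structure=_STRUCT6)
    labels, n = ndimage.label(region, structure=_STRUCT6)
    if n == 0:
        raise SegmentationError("empty region after post-processing")
    region = labels == (np.argmax(ndimage.sum_labels(region, labels, np.arange(1, n + 1))) + 1)

    if shell_mm > 0:
        dist = ndimage.distance_transform_edt(~region, sampling=volume.spacing)
        region = dist <= shell_mm

    side = seed.side
    mask = GlobeMask(data=region, spacing=volume.spacing, side=side, gaze=volume.gaze, subject_id=volume.subject_id)
    if mask_volume_ml(mask) < min_volume_ml:
        raise SegmentationError(
            f"segmented region {mask_volume_ml(mask):.2f} ml below minimum {min_volume_ml} ml (bad seed?)"
        )
    return mask


def centroid_mm(mask: GlobeMask | np.ndarray, spacing: Sequence[float] | None = None, **meta) -> CentroidMM:
    """Unweighted mean of member voxel centres, each axis scaled by its spacing.

    This is the pixel-to-millimetre conversion done per axis, which matters
    because the voxels are anisotropic.
    """
    if isinstance(mask, GlobeMask):
        arr, sp = mask.data, np.asarray(mask.spacing, float)
        meta.setdefault("side", mask.side)
        meta.setdefault("gaze", mask.gaze)
    else:
        if spacing is None:
            raise ValueError("spacing required for a bare array mask")
        arr, sp = np.asarray(mask, bool), np.asarray(spacing, float)
    idx = np.argwhere(arr)
    if idx.size == 0:
        raise ValueError("cannot take the centroid of an empty mask")
    c = idx.mean(axis=0) * sp
    return CentroidMM.from_array(c, **meta)


def mask_volume_ml(mask: GlobeMask | np.ndarray, spacing: Sequence[float] | None = None) -> float:
    """Voxel count × voxel volume, in millilitres."""
    if isinstance(mask, GlobeMask):
        arr, sp = mask.data, mask.spacing
    else:
        if spacing is None:
            raise ValueError("spacing required for a bare array mask")
        arr, sp = np.asarray(mask, bool), spacing
    n = int(np.count_nonzero(arr))
    if n == 0:
        raise ValueError("empty mask has no volume")
    return n * float(np.prod(sp)) / 1000.0


def dice(a: np.ndarray | GlobeMask, b: np.ndarray | GlobeMask) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|)."""
    aa = a.data if isinstance(a, GlobeMask) else np.asarray(a, bool)
    bb = b.data if isinstance(b, GlobeMask) else np.asarray(b, bool)
    denom = aa.sum() + bb.sum()
    if denom == 0:
        raise ValueError("both masks empty")
    return float(2.0 * np.logical_and(aa, bb).sum() / denom)


_PLANE_AXES = {"axial": (0, 1), "sagittal": (1, 2)}


def estimate_rotation_deg(
    centroid1: CentroidMM,
    pole1: CentroidMM,
    centroid2: CentroidMM,
    pole2: CentroidMM,
    plane: str = "axial",
) -> float:
    """Globe rotation between two gazes from centroid→pole vectors.

    The anterior-pole landmark (the lens centroid in the phantom) and the
    globe centroid define a gaze vector per acquisition; the signed angle
    between the two vectors, projected into the analysis plane, estimates
    the rotation.  Because both vectors are differences of points that share
    any common translation, globe translation cancels.
    """
    if plane not in _PLANE_AXES:
        raise ValueError(f"plane must be one of {tuple(_PLANE_AXES)}, got {plane!r}")
    i, j = _PLANE_AXES[plane]
    v1 = (pole1.as_array() - centroid1.as_array())[[i, j]]
    v2 = (pole2.as_array() - centroid2.as_array())[[i, j]]
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-6 or n2 < 1e-6:
        raise ValueError("pole coincides with centroid; rotation undefined")
    cross = v1[0] * v2[1] - v1[1] * v2[0]
    dot = float(v1 @ v2)
    return float(np.degrees(np.arctan2(cross, dot)))


def find_lens_pole(volume: Volume, globe_mask: GlobeMask) -> CentroidMM:
    """Locate the lens inside a segmented globe and return its centroid.

    The lens is the dark inclusion in the bright interior: voxels of the
    filled globe mask darker than 60 % of the in-mask median, largest
    connected component.
    """
    data = np.asarray(volume.data, float)
    inside = data[globe_mask.data]
    med = float(np.median(inside))
    lens = globe_mask.data & (data < 0.6 * med)
    labels, n = ndimage.label(lens, structure=_STRUCT6)
    if n == 0:
        raise SegmentationError("no lens-like inclusion found in the globe mask")
    sizes = ndimage.sum_labels(lens, labels, np.arange(1, n + 1))
    lens = labels == (int(np.argmax(sizes)) + 1)
    return centroid_mm(lens, volume.spacing, side=globe_mask.side, gaze=globe_mask.gaze, source="lens")
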