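"""Volume and mask I/O with spacing/orientation metadata.

The in-memory containers are small dataclasses around numpy arrays, indexed
``(i, j, k)`` along the patient-frame axes ``(x, y, z)`` defined in
:mod:`oculotrans.geometry` (LAS: +x patient left, +y anterior, +z superior).
NIfTI files written by this module carry that frame in the affine; files in
other orientations are reoriented on read so downstream angle conventions
always see one frame.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom

GAZES = ("central", "right", "left", "up", "down")

__all__ = ["Volume", "GlobeMask", "read_volume", "write_volume", "read_mask", "write_mask", "read_dicom_series", "GAZES"]


@dataclass
class Volume:
    """A single-gaze volumetric image.

    ``data[i, j, k]`` is the intensity at patient-frame position
    ``(i*sx, j*sy, k*sz)`` mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    frame: str = "LAS"
    gaze: str = "central"
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.size == 0:
            raise ValueError("volume grid must be non-empty and 3-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        if self.gaze not in GAZES:
            raise ValueError(f"gaze must be one of {GAZES}, got {self.gaze!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def center_mm(self) -> np.ndarray:
        """Physical centre of the grid (rotation centre for head motion)."""
        return (np.asarray(self.shape) - 1) * np.asarray(self.spacing) / 2.0

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def with_data(self, data: np.ndarray, **overrides) -> "Volume":
        kw = dict(spacing=self.spacing, frame=self.frame, gaze=self.gaze, subject_id=self.subject_id)
        kw.update(overrides)
        return Volume(data=data, **kw)


@dataclass
class GlobeMask:
    """Binary voxel set for one eye, aligned to its parent :class:`Volume`."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    side: str
    gaze: str = "central"
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3-D")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        self.spacing = tuple(float(s) for s in self.spacing)

    def voxel_count(self) -> int:
        return int(self.data.sum())


def _las_affine(spacing) -> np.ndarray:
    # our array axes are (+x left, +y anterior, +z superior); NIfTI world is RAS,
    # so the first axis carries a negative column
    sx, sy, sz = spacing
    aff = np.diag([-sx, sy, sz, 1.0])
    return aff


def write_volume(volume: Volume, path: str | os.PathLike) -> Path:
    """Write a float32 NIfTI-1 with the spacing in the header (lossless)."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32), _las_affine(volume.spacing))
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))
    return path


def write_mask(mask: GlobeMask, path: str | os.PathLike) -> Path:
    """Write a binary mask as uint8 {0,1} NIfTI for viewer interoperability."""
    path = Path(path)
    img = nib.Nifti1Image(mask.data.astype(np.uint8), _las_affine(mask.spacing))
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))
    return path


def _raw_pixdim(path: Path) -> np.ndarray:
    """pixdim[1:4] straight from the file, before nibabel's header repair."""
    import gzip

    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rb") as fh:  # type: ignore[operator]
        hdr = nib.Nifti1Header.from_fileobj(fh, check=False)
    return np.asarray(hdr["pixdim"][1:4], float)


def _load_nifti_las(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    if np.any(_raw_pixdim(path) == 0):
        # refuse to guess: nibabel would silently substitute 1 mm
        raise ValueError(f"{path}: missing voxel spacing in header")
    img = nib.load(str(path))
    canonical = nib.as_closest_canonical(img)  # RAS
    data = np.asanyarray(canonical.dataobj)
    data = data[::-1, :, :].copy()  # RAS -> LAS
    # zooms are stored as float32 in the header; undo the representation error
    spacing = tuple(round(float(z), 6) for z in canonical.header.get_zooms()[:3])
    return data, spacing  # type: ignore[return-value]


def read_volume(path: str | os.PathLike, gaze: str = "central", subject_id: str = "") -> Volume:
    """Read a NIfTI file or a single-series DICOM directory into the LAS frame."""
    path = Path(path)
    if path.is_dir():
        return read_dicom_series(path, gaze=gaze, subject_id=subject_id)
    data, spacing = _load_nifti_las(path)
    return Volume(data=np.asarray(data, dtype=np.float32), spacing=spacing, gaze=gaze, subject_id=subject_id)


def read_mask(path: str | os.PathLike, side: str, gaze: str = "central", subject_id: str = "") -> GlobeMask:
    data, spacing = _load_nifti_las(Path(path))
    return GlobeMask(data=data > 0, spacing=spacing, side=side, gaze=gaze, subject_id=subject_id)


def read_dicom_series(directory: str | os.PathLike, gaze: str = "central", subject_id: str = "") -> Volume:
    """Read a directory of single-series axial DICOM slices.

    Slices are sorted by their position along the slice normal, so reversed or
    shuffled file order yields the same volume.  Only the canonical axial
    orientation (rows along patient-posterior, columns along patient-left) is
    supported; anything else, or a directory mixing series, is an error.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.suffix.lower() in (".dcm", ".ima") or p.is_file())
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f), force=False)
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise ValueError(f"{directory}: no DICOM slices found")
    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in slices}
    if len(uids) != 1:
        raise ValueError(f"{directory}: mixed DICOM series ({len(uids)} SeriesInstanceUIDs)")
    ref = slices[0]
    if not hasattr(ref, "PixelSpacing") or not hasattr(ref, "ImagePositionPatient"):
        raise ValueError(f"{directory}: DICOM slices missing PixelSpacing/ImagePositionPatient")
    iop = np.asarray(getattr(ref, "ImageOrientationPatient", [1, 0, 0, 0, 1, 0]), float)
    row_dir, col_dir = iop[:3], iop[3:]
    if not (np.allclose(row_dir, [1, 0, 0], atol=1e-3) and np.allclose(col_dir, [0, 1, 0], atol=1e-3)):
        raise ValueError("only canonical axial DICOM orientation is supported")
    normal = np.cross(row_dir, col_dir)  # LPS +z
    order = np.argsort([float(np.dot(np.asarray(ds.ImagePositionPatient, float), normal)) for ds in slices])
    slices = [slices[i] for i in order]
    positions = [float(np.dot(np.asarray(ds.ImagePositionPatient, float), normal)) for ds in slices]
    gaps = np.diff(positions)
    if len(gaps) and (np.any(gaps <= 0) or np.ptp(gaps) > 1e-3):
        raise ValueError("DICOM slice positions are not uniformly spaced")
    dz = float(gaps[0]) if len(gaps) else float(getattr(ref, "SliceThickness", 0.0))
    if dz <= 0:
        raise ValueError("cannot determine DICOM slice spacing")
    dr, dc = (float(v) for v in ref.PixelSpacing)  # row spacing, column spacing
    # pixel_array is (row, col) = (along +y_LPS posterior, along +x_LPS left)
    stack = np.stack([ds.pixel_array.astype(np.float32) for ds in slices], axis=-1)  # (row, col, z)
    data = np.transpose(stack, (1, 0, 2))  # (x_left, y_posterior, z_superior)
    data = data[:, ::-1, :].copy()  # LPS -> LAS (flip posterior to anterior)
    return Volume(data=data, spacing=(dc, dr, dz), gaze=gaze, subject_id=subject_id)
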