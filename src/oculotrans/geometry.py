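"""Rigid 3-D transforms in the patient frame.

Every module in the package works in one fixed patient frame:

* ``+x`` toward the patient's left, ``+y`` anterior, ``+z`` superior;
* world coordinates in millimetres; voxel index ``i`` along an axis maps to
  coordinate ``i * spacing`` (voxel centres sit at integer multiples of the
  spacing, the first voxel centre at the origin).

A :class:`RigidTransform` is a proper rigid point mapping
``p -> R @ p + o`` with ``R`` orthonormal, ``det R = +1``.  Convenience
constructors express the rotation as extrinsic x-y-z Euler angles about an
arbitrary centre, which is how head motion and registration results are
reported (angles in degrees, translations in millimetres).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = ["RigidTransform"]

_EPS_ORTHO = 1e-8


class RigidTransform:
    """Proper rigid transform ``p -> matrix @ p + offset`` (mm)."""

    __slots__ = ("matrix", "offset")

    def __init__(self, matrix: np.ndarray | None = None, offset: Sequence[float] | None = None):
        m = np.eye(3) if matrix is None else np.asarray(matrix, dtype=float)
        o = np.zeros(3) if offset is None else np.asarray(offset, dtype=float)
        if m.shape != (3, 3) or o.shape != (3,):
            raise ValueError("matrix must be 3x3 and offset length 3")
        if not (np.all(np.isfinite(m)) and np.all(np.isfinite(o))):
            raise ValueError("non-finite rigid transform")
        if not np.allclose(m @ m.T, np.eye(3), atol=1e-6) or abs(np.linalg.det(m) - 1.0) > 1e-6:
            raise ValueError("matrix is not a proper rotation (orthonormal, det +1)")
        # re-orthonormalise so long compositions stay rigid
        u, _, vt = np.linalg.svd(m)
        self.matrix = u @ vt
        self.offset = o

    # -- constructors ---------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_euler(
        cls,
        rotation_deg: Sequence[float] = (0.0, 0.0, 0.0),
        translation_mm: Sequence[float] = (0.0, 0.0, 0.0),
        center_mm: Sequence[float] = (0.0, 0.0, 0.0),
    ) -> "RigidTransform":
        """Rotation about ``center_mm`` followed by a translation.

        ``rotation_deg`` are extrinsic x-y-z Euler angles, i.e. the composite
        rotation is ``Rz @ Ry @ Rx``.  The point mapping is
        ``p -> R @ (p - c) + c + t``.
        """
        r = Rotation.from_euler("xyz", np.asarray(rotation_deg, float), degrees=True).as_matrix()
        c = np.asarray(center_mm, float)
        t = np.asarray(translation_mm, float)
        return cls(r, c + t - r @ c)

    @classmethod
    def from_axis_angle(
        cls,
        axis: Sequence[float],
        angle_deg: float,
        center_mm: Sequence[float] = (0.0, 0.0, 0.0),
        translation_mm: Sequence[float] = (0.0, 0.0, 0.0),
    ) -> "RigidTransform":
        ax = np.asarray(axis, float)
        n = np.linalg.norm(ax)
        if n == 0:
            raise ValueError("zero rotation axis")
        r = Rotation.from_rotvec(ax / n * np.deg2rad(angle_deg)).as_matrix()
        c = np.asarray(center_mm, float)
        t = np.asarray(translation_mm, float)
        return cls(r, c + t - r @ c)

    # -- algebra --------------------------------------------------------
    def apply(self, points: Iterable[float] | np.ndarray) -> np.ndarray:
        """Map one point (shape ``(3,)``) or many (shape ``(n, 3)``)."""
        p = np.asarray(points, dtype=float)
        single = p.ndim == 1
        p = np.atleast_2d(p)
        out = p @ self.matrix.T + self.offset
        return out[0] if single else out

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self ∘ other``: apply ``other`` first, then ``self``."""
        return RigidTransform(self.matrix @ other.matrix, self.matrix @ other.offset + self.offset)

    def inverse(self) -> "RigidTransform":
        rt = self.matrix.T
        return RigidTransform(rt, -rt @ self.offset)

    # -- reporting ------------------------------------------------------
    @property
    def rotation_deg(self) -> np.ndarray:
        """Extrinsic x-y-z Euler angles in degrees."""
        return Rotation.from_matrix(self.matrix).as_euler("xyz", degrees=True)

    def rotation_magnitude_deg(self) -> float:
        return float(np.rad2deg(Rotation.from_matrix(self.matrix).magnitude()))

    def translation_about(self, center_mm: Sequence[float] = (0.0, 0.0, 0.0)) -> np.ndarray:
        """Translation component when the rotation is taken about ``center_mm``."""
        c = np.asarray(center_mm, float)
        return self.apply(c) - c

    def is_identity(self, atol_deg: float = 1e-9, atol_mm: float = 1e-9) -> bool:
        return (
            self.rotation_magnitude_deg() <= atol_deg
            and float(np.max(np.abs(self.offset))) <= atol_mm
        )

    # -- serialisation --------------------------------------------------
    def to_dict(self, center_mm: Sequence[float] = (0.0, 0.0, 0.0)) -> dict:
        return {
            "convention": "extrinsic-xyz, patient frame LAS (+x left, +y anterior, +z superior)",
            "rotation_deg": [float(v) for v in self.rotation_deg],
            "translation_mm": [float(v) for v in self.translation_about(center_mm)],
            "center_mm": [float(v) for v in np.asarray(center_mm, float)],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls.from_euler(d["rotation_deg"], d["translation_mm"], d.get("center_mm", (0, 0, 0)))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        ang = np.round(self.rotation_deg, 4)
        return f"RigidTransform(rot_xyz={ang.tolist()} deg, offset={np.round(self.offset, 4).tolist()} mm)"
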