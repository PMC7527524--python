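"""Distance and direction of eyeball-centroid movement between gazes.

Horizontal gaze is analysed in the axial (x–y) plane, vertical gaze in the
sagittal (y–z) plane.  The direction convention follows the left eye: in the
axial plane medial = 0°, anterior = 90°, lateral = 180°, posterior = 270°;
for the right eye the medial component is sign-flipped (the "×(−1)" rule)
so both eyes share one convention.  In the sagittal plane anterior = 0°,
up = +90°, down = −90° for either eye.

The printed one-argument arctangent of a coordinate ratio is quadrant
ambiguous; the two-argument arctangent is used throughout, which is the only
reading consistent with reported directions beyond ±90°.  Angles can be
reported in the signed range (−180°, 180°] or the positive range [0°, 360°).

Displacements are computed from *points*: the secondary-gaze centroid is
mapped through the recovered head-motion transform rather than re-measured
on a resampled mask, preserving sub-voxel accuracy (vertical displacements
are typically below the 0.6 mm slice thickness).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .coregistration import (
    DEFAULT_RESIDUAL_THRESHOLD,
    AlignmentReport,
    build_static_mask,
    register_static,
)
from .globe_segmentation import (
    CentroidMM,
    SeedSpec,
    centroid_mm,
    estimate_rotation_deg,
    find_lens_pole,
    mask_volume_ml,
    segment_globe,
)
from .volume_io import Volume

__all__ = [
    "Displacement",
    "EyeFrame",
    "DisplacementConfig",
    "DisplacementResult",
    "StageError",
    "horizontal_displacement",
    "vertical_displacement",
    "wrap_angle",
    "end_to_end_displacement",
]

ANGLE_RANGES = ("signed", "positive")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def wrap_angle(theta: float, angle_range: str = "signed") -> float:
    """Canonical representative of an angle in the requested range.

    signed: (−180, 180];  positive: [0, 360).
    """
    if not math.isfinite(theta):
        raise ValueError("angle must be finite")
    if angle_range == "positive":
        return float(theta % 360.0)
    if angle_range == "signed":
        w = theta - 360.0 * math.floor((theta + 180.0) / 360.0)
        return 180.0 if w == -180.0 else float(w)
    raise ValueError(f"angle_range must be one of {ANGLE_RANGES}, got {angle_range!r}")


@dataclass
class EyeFrame:
    """Per-eye in-plane axes: medial unit vector and anterior ŷ."""

    side: str

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")

    @property
    def medial(self) -> np.ndarray:
        # patient frame has +x toward the patient's left; medial points at the nose
        return np.array([1.0, 0.0, 0.0]) if self.side == "right" else np.array([-1.0, 0.0, 0.0])

    @property
    def anterior(self) -> np.ndarray:
        return np.array([0.0, 1.0, 0.0])


@dataclass
class Displacement:
    """Distance d (mm) and direction theta (deg) of centroid movement.

    ``theta_deg`` is NaN, and ``theta_defined`` False, exactly when d = 0.
    ``out_of_plane_mm`` reports the component orthogonal to the analysis
    plane (not analysed, kept for transparency).
    """

    d: float
    theta_deg: float
    plane: str
    angle_range: str = "signed"
    side: str = ""
    gaze: str = ""
    out_of_plane_mm: float = float("nan")

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ValueError("distance must be >= 0")
        if self.plane not in ("axial", "sagittal"):
            raise ValueError(f"plane must be 'axial' or 'sagittal', got {self.plane!r}")
        if self.angle_range not in ANGLE_RANGES:
            raise ValueError(f"angle_range must be one of {ANGLE_RANGES}")

    @property
    def theta_defined(self) -> bool:
        return not math.isnan(self.theta_deg)

    def theta_in(self, angle_range: str) -> float:
        if not self.theta_defined:
            return float("nan")
        return wrap_angle(self.theta_deg, angle_range)


def _make_displacement(du: float, dv: float, plane: str, angle_range: str, side: str, gaze: str, out_of_plane: float) -> Displacement:
    d = math.hypot(du, dv)
    theta = float("nan") if d == 0.0 else wrap_angle(math.degrees(math.atan2(dv, du)), angle_range)
    return Displacement(d=d, theta_deg=theta, plane=plane, angle_range=angle_range, side=side, gaze=gaze, out_of_plane_mm=out_of_plane)


def _check_pair(c1: CentroidMM, c2: CentroidMM) -> None:
    if c1.side and c2.side and c1.side != c2.side:
        raise ValueError(f"centroids from different eyes: {c1.side!r} vs {c2.side!r}")


def horizontal_displacement(
    c1: CentroidMM, c2: CentroidMM, side: str, angle_range: str = "signed", gaze: str = ""
) -> Displacement:
    """Axial-plane displacement from central (c1) to horizontal gaze (c2).

    The medial component is the per-eye medial projection of Δx — for the
    right eye this is the ×(−1) mirroring of the raw x shift — so 0° is
    medial and 90° anterior for both eyes.
    """
    _check_pair(c1, c2)
    frame = EyeFrame(side)
    delta = c2.as_array() - c1.as_array()
    du = float(delta @ frame.medial)
    dv = float(delta @ frame.anterior)
    return _make_displacement(du, dv, "axial", angle_range, side, gaze, out_of_plane=float(delta[2]))


def vertical_displacement(
    c1: CentroidMM, c2: CentroidMM, angle_range: str = "signed", side: str = "", gaze: str = ""
) -> Displacement:
    """Sagittal-plane displacement: anterior = 0°, up = +90°, down = −90°."""
    _check_pair(c1, c2)
    delta = c2.as_array() - c1.as_array()
    return _make_displacement(float(delta[1]), float(delta[2]), "sagittal", angle_range, side, gaze, out_of_plane=float(delta[0]))


@dataclass
class DisplacementConfig:
    """Tunables for the end-to-end single-pair measurement."""

    seed_tolerance: float = 0.25
    shell_mm: float = 0.0
    min_volume_ml: float = 1.0
    dilation_mm: float = 3.0
    residual_threshold: float = DEFAULT_RESIDUAL_THRESHOLD
    bounds_deg: float = 10.0
    bounds_mm: float = 10.0
    angle_range: str = "signed"
    register: bool = True  # disable only for pre-aligned volumes


@dataclass
class DisplacementResult:
    displacement: Displacement
    alignment: AlignmentReport
    centroid_primary: CentroidMM
    centroid_secondary_aligned: CentroidMM
    rotation_deg: float = float("nan")
    globe_volume_ml: float = float("nan")
    info: dict = field(default_factory=dict)


def _gaze_plane(gaze: str) -> str:
    if gaze in ("right", "left"):
        return "axial"
    if gaze in ("up", "down"):
        return "sagittal"
    raise ValueError(f"secondary volume must have an eccentric gaze label, got {gaze!r}")


def end_to_end_displacement(
    primary: Volume,
    secondary: Volume,
    side: str,
    config: DisplacementConfig | None = None,
) -> DisplacementResult:
    """Segment, register on static tissue, and measure one eye's displacement.

    Orchestrates: globe segmentation in both volumes (both eyes in the
    primary, to mask them out of the registration), static-tissue rigid
    registration, mapping of the secondary centroid through the recovered
    transform as a point, and the plane displacement appropriate for the
    secondary gaze.  Stage failures raise :class:`StageError` naming the
    stage.
    """
    cfg = config or DisplacementConfig()
    plane = _gaze_plane(secondary.gaze)

    def run(stage, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError(stage, str(exc)) from exc

    masks1 = {
        s: run(
            "segment-primary",
            segment_globe,
            primary,
            SeedSpec(tolerance=cfg.seed_tolerance, side=s),
            shell_mm=cfg.shell_mm,
            min_volume_ml=cfg.min_volume_ml,
        )
        for s in ("right", "left")
    }
    mask2 = run(
        "segment-secondary",
        segment_globe,
        secondary,
        SeedSpec(tolerance=cfg.seed_tolerance, side=side),
        shell_mm=cfg.shell_mm,
        min_volume_ml=cfg.min_volume_ml,
    )
    c1 = centroid_mm(masks1[side])
    c2 = centroid_mm(mask2)

    if cfg.register:
        static = run("static-mask", build_static_mask, primary, list(masks1.values()), cfg.dilation_mm)
        report = run(
            "register",
            register_static,
            secondary,
            primary,
            static,
            bounds_deg=cfg.bounds_deg,
            bounds_mm=cfg.bounds_mm,
            threshold=cfg.residual_threshold,
        )
    else:
        from .geometry import RigidTransform

        report = AlignmentReport(
            residual=0.0, passed=True, transform=RigidTransform.identity(), threshold=cfg.residual_threshold
        )

    c2_aligned = CentroidMM.from_array(
        report.transform.apply(c2.as_array()), side=side, gaze=secondary.gaze, source="aligned"
    )

    if plane == "axial":
        disp = horizontal_displacement(c1, c2_aligned, side, angle_range=cfg.angle_range, gaze=secondary.gaze)
    else:
        disp = vertical_displacement(c1, c2_aligned, angle_range=cfg.angle_range, side=side, gaze=secondary.gaze)

    rotation = float("nan")
    try:
        pole1 = find_lens_pole(primary, masks1[side])
        pole2 = find_lens_pole(secondary, mask2)
        pole2_aligned = CentroidMM.from_array(report.transform.apply(pole2.as_array()), side=side)
        rotation = estimate_rotation_deg(c1, pole1, c2_aligned, pole2_aligned, plane=plane)
    except Exception:  # noqa: BLE001 - rotation is auxiliary; NaN when no pole landmark
        pass

    return DisplacementResult(
        displacement=disp,
        alignment=report,
        centroid_primary=c1,
        centroid_secondary_aligned=c2_aligned,
        rotation_deg=rotation,
        globe_volume_ml=mask_volume_ml(masks1[side]),
        info={"centroid_secondary_raw": c2},
    )
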