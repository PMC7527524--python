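"""Synthetic multi-gaze orbital phantom with known ground truth.

The study design this package analyses acquires one T2-weighted orbital
volume per gaze direction (central, right, left, up, down; 0.7 × 0.7 × 0.6 mm
voxels, 256 × 256 × 67 grid) with fixation targets at 30° (horizontal) and
20° (vertical) eccentricity.  Real acquisitions of that kind are not
redistributable, so this module renders a digital stand-in that reproduces
the features the downstream pipeline depends on:

* two ellipsoidal globes (bright vitreous interior, dark 1 mm scleral shell,
  embedded dark lens near the anterior pole) inside orbital fat;
* static structures — fat, bony walls, four point fiducials — identical in
  the scene frame across gazes;
* each secondary gaze rendered with the globe *rotated about its own centre*
  by the fixation angle AND the centre *translated* by a configurable
  sub-millimetre vector (the quantity the pipeline is built to recover);
* a random rigid head-motion perturbation between acquisitions, and additive
  Gaussian acquisition noise.

Everything is rendered analytically (ellipsoid occupancy with sub-voxel
supersampling), so ground truth — rotation, translation, head motion, and
binary truth masks — is exact and returned alongside the volumes.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .geometry import RigidTransform
from .volume_io import GAZES, GlobeMask, Volume, write_volume

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "GazeTruth",
    "generate_phantom",
    "apply_rigid",
    "default_true_translations",
    "small_test_config",
    "write_phantom",
    "ConfigError",
    "GeometryError",
]

SIDES = ("right", "left")  # patient right at -x side of midline, left at +x

# T2-like tissue intensities; arbitrary but fixed.  Registration and
# segmentation must not depend on the absolute values.
INTENSITY = {
    "background": 0.0,
    "fat": 0.6,
    "bone": 0.05,
    "sclera": 0.2,
    "vitreous": 1.0,
    "lens": 0.35,
    "landmark": 0.9,
    "soft_tissue": 0.55,
}

# Per-contrast cohort-mean displacement (d mm, theta deg) used for the default
# true translations: distance/direction of globe-centre movement measured in
# the plane conventions of the kinematics module (axial plane in the left-eye
# convention for horizontal gaze, sagittal plane for vertical gaze).
CONTRAST_DISPLACEMENT = {
    "abduction": (0.69, -131.3),
    "adduction": (0.68, -4.2),
    "elevation": (0.43, -96.8),
    "depression": (0.44, 101.8),
}


class ConfigError(ValueError):
    """Invalid phantom configuration."""


class GeometryError(ValueError):
    """Configured scene does not fit the grid."""


def contrast_for(gaze: str, side: str) -> str:
    """Map (gaze, eye side) to the movement contrast of that eye."""
    if gaze == "up":
        return "elevation"
    if gaze == "down":
        return "depression"
    if gaze in ("right", "left"):
        return "abduction" if gaze == side else "adduction"
    raise ValueError(f"no contrast for gaze {gaze!r}")


def _contrast_vector(gaze: str, side: str, d_mm: float, theta_deg: float) -> np.ndarray:
    """Patient-frame translation vector from in-plane (d, theta).

    Horizontal: theta is measured with medial = 0 deg, anterior = 90 deg
    (left-eye convention); medial is -x for the left eye, +x for the right.
    Vertical: anterior = 0 deg, up = 90 deg; identical for both eyes.
    """
    th = math.radians(theta_deg)
    if gaze in ("right", "left"):
        du, dv = d_mm * math.cos(th), d_mm * math.sin(th)  # medial, anterior
        dx = du if side == "right" else -du
        return np.array([dx, dv, 0.0])
    dy, dz = d_mm * math.cos(th), d_mm * math.sin(th)
    return np.array([0.0, dy, dz])


def default_true_translations() -> dict[str, dict[str, np.ndarray]]:
    """Default per-gaze, per-eye globe-centre translations (mm, scene frame).

    Derived from the cohort-mean per-contrast displacements in
    :data:`CONTRAST_DISPLACEMENT`; horizontally the globes move with the gaze,
    vertically against it.
    """
    out: dict[str, dict[str, np.ndarray]] = {}
    for gaze in ("right", "left", "up", "down"):
        out[gaze] = {}
        for side in SIDES:
            d, th = CONTRAST_DISPLACEMENT[contrast_for(gaze, side)]
            out[gaze][side] = _contrast_vector(gaze, side, d, th)
    return out


@dataclass
class PhantomConfig:
    """Geometry, motion and acquisition parameters of the phantom.

    Defaults reproduce the study acquisition: 256 × 256 × 67 grid at
    0.7 × 0.7 × 0.6 mm, emmetropic axial length 25.27 mm (spherical globes of
    that diameter), fixation targets at 30°/20°, head motion capped at
    2°/2 mm, noise at 2 % of the vitreous intensity.
    """

    grid_shape: tuple[int, int, int] = (256, 256, 67)
    spacing: tuple[float, float, float] = (0.7, 0.7, 0.6)
    axial_length: float = 25.27
    globe_semi_axes: tuple[float, float, float] | None = None  # default: sphere of radius AL/2
    sclera_thickness_mm: float = 1.0
    interpupillary_offset: float | None = None  # each globe centre's |x| from midline
    globe_center_y: float | None = None
    gaze_angle_horizontal_deg: float = 30.0
    gaze_angle_vertical_deg: float = 20.0
    true_translation: Mapping[str, Mapping[str, Sequence[float]]] | None = None
    head_motion_max_rotation_deg: float = 2.0
    head_motion_max_translation_mm: float = 2.0
    noise_sd: float = 0.02  # fraction of the vitreous intensity
    supersample: int = 3
    seed: int = 0
    gazes: tuple[str, ...] = GAZES

    # ---- derived geometry --------------------------------------------
    def semi_axes(self) -> np.ndarray:
        if self.globe_semi_axes is not None:
            return np.asarray(self.globe_semi_axes, float)
        r = self.axial_length / 2.0
        return np.array([r, r, r])

    def inner_semi_axes(self) -> np.ndarray:
        return self.semi_axes() - self.sclera_thickness_mm

    def extent_mm(self) -> np.ndarray:
        return (np.asarray(self.grid_shape) - 1) * np.asarray(self.spacing)

    def grid_center(self) -> np.ndarray:
        return self.extent_mm() / 2.0

    def ipd_half(self) -> float:
        if self.interpupillary_offset is not None:
            return float(self.interpupillary_offset)
        return 2.45 * float(np.max(self.semi_axes()))

    def globe_y(self) -> float:
        if self.globe_center_y is not None:
            return float(self.globe_center_y)
        return 0.67 * float(self.extent_mm()[1])

    def globe_center(self, side: str) -> np.ndarray:
        cx, _, cz = self.grid_center()
        sign = -1.0 if side == "right" else 1.0  # patient right sits at -x
        return np.array([cx + sign * self.ipd_half(), self.globe_y(), cz])

    def translations(self) -> dict[str, dict[str, np.ndarray]]:
        if self.true_translation is None:
            return default_true_translations()
        out: dict[str, dict[str, np.ndarray]] = {}
        for gaze in ("right", "left", "up", "down"):
            out[gaze] = {}
            for side in SIDES:
                vec = (
                    self.true_translation.get(gaze, {}).get(side, (0.0, 0.0, 0.0))
                    if isinstance(self.true_translation, Mapping)
                    else (0.0, 0.0, 0.0)
                )
                out[gaze][side] = np.asarray(vec, float)
        return out

    def validate(self) -> None:
        shp = np.asarray(self.grid_shape)
        if shp.shape != (3,) or np.any(shp < 8):
            raise ConfigError(f"grid_shape must be three sizes >= 8, got {self.grid_shape}")
        if any(s <= 0 for s in self.spacing):
            raise ConfigError("all spacings must be > 0")
        if self.supersample < 1 or int(self.supersample) != self.supersample:
            raise ConfigError("supersample must be an integer >= 1")
        for name, ang in (
            ("horizontal", self.gaze_angle_horizontal_deg),
            ("vertical", self.gaze_angle_vertical_deg),
        ):
            # 0 deg is allowed so pure-translation / identity studies are expressible
            if not (0.0 <= ang <= 45.0):
                raise ConfigError(f"{name} gaze angle must lie in [0, 45] deg, got {ang}")
        semi = self.semi_axes()
        if np.any(semi <= 0) or np.any(self.inner_semi_axes() <= 0):
            raise ConfigError("degenerate globe semi-axes (check sclera thickness)")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        # both globes, at every configured gaze translation, must stay 5 mm
        # inside the sampled grid
        margin = 5.0
        extent = self.extent_mm()
        trans = self.translations()
        for side in SIDES:
            c = self.globe_center(side)
            for gaze in GAZES:
                t = np.zeros(3) if gaze == "central" else trans[gaze][side]
                lo = c + t - np.max(semi)
                hi = c + t + np.max(semi)
                if np.any(lo < margin) or np.any(hi > extent - margin):
                    raise GeometryError(
                        f"globe ({side}, {gaze}) extends within {margin} mm of the grid "
                        f"boundary: centre {c + t}, semi-axes {semi}, extent {extent}"
                    )


# ---------------------------------------------------------------------------
# ellipsoid rendering
# ---------------------------------------------------------------------------


@dataclass
class _Ellipsoid:
    center: np.ndarray
    semi_axes: np.ndarray
    rot: np.ndarray  # 3x3, local -> world
    value: float

    def transformed(self, t: RigidTransform) -> "_Ellipsoid":
        return _Ellipsoid(t.apply(self.center), self.semi_axes, t.matrix @ self.rot, self.value)

    def volume_mm3(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * math.pi * a * b * c


def _occupancy(shape, spacing, e: _Ellipsoid, supersample: int):
    """Fractional in-ellipsoid occupancy on the bounding-box subgrid.

    Returns ``(slices, occ)`` or ``None`` when the ellipsoid misses the grid.
    Occupancy is the mean of ``supersample**3`` inside-tests per voxel.
    """
    spacing = np.asarray(spacing, float)
    # conservative world-axis half extents of a rotated ellipsoid
    half = np.sqrt(((e.rot * e.semi_axes[None, :]) ** 2).sum(axis=1))
    lo = np.maximum(np.floor((e.center - half) / spacing).astype(int) - 1, 0)
    hi = np.minimum(np.ceil((e.center + half) / spacing).astype(int) + 2, np.asarray(shape))
    if np.any(hi <= lo):
        return None
    axes_idx = [np.arange(lo[d], hi[d]) for d in range(3)]
    grid = np.stack(np.meshgrid(*axes_idx, indexing="ij"), axis=-1).astype(float)  # (nx,ny,nz,3)
    centers = grid.reshape(-1, 3) * spacing  # voxel-centre world coords
    s = int(supersample)
    off1 = (np.arange(s) + 0.5) / s - 0.5
    offs = np.stack(np.meshgrid(off1, off1, off1, indexing="ij"), axis=-1).reshape(-1, 3) * spacing
    pts = centers[:, None, :] + offs[None, :, :]  # (nvox, s^3, 3)
    local = (pts - e.center) @ e.rot  # world -> local axes (rot columns are local axes)
    r2 = ((local / e.semi_axes) ** 2).sum(axis=-1)
    occ = (r2 <= 1.0).mean(axis=1).reshape([len(a) for a in axes_idx])
    sl = tuple(slice(int(lo[d]), int(hi[d])) for d in range(3))
    return sl, occ


def _paint(canvas: np.ndarray, shape, spacing, e: _Ellipsoid, supersample: int) -> None:
    res = _occupancy(shape, spacing, e, supersample)
    if res is None:
        return
    sl, occ = res
    region = canvas[sl]
    canvas[sl] = region * (1.0 - occ) + e.value * occ


def _binary_mask(shape, spacing, e: _Ellipsoid, supersample: int) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    res = _occupancy(shape, spacing, e, supersample)
    if res is not None:
        sl, occ = res
        mask[sl] = occ >= 0.5
    return mask


# ---------------------------------------------------------------------------
# scene construction
# ---------------------------------------------------------------------------


def _static_primitives(cfg: PhantomConfig) -> list[_Ellipsoid]:
    a = float(np.max(cfg.semi_axes()))
    cx, _, cz = cfg.grid_center()
    gy = cfg.globe_y()
    eye = np.eye(3)
    prims: list[_Ellipsoid] = []
    # orbital fat around each globe (slightly posterior of the globe centre)
    fat_z = min(1.5 * a, cz - 0.5)
    for side in SIDES:
        gc = cfg.globe_center(side)
        prims.append(
            _Ellipsoid(np.array([gc[0], gy - 0.6 * a, cz]), np.array([1.5 * a, 2.1 * a, fat_z]), eye, INTENSITY["fat"])
        )
    # bone: nasal bridge, lateral walls, orbital apex slab (elongated ellipsoids)
    prims.append(_Ellipsoid(np.array([cx, gy, cz]), np.array([0.32 * a, 2.0 * a, 1.2 * a]), eye, INTENSITY["bone"]))
    for sign in (-1.0, 1.0):
        prims.append(
            _Ellipsoid(
                np.array([cx + sign * (cfg.ipd_half() + 1.6 * a), gy, cz]),
                np.array([0.25 * a, 2.0 * a, 1.2 * a]),
                eye,
                INTENSITY["bone"],
            )
        )
    prims.append(
        _Ellipsoid(np.array([cx, gy - 2.8 * a, cz]), np.array([cfg.ipd_half() + a, 0.4 * a, 1.2 * a]), eye, INTENSITY["bone"])
    )
    # posterior soft-tissue canal per side (optic nerve / muscle cone): merges
    # with the orbital fat, passes through the apex bone, and leaves the field
    # of view posteriorly, so a region grow seeded in fat can escape the grid
    # (the leak the segmenter must detect).  Painted after the bone.
    for side in SIDES:
        gc = cfg.globe_center(side)
        prims.append(
            _Ellipsoid(
                np.array([gc[0], 0.0, cz]),
                np.array([0.8 * a, max(gy - 2.4 * a, 0.6 * a), 0.8 * a]),
                eye,
                INTENSITY["soft_tissue"],
            )
        )
    # four bright point fiducials (asymmetric placement gives the registration
    # leverage in every degree of freedom)
    r = max(0.12 * a, 0.9)
    for pos in (
        (cx - 3.2 * a, gy - 2.0 * a, cz + 0.8 * a),
        (cx + 3.2 * a, gy - 2.0 * a, cz - 0.8 * a),
        (cx - 1.2 * a, gy - 3.6 * a, cz - 0.64 * a),
        (cx + 1.2 * a, gy - 3.6 * a, cz + 0.64 * a),
    ):
        prims.append(_Ellipsoid(np.asarray(pos, float), np.array([r, r, r]), eye, INTENSITY["landmark"]))
    return prims


def _gaze_rotation(cfg: PhantomConfig, gaze: str) -> tuple[float, np.ndarray]:
    """(angle deg, axis) of the globe rotation for a gaze, in the scene frame."""
    if gaze == "central":
        return 0.0, np.array([0.0, 0.0, 1.0])
    if gaze == "right":
        return cfg.gaze_angle_horizontal_deg, np.array([0.0, 0.0, 1.0])
    if gaze == "left":
        return cfg.gaze_angle_horizontal_deg, np.array([0.0, 0.0, -1.0])
    if gaze == "up":
        return cfg.gaze_angle_vertical_deg, np.array([1.0, 0.0, 0.0])
    if gaze == "down":
        return cfg.gaze_angle_vertical_deg, np.array([-1.0, 0.0, 0.0])
    raise ValueError(f"unknown gaze {gaze!r}")


def _globe_primitives(cfg: PhantomConfig, gaze: str):
    """Globe layers + per-side geometry records for one gaze (scene frame)."""
    angle, axis = _gaze_rotation(cfg, gaze)
    trans = cfg.translations()
    semi = cfg.semi_axes()
    inner = cfg.inner_semi_axes()
    prims: list[_Ellipsoid] = []
    records = {}
    for side in SIDES:
        c0 = cfg.globe_center(side)
        t = np.zeros(3) if gaze == "central" else trans[gaze][side]
        rot = RigidTransform.from_axis_angle(axis, angle).matrix
        c = c0 + t
        # lens embedded strictly inside the vitreous, on the gaze axis; its
        # centroid serves as the anterior-pole landmark for rotation estimates
        lens_local = np.array([0.0, 0.55 * inner[1], 0.0])
        lens_c = c0 + rot @ lens_local + t
        lens_semi = np.array([0.4 * inner[0], 0.28 * inner[1], 0.4 * inner[2]])
        prims.append(_Ellipsoid(c, semi.copy(), rot, INTENSITY["sclera"]))
        prims.append(_Ellipsoid(c, inner.copy(), rot, INTENSITY["vitreous"]))
        prims.append(_Ellipsoid(lens_c, lens_semi, rot, INTENSITY["lens"]))
        records[side] = {
            "center_scene": c,
            "translation": t,
            "outer": _Ellipsoid(c, semi.copy(), rot, 1.0),
            "inner": _Ellipsoid(c, inner.copy(), rot, 1.0),
            "lens_center_scene": lens_c,
        }
    return angle, axis, prims, records


# ---------------------------------------------------------------------------
# truth containers
# ---------------------------------------------------------------------------


@dataclass
class GazeTruth:
    """Ground truth for one generated gaze volume."""

    gaze: str
    rotation_angle_deg: float
    rotation_axis: np.ndarray
    translation_mm: dict[str, np.ndarray]  # per side, scene (primary patient) frame
    head_motion: RigidTransform
    globe_center_scene_mm: dict[str, np.ndarray]
    globe_center_acq_mm: dict[str, np.ndarray]
    lens_center_acq_mm: dict[str, np.ndarray]
    globe_mask: dict[str, np.ndarray]  # interior (vitreous+lens) truth, acquisition frame
    globe_outer_mask: dict[str, np.ndarray]  # full globe incl. scleral shell


@dataclass
class PhantomTruth:
    """Full truth record: per-gaze :class:`GazeTruth` plus static orbit masks."""

    config: PhantomConfig
    gaze: dict[str, GazeTruth]
    orbit_mask: dict[str, np.ndarray]  # per side, central frame

    def globe_mask_as(self, gaze: str, side: str, kind: str = "interior") -> GlobeMask:
        arr = self.gaze[gaze].globe_mask[side] if kind == "interior" else self.gaze[gaze].globe_outer_mask[side]
        return GlobeMask(data=arr, spacing=self.config.spacing, side=side, gaze=gaze)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def generate_phantom(cfg: PhantomConfig) -> tuple[dict[str, Volume], PhantomTruth]:
    """Render one phantom subject: one volume per configured gaze plus truth.

    Deterministic: the same config (including seed) yields bit-identical
    volumes and truth, independent of which subset of gazes is rendered.
    """
    cfg.validate()
    shape = tuple(int(n) for n in cfg.grid_shape)
    spacing = cfg.spacing
    center = cfg.grid_center()
    statics = _static_primitives(cfg)

    # draw head motion for all four secondary gazes in fixed order so a gaze
    # subset does not change the draws
    rng = np.random.default_rng(cfg.seed)
    head: dict[str, RigidTransform] = {"central": RigidTransform.identity()}
    for gaze in ("right", "left", "up", "down"):
        rot = rng.uniform(-cfg.head_motion_max_rotation_deg, cfg.head_motion_max_rotation_deg, 3)
        tra = rng.uniform(-cfg.head_motion_max_translation_mm, cfg.head_motion_max_translation_mm, 3)
        head[gaze] = RigidTransform.from_euler(rot, tra, center_mm=center)

    volumes: dict[str, Volume] = {}
    truths: dict[str, GazeTruth] = {}
    orbit_mask: dict[str, np.ndarray] = {}

    for gaze in GAZES:
        if gaze not in cfg.gazes:
            continue
        h = head[gaze]
        angle, axis, globes, records = _globe_primitives(cfg, gaze)
        canvas = np.zeros(shape, dtype=np.float64)
        for e in statics + globes:
            _paint(canvas, shape, spacing, e.transformed(h), cfg.supersample)
        if cfg.noise_sd > 0:
            noise_rng = np.random.default_rng([int(cfg.seed), GAZES.index(gaze), 7919])
            canvas = canvas + noise_rng.normal(0.0, cfg.noise_sd * INTENSITY["vitreous"], shape)
        vol = Volume(data=canvas.astype(np.float32), spacing=spacing, gaze=gaze)
        volumes[gaze] = vol

        g = GazeTruth(
            gaze=gaze,
            rotation_angle_deg=0.0 if gaze == "central" else angle,
            rotation_axis=axis,
            translation_mm={s: records[s]["translation"] for s in SIDES},
            head_motion=h,
            globe_center_scene_mm={s: records[s]["center_scene"] for s in SIDES},
            globe_center_acq_mm={s: h.apply(records[s]["center_scene"]) for s in SIDES},
            lens_center_acq_mm={s: h.apply(records[s]["lens_center_scene"]) for s in SIDES},
            globe_mask={
                s: _binary_mask(shape, spacing, records[s]["inner"].transformed(h), cfg.supersample) for s in SIDES
            },
            globe_outer_mask={
                s: _binary_mask(shape, spacing, records[s]["outer"].transformed(h), cfg.supersample) for s in SIDES
            },
        )
        truths[gaze] = g
        if gaze == "central":
            a = float(np.max(cfg.semi_axes()))
            cz = center[2]
            fat_z = min(1.5 * a, cz - 0.5)
            for side in SIDES:
                gc = cfg.globe_center(side)
                fat = _Ellipsoid(
                    np.array([gc[0], cfg.globe_y() - 0.6 * a, cz]),
                    np.array([1.5 * a, 2.1 * a, fat_z]),
                    np.eye(3),
                    1.0,
                )
                orbit_mask[side] = _binary_mask(shape, spacing, fat, cfg.supersample)

    return volumes, PhantomTruth(config=cfg, gaze=truths, orbit_mask=orbit_mask)


def apply_rigid(volume: Volume, transform: RigidTransform, interpolation: str = "linear", background: float = 0.0) -> Volume:
    """Resample ``volume`` moved *by* ``transform`` onto its own grid.

    The output satisfies ``out(x) = in(T^{-1} x)``: a feature at point ``p``
    appears at ``T(p)`` afterwards.  Out-of-field voxels take ``background``.
    """
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"interpolation must be 'linear' or 'nearest', got {interpolation!r}")
    inv = transform.inverse()
    s = np.asarray(volume.spacing, float)
    matrix = (inv.matrix * s[None, :]) / s[:, None]  # diag(1/s) @ R @ diag(s)
    offset = inv.offset / s
    order = 1 if interpolation == "linear" else 0
    data = ndimage.affine_transform(
        np.asarray(volume.data, dtype=np.float64 if order else volume.data.dtype),
        matrix,
        offset=offset,
        order=order,
        mode="constant",
        cval=background,
    )
    return volume.with_data(data.astype(volume.data.dtype))


def small_test_config(seed: int = 0, **overrides) -> PhantomConfig:
    """Desk-scale phantom (96 × 96 × 48 grid, 15 mm globes, same spacing).

    Same motion model and intensities as the full-size default; used where a
    full 256 × 256 × 67 render would be needlessly slow.
    """
    kw = dict(grid_shape=(96, 96, 48), axial_length=15.0, seed=seed)
    kw.update(overrides)
    return PhantomConfig(**kw)


def write_phantom(volumes: dict[str, Volume], truth: PhantomTruth, outdir: str | Path) -> Path:
    """Write volumes as NIfTI and the scalar truth record as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for gaze, vol in volumes.items():
        write_volume(vol, outdir / f"{gaze}.nii.gz")
    center = truth.config.grid_center()
    rec = {}
    for gaze, g in truth.gaze.items():
        rec[gaze] = {
            "rotation_angle_deg": float(g.rotation_angle_deg),
            "rotation_axis": [float(v) for v in g.rotation_axis],
            "translation_mm": {s: [float(v) for v in g.translation_mm[s]] for s in SIDES},
            "head_motion": g.head_motion.to_dict(center_mm=center),
            "globe_center_scene_mm": {s: [float(v) for v in g.globe_center_scene_mm[s]] for s in SIDES},
        }
    cfgd = dataclasses.asdict(truth.config)
    cfgd["true_translation"] = {
        gz: {s: [float(v) for v in vec] for s, vec in per.items()} for gz, per in truth.config.translations().items()
    }
    (outdir / "truth.json").write_text(json.dumps({"config": cfgd, "gaze": rec}, indent=2, default=str))
    return outdir
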