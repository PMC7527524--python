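"""End-to-end orchestration: volumes in, displacement CSV and tables out.

A run processes a cohort of subjects — either phantom-generated (the default
when no file manifest is given) or loaded from per-gaze NIfTI paths — through
segmentation, static-tissue registration, displacement measurement, one-eye
selection and the cohort tables.  Every seed, threshold and alignment
residual lands in a JSON run log so each number in the output tables is
reproducible from the log alone.  Failing subjects are excluded with a
logged reason; the run only fails outright if every subject fails.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_stats import build_tables
from .globe_segmentation import mask_volume_ml
from .kinematics import DisplacementConfig, end_to_end_displacement, wrap_angle
from .phantom import PhantomConfig, generate_phantom
from .volume_io import GAZES, Volume, read_volume

__all__ = ["RunConfig", "RunReport", "run_all", "load_run_config"]

GAZE_ORDER = GAZES  # central first, then right, left, up, down (scan order)

DISPLACEMENT_COLUMNS = [
    "subject",
    "gaze",
    "side",
    "d_mm",
    "theta_signed_deg",
    "theta_positive_deg",
    "out_of_plane_mm",
    "alignment_residual",
    "rotation_deg",
]


@dataclass
class RunConfig:
    """Configuration of a full cohort run."""

    outdir: str = "oculotrans_run"
    subjects: list[dict] = field(default_factory=list)  # [{id, volumes: {gaze: path}}]
    n_phantom_subjects: int = 0  # used when no file manifest is given
    phantom: dict = field(default_factory=dict)  # PhantomConfig overrides
    phantom_seed: int = 0
    eye_selection_seed: int = 0
    displacement: dict = field(default_factory=dict)  # DisplacementConfig overrides
    sides: tuple[str, ...] = ("right", "left")
    qc_overlays: bool = True

    def displacement_config(self) -> DisplacementConfig:
        return DisplacementConfig(**self.displacement)


@dataclass
class RunReport:
    outdir: Path
    displacements: pd.DataFrame
    table1: pd.DataFrame
    table2: pd.DataFrame
    n_subjects: int
    n_failed: int
    exclusions: dict[str, str]

    @property
    def exit_code(self) -> int:
        return 0 if self.n_failed == 0 else 3


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def _phantom_subject(cfg: RunConfig, index: int) -> tuple[str, dict[str, Volume], object]:
    overrides = dict(cfg.phantom)
    overrides["seed"] = int(cfg.phantom_seed + index)
    pcfg = PhantomConfig(**overrides)
    volumes, truth = generate_phantom(pcfg)
    return f"P{index:03d}", volumes, truth


def _load_subject(entry: dict) -> tuple[str, dict[str, Volume], None]:
    sid = str(entry["id"])
    volumes = {}
    for gaze, path in entry["volumes"].items():
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"volume for gaze {gaze!r} not found: {p}")
        volumes[gaze] = read_volume(p, gaze=gaze, subject_id=sid)
    if "central" not in volumes:
        raise ValueError(f"subject {sid}: central-gaze volume is required")
    return sid, volumes, None


def _measure_biometry(sid: str, volumes, results, truth) -> dict:
    """Biometry row from the images (+ truth orbit volume for phantoms)."""
    row = {"subject": sid, "axial_length_mm": np.nan, "ocular_volume_ml": np.nan, "orbital_volume_ml": np.nan}
    vols = [r.globe_volume_ml for r in results if np.isfinite(r.globe_volume_ml)]
    if vols:
        row["ocular_volume_ml"] = float(np.mean(vols))
    if truth is not None:
        spacing = truth.config.spacing
        row["orbital_volume_ml"] = float(
            np.mean([mask_volume_ml(truth.orbit_mask[s], spacing) for s in truth.orbit_mask])
        )
        row["axial_length_mm"] = float(2.0 * np.max(truth.config.semi_axes()))
    return row


def _qc_overlay(primary: Volume, result, outpath: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    c1 = result.centroid_primary
    c2 = result.centroid_secondary_aligned
    sz = primary.spacing
    k = int(round(c1.z / sz[2]))
    k = min(max(k, 0), primary.shape[2] - 1)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(primary.data[:, :, k].T, origin="lower", cmap="gray",
              extent=(0, (primary.shape[0] - 1) * sz[0], 0, (primary.shape[1] - 1) * sz[1]))
    ax.plot(c1.x, c1.y, "o", color="yellow", ms=5, label="central")
    ax.plot(c2.x, c2.y, "o", color="red", ms=5, label="aligned secondary")
    ax.annotate("", xy=(c2.x, c2.y), xytext=(c1.x, c1.y), arrowprops=dict(color="deepskyblue", arrowstyle="->"))
    ax.set_xlabel("x (mm, patient left)")
    ax.set_ylabel("y (mm, anterior)")
    ax.legend(loc="lower right", fontsize=7)
    ax.set_title(f"{c2.gaze} / {c2.side} eye: d={result.displacement.d:.2f} mm", fontsize=9)
    fig.savefig(outpath, dpi=90)
    plt.close(fig)


def run_all(cfg: RunConfig) -> RunReport:
    """Run the whole pipeline for a cohort; see the module docstring."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dcfg = cfg.displacement_config()

    subject_sources: list = []
    if cfg.subjects:
        subject_sources = [("file", entry) for entry in cfg.subjects]
    elif cfg.n_phantom_subjects > 0:
        subject_sources = [("phantom", i) for i in range(cfg.n_phantom_subjects)]
    else:
        raise ValueError("config names no subjects: set subjects or n_phantom_subjects")

    rows: list[dict] = []
    bio_rows: list[dict] = []
    exclusions: dict[str, str] = {}
    log: dict = {
        "version": __version__,
        "config": dataclasses.asdict(cfg),
        "subjects": {},
    }

    for kind, src in subject_sources:
        sid = None
        try:
            if kind == "phantom":
                sid, volumes, truth = _phantom_subject(cfg, src)
            else:
                sid, volumes, truth = _load_subject(src)
            results = []
            subject_log = {}
            for gaze in GAZE_ORDER:
                if gaze == "central" or gaze not in volumes:
                    continue
                for side in cfg.sides:
                    res = end_to_end_displacement(volumes["central"], volumes[gaze], side, dcfg)
                    results.append(res)
                    disp = res.displacement
                    rows.append(
                        {
                            "subject": sid,
                            "gaze": gaze,
                            "side": side,
                            "d_mm": disp.d,
                            "theta_signed_deg": disp.theta_in("signed"),
                            "theta_positive_deg": disp.theta_in("positive"),
                            "out_of_plane_mm": disp.out_of_plane_mm,
                            "alignment_residual": res.alignment.residual,
                            "rotation_deg": res.rotation_deg,
                        }
                    )
                    subject_log[f"{gaze}/{side}"] = {
                        "alignment_residual": res.alignment.residual,
                        "alignment_passed": res.alignment.passed,
                        "transform": res.alignment.transform.to_dict(volumes["central"].center_mm()),
                    }
                    if cfg.qc_overlays and side == cfg.sides[0]:
                        qcdir = outdir / "qc"
                        qcdir.mkdir(exist_ok=True)
                        _qc_overlay(volumes["central"], res, qcdir / f"{sid}_{gaze}.png")
            bio_rows.append(_measure_biometry(sid, volumes, results, truth))
            log["subjects"][sid] = subject_log
        except Exception as exc:  # noqa: BLE001 - per-subject fault isolation
            sid = sid or (f"P{src:03d}" if kind == "phantom" else str(src.get("id", "?")))
            exclusions[sid] = str(exc)
            log["subjects"][sid] = {"excluded": str(exc)}

    if not rows:
        raise RuntimeError(f"all subjects failed: {exclusions}")

    displacements = pd.DataFrame(rows, columns=DISPLACEMENT_COLUMNS)
    biometry = pd.DataFrame(bio_rows)
    displacements.to_csv(outdir / "displacements.csv", index=False)
    biometry.to_csv(outdir / "biometry.csv", index=False)

    try:
        table1, table2 = build_tables(displacements, biometry, one_eye_seed=cfg.eye_selection_seed)
    except ValueError as exc:  # e.g. a single-subject run: no cohort to summarise
        log["tables"] = f"not built: {exc}"
        table1, table2 = pd.DataFrame(), pd.DataFrame()
    table1.to_csv(outdir / "table1.csv", index=False)
    table2.to_csv(outdir / "table2.csv", index=False)

    log["exclusions"] = exclusions
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, default=str))

    return RunReport(
        outdir=outdir,
        displacements=displacements,
        table1=table1,
        table2=table2,
        n_subjects=len(subject_sources) - len(exclusions),
        n_failed=len(exclusions),
        exclusions=exclusions,
    )
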