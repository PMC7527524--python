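"""Shared phantom fixtures.

Phantom generation is the slow part of the suite, so the commonly reused
subjects are session-scoped.  ``tiny`` configs (64 × 64 × 36 grid, 9 mm
globes) are for tests that only need geometry plumbing; the ``small``
desk-scale config (96 × 96 × 48, 15 mm globes) is used wherever measurement
accuracy matters.
"""

import numpy as np
import pytest

import oculotrans as ot


def tiny_config(**overrides):
    kw = dict(
        grid_shape=(64, 64, 36),
        axial_length=9.0,
        seed=0,
        gazes=("central", "right"),
    )
    kw.update(overrides)
    return ot.PhantomConfig(**kw)


@pytest.fixture(scope="session")
def still_phantom():
    """Small phantom: default translations, no head motion, no noise."""
    cfg = ot.small_test_config(
        seed=11,
        gazes=("central", "right"),
        noise_sd=0.0,
        head_motion_max_rotation_deg=0.0,
        head_motion_max_translation_mm=0.0,
    )
    volumes, truth = ot.generate_phantom(cfg)
    return cfg, volumes, truth


@pytest.fixture(scope="session")
def noisy_phantom():
    """Small phantom under full study conditions (head motion + noise)."""
    cfg = ot.small_test_config(seed=1, gazes=("central", "right"))
    volumes, truth = ot.generate_phantom(cfg)
    return cfg, volumes, truth


@pytest.fixture(scope="session")
def pure_rotation_phantom():
    """Small phantom: 30 deg gaze rotation, zero translation, no motion/noise."""
    cfg = ot.small_test_config(
        seed=5,
        gazes=("central", "right"),
        true_translation={},
        head_motion_max_rotation_deg=0.0,
        head_motion_max_translation_mm=0.0,
        noise_sd=0.0,
    )
    volumes, truth = ot.generate_phantom(cfg)
    return cfg, volumes, truth


def truth_displacement(truth, gaze, side):
    """(d, theta_signed) of the configured true translation for one eye."""
    t = truth.gaze[gaze].translation_mm[side]
    if gaze in ("right", "left"):
        du = t[0] if side == "right" else -t[0]  # medial component
        dv = t[1]
    else:
        du, dv = t[1], t[2]
    d = float(np.hypot(du, dv))
    theta = float(np.degrees(np.arctan2(dv, du)))
    return d, theta
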