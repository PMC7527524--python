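"""Static-tissue registration: mask construction, recovery, residual checks."""

import numpy as np
import pytest
from skimage.filters import threshold_otsu

import oculotrans as ot
from oculotrans.coregistration import build_static_mask

from conftest import tiny_config


def _transform_error(recovered, head_motion, center):
    """Rotation (deg) and translation (mm) error of recovered ≈ head_motion⁻¹."""
    err = recovered.compose(head_motion)
    return err.rotation_magnitude_deg(), float(np.linalg.norm(err.translation_about(center)))


@pytest.fixture(scope="module")
def segmented_central(noisy_phantom):
    cfg, vols, truth = noisy_phantom
    masks = [ot.segment_globe(vols["central"], ot.SeedSpec(side=s)) for s in ("left", "right")]
    return vols, truth, masks


class TestStaticMask:
    def test_no_globes_no_dilation_equals_foreground(self, noisy_phantom):
        _, vols, _ = noisy_phantom
        v = vols["central"]
        static = build_static_mask(v, [], dilation_mm=0.0, fov_margin_mm=0.0)
        fg = np.asarray(v.data, float) > threshold_otsu(np.asarray(v.data, float))
        np.testing.assert_array_equal(static, fg)

    def test_excludes_dilated_truth_globes(self, segmented_central):
        vols, truth, masks = segmented_central
        static = build_static_mask(vols["central"], masks, dilation_mm=3.0)
        for side in ("left", "right"):
            assert not np.any(static & truth.gaze["central"].globe_outer_mask[side])

    def test_dilation_monotonicity(self, segmented_central):
        vols, _, masks = segmented_central
        counts = [
            build_static_mask(vols["central"], masks, dilation_mm=d).sum() for d in (0.0, 1.5, 3.0, 6.0)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_empty_static_mask_is_an_error(self, segmented_central):
        vols, _, masks = segmented_central
        with pytest.raises(ValueError, match="empty"):
            build_static_mask(vols["central"], masks, dilation_mm=1e4)


class TestRegister:
    def test_self_registration_is_identity(self, segmented_central):
        vols, _, masks = segmented_central
        static = build_static_mask(vols["central"], masks)
        report = ot.register_static(vols["central"], vols["central"], static)
        assert report.passed
        assert report.transform.rotation_magnitude_deg() <= 0.05
        assert np.linalg.norm(report.transform.translation_about(vols["central"].center_mm())) <= 0.05
        assert report.residual <= 1e-3

    def test_recovers_known_head_motion_noiseless(self):
        # same scene as the still phantom, but with a head-motion draw baked in
        cfg = ot.small_test_config(seed=11, gazes=("central", "right"), noise_sd=0.0)
        vols, truth = ot.generate_phantom(cfg)
        masks = [ot.segment_globe(vols["central"], ot.SeedSpec(side=s)) for s in ("left", "right")]
        static = build_static_mask(vols["central"], masks)
        report = ot.register_static(vols["right"], vols["central"], static)
        rot_err, tra_err = _transform_error(
            report.transform, truth.gaze["right"].head_motion, vols["central"].center_mm()
        )
        assert rot_err <= 0.1 and tra_err <= 0.1
        assert report.passed

    def test_recovery_under_noise(self):
        worst = (0.0, 0.0)
        for seed in (21, 22, 23):
            cfg = ot.small_test_config(seed=seed, gazes=("central", "right"))
            vols, truth = ot.generate_phantom(cfg)
            masks = [ot.segment_globe(vols["central"], ot.SeedSpec(side=s)) for s in ("left", "right")]
            static = build_static_mask(vols["central"], masks)
            report = ot.register_static(vols["right"], vols["central"], static)
            rot_err, tra_err = _transform_error(
                report.transform, truth.gaze["right"].head_motion, vols["central"].center_mm()
            )
            worst = (max(worst[0], rot_err), max(worst[1], tra_err))
        assert worst[0] <= 0.3 and worst[1] <= 0.2

    def test_symmetry_forward_equals_inverse_backward(self):
        cfg = ot.small_test_config(seed=11, gazes=("central", "right"), noise_sd=0.0)
        vols, _ = ot.generate_phantom(cfg)
        masks_c = [ot.segment_globe(vols["central"], ot.SeedSpec(side=s)) for s in ("left", "right")]
        masks_r = [ot.segment_globe(vols["right"], ot.SeedSpec(side=s)) for s in ("left", "right")]
        fwd = ot.register_static(vols["right"], vols["central"], build_static_mask(vols["central"], masks_c))
        bwd = ot.register_static(vols["central"], vols["right"], build_static_mask(vols["right"], masks_r))
        diff = fwd.transform.compose(bwd.transform)
        assert diff.rotation_magnitude_deg() <= 0.1
        assert np.linalg.norm(diff.translation_about(vols["central"].center_mm())) <= 0.1

    def test_globe_displacement_does_not_move_the_recovered_transform(self):
        # identical head motion (same seed), globes still vs displaced 2 mm
        base = dict(seed=31, gazes=("central", "right"), noise_sd=0.0)
        cfg_still = ot.small_test_config(true_translation={}, **base)
        cfg_moved = ot.small_test_config(
            true_translation={"right": {"left": (-2.0, 0, 0), "right": (-2.0, 0, 0)}}, **base
        )
        recovered = []
        for cfg in (cfg_still, cfg_moved):
            vols, truth = ot.generate_phantom(cfg)
            masks = [ot.segment_globe(vols["central"], ot.SeedSpec(side=s)) for s in ("left", "right")]
            static = build_static_mask(vols["central"], masks)
            recovered.append(ot.register_static(vols["right"], vols["central"], static).transform)
        diff = recovered[0].compose(recovered[1].inverse())
        center = cfg_still.grid_center()
        assert diff.rotation_magnitude_deg() <= 0.1
        assert np.linalg.norm(diff.translation_about(center)) <= 0.1


class TestCheckAlignment:
    def test_aligned_phantom_passes(self, still_phantom):
        _, vols, _ = still_phantom
        masks = [ot.segment_globe(vols["central"], ot.SeedSpec(side=s)) for s in ("left", "right")]
        static = build_static_mask(vols["central"], masks)
        report = ot.check_alignment(vols["central"], vols["central"], static)
        assert report.passed and report.residual <= 1e-6

    def test_two_mm_offset_fails_default_threshold(self, still_phantom):
        _, vols, _ = still_phantom
        masks = [ot.segment_globe(vols["central"], ot.SeedSpec(side=s)) for s in ("left", "right")]
        static = build_static_mask(vols["central"], masks)
        off = ot.apply_rigid(vols["central"], ot.RigidTransform.from_euler((0, 0, 0), (2.0, 0, 0)))
        report = ot.check_alignment(vols["central"], off, static)
        assert not report.passed and report.residual > 0.02

    def test_vacuous_threshold_always_passes(self, still_phantom):
        _, vols, _ = still_phantom
        masks = [ot.segment_globe(vols["central"], ot.SeedSpec(side=s)) for s in ("left", "right")]
        static = build_static_mask(vols["central"], masks)
        off = ot.apply_rigid(vols["central"], ot.RigidTransform.from_euler((3, 0, 0), (5.0, 0, 0)))
        assert ot.check_alignment(vols["central"], off, static, threshold=1.0).passed
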