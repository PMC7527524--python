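"""Region growing, centroids, mask volumes, and rotation estimation."""

import numpy as np
import pytest

import oculotrans as ot
from oculotrans.globe_segmentation import SegmentationError, find_lens_pole

SPACING = (0.7, 0.7, 0.6)


def _sphere_volume(shape=(60, 60, 40), center=(30, 30, 20), radius=8.0):
    idx = np.indices(shape).astype(float)
    r2 = sum(((idx[d] - center[d]) * SPACING[d]) ** 2 for d in range(3))
    sphere = r2 <= radius**2
    return ot.Volume(data=np.where(sphere, 1.0, 0.0).astype(np.float32), spacing=SPACING), sphere


class TestSegmentGlobe:
    def test_two_level_sphere_is_segmented_exactly(self):
        vol, sphere = _sphere_volume()
        mask = ot.segment_globe(vol, ot.SeedSpec(index=(30, 30, 20), side="left"), min_volume_ml=0.5)
        np.testing.assert_array_equal(mask.data, sphere)

    def test_dice_against_phantom_truth(self, noisy_phantom):
        _, vols, truth = noisy_phantom
        for side in ("left", "right"):
            mask = ot.segment_globe(vols["central"], ot.SeedSpec(side=side))
            assert ot.dice(mask, truth.globe_mask_as("central", side)) >= 0.95

    def test_fat_seed_leaks_or_is_too_small(self, noisy_phantom):
        cfg, vols, _ = noisy_phantom
        gc = cfg.globe_center("left")
        fat_idx = tuple(int(v) for v in (gc + np.array([0.0, -10.5, 0.0])) / np.asarray(SPACING))
        with pytest.raises(SegmentationError):
            ot.segment_globe(vols["central"], ot.SeedSpec(index=fat_idx, side="left"))

    def test_background_seed_rejected(self, noisy_phantom):
        _, vols, _ = noisy_phantom
        with pytest.raises(SegmentationError, match="background"):
            ot.segment_globe(vols["central"], ot.SeedSpec(index=(1, 1, 1), side="left"))

    def test_intensity_scale_invariance(self, noisy_phantom):
        _, vols, _ = noisy_phantom
        v = vols["central"]
        doubled = v.with_data(v.data * 2.0)
        a = ot.segment_globe(v, ot.SeedSpec(side="left"))
        b = ot.segment_globe(doubled, ot.SeedSpec(side="left"))
        np.testing.assert_array_equal(a.data, b.data)

    def test_shell_option_grows_the_mask(self, noisy_phantom):
        _, vols, truth = noisy_phantom
        plain = ot.segment_globe(vols["central"], ot.SeedSpec(side="left"))
        shelled = ot.segment_globe(vols["central"], ot.SeedSpec(side="left"), shell_mm=1.0)
        assert shelled.voxel_count() > plain.voxel_count()
        assert np.all(shelled.data[plain.data])
        # the 1 mm shell brings the volume toward the outer (sclera-inclusive) truth
        outer = ot.mask_volume_ml(truth.globe_mask_as("central", "left", "outer"))
        assert abs(ot.mask_volume_ml(shelled) - outer) < abs(ot.mask_volume_ml(plain) - outer)


class TestCentroid:
    @pytest.mark.parametrize(
        "voxels, expected",
        [
            ([(3, 4, 5)], (2.1, 2.8, 3.0)),  # one-point mean, index x spacing
            ([(i, j, k) for i in (9, 10, 11) for j in (9, 10, 11) for k in (9, 10, 11)], (7.0, 7.0, 6.0)),
        ],
    )
    def test_small_masks_against_hand_computed_values(self, voxels, expected):
        grid = np.zeros((20, 20, 20), dtype=bool)
        for v in voxels:
            grid[v] = True
        c = ot.centroid_mm(grid, SPACING)
        assert np.allclose(c.as_array(), expected, atol=1e-12)

    def test_random_mask_matches_bruteforce_list_mean(self):
        rng = np.random.default_rng(12)
        grid = np.zeros((30, 25, 20), dtype=bool)
        pts = rng.integers(0, (30, 25, 20), size=(50, 3))
        for p in pts:
            grid[tuple(p)] = True
        c = ot.centroid_mm(grid, SPACING)
        coords = [(i * 0.7, j * 0.7, k * 0.6) for i, j, k in np.argwhere(grid)]
        brute = np.mean(coords, axis=0)
        assert np.allclose(c.as_array(), brute, rtol=1e-13, atol=0)

    def test_integer_shift_moves_centroid_exactly(self):
        rng = np.random.default_rng(5)
        grid = np.zeros((30, 30, 30), dtype=bool)
        grid[8:14, 9:13, 10:15] = rng.random((6, 4, 5)) > 0.4
        shifted = np.roll(grid, (2, 3, 1), axis=(0, 1, 2))
        d = ot.centroid_mm(shifted, SPACING).as_array() - ot.centroid_mm(grid, SPACING).as_array()
        assert np.allclose(d, np.array([2, 3, 1]) * np.asarray(SPACING), atol=1e-12)

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError):
            ot.centroid_mm(np.zeros((4, 4, 4), bool), SPACING)
        with pytest.raises(ValueError):
            ot.mask_volume_ml(np.zeros((4, 4, 4), bool), SPACING)


class TestMaskVolume:
    def test_thousand_unit_voxels_is_one_ml(self):
        grid = np.zeros((20, 20, 20), dtype=bool)
        grid[:10, :10, :10] = True
        assert ot.mask_volume_ml(grid, (1.0, 1.0, 1.0)) == pytest.approx(1.0)

    def test_phantom_truth_globe_within_two_percent_of_analytic(self, still_phantom):
        import math

        cfg, _, truth = still_phantom
        analytic = 4 / 3 * math.pi * float(np.prod(cfg.inner_semi_axes())) / 1000.0
        measured = ot.mask_volume_ml(truth.globe_mask_as("central", "right"))
        assert abs(measured - analytic) / analytic <= 0.02


class TestRotationEstimate:
    def test_identical_gaze_gives_zero(self):
        c = ot.CentroidMM(10, 10, 10)
        p = ot.CentroidMM(10, 16, 10)
        assert ot.estimate_rotation_deg(c, p, c, p) == pytest.approx(0.0)

    def test_coincident_pole_is_an_error(self):
        c = ot.CentroidMM(10, 10, 10)
        with pytest.raises(ValueError):
            ot.estimate_rotation_deg(c, c, c, c)

    def test_pure_rotation_recovered_within_one_degree(self, pure_rotation_phantom):
        _, vols, _ = pure_rotation_phantom
        rot = self._measured_rotation(vols)
        assert rot == pytest.approx(30.0, abs=1.0)

    def test_rotation_with_translation_recovered(self, still_phantom):
        # translation cancels in the centroid->pole difference vectors
        _, vols, _ = still_phantom
        rot = self._measured_rotation(vols)
        assert rot == pytest.approx(30.0, abs=1.5)

    @staticmethod
    def _measured_rotation(vols):
        m1 = ot.segment_globe(vols["central"], ot.SeedSpec(side="left"))
        m2 = ot.segment_globe(vols["right"], ot.SeedSpec(side="left"))
        c1, c2 = ot.centroid_mm(m1), ot.centroid_mm(m2)
        p1 = find_lens_pole(vols["central"], m1)
        p2 = find_lens_pole(vols["right"], m2)
        # gaze right = +30 deg about +z; in the axial plane the signed angle
        # from central to right gaze is positive with our axis conventions
        return abs(ot.estimate_rotation_deg(c1, p1, c2, p2, plane="axial"))
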