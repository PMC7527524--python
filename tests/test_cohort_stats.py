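"""Cohort statistics: eye selection, summaries, tests, correlations, tables."""

import io

import numpy as np
import pandas as pd
import pytest

import oculotrans as ot
from oculotrans.cohort_stats import (
    CONTRASTS,
    SubjectRecord,
    apply_eye_selection,
    summarize_direction,
)


class TestSelectOneEye:
    def test_two_subjects_one_each(self):
        sides = set(ot.select_one_eye(["a", "b"], seed=0).values())
        assert sides == {"right", "left"}

    def test_even_cohort_splits_evenly(self):
        assignment = ot.select_one_eye([f"s{i}" for i in range(56)], seed=3)
        counts = pd.Series(list(assignment.values())).value_counts()
        assert counts["right"] == 28 and counts["left"] == 28

    def test_deterministic_given_seed(self):
        ids = [f"s{i}" for i in range(15)]
        assert ot.select_one_eye(ids, seed=9) == ot.select_one_eye(ids, seed=9)
        assert ot.select_one_eye(ids, seed=9) != ot.select_one_eye(ids, seed=10)

    def test_missing_eye_warns_and_keeps_available(self):
        # pick a seed whose assignment gives subject b the (absent) right eye
        seed = next(s for s in range(50) if ot.select_one_eye(["a", "b"], s)["b"] == "right")
        df = pd.DataFrame(
            {
                "subject": ["a", "a", "b"],
                "gaze": ["right", "right", "right"],
                "side": ["right", "left", "left"],
                "d_mm": [0.5, 0.6, 0.7],
                "theta_signed_deg": [0.0, 0.0, 0.0],
            }
        )
        with pytest.warns(UserWarning, match="missing"):
            out = apply_eye_selection(df, seed=seed)
        assert set(out["subject"]) == {"a", "b"}
        assert out[out["subject"] == "b"]["side"].item() == "left"


class TestSummaries:
    def test_ci_width_is_exact(self):
        rng = np.random.default_rng(0)
        v = rng.normal(0.5, 0.2, 37)
        row = ot.summarize(v)
        assert row.ci_high - row.ci_low == pytest.approx(2 * 1.96 * row.sd / np.sqrt(row.n), abs=1e-12)
        assert row.ci_low <= row.mean <= row.ci_high

    def test_zero_sd_collapses_ci(self):
        row = ot.summarize([0.4, 0.4, 0.4])
        assert row.sd == pytest.approx(0.0, abs=1e-12)
        assert row.ci_high - row.ci_low == pytest.approx(0.0, abs=1e-12)
        assert row.mean == pytest.approx(0.4)

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            ot.summarize([1.0])
        with pytest.raises(ValueError):
            ot.summarize_from_moments(0.5, 0.1, 1)

    def test_direction_equal_angles(self):
        arith, circ = summarize_direction([30.0, 30.0, 30.0])
        assert arith.mean == pytest.approx(30.0) and arith.sd == pytest.approx(0.0)
        assert circ.mean_deg == pytest.approx(30.0, abs=1e-9) and circ.circ_sd_deg == pytest.approx(0.0, abs=1e-6)

    def test_direction_antipodal_wrap_divergence(self):
        # arithmetic and circular summaries legitimately diverge at the wrap point
        arith, circ = summarize_direction([-179.0, 179.0])
        assert arith.mean == pytest.approx(0.0)
        assert abs(circ.mean_deg) == pytest.approx(180.0, abs=1e-6)

    def test_direction_circular_mean_matches_vector_sum_oracle(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(-180, 180, 40)
        _, circ = summarize_direction(a)
        rad = np.deg2rad(a)
        oracle = np.degrees(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean()))
        assert circ.mean_deg == pytest.approx(oracle, abs=1e-9)

    def test_direction_range_mismatch_is_an_error(self):
        with pytest.raises(ValueError, match="range"):
            summarize_direction([10.0, 220.0], angle_range="signed")


class TestCompareGazes:
    def test_identical_samples(self):
        t, p = ot.compare_gazes([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_matches_hand_computed_pooled_formula(self):
        a = np.array([0.5, 0.7, 0.9])
        b = np.array([0.4, 0.6, 0.8])
        t, p = ot.compare_gazes(a, b)
        sp2 = ((a.var(ddof=1)) * 2 + (b.var(ddof=1)) * 2) / 4
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert t == pytest.approx(t_hand, abs=1e-12)

    def test_sign_symmetry(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(0.7, 0.2, 20), rng.normal(0.5, 0.2, 25)
        t1, p1 = ot.compare_gazes(a, b)
        t2, p2 = ot.compare_gazes(b, a)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_degenerate_variance(self):
        assert ot.compare_gazes([1.0, 1.0], [1.0, 1.0]) == (0.0, 1.0)
        with pytest.raises(ValueError):
            ot.compare_gazes([1.0, 1.0], [2.0, 2.0])


class TestCorrelate:
    def test_perfect_negative_line(self):
        x = np.linspace(0, 1, 10)
        row = ot.correlate(x, -2 * x + 1)
        assert row.r == pytest.approx(-1.0)

    def test_affine_invariance_up_to_sign(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=30), rng.normal(size=30)
        base = ot.correlate(x, y).r
        assert ot.correlate(3 * x + 2, y).r == pytest.approx(base, abs=1e-12)
        assert ot.correlate(-3 * x + 2, y).r == pytest.approx(-base, abs=1e-12)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            ot.correlate([1.0, 2.0], [3.0, 4.0])  # n < 3
        with pytest.raises(ValueError):
            ot.correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])  # zero variance


class TestSubjectRecord:
    def test_biometry_bounds_enforced(self):
        with pytest.raises(ValueError):
            SubjectRecord("s", "left", axial_length_mm=40.0, ocular_volume_ml=7.0, orbital_volume_ml=26.0)
        with pytest.raises(ValueError):
            SubjectRecord("s", "left", axial_length_mm=24.0, ocular_volume_ml=-1.0, orbital_volume_ml=26.0)


class TestBuildTables:
    def test_recovers_designed_correlation(self):
        disp, bio = ot.simulate_cohort(n_subjects=200, seed=7, r_axial={c: -0.5 for c in CONTRASTS})
        t1, t2 = ot.build_tables(disp, bio, one_eye_seed=7)
        row = t2[(t2["contrast"] == "abduction") & (t2["covariate"] == "axial_length_mm")]
        assert -0.6 <= row["r"].item() <= -0.4
        assert bool(row["significant"].item())

    def test_zero_translation_cohort_has_small_positive_noise_floor(self):
        disp, bio = ot.simulate_cohort(
            n_subjects=100, seed=5, mean_distance={c: 0.0 for c in CONTRASTS}
        )
        t1, _ = ot.build_tables(disp, bio, one_eye_seed=5)
        assert (t1["d_mean_mm"] > 0).all()
        assert (t1["d_mean_mm"] < 0.25).all()

    def test_rerun_is_byte_identical(self):
        out = []
        for _ in range(2):
            disp, bio = ot.simulate_cohort(n_subjects=40, seed=3)
            t1, t2 = ot.build_tables(disp, bio, one_eye_seed=3)
            buf = io.StringIO()
            t1.to_csv(buf, index=False)
            t2.to_csv(buf, index=False)
            out.append(buf.getvalue())
        assert out[0] == out[1]

    def test_constant_biometry_yields_nan_rows_not_errors(self):
        disp, bio = ot.simulate_cohort(n_subjects=20, seed=1)
        bio["axial_length_mm"] = 24.0
        _, t2 = ot.build_tables(disp, bio, one_eye_seed=1)
        sub = t2[t2["covariate"] == "axial_length_mm"]
        assert sub["r"].isna().all()
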