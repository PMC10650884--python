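"""Preprocessing chain: resultant, jerk, RMS, segmentation, labels."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from motorgrade.cohort import RawRecording
from motorgrade.preprocess import (
    PreprocessConfig,
    binarize_severity,
    compute_jerk,
    compute_resultant,
    preprocess_recording,
    rms_window,
    segment_sequence,
    standardize_segment,
)


def make_recording(samples, severity=0, cohort="HOA", fs=80.0):
    return RawRecording(
        participant_id="P01",
        session_id="S1",
        cohort=cohort,
        task="HM",
        severity=severity,
        sampling_rate=fs,
        samples=samples,
    )


class TestResultant:
    def test_pythagorean_triple(self):
        samples = np.zeros((1, 2, 3))
        samples[0, 0] = (1.0, 2.0, 2.0)
        assert compute_resultant(make_recording(samples))[0, 0] == pytest.approx(3.0)

    def test_zero_vector(self):
        samples = np.zeros((4, 2, 3))
        assert np.all(compute_resultant(make_recording(samples)) == 0.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        samples = rng.normal(size=(200, 2, 3))
        result = compute_resultant(make_recording(samples))
        # independent elementwise oracle
        for j in range(200):
            for i in range(2):
                expected = np.sqrt(sum(samples[j, i, k] ** 2 for k in range(3)))
                assert abs(result[j, i] - expected) < 1e-12

    def test_rotation_invariance(self):
        rng = np.random.default_rng(1)
        samples = rng.normal(size=(100, 2, 3))
        base = compute_resultant(make_recording(samples))
        for seed in range(5):
            R = Rotation.random(rng=np.random.default_rng(seed)).as_matrix()
            rotated = samples @ R.T
            np.testing.assert_allclose(
                compute_resultant(make_recording(rotated)), base, atol=1e-9
            )


class TestJerk:
    def test_constant_series_gives_zeros(self):
        assert np.all(compute_jerk(np.full(10, 3.0), 80.0) == 0.0)

    def test_difference_formula(self):
        np.testing.assert_allclose(
            compute_jerk(np.array([0.0, 1.0, 3.0]), 1.0), [1.0, 2.0]
        )

    def test_linear_ramp_recovers_slope(self):
        t = np.arange(400) / 80.0
        jerk = compute_jerk(2.5 * t, 80.0)
        np.testing.assert_allclose(jerk, 2.5, atol=1e-9)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            compute_jerk(np.array([1.0]), 80.0)


class TestRmsWindow:
    def test_constant_series(self):
        out = rms_window(np.full(200, -2.0), 80.0)
        np.testing.assert_allclose(out, 2.0)

    def test_zero_series(self):
        assert np.all(rms_window(np.zeros(200), 80.0) == 0.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=300)
        out = rms_window(x, 80.0)
        w = 80
        expected = np.array(
            [np.sqrt(np.mean(x[k : k + w] ** 2)) for k in range(300 - w + 1)]
        )
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_output_length_formula_with_stride(self):
        for n, stride in [(400, 1), (400, 80), (777, 13)]:
            out = rms_window(np.ones(n), 80.0, stride=stride)
            assert out.shape[0] == (n - 80) // stride + 1

    def test_shorter_than_window_rejected(self):
        with pytest.raises(ValueError):
            rms_window(np.ones(50), 80.0)


class TestSegmentation:
    def test_exact_window(self):
        wins = segment_sequence(np.ones((400, 2)), 400, 80)
        assert len(wins) == 1 and wins[0].shape == (400, 2)

    @pytest.mark.parametrize("n,expected", [(480, 2), (479, 1), (399, 0), (640, 4)])
    def test_window_count_formula(self, n, expected):
        assert len(segment_sequence(np.ones((n, 2)), 400, 80)) == expected

    def test_short_sequence_warns_and_returns_empty(self, caplog):
        with caplog.at_level("WARNING", logger="motorgrade.preprocess"):
            wins = segment_sequence(np.ones((399, 2)), 400, 80)
        assert wins == []
        assert any("shorter than window" in r.message for r in caplog.records)

    def test_windows_are_contiguous_strided_views_of_input(self):
        x = np.arange(1000, dtype=float).reshape(500, 2)
        wins = segment_sequence(x, 400, 80)
        for k, w in enumerate(wins):
            np.testing.assert_array_equal(w, x[k * 80 : k * 80 + 400])


class TestStandardize:
    def test_zero_mean_unit_sd(self):
        rng = np.random.default_rng(3)
        out = standardize_segment(rng.normal(2.0, 5.0, size=(400, 2)))
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(out.std(axis=0), 1.0, atol=1e-9)

    def test_constant_channel_becomes_zeros(self):
        w = np.ones((400, 2))
        w[:, 1] = np.random.default_rng(0).normal(size=400)
        out = standardize_segment(w)
        assert np.all(out[:, 0] == 0.0)
        assert np.all(np.isfinite(out))

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        once = standardize_segment(rng.normal(size=(400, 2)))
        np.testing.assert_allclose(standardize_segment(once), once, atol=1e-9)


class TestBinarize:
    @pytest.mark.parametrize(
        "severity,expected",
        [(0, "low"), (1, "low"), (2, "dropped"), (3, "high"), (4, "high")],
    )
    def test_mapping(self, severity, expected):
        assert binarize_severity(severity) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            binarize_severity(5)


class TestFullChain:
    def test_segment_count_follows_chained_length_formulas(self):
        rng = np.random.default_rng(5)
        n = 1600  # 20 s at 80 Hz
        samples = rng.normal(size=(n, 2, 3))
        segs = preprocess_recording(make_recording(samples))
        n_rms = (n - 1) - 80 + 1  # jerk drops 1, RMS drops w-1
        assert len(segs) == (n_rms - 400) // 80 + 1

    def test_severity_two_recording_yields_nothing(self):
        samples = np.random.default_rng(6).normal(size=(1600, 2, 3))
        segs = preprocess_recording(make_recording(samples, severity=2, cohort="PD"))
        assert segs == []

    def test_hoa_segments_all_low_and_share_group(self):
        samples = np.random.default_rng(7).normal(size=(800, 2, 3))
        segs = preprocess_recording(make_recording(samples))
        assert len(segs) > 1
        assert all(s.label == "low" for s in segs)
        assert len({s.group_id for s in segs}) == 1

    def test_segments_standardized(self):
        samples = np.random.default_rng(8).normal(size=(800, 2, 3))
        for seg in preprocess_recording(make_recording(samples)):
            np.testing.assert_allclose(seg.window.mean(axis=0), 0.0, atol=1e-8)
            np.testing.assert_allclose(seg.window.std(axis=0), 1.0, atol=1e-8)

    def test_length_bookkeeping_random_configs(self):
        # closed-form output length at every stage for random (n, stride)
        rng = np.random.default_rng(9)
        for _ in range(200):
            n = int(rng.integers(500, 3000))
            stride = int(rng.integers(1, 200))
            samples = rng.normal(size=(n, 2, 3))
            cfg = PreprocessConfig(segment_stride=stride)
            segs = preprocess_recording(make_recording(samples), cfg)
            n_rms = (n - 1) - 80 + 1
            expected = max(0, (n_rms - 400) // stride + 1) if n_rms >= 400 else 0
            assert len(segs) == expected
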