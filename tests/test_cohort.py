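"""Synthetic cohort generator: determinism, severity structure, spectra."""

import numpy as np
import pytest
from scipy.signal import periodogram

from motorgrade.cohort import (
    CohortSpec,
    MovementParams,
    generate_cohort,
    read_cohort,
    severity_to_params,
    simulate_recording,
    write_cohort,
)


def quiet_params(**overrides) -> MovementParams:
    base = dict(
        base_frequency=2.5,
        amplitude=0.5,
        decrement_rate=0.0,
        tremor_frequency=5.0,
        tremor_amplitude=0.0,
        hesitation_rate=0.0,
        phase_jitter_sd=0.0,
        noise_sd=0.0,
    )
    base.update(overrides)
    return MovementParams(**base)


class TestSeverityToParams:
    def test_severity_zero_has_no_tremor_or_hesitation(self):
        p = severity_to_params(0, "HOA", "FT", np.random.default_rng(0))
        assert p.tremor_amplitude == 0.0
        assert p.hesitation_rate == 0.0

    @pytest.mark.parametrize("lo,hi", [(0, 2), (1, 4), (0, 4)])
    def test_monotone_in_severity_under_shared_rng(self, lo, hi):
        pl = severity_to_params(lo, "PD", "HM", np.random.default_rng(42))
        ph = severity_to_params(hi, "PD", "HM", np.random.default_rng(42))
        assert ph.amplitude <= pl.amplitude
        assert ph.tremor_amplitude >= pl.tremor_amplitude
        assert ph.hesitation_rate >= pl.hesitation_rate
        assert ph.decrement_rate >= pl.decrement_rate
        assert ph.phase_jitter_sd >= pl.phase_jitter_sd

    def test_deterministic_under_fixed_seed(self):
        a = severity_to_params(2, "PD", "PS", np.random.default_rng(5))
        b = severity_to_params(2, "PD", "PS", np.random.default_rng(5))
        assert a == b

    @pytest.mark.parametrize("sev", [-1, 5])
    def test_out_of_range_severity_rejected(self, sev):
        with pytest.raises(ValueError):
            severity_to_params(sev, "PD", "FT", np.random.default_rng(0))

    def test_hoa_must_be_severity_zero(self):
        with pytest.raises(ValueError):
            severity_to_params(3, "HOA", "FT", np.random.default_rng(0))


class TestSimulateRecording:
    def test_sample_count(self):
        s = simulate_recording(quiet_params(), 5.0, 80.0, np.random.default_rng(0))
        assert s.shape == (400, 2, 3)

    def test_all_zero_when_every_amplitude_is_zero(self):
        p = quiet_params(amplitude=0.0, gravity=(0.0, 0.0, 0.0))
        s = simulate_recording(p, 5.0, 80.0, np.random.default_rng(0))
        assert np.all(s == 0.0)

    def test_pure_tone_resultant_peaks_at_base_frequency(self):
        # noiseless, tremorless movement along the gravity axis: the
        # resultant is 1 + signal, so its non-DC periodogram peak must
        # sit at the movement frequency (brute-force periodogram argmax)
        p = quiet_params(base_frequency=3.0)
        s = simulate_recording(p, 20.0, 80.0, np.random.default_rng(0))
        resultant = np.sqrt((s[:, 0, :] ** 2).sum(axis=1))
        freqs, power = periodogram(resultant - resultant.mean(), fs=80.0)
        assert abs(freqs[np.argmax(power)] - 3.0) < 0.1

    def test_each_axis_is_sinusoidal_when_deterministic(self):
        p = quiet_params(base_frequency=2.0)
        s = simulate_recording(p, 10.0, 80.0, np.random.default_rng(0))
        t = np.arange(800) / 80.0
        expected = 1.0 + 0.5 * np.cos(2 * np.pi * 2.0 * t)  # z-axis, sensor 1
        np.testing.assert_allclose(s[:, 0, 2], expected, atol=1e-12)

    def test_invalid_duration_rejected(self):
        with pytest.raises(ValueError):
            simulate_recording(quiet_params(), -1.0, 80.0, np.random.default_rng(0))

    def test_severe_recordings_show_tremor_band_peak(self):
        # severity >= 3 injects a 4-6 Hz tremor absent at severity 0
        rng = np.random.default_rng(3)
        for sev, expect in [(0, False), (4, True)]:
            p = severity_to_params(sev, "PD", "HM", rng)
            s = simulate_recording(p, 20.0, 80.0, rng)
            resultant = np.sqrt((s[:, 0, :] ** 2).sum(axis=1))
            freqs, power = periodogram(resultant - resultant.mean(), fs=80.0)
            band = (freqs >= 4.0) & (freqs <= 6.0)
            outside = (freqs > 0.5) & ~band
            has_peak = power[band].max() > power[outside].max()
            assert has_peak == expect


class TestGenerateCohort:
    def test_deterministic_metadata(self):
        spec = CohortSpec(n_pd=4, n_hoa=2, tasks=("FT",), duration=6.0, seed=9)
        _, m1 = generate_cohort(spec)
        _, m2 = generate_cohort(spec)
        assert m1.equals(m2)

    def test_no_hoa_requested_yields_no_hoa(self):
        spec = CohortSpec(n_pd=3, n_hoa=0, tasks=("FT",), duration=6.0, seed=1)
        _, manifest = generate_cohort(spec)
        assert (manifest["cohort"] == "PD").all()

    def test_session_counts_match_study_shape_in_expectation(self):
        # 20 PD + 8 HOA with retest fraction ~0.68 emulates the study's
        # 48-session shape; check expected counts over a few seeds
        totals = []
        for seed in range(5):
            spec = CohortSpec(tasks=("FT",), duration=6.0, seed=seed)
            _, manifest = generate_cohort(spec)
            totals.append(
                manifest.groupby(["participant_id", "session_id"]).ngroups
            )
        expected = 28 * 1.68
        assert abs(np.mean(totals) - expected) < 6

    def test_hoa_recordings_are_severity_zero(self, small_cohort):
        _, manifest = small_cohort
        hoa = manifest[manifest["cohort"] == "HOA"]
        assert (hoa["severity"] == 0).all()

    def test_empty_task_set_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(tasks=())

    def test_severity_amplitude_effect_size_exceeds_one_sd(self):
        # mild (0/1) vs severe (3/4) recordings separate by > 1 pooled SD
        # in mean movement amplitude (std of the resultant about its mean)
        rng = np.random.default_rng(12)
        amplitudes = {"mild": [], "severe": []}
        for _ in range(50):
            for group, sev in (("mild", rng.integers(0, 2)), ("severe", rng.integers(3, 5))):
                p = severity_to_params(int(sev), "PD", "HM", rng)
                s = simulate_recording(p, 10.0, 80.0, rng)
                resultant = np.sqrt((s[:, 0, :] ** 2).sum(axis=1))
                amplitudes[group].append(resultant.std())
        mild, severe = map(np.asarray, (amplitudes["mild"], amplitudes["severe"]))
        pooled_sd = np.sqrt((mild.var(ddof=1) + severe.var(ddof=1)) / 2)
        effect = (mild.mean() - severe.mean()) / pooled_sd
        assert effect > 1.0


class TestCsvRoundTrip:
    def test_cohort_written_and_read_back(self, tmp_path, small_cohort):
        recordings, manifest = small_cohort
        subset, sub_manifest = recordings[:4], manifest.iloc[:4]
        path = write_cohort(subset, sub_manifest, tmp_path / "cohort")
        back, back_manifest = read_cohort(path)
        assert len(back) == 4
        for orig, rt in zip(subset, back):
            assert rt.recording_id == orig.recording_id
            assert rt.severity == orig.severity
            np.testing.assert_allclose(rt.samples, orig.samples, atol=1e-9)
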