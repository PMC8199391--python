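"""Signal cleaning, extrema, respiratory rate and the breathing flags."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import respmotion as rm
from respmotion.breathing import BreathingConfig


def sinusoid(freq_hz: float, duration_s: float = 60.0, fs: float = 5.0, amp: float = 1.0):
    t = np.arange(int(duration_s * fs)) / fs
    return rm.BreathSignal(amp * np.sin(2 * np.pi * freq_hz * t), fs=fs)


class TestCleanSignal:
    def test_constant_and_ramp_removed(self):
        n = 300
        const = rm.clean_signal(rm.BreathSignal(np.full(n, 3.7), fs=5.0))
        assert np.abs(const.samples).max() < 1e-9
        ramp = rm.clean_signal(rm.BreathSignal(np.linspace(0, 10, n), fs=5.0))
        interior = ramp.samples[25:-25]
        assert np.abs(interior).max() < 1e-6 * 10

    def test_passband_and_stopband(self):
        """0.25 Hz (15 BPM) passes nearly untouched; 0.01 Hz drift is crushed."""
        inband = rm.clean_signal(sinusoid(0.25, 60.0))
        assert np.abs(inband.samples[50:-50]).max() >= 0.9
        drift = rm.clean_signal(sinusoid(0.01, 120.0))
        assert np.abs(drift.samples).max() <= 0.2

    def test_output_is_centred(self):
        cleaned = rm.clean_signal(sinusoid(0.2, 80.0))
        assert abs(cleaned.samples.mean()) < 1e-6 * cleaned.samples.std()

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError, match="minimum"):
            rm.clean_signal(rm.BreathSignal(np.zeros(20), fs=5.0))

    def test_idempotent_within_tolerance(self):
        """Cleaning an already-cleaned signal changes it by < 1% RMS."""
        sig, _ = rm.synth_breath_signal(
            rm.BreathScript(rr_bpm=12, duration_s=300, drift_slope=0.3, noise_sd=0.05, seed=5)
        )
        once = rm.clean_signal(sig)
        twice = rm.clean_signal(once)
        rms = np.sqrt(np.mean(once.samples**2))
        assert np.sqrt(np.mean((twice.samples - once.samples) ** 2)) < 0.01 * rms


class TestFindExtrema:
    def test_counts_on_pure_sinusoid(self):
        ex = rm.find_extrema(rm.clean_signal(sinusoid(0.25, 60.0)))
        assert ex.n_peaks == 15
        assert ex.n_troughs == 15

    def test_silent_signal_has_no_extrema(self):
        ex = rm.find_extrema(rm.BreathSignal(np.zeros(300), fs=5.0, cleaned=True))
        assert ex.n_peaks == 0 and ex.n_troughs == 0

    def test_alternation_enforced(self):
        sig, _ = rm.synth_breath_signal(
            rm.BreathScript(rr_bpm=10, duration_s=120, noise_sd=0.15, seed=3)
        )
        ex = rm.find_extrema(rm.clean_signal(sig))
        merged = sorted(
            [(t, 0) for t in ex.peak_times] + [(t, 1) for t in ex.trough_times]
        )
        kinds = [k for _, k in merged]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))

    def test_noisy_peak_count_within_one(self):
        """Monte Carlo: with noise sd 0.2 x amplitude, the detected peak count
        stays within +/-1 of truth in at least 95% of seeds."""
        hits = 0
        n_seeds = 50
        for seed in range(n_seeds):
            sig, ann = rm.synth_breath_signal(
                rm.BreathScript(rr_bpm=12, duration_s=60, noise_sd=0.2, seed=seed)
            )
            ex = rm.find_extrema(rm.clean_signal(sig))
            if abs(ex.n_peaks - len(ann["peak_times"])) <= 1:
                hits += 1
        assert hits >= 0.95 * n_seeds


class TestRespiratoryRate:
    def test_full_minute_count(self):
        ex = rm.ExtremaSet.from_times(np.arange(15) * 4 + 1, np.arange(15) * 4 + 3)
        assert rm.respiratory_rate(ex, 60.0) == 15

    def test_short_video_scaling(self):
        """6 peaks / 5 troughs in 30 s scale to 12 breaths per minute."""
        ex = rm.ExtremaSet.from_times(np.arange(6) * 5 + 1, np.arange(5) * 5 + 3.5)
        assert rm.respiratory_rate(ex, 30.0) == pytest.approx(12.0)

    def test_no_extrema_gives_zero(self):
        ex = rm.ExtremaSet.from_times([], [])
        assert rm.respiratory_rate(ex, 45.0) == 0.0


def extrema_with_amplitudes(amps):
    """Troughs at value 0, each followed by a peak of the given amplitude."""
    pt = np.arange(len(amps)) * 4.0 + 2.0
    tt = np.arange(len(amps)) * 4.0
    return rm.ExtremaSet.from_times(pt, tt, peak_values=np.asarray(amps, float),
                                    trough_values=np.zeros(len(amps)))


class TestRhythmicity:
    def test_constant_amplitude_is_rhythmic(self):
        flag, amps, _ = rm.rhythmicity(extrema_with_amplitudes([1.0] * 6), thresh1=1e-6)
        assert flag is True
        assert amps == pytest.approx(np.ones(6))

    @pytest.mark.parametrize("thresh1,expected", [(0.5, False), (1.0, True)])
    def test_outlier_amplitude_against_threshold(self, thresh1, expected):
        """Amplitudes {1,1,1,2}: the 2.0 breath violates median +/- 0.5 but
        fits within median +/- 1.0."""
        flag, _, _ = rm.rhythmicity(extrema_with_amplitudes([1.0, 1.0, 1.0, 2.0]), thresh1=thresh1)
        assert flag is expected

    def test_undefined_below_two_breaths(self):
        flag, _, _ = rm.rhythmicity(extrema_with_amplitudes([1.0]))
        assert flag is None

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.floats(0.1, 5.0), min_size=2, max_size=12),
           st.floats(0.01, 3.0), st.floats(0.0, 2.0))
    def test_monotone_in_threshold(self, amps, t, extra):
        """Rhythmic at threshold t implies rhythmic at every larger threshold."""
        ex = extrema_with_amplitudes(amps)
        at_t, _, _ = rm.rhythmicity(ex, thresh1=t)
        at_larger, _, _ = rm.rhythmicity(ex, thresh1=t + extra)
        if at_t:
            assert at_larger


class TestStability:
    def test_periodic_is_stable(self):
        ex = rm.ExtremaSet.from_times(np.arange(5) * 4.0, np.arange(5) * 4.0 + 2.0)
        flag, d1, d2, _ = rm.stability(ex, thresh2=1e-9)
        assert flag is True
        assert np.abs(d1).max() == 0.0 and np.abs(d2).max() == 0.0

    @pytest.mark.parametrize("thresh2,expected", [(1.5, False), (2.5, True)])
    def test_irregular_wavelengths_against_threshold(self, thresh2, expected):
        """Peak times {0,4,8,14}: wavelengths {4,4,6}, deviations {0,0,2}."""
        ex = rm.ExtremaSet.from_times([0.0, 4.0, 8.0, 14.0], [2.0, 6.0, 10.0])
        flag, d1, _, _ = rm.stability(ex, thresh2=thresh2)
        assert flag is expected
        assert sorted(d1) == pytest.approx([0.0, 0.0, 2.0])

    def test_undefined_with_few_extrema(self):
        ex = rm.ExtremaSet.from_times([0.0, 4.0], [2.0, 6.0])
        flag, _, _, _ = rm.stability(ex)
        assert flag is None


class TestAnalyzeBreathing:
    def test_windowed_rr_tracks_truth(self):
        sig, _ = rm.synth_breath_signal(rm.BreathScript(rr_bpm=12, duration_s=120))
        m = rm.analyze_breathing(sig.samples, fs=5.0)
        assert len(m.rr_values) == 61  # starts 0..60 s
        assert np.all((m.rr_values >= 11) & (m.rr_values <= 13))
        assert m.rhythmic is True and m.stable is True

    def test_short_video_single_scaled_rr(self):
        sig, _ = rm.synth_breath_signal(rm.BreathScript(rr_bpm=12, duration_s=30))
        m = rm.analyze_breathing(sig.samples, fs=5.0)
        assert m.status == "short"
        assert len(m.rr_values) == 1
        assert m.rr_values[0] == pytest.approx(12.0, abs=2.0)
        assert m.rhythmic is None and m.stable is None

    def test_swept_rr_is_monotone_within_one(self):
        """A chirp from 8 to 16 BPM yields a near-monotone RR series."""
        sig, _ = rm.synth_breath_signal(
            rm.BreathScript(rr_bpm=(8.0, 16.0), duration_s=180)
        )
        m = rm.analyze_breathing(sig.samples, fs=5.0)
        assert np.all(np.diff(m.rr_values) >= -1.0)
        assert m.rr_values[0] <= 10 and m.rr_values[-1] >= 14

    def test_all_invalid_track_reports_empty(self):
        m = rm.analyze_breathing(np.full(300, np.nan), fs=5.0)
        assert m.status == "empty"
        assert len(m.rr_values) == 0

    def test_scale_invariance(self):
        """Multiplying the raw signal by k changes neither RR nor the flags."""
        sig, _ = rm.synth_breath_signal(
            rm.BreathScript(rr_bpm=10, duration_s=120, noise_sd=0.1,
                            modulation=([0, 60, 120], [1.0, 1.4, 1.0]), seed=11)
        )
        m1 = rm.analyze_breathing(sig.samples, fs=5.0)
        m2 = rm.analyze_breathing(sig.samples * 37.5, fs=5.0)
        assert np.array_equal(m1.rr_values, m2.rr_values)
        assert m1.rhythmic == m2.rhythmic and m1.stable == m2.stable


class TestEvaluateRR:
    def test_benchmark_pairs_reproduce_published_mae(self):
        gt = [p[0] for p in rm.REFERENCE_RR_PAIRS]
        est = [p[1] for p in rm.REFERENCE_RR_PAIRS]
        mae, report = rm.evaluate_rr(gt, est)
        assert mae == pytest.approx(1.75, abs=1e-12)
        assert len(report) == 8

    def test_identical_and_single_pair(self):
        assert rm.evaluate_rr([5, 9], [5, 9])[0] == 0.0
        assert rm.evaluate_rr([10], [13])[0] == 3.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            rm.evaluate_rr([1, 2], [1])
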