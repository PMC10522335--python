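"""Trace analysis: peaks, intervals, histograms, correlation, phase."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hyphal_dialogue import (
    PeakSeries,
    Trace,
    detect_peaks,
    interval_statistics,
    pearson_correlation,
    phase_relation,
    relative_frequency_histogram,
    slowdown_statistic,
    windowed_correlation,
)
from hyphal_dialogue.synthetic import PulseTrainSpec, generate_pulse_trace


def _sine(period=100.0, duration=350.0, dt=1.0, phase=0.0):
    t = np.arange(0.0, duration + dt / 2, dt)
    return Trace(t, np.sin(2 * np.pi * t / period + phase))


class TestTrace:
    def test_rejects_nonuniform_grid(self):
        with pytest.raises(ValueError, match="uniform"):
            Trace(np.array([0.0, 1.0, 2.5]), np.zeros(3))

    def test_rejects_nonfinite_values(self):
        with pytest.raises(ValueError):
            Trace(np.arange(3.0), np.array([0.0, np.nan, 1.0]))

    def test_window(self):
        tr = _sine().window(100.0, 200.0)
        assert tr.times[0] == 100.0 and tr.times[-1] == 200.0


class TestDetectPeaks:
    def test_sine_maxima(self):
        peaks = detect_peaks(_sine(), min_prominence_fraction=0.2,
                             min_distance=30.0)
        np.testing.assert_allclose(peaks.peak_times, [25.0, 125.0, 225.0, 325.0],
                                   atol=1.0)

    def test_constant_trace_has_no_peaks(self):
        tr = Trace(np.arange(100.0), np.full(100, 3.0))
        assert detect_peaks(tr).n == 0

    def test_short_trace_warns(self):
        tr = Trace(np.arange(2.0), np.array([0.0, 1.0]))
        with pytest.warns(UserWarning):
            assert detect_peaks(tr).n == 0

    def test_recovers_exact_pulse_count_without_jitter(self):
        trace, truth = generate_pulse_trace(
            PulseTrainSpec(period_mean=104.0, period_sd=0.0, n_pulses=10, seed=0))
        peaks = detect_peaks(trace)
        assert peaks.n == 10
        np.testing.assert_allclose(peaks.peak_times, truth, atol=5.0)

    def test_min_distance_keeps_more_prominent_peak(self):
        t = np.arange(0.0, 100.0)
        v = np.zeros(100)
        v[40] = 1.0
        v[50] = 2.0  # within min_distance of the smaller peak
        v[90] = 1.5
        peaks = detect_peaks(Trace(t, v), min_distance=20.0, detrend=False)
        np.testing.assert_array_equal(peaks.peak_times, [50.0, 90.0])

    def test_noise_robustness(self):
        """<= 1 spurious/lost peak per 50 pulses at 5% amplitude noise."""
        clean = PulseTrainSpec(period_mean=104.0, period_sd=28.0, n_pulses=50,
                               seed=11)
        noisy = clean.replace(noise_sd=0.05)
        n_clean = detect_peaks(generate_pulse_trace(clean)[0]).n
        n_noisy = detect_peaks(generate_pulse_trace(noisy)[0]).n
        assert abs(n_noisy - n_clean) <= 1


class TestIntervalStatistics:
    @pytest.mark.parametrize("times,mean,sd,n", [
        ([10.0, 120.0, 230.0, 340.0], 110.0, 0.0, 3),
        ([0.0, 100.0], 100.0, None, 1),
        ([5.0], None, None, 0),
    ])
    def test_examples(self, times, mean, sd, n):
        stats = interval_statistics(PeakSeries(np.array(times),
                                               np.ones(len(times))))
        assert stats.n == n
        if mean is None:
            assert stats.mean is None
        else:
            assert stats.mean == pytest.approx(mean)
        if sd is None:
            assert stats.sd is None
        else:
            assert stats.sd == pytest.approx(sd)

    @given(st.floats(-1000, 1000), st.floats(0.1, 100))
    def test_invariance_under_translation_and_intensity_scaling(self, shift, gain):
        trace, _ = generate_pulse_trace(
            PulseTrainSpec(period_mean=104.0, period_sd=20.0, n_pulses=12, seed=4))
        base = interval_statistics(detect_peaks(trace))
        moved = Trace(trace.times + shift, gain * trace.values)
        other = interval_statistics(detect_peaks(moved))
        assert other.n == base.n
        assert other.mean == pytest.approx(base.mean, rel=1e-9)
        assert other.sd == pytest.approx(base.sd, rel=1e-9, abs=1e-9)


class TestHistogram:
    def test_counting_example(self):
        stats = interval_statistics(
            PeakSeries(np.array([0.0, 100.0, 200.0, 340.0]), np.ones(4)))
        hist = relative_frequency_histogram(stats, bin_width=20.0, origin=0.0)
        np.testing.assert_allclose(hist.bin_edges, [100, 120, 140, 160])
        np.testing.assert_allclose(hist.relative_frequencies, [2 / 3, 0.0, 1 / 3])

    def test_single_interval(self):
        stats = interval_statistics(PeakSeries(np.array([0.0, 50.0]), np.ones(2)))
        hist = relative_frequency_histogram(stats, bin_width=20.0)
        assert hist.relative_frequencies.tolist() == [1.0]

    @given(st.integers(0, 2**31 - 1))
    def test_frequencies_sum_to_one(self, seed):
        trace, truth = generate_pulse_trace(
            PulseTrainSpec(period_mean=104.0, period_sd=28.0, n_pulses=10,
                           seed=seed))
        stats = interval_statistics(PeakSeries(truth, np.ones(len(truth))))
        hist = relative_frequency_histogram(stats)
        assert hist.relative_frequencies.sum() == pytest.approx(1.0)

    def test_empty(self):
        stats = interval_statistics(PeakSeries(np.empty(0), np.empty(0)))
        assert len(relative_frequency_histogram(stats).bin_edges) == 0


class TestPearson:
    def test_trivial_cases(self):
        t = np.arange(3.0)
        a = Trace(t, np.array([1.0, 2.0, 3.0]))
        b = Trace(t, np.array([3.0, 2.0, 1.0]))
        assert pearson_correlation(a, b) == pytest.approx(-1.0)
        assert pearson_correlation(a, a) == pytest.approx(1.0)

    def test_antiphase_sines(self):
        a, b = _sine(100, 300), _sine(100, 300, phase=np.pi)
        assert pearson_correlation(a, b) == pytest.approx(-1.0, abs=1e-6)

    def test_zero_variance_is_marked_undefined(self):
        t = np.arange(10.0)
        assert pearson_correlation(Trace(t, np.ones(10)),
                                   Trace(t, np.arange(10.0))) is None

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation(Trace(np.arange(5.0), np.ones(5)),
                                Trace(np.arange(4.0), np.ones(4)))


class TestWindowedCorrelation:
    def test_identical_traces(self):
        tr = _sine()
        _, corrs = windowed_correlation(tr, tr, 100.0)
        np.testing.assert_allclose(corrs, 1.0)

    def test_nonoverlapping_window_count(self):
        tr = _sine(duration=400.0)
        centers, _ = windowed_correlation(tr, tr, 100.0, step=100.0)
        assert len(centers) == 4

    def test_change_point_crossing(self):
        """Uncorrelated-noise segment followed by an anti-phase segment:
        the correlation series moves from ~0 to strongly negative."""
        rng = np.random.default_rng(0)
        dt, n1 = 5.0, 200
        noise1, noise2 = rng.normal(0, 1, n1), rng.normal(0, 1, n1)
        t2 = np.arange(300) * dt
        wave1 = np.sin(2 * np.pi * t2 / 100.0)
        wave2 = np.sin(2 * np.pi * t2 / 100.0 + np.pi)
        t = np.arange(n1 + 300) * dt
        a = Trace(t, np.concatenate([noise1, wave1]))
        b = Trace(t, np.concatenate([noise2, wave2]))
        centers, corrs = windowed_correlation(a, b, 300.0, 100.0)
        early = corrs[centers < n1 * dt - 300]
        late = corrs[centers > n1 * dt + 300]
        assert np.max(np.abs(early)) < 0.35
        assert np.max(late) < -0.9


class TestPhaseRelation:
    def test_in_phase_sines(self):
        res = phase_relation(_sine(), _sine())
        assert res.label == "in-phase"
        assert res.lag_fraction == pytest.approx(0.0, abs=0.02) or \
            res.lag_fraction == pytest.approx(1.0, abs=0.02)

    def test_anti_phase_sines(self):
        res = phase_relation(_sine(), _sine(phase=np.pi))
        assert res.label == "anti-phase"
        assert res.lag_fraction == pytest.approx(0.5, abs=0.02)

    def test_non_oscillatory_input_flagged(self):
        t = np.arange(200.0)
        flat = Trace(t, np.ones(200))
        res = phase_relation(flat, _sine(duration=199.0))
        assert res.label == "uncoordinated"
        assert "non-oscillatory" in res.note

    def test_symmetry(self):
        """Swapping the arguments keeps the label; lags sum to ~1 (mod 1)."""
        a, b = _sine(100, 400), _sine(100, 400, phase=0.4 * np.pi)
        ab, ba = phase_relation(a, b), phase_relation(b, a)
        assert ab.label == ba.label
        total = (ab.lag_fraction + ba.lag_fraction) % 1.0
        assert min(total, 1 - total) < 0.05


class TestSlowdown:
    def _peaks(self, start, stop, spacing):
        return np.arange(start, stop, spacing)

    def test_arithmetic_example(self):
        a = PeakSeries(np.concatenate([
            self._peaks(0, 1000, 100),
            self._peaks(1000, 2000, 150),
            self._peaks(2000, 3000, 110)]), np.ones(1))
        ratio = slowdown_statistic(a, a, (0, 999), (1000, 1999), (2000, 2999))
        assert ratio == pytest.approx(150 / 105, rel=1e-6)

    def test_uniform_rate_gives_unity(self):
        a = PeakSeries(self._peaks(0, 3000, 100), np.ones(1))
        assert slowdown_statistic(a, a, (0, 1000), (1000, 2000),
                                  (2000, 3000)) == pytest.approx(1.0)

    def test_insufficient_peaks_marked_undefined(self):
        a = PeakSeries(np.array([10.0]), np.ones(1))
        assert slowdown_statistic(a, a, (0, 100), (100, 200), (200, 300)) is None
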