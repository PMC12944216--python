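import numpy as np
import pytest

import mosswave as mw
from conftest import gaussian_wave
from mosswave.segment import ROITraceSet
from mosswave.waves import (
    GAUSS_FW10_PER_SIGMA,
    GAUSS_RISE_PER_SIGMA,
    WaveDetector,
    WaveTable,
    cross_correlation_matrix,
    detect_waves,
    pulse_metrics,
    response_latency,
    wave_intervals,
    wave_probability,
)


def _trace_set(dff, dt=1.0):
    dff = np.atleast_2d(np.asarray(dff, dtype=float))
    k = dff.shape[0]
    return ROITraceSet(
        roi_ids=np.arange(1, k + 1),
        traces=dff + 1.0,
        f0=np.ones(k),
        dff=dff,
        areas=np.full(k, 20),
        centroids=np.zeros((k, 2)),
        frame_interval_s=dt,
    )


class TestDetectWaves:
    def test_flat_noisy_trace_no_waves(self, rng):
        trace = rng.normal(0.0, 1e-3, 500)
        assert detect_waves(trace) == []

    def test_gaussian_closed_forms(self):
        """FW10 = 4.29193*sigma, rise = fall = 1.68692*sigma, within a frame."""
        sigma, A = 14.0, 2.0
        times = np.arange(600.0)
        trace = gaussian_wave(times, 300.0, A, sigma)
        (ev,) = detect_waves(trace)
        assert ev.peak_time_s == 300.0
        assert ev.peak_value == pytest.approx(A, abs=1e-6)
        assert ev.fw10_s == pytest.approx(GAUSS_FW10_PER_SIGMA * sigma, abs=1.0)
        assert ev.fw10_s == pytest.approx(60.1, abs=1.0)
        assert ev.rise_s == pytest.approx(GAUSS_RISE_PER_SIGMA * sigma, abs=1.0)
        assert ev.rise_s == pytest.approx(23.6, abs=1.0)
        assert abs(ev.rise_s - ev.fall_s) <= 1.0  # symmetry

    @pytest.mark.parametrize("sigma", [7.0, 14.0, 28.0])
    def test_closed_forms_across_scales(self, sigma):
        times = np.arange(0.0, 40 * sigma)
        trace = gaussian_wave(times, 20 * sigma, 1.5, sigma)
        (ev,) = detect_waves(trace)
        assert ev.fw10_s == pytest.approx(GAUSS_FW10_PER_SIGMA * sigma, abs=1.0)
        assert ev.rise_s == pytest.approx(GAUSS_RISE_PER_SIGMA * sigma, abs=1.0)
        assert abs(ev.rise_s - ev.fall_s) <= 1.0

    def test_two_waves_interval(self):
        times = np.arange(500.0)
        trace = gaussian_wave(times, 100.0, 2.0, 10.0) + gaussian_wave(times, 300.0, 2.0, 10.0)
        evs = detect_waves(trace)
        assert len(evs) == 2
        assert evs[1].peak_time_s - evs[0].peak_time_s == 200.0

    def test_close_peaks_merged(self):
        times = np.arange(200.0)
        trace = gaussian_wave(times, 100.0, 2.0, 3.0)
        trace[105] = trace.max() * 0.9  # satellite 5 s away
        evs = detect_waves(trace)
        assert len(evs) == 1

    def test_boundary_truncation_flagged(self):
        times = np.arange(150.0)
        trace = gaussian_wave(times, 30.0, 2.0, 20.0)  # left tail cut at t=0
        evs = detect_waves(trace)
        assert len(evs) == 1 and evs[0].truncated
        # an interior wave with full tails is not flagged
        times = np.arange(400.0)
        (ev,) = detect_waves(gaussian_wave(times, 200.0, 2.0, 20.0))
        assert not ev.truncated


class TestWaveIntervals:
    def _events(self, times):
        return [
            mw.waves.WaveEvent(1, t, 1, 1, t - 10, t + 10, 20, 5, 5, 0.0)
            for t in times
        ]

    def test_regular_peaks(self):
        out = wave_intervals(self._events([0.0, 150.0, 300.0]))
        np.testing.assert_array_equal(out["intervals_s"], [150.0, 150.0])
        assert out["cv_pct"] == 0.0
        assert out["frequency_per_min"] == pytest.approx(0.4)

    def test_hand_computed_cv(self):
        out = wave_intervals(self._events([0.0, 100.0, 300.0]))
        np.testing.assert_array_equal(out["intervals_s"], [100.0, 200.0])
        assert out["mean_s"] == 150.0
        assert out["cv_pct"] == pytest.approx(100 * np.sqrt(5000) / 150, abs=0.05)
        assert out["cv_pct"] == pytest.approx(47.1, abs=0.1)

    def test_too_few_events_empty(self):
        out = wave_intervals(self._events([50.0]))
        assert out["intervals_s"].size == 0
        assert np.isnan(out["cv_pct"])

    def test_within_roi_cv_below_across_roi_cv(self, default_colony):
        """Programmed per-ROI characteristic intervals: within-ROI interval CV
        is below the pooled across-ROI CV."""
        _, gt, _ = default_colony
        within, pooled = [], []
        for region in gt.program.waves:
            t = np.sort([w.peak_time_s for w in region if w.peak_time_s > 300])
            iv = np.diff(t)
            pooled.extend(iv)
            if iv.size >= 3:
                within.append(iv.std(ddof=1) / iv.mean())
        pooled = np.asarray(pooled)
        across_cv = pooled.std(ddof=1) / pooled.mean()
        assert np.median(within) < across_cv


class TestResponseLatency:
    def test_gaussian_closed_form(self):
        times = np.arange(600.0)
        onset = 200.0
        trace = gaussian_wave(times, onset + 30.0, 2.0, 10.0)
        evs = detect_waves(trace)
        lat = response_latency(evs, onset)
        # 10% point of a Gaussian: peak - sigma*sqrt(2 ln 10)
        assert lat == pytest.approx(30.0 - 10.0 * np.sqrt(2 * np.log(10)), abs=0.5)
        assert lat == pytest.approx(8.5, abs=0.5)

    def test_wave_before_onset_missing(self):
        times = np.arange(600.0)
        trace = gaussian_wave(times, 100.0, 2.0, 10.0)
        evs = detect_waves(trace)
        assert response_latency(evs, 400.0) is None

    def test_latency_drift_recovered(self):
        """5-pulse protocol with programmed 25->64 s drift: recovered per-pulse
        mean latencies are monotonically nondecreasing."""
        from mosswave.synthetic import WaveParams

        pulses = [(i * 360.0, i * 360.0 + 300.0) for i in range(5)]
        prot = mw.StimulusProtocol(pulses=pulses, recording_duration_s=1900.0)
        params = WaveParams(tip_interval_median_s=None, spont_interval_mean_s=None,
                            latency_sd_s=8.0, response_prob=1.0)
        per_pulse = [[] for _ in range(5)]
        for seed in range(25):
            g = mw.build_geometry(seed=seed, n_filaments=2, cells_per_filament=2)
            prog = mw.schedule_waves(g, prot, params, seed=seed + 50)
            _, _, dff = mw.synthetic.program_traces(prog, frame_interval_s=1.0)
            for r in range(dff.shape[0]):
                evs = detect_waves(dff[r])
                for i, (on, off) in enumerate(pulses):
                    win = [e for e in evs if on <= e.peak_time_s < on + 360.0]
                    if win:
                        lat = response_latency(win, on)
                        if lat is not None and lat >= 0:
                            per_pulse[i].append(lat)
        means = np.array([np.mean(v) for v in per_pulse])
        assert (np.diff(means) > -2.0).all()
        assert means[-1] > means[0] + 20

    def test_typical_latency_magnitude(self, default_colony):
        """First-pulse latencies on the benchmark colony are tens of seconds."""
        _, gt, _ = default_colony
        _, _, dff = mw.synthetic.program_traces(gt.program, frame_interval_s=1.0)
        lats = []
        for r in range(dff.shape[0]):
            evs = detect_waves(dff[r])
            lat = response_latency(evs, 300.0)
            if lat is not None:
                lats.append(lat)
        assert 5.0 < np.mean(lats) < 80.0


class TestWaveProbability:
    def _table(self, spans):
        evs = [
            mw.waves.WaveEvent(i + 1, (a + b) / 2, 1, 1, a, b, b - a, 5, 5, 0.0)
            for i, (a, b) in enumerate(spans)
        ]
        return WaveTable(events=evs)

    def test_synchronized_wave_probability_one(self):
        table = self._table([(100, 160)] * 4)
        times = np.arange(300.0)
        p = wave_probability(table, 4, times)
        assert p[130] == 1.0
        assert p[50] == 0.0

    def test_no_waves_zero(self):
        p = wave_probability(WaveTable(), 5, np.arange(100.0))
        np.testing.assert_array_equal(p, 0.0)

    def test_partial_fraction(self):
        table = self._table([(100, 160), (120, 180), (400, 420), (500, 520)])
        p = wave_probability(table, 4, np.arange(600.0))
        assert p[130] == 0.5
        assert p.min() >= 0.0 and p.max() <= 1.0

    def test_integral_equals_mean_fw10_for_synchronized_wave(self):
        table = self._table([(100, 160), (100, 170)])
        times = np.arange(0.0, 300.0, 1.0)
        p = wave_probability(table, 2, times)
        mean_fw10 = np.mean([60, 70])
        assert np.trapezoid(p, times) == pytest.approx(mean_fw10, abs=1.5)


class TestCrossCorrelation:
    def test_identical_traces(self, rng):
        x = rng.normal(size=300)
        m = cross_correlation_matrix(np.stack([x, x]), max_lag_s=10)
        assert m[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_shifted_copy_recovered(self, rng):
        x = np.convolve(rng.normal(size=730), np.ones(10) / 10, mode="valid")
        a, b = x[30:630], x[:600]  # b = a delayed by 30 s
        m = cross_correlation_matrix(np.stack([a, b]), max_lag_s=40)
        assert m[0, 1] == pytest.approx(1.0, abs=1e-9)
        m_short = cross_correlation_matrix(np.stack([a, b]), max_lag_s=5)
        assert m_short[0, 1] < 0.9

    def test_zero_variance_flagged_nan(self, rng):
        x = rng.normal(size=100)
        m = cross_correlation_matrix(np.stack([x, np.zeros(100)]), max_lag_s=10)
        assert np.isnan(m[0, 1]) and np.isnan(m[1, 0])
        assert m[0, 0] == 1.0

    def test_independent_noise_low_correlation(self):
        """Null distribution: independent white noise traces (t=3600) show
        max lagged correlation < 0.2 in >95% of pairs."""
        rng = np.random.default_rng(11)
        X = rng.normal(size=(12, 3600))
        m = cross_correlation_matrix(X, max_lag_s=120)
        off = m[np.triu_indices(12, 1)]
        assert (np.abs(off) < 0.2).mean() > 0.95


class TestPulseMetrics:
    def _setup(self, scale_second=1.0):
        times = np.arange(720.0)
        pulses = [(0.0, 60.0), (360.0, 420.0)]
        prot = mw.StimulusProtocol(pulses=pulses, recording_duration_s=720.0)
        base = gaussian_wave(times, 80.0, 2.0, 15.0)
        second = gaussian_wave(times, 440.0, 2.0 * scale_second, 15.0)
        ts = _trace_set(np.stack([base + second] * 3))
        table = WaveDetector().fit(ts).table_
        return table, ts, prot

    def test_identical_responses_auc_one(self):
        table, ts, prot = self._setup(1.0)
        pm = pulse_metrics(table, ts, prot)
        np.testing.assert_allclose(pm.auc_normalized, [1.0, 1.0], atol=0.02)

    def test_auc_linearity(self):
        table, ts, prot = self._setup(0.5)
        pm = pulse_metrics(table, ts, prot)
        assert pm.auc_normalized[1] == pytest.approx(0.5, abs=0.02)

    def test_wave_counts_partition(self):
        table, ts, prot = self._setup(1.0)
        pm = pulse_metrics(table, ts, prot)
        assert pm.waves_per_roi.sum() * ts.n_rois == len(table)

    def test_snippet_window(self):
        table, ts, _ = self._setup(1.0)
        sn = table.snippets(ts, window_s=120.0)
        assert sn.shape[1] == 121
        np.testing.assert_allclose(sn.max(axis=1), 1.0)
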