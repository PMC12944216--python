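import numpy as np
import pytest

import mosswave as mw
from mosswave.synthetic import (
    AcquisitionModel,
    ScheduledWave,
    WaveParams,
    program_traces,
    rasterize_geometry,
)

SILENT = WaveParams(interval_mean_s=None, tip_interval_median_s=None,
                    spont_interval_mean_s=None)


def _protocol(pulses, duration):
    return mw.StimulusProtocol(pulses=pulses, recording_duration_s=duration)


class TestBuildGeometry:
    def test_minimal_colony(self):
        g = mw.build_geometry(seed=1, n_filaments=1, cells_per_filament=1, branch_prob=0)
        assert len(g.filaments) == 1
        assert len(g.cells) == 1
        assert g.cells[0].cell_type in ("CA", "CH")
        assert g.n_regions >= 1

    def test_deterministic(self):
        a = mw.build_geometry(seed=1, n_filaments=2, cells_per_filament=5, branch_prob=0.3)
        b = mw.build_geometry(seed=1, n_filaments=2, cells_per_filament=5, branch_prob=0.3)
        assert len(a.cells) == len(b.cells)
        for fa, fb in zip(a.filaments, b.filaments):
            np.testing.assert_array_equal(fa, fb)
        assert [c.cell_type for c in a.cells] == [c.cell_type for c in b.cells]

    def test_cell_count_without_branches(self):
        g = mw.build_geometry(seed=1, n_filaments=2, cells_per_filament=5, branch_prob=0.0)
        assert len(g.cells) == 10

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            mw.build_geometry(seed=0, n_filaments=0, cells_per_filament=3)

    def test_ca_tips_have_exactly_one_apical_region(self):
        """Exhaustive scan: every CA tip cell owns exactly one CA* region at
        its apical (distal) end."""
        g = mw.build_geometry(seed=7, n_filaments=3, cells_per_filament=4, branch_prob=0.3)
        ca_tips = [i for i, c in enumerate(g.cells) if c.cell_type == "CA"]
        assert ca_tips, "expected at least one CA tip in this colony"
        for ci in ca_tips:
            regions = [r for r in g.roi_regions if r.cell_index == ci]
            stars = [r for r in regions if r.cell_type == "CA*"]
            assert len(stars) == 1
            star = stars[0]
            assert star.s1_um == pytest.approx(g.cells[ci].s1_um)  # apical end
        # CA* occurs nowhere else
        for r in g.roi_regions:
            if r.cell_type == "CA*":
                assert g.cells[r.cell_index].cell_type == "CA"

    def test_cells_contiguous_within_filament(self):
        g = mw.build_geometry(seed=3, n_filaments=2, cells_per_filament=4)
        for fid in range(len(g.filaments)):
            cells = [c for c in g.cells if c.filament_id == fid]
            cells.sort(key=lambda c: c.s0_um)
            for a, b in zip(cells, cells[1:]):
                assert a.s1_um == pytest.approx(b.s0_um)


class TestScheduleWaves:
    def test_silent_colony(self):
        g = mw.build_geometry(seed=1, n_filaments=2, cells_per_filament=2)
        prog = mw.schedule_waves(g, _protocol([], 600.0), SILENT, seed=0)
        assert prog.n_waves() == 0

    def test_empty_geometry_rejected(self):
        g = mw.build_geometry(seed=1, n_filaments=1, cells_per_filament=1)
        g.roi_regions = []
        with pytest.raises(ValueError):
            mw.schedule_waves(g, _protocol([], 100.0), seed=0)

    def test_refractory_period_respected(self):
        g = mw.build_geometry(seed=2, n_filaments=3, cells_per_filament=3)
        prog = mw.schedule_waves(g, _protocol([(100.0, 2000.0)], 2000.0), seed=4)
        for region in prog.waves:
            t = np.array([w.peak_time_s for w in region])
            if t.size > 1:
                assert np.diff(np.sort(t)).min() >= prog.params.refractory_s

    def test_pulse_locking_and_latency_drift(self):
        """Monte Carlo over many seeds: every responsive ROI fires once per
        pulse window and mean latency is nondecreasing across pulses."""
        pulses = [(i * 240.0, i * 240.0 + 60.0) for i in range(10)]
        prot = _protocol(pulses, 2640.0)
        params = WaveParams(
            tip_interval_median_s=None, spont_interval_mean_s=None,
            latency_drift_s_per_pulse=2.0, response_prob=1.0,
        )
        lat_sums = np.zeros(10)
        n_regions = 0
        offset = np.sqrt(2 * np.log(10))
        for seed in range(100):
            g = mw.build_geometry(seed=seed, n_filaments=1, cells_per_filament=2)
            prog = mw.schedule_waves(g, prot, params, seed=seed + 1000)
            for region in prog.waves:
                locked = [w for w in region if w.stimulus_locked]
                per_pulse = {w.pulse_index for w in locked}
                assert per_pulse == set(range(10))
                for w in locked:
                    on = pulses[w.pulse_index][0]
                    lat_sums[w.pulse_index] += (
                        w.peak_time_s - offset * w.sigma_s - on
                    )
            n_regions += len(prog.waves)
        mean_lat = lat_sums / n_regions
        # drift 2 s/pulse with jitter SD 24/sqrt(n~200): clearly nondecreasing
        assert (np.diff(mean_lat) > -1.5).all()
        assert mean_lat[-1] > mean_lat[0] + 10

    def test_within_roi_interval_cv(self):
        """One long pulse, characteristic interval 150 s, CV 19%: realized
        per-ROI CV lies in [10%, 30%] for ROIs with >= 8 waves."""
        prot = _protocol([(0.0, 1800.0)], 1800.0)
        params = WaveParams(
            interval_mean_s=150.0, interval_across_cv=0.0,
            tip_interval_median_s=None, spont_interval_mean_s=None,
            latency_sd_s=5.0, fw10_cv=0.0,
        )
        cvs = []
        for seed in range(30):
            g = mw.build_geometry(seed=seed, n_filaments=1, cells_per_filament=1)
            prog = mw.schedule_waves(g, prot, params, seed=seed + 77)
            for region in prog.waves:
                t = np.sort([w.peak_time_s for w in region])
                if t.size >= 8:
                    iv = np.diff(t)
                    cvs.append(iv.std(ddof=1) / iv.mean())
        assert len(cvs) >= 10
        assert 0.10 < np.median(cvs) < 0.30

    def test_deterministic(self):
        g = mw.build_geometry(seed=2, n_filaments=2, cells_per_filament=3)
        prot = _protocol([(100.0, 500.0)], 600.0)
        a = mw.schedule_waves(g, prot, seed=9)
        b = mw.schedule_waves(g, prot, seed=9)
        assert a.schedule_dict() == b.schedule_dict()


class TestRenderStack:
    def _one_region(self):
        g = mw.build_geometry(seed=4, n_filaments=1, cells_per_filament=1)
        prot = _protocol([], 600.0)
        prog = mw.schedule_waves(g, prot, SILENT, seed=0)
        return g, prog

    def test_static_scene_without_noise_or_waves(self):
        g, prog = self._one_region()
        acq = AcquisitionModel(noise=False)
        stack, _ = mw.render_stack(g, prog, acq, duration_s=20, seed=0)
        assert np.ptp(stack.data.astype(int), axis=0).max() == 0

    def test_closed_form_wave_amplitude(self):
        g, prog = self._one_region()
        prog.waves[0] = [ScheduledWave(300.0, 2.0, 14.0)]
        acq = AcquisitionModel(noise=False, background_level=0.0)
        stack, gt = mw.render_stack(g, prog, acq, duration_s=600, seed=0)
        lab = gt.label_map.labels
        trace = stack.data[:, lab == 1].mean(axis=1)
        f0 = trace.min()
        dff = (trace - f0) / f0
        assert np.argmax(dff) == 300
        assert dff.max() == pytest.approx(2.0, rel=0.05)

    def test_bit_identical_for_fixed_seed(self):
        g = mw.build_geometry(seed=6, n_filaments=2, cells_per_filament=2)
        prot = _protocol([(100.0, 600.0)], 600.0)
        prog = mw.schedule_waves(g, prot, seed=1)
        a, _ = mw.render_stack(g, prog, duration_s=60, seed=5)
        b, _ = mw.render_stack(g, prog, duration_s=60, seed=5)
        np.testing.assert_array_equal(a.data, b.data)

    def test_label_map_matches_rendered_footprint(self):
        g, prog = self._one_region()
        lm, weights = rasterize_geometry(g)
        footprint = weights.max(axis=0) > 0
        np.testing.assert_array_equal(lm.labels > 0, footprint)

    def test_geometry_exceeding_bounds_raises(self):
        g, prog = self._one_region()
        acq = AcquisitionModel(noise=False, frame_shape=(5, 5))
        with pytest.raises(ValueError, match="filament"):
            mw.render_stack(g, prog, acq, duration_s=10, seed=0)

    def test_noiseless_trace_matches_program(self):
        """ROI-averaged rendered dF/F0 equals the programmed trace up to
        PSF-bleed and quantization tolerance."""
        g = mw.build_geometry(seed=8, n_filaments=1, cells_per_filament=2)
        prot = _protocol([(50.0, 550.0)], 600.0)
        prog = mw.schedule_waves(g, prot, seed=3)
        acq = AcquisitionModel(noise=False, background_level=0.0)
        stack, gt = mw.render_stack(g, prog, acq, duration_s=600, seed=0)
        _, _, dff_true = program_traces(prog, 600.0)
        lab = gt.label_map.labels
        errs = []
        for r in range(gt.label_map.n_rois):
            trace = stack.data[:, lab == r + 1].mean(axis=1)
            f0 = np.percentile(trace, 1)
            dff = (trace - f0) / f0
            errs.append(np.abs(dff - dff_true[r]).max())
        # residual error is PSF bleed plus 16-bit quantization
        assert max(errs) < 0.05, f"per-region max |rendered - programmed| = {errs}"

    def test_programmed_waves_time_symmetric(self):
        """|rise - fall| = 0 by construction on the noiseless programmed trace."""
        times = np.arange(0.0, 600.0)
        wave = 2.0 * np.exp(-((times - 300.0) ** 2) / (2 * 16.0**2))
        np.testing.assert_allclose(wave[1:300], wave[301:][::-1], atol=1e-12)
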