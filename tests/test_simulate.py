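import numpy as np
import pytest
from dataclasses import replace

from sdrmap.errors import ParameterError, SpecificationError
from sdrmap.grid import Wall, build_default_grid
from sdrmap.simulate import (ChannelQuality, ChannelQualityTruth, EpisodeSpec,
                             PacingBlock, RTFieldParams, RhythmParams,
                             egm_waveform_derivative, generate_beat_series,
                             generate_egm, generate_rt_field,
                             generate_surface_lead, n_samples_for_window)

FS = 2048.0


def flat_params(rv=360.0, lv=430.0, sep=395.0, **kw):
    kw.setdefault("at_noise_sd_ms", 0.0)
    return RTFieldParams.from_wall_means(
        {Wall.RV: rv, Wall.LV: lv, Wall.SEPTUM: sep}, rr_ms=1000.0, **kw)


class TestRTField:
    def test_zero_noise_zero_gradients_constant_per_wall(self, default_grid):
        field = generate_rt_field(default_grid, flat_params(), 1000.0)
        for wall, expect in ((Wall.RV, 360.0), (Wall.LV, 430.0)):
            vals = [v for a, v in zip(default_grid.electrodes(), field.rt_ms)
                    if a.wall is wall]
            assert np.allclose(vals, expect)

    def test_same_seed_same_field(self, default_grid):
        p = flat_params(dispersion_noise_sd_ms=12.0, at_noise_sd_ms=4.0,
                        seed=42)
        f1 = generate_rt_field(default_grid, p, 900.0)
        f2 = generate_rt_field(default_grid, p, 900.0)
        assert np.array_equal(f1.rt_ms, f2.rt_ms)
        assert np.array_equal(f1.at_ms, f2.at_ms)

    def test_interventricular_difference_grows_by_closed_form(self, default_grid):
        """beta_LV 0.10 vs beta_RV 0.04: RR 600 -> 1000 widens the LV-RV
        mean difference by 0.06 x 400 = 24 ms exactly (no noise)."""
        slopes = {Wall.RV: 0.04, Wall.LV: 0.10, Wall.SEPTUM: 0.07}
        p = RTFieldParams(rt_intercept_ms={Wall.RV: 300, Wall.LV: 320,
                                           Wall.SEPTUM: 310},
                          restitution_slope_ms_per_ms=slopes,
                          at_noise_sd_ms=0.0)
        diff = {}
        for rr in (600.0, 1000.0):
            f = generate_rt_field(default_grid, p, rr)
            diff[rr] = f.wall_mean(Wall.LV) - f.wall_mean(Wall.RV)
        assert diff[1000.0] - diff[600.0] == pytest.approx(24.0, abs=1e-9)

    def test_divergence_mode_requires_lv_steeper(self):
        with pytest.raises(ParameterError):
            RTFieldParams(rt_intercept_ms={Wall.RV: 300},
                          restitution_slope_ms_per_ms={Wall.RV: 0.1,
                                                       Wall.LV: 0.1,
                                                       Wall.SEPTUM: 0.1})

    def test_invalid_rr_rejected(self, default_grid):
        with pytest.raises(ParameterError):
            generate_rt_field(default_grid, flat_params(), 0.0)


class TestEgm:
    def test_sample_count_floor(self):
        assert n_samples_for_window(2048.0, 1200.0) == 2457
        tr = generate_egm(40, 363, fs_hz=2048.0, beat_window_ms=1200.0)
        assert tr.signal.size == 2457

    def test_analytic_derivative_extrema_at_fiducials(self):
        """Oracle: argmin/argmax of the closed-form dV/dt on the sample
        grid sit at the requested AT/RT within one sample."""
        at, rt = 40.0, 363.0
        t = np.arange(n_samples_for_window(FS, 600.0)) / FS * 1000.0
        d = egm_waveform_derivative(t, at, rt)
        qrs = (t >= 0) & (t <= 150)
        tw = (t > 150) & (t <= 540)
        dt = 1000.0 / FS
        assert abs(t[qrs][np.argmin(d[qrs])] - at) <= dt
        assert abs(t[tw][np.argmax(d[tw])] - rt) <= dt

    def test_injury_offset_matches_t_amplitude(self):
        """injury_fraction 1.0 shifts the ST baseline by one T amplitude
        (within 2%), measured on the constructed waveform."""
        q = ChannelQualityTruth(ChannelQuality.INJURY, injury_fraction=1.0)
        tr = generate_egm(40, 363, q, FS, 600.0)
        clean = generate_egm(40, 363, fs_hz=FS, beat_window_ms=600.0)
        t = np.arange(tr.signal.size) / FS * 1000.0
        st = (t >= 120) & (t <= 160)
        tq = (t >= 0) & (t <= 20)
        offset = (np.median(tr.signal[st]) - np.median(tr.signal[tq]))
        t_amp = np.ptp(clean.signal[(t > 150)])
        assert offset == pytest.approx(t_amp, rel=0.02)

    def test_fiducial_order_enforced(self):
        with pytest.raises(ParameterError):
            generate_egm(400, 300, fs_hz=FS, beat_window_ms=600.0)

    def test_noisy_channels_reproducible_with_rng(self):
        q = ChannelQualityTruth(ChannelQuality.NOISY)
        a = generate_egm(40, 363, q, FS, 600.0,
                         rng=np.random.default_rng(7)).signal
        b = generate_egm(40, 363, q, FS, 600.0,
                         rng=np.random.default_rng(7)).signal
        assert np.array_equal(a, b)


class TestBeatSeries:
    def test_paced_beat_count(self):
        rec = generate_beat_series(RhythmParams(
            blocks=(PacingBlock("B", 100.0, 120.0),), seed=0))
        assert len(rec.beats) == 200
        assert (rec.beats["beat_class"] == "PACED").all()

    def test_episode_yields_consecutive_ectopic_run(self):
        spec = EpisodeSpec(n_beats=12, duration_s=6.0, start_s=20.0)
        rec = generate_beat_series(RhythmParams(
            blocks=(PacingBlock("B", 60.0, 60.0, episodes=(spec,)),), seed=0))
        cls = rec.beats["beat_class"].tolist()
        runs, cur = [], 0
        for c in cls:
            cur = cur + 1 if c == "ECTOPIC" else 0
            runs.append(cur)
        assert max(runs) == 12

    def test_long_episode_without_defib_rejected(self):
        with pytest.raises(SpecificationError):
            EpisodeSpec(n_beats=30, duration_s=12.0, n_defibs=0)

    def test_episode_exceeding_block_rejected(self):
        with pytest.raises(SpecificationError):
            PacingBlock("B", 60.0, 30.0,
                        episodes=(EpisodeSpec(8, 5.0, start_s=28.0),))

    def test_determinism(self):
        params = RhythmParams(blocks=(PacingBlock("B", 80.0, 60.0,
                                                  ectopy_hazard=0.3),),
                              seed=9)
        a = generate_beat_series(params).beats
        b = generate_beat_series(params).beats
        assert a.equals(b)

    def test_polymorphic_runs_alternate_and_monomorphic_do_not(self):
        def signs(poly):
            spec = EpisodeSpec(n_beats=8, duration_s=4.0, start_s=10.0,
                               polymorphic=poly)
            rec = generate_beat_series(RhythmParams(
                blocks=(PacingBlock("B", 60.0, 60.0, episodes=(spec,)),),
                seed=1))
            ect = rec.beats[rec.beats["beat_class"] == "ECTOPIC"]
            return np.sign(ect["morphology_index"].to_numpy())
        assert (np.diff(signs(True)) != 0).any()
        assert (np.diff(signs(False)) == 0).all()


class TestSurfaceLead:
    def test_qt_measurable_within_2ms(self):
        from sdrmap.arrhythmia import measure_lead_intervals
        lead = generate_surface_lead([100 + 600 * i for i in range(6)], 453.0)
        m = measure_lead_intervals(lead.signal, 1024.0, n_beats=5)
        assert m.qt_ms == pytest.approx(453.0, abs=2.0)
        assert m.rr_ms == pytest.approx(600.0, abs=1.0)

    def test_qt_longer_than_rr_rejected(self):
        with pytest.raises(ParameterError):
            generate_surface_lead([0.0, 600.0], 700.0)

    def test_empty_beat_stream_gives_empty_signal(self):
        assert generate_surface_lead([], 400.0).signal.size == 0
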