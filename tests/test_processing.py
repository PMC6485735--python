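import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vhlift import processing as proc
from vhlift.models import SineLiftParams, lf_curve
from vhlift.synthetic import LiftSimConfig, synth_lift_trial

FS = 500.0
DT = 1.0 / FS


def make_trace(n=1000, **channels):
    """Trace with constant-zero channels unless overridden."""
    time = np.arange(n) * DT
    base = {k: np.zeros(n) for k in
            ("thumb_normal", "index_normal", "thumb_vertical", "index_vertical")}
    base.update(channels)
    return proc.ForceTrace(time=time, **base)


class TestForceTrace:
    def test_rejects_nonuniform_time(self):
        t = np.arange(1000) * DT
        t[500] += 0.5 * DT
        with pytest.raises(ValueError, match="uniform"):
            proc.ForceTrace(
                time=t,
                thumb_normal=np.zeros(1000),
                index_normal=np.zeros(1000),
                thumb_vertical=np.zeros(1000),
                index_vertical=np.zeros(1000),
            )

    def test_rejects_mismatched_lengths(self):
        with pytest.raises(ValueError, match="length"):
            make_trace(thumb_normal=np.zeros(999))

    def test_sampling_rate(self):
        assert make_trace().sampling_rate == pytest.approx(FS)


class TestPreprocess:
    def test_dc_signal_unchanged(self):
        trace = make_trace(thumb_vertical=np.ones(1000))
        out = proc.preprocess(trace)
        np.testing.assert_allclose(out.thumb_vertical, 1.0, atol=1e-9)

    def test_50hz_sinusoid_strongly_attenuated(self):
        t = np.arange(2000) * DT
        trace = make_trace(n=2000, thumb_vertical=np.sin(2 * np.pi * 50 * t))
        out = proc.preprocess(trace)
        # steady-state amplitude, away from the edges
        amp = np.max(np.abs(out.thumb_vertical[500:1500]))
        assert amp < 0.05

    def test_missing_sample_linearly_interpolated(self):
        x = np.ones(1000)
        x[400], x[401] = 1.0, 2.0
        x[402] = np.nan  # between 2.0 and values back at 1.0? craft midpoint
        x = np.ones(1000)
        x[400] = 1.0
        x[402] = 2.0
        x[401] = np.nan
        trace = make_trace(thumb_vertical=x)
        filled = proc._interpolate_missing(trace.thumb_vertical, 0.1)
        assert filled[401] == pytest.approx(1.5)

    def test_too_many_missing_rejected(self):
        x = np.ones(1000)
        x[:200] = np.nan  # 20% missing
        with pytest.raises(proc.TechnicalError):
            proc.preprocess(make_trace(thumb_vertical=x))

    def test_short_trace_rejected(self):
        with pytest.raises(proc.TechnicalError, match="1 s"):
            proc.preprocess(make_trace(n=200))

    def test_zero_phase_symmetric_pulse_peak_unmoved(self):
        n = 2000
        x = np.zeros(n)
        center = 1000
        width = 100
        idx = np.arange(n)
        pulse = np.exp(-0.5 * ((idx - center) / width) ** 2)
        out = proc.preprocess(make_trace(n=n, thumb_vertical=pulse))
        assert abs(int(np.argmax(out.thumb_vertical)) - center) <= 1


class TestGripLoad:
    def test_lf_is_sum_of_verticals(self):
        trace = make_trace(thumb_vertical=np.ones(1000), index_vertical=np.ones(1000))
        gls = proc.grip_load(trace)
        np.testing.assert_allclose(gls.lf, 2.0)

    def test_gf_is_mean_of_normals(self):
        trace = make_trace(
            thumb_normal=np.full(1000, 2.0), index_normal=np.full(1000, 4.0)
        )
        gls = proc.grip_load(trace)
        np.testing.assert_allclose(gls.gf, 3.0)

    def test_ramp_rate(self):
        t = np.arange(1000) * DT
        trace = make_trace(thumb_vertical=3.0 * t)
        gls = proc.grip_load(trace)
        np.testing.assert_allclose(gls.lfr[1:-1], 3.0, atol=1e-9)


class TestDetectEvents:
    def test_ramp_crossings(self):
        t = np.arange(1500) * DT
        trace = make_trace(n=1500, thumb_vertical=t, thumb_normal=2 * t)
        gls = proc.grip_load(trace)
        ev = proc.detect_events(gls, cube_weight=1.962)
        assert ev.lf_onset == pytest.approx(0.1, abs=DT / 2)
        assert ev.liftoff == pytest.approx(1.962, abs=DT / 2)

    def test_all_zero_lf_raises_no_lift(self):
        gls = proc.grip_load(make_trace())
        with pytest.raises(proc.NoLiftError):
            proc.detect_events(gls, cube_weight=1.0)

    def test_no_weight_crossing_raises(self):
        t = np.arange(1000) * DT
        trace = make_trace(thumb_vertical=np.minimum(t, 0.5), thumb_normal=2 * t)
        gls = proc.grip_load(trace)
        with pytest.raises(proc.NoLiftoffError):
            proc.detect_events(gls, cube_weight=1.962)

    @pytest.mark.parametrize("delay", [100.0, 200.0])
    def test_sum_model_liftoff_at_contact_plus_d_plus_delay(self, delay):
        cfg = LiftSimConfig(noise_sd=0.0, visual_delay=delay, true_w_v=0.36)
        rec = synth_lift_trial(cfg)
        gls = proc.grip_load(rec.trace)
        ev = proc.detect_events(gls, cfg.cube_weight)
        expected = rec.truth_contact + cfg.true_duration_d + delay / 1000.0
        assert ev.liftoff == pytest.approx(expected, abs=DT)

    def test_event_ordering_invariant(self):
        cfg = LiftSimConfig(noise_sd=0.02, visual_delay=100, seed=9)
        rec = synth_lift_trial(cfg)
        gls = proc.grip_load(proc.preprocess(rec.trace))
        ev = proc.detect_events(gls, cfg.cube_weight)
        assert ev.lf_onset <= ev.liftoff
        assert ev.gf_onset <= ev.liftoff


class TestForceParameters:
    def test_lfr_max_on_noiseless_base_curve(self):
        p = SineLiftParams(m=1.962, d=0.4, onset=0.5)
        t = np.arange(0, 1.5, DT)
        lf = lf_curve(p, t)
        trace = make_trace(n=t.size, thumb_vertical=lf, thumb_normal=2 * lf)
        gls = proc.grip_load(trace)
        ev = proc.detect_events(gls, 1.962)
        fp = proc.force_parameters(gls, ev)
        assert fp.lfr_max == pytest.approx(2 * 1.962 / 0.4, rel=1e-3)

    def test_lpd_is_liftoff_minus_onset(self):
        gls = proc.grip_load(make_trace(thumb_vertical=np.linspace(0, 4, 1000)))
        ev = proc.LiftEvents(lf_onset=0.2, gf_onset=0.2, liftoff=0.7)
        fp = proc.force_parameters(gls, ev)
        assert fp.lpd == pytest.approx(0.5)

    def test_gf_at_liftoff_on_ramp(self):
        t = np.arange(1000) * DT
        trace = make_trace(thumb_vertical=5 * t, thumb_normal=5 * t, index_normal=5 * t)
        gls = proc.grip_load(trace)
        ev = proc.LiftEvents(lf_onset=0.1, gf_onset=0.1, liftoff=0.6)
        fp = proc.force_parameters(gls, ev)
        assert fp.gf_at_lo == pytest.approx(3.0, abs=1e-9)

    def test_window_truncation_flagged(self):
        gls = proc.grip_load(make_trace(thumb_vertical=np.linspace(0, 4, 1000)))
        ev = proc.LiftEvents(lf_onset=0.01, gf_onset=0.01, liftoff=1.97)
        fp = proc.force_parameters(gls, ev)
        assert fp.truncated_window


class TestBinnedAreas:
    @staticmethod
    def _gls_with_lf(lf):
        trace = make_trace(n=lf.size, thumb_vertical=lf)
        return proc.grip_load(trace)

    def test_constant_signal_bins(self):
        gls = self._gls_with_lf(np.ones(1000))
        ev = proc.LiftEvents(lf_onset=0.0, gf_onset=0.2, liftoff=0.5)
        bins = proc.binned_areas(gls, ev)
        np.testing.assert_allclose(bins.lf, 0.1, atol=1e-9)

    def test_bins_sum_to_total_area(self):
        rng = np.random.default_rng(3)
        lf = rng.normal(0, 1, 1200)
        gls = self._gls_with_lf(lf)
        ev = proc.LiftEvents(lf_onset=0.0, gf_onset=0.1, liftoff=0.5)
        bins = proc.binned_areas(gls, ev)
        i0 = 50
        total = np.trapezoid(gls.lf[i0 : i0 + 501], dx=DT)
        assert np.sum(bins.lf) == pytest.approx(total, abs=1e-9)

    def test_ramp_first_bin(self):
        t = np.arange(1000) * DT
        gls = self._gls_with_lf(t)  # lf(t) = t starting at onset 0
        ev = proc.LiftEvents(lf_onset=0.0, gf_onset=0.0, liftoff=0.5)
        bins = proc.binned_areas(gls, ev)
        assert bins.lf[0] == pytest.approx(0.005, abs=1e-9)

    def test_invariant_to_preonset_trimming(self):
        rng = np.random.default_rng(4)
        lf = rng.normal(1, 0.2, 1400)
        gls_full = self._gls_with_lf(lf)
        ev_full = proc.LiftEvents(lf_onset=0.0, gf_onset=0.4, liftoff=0.6)
        trimmed = self._gls_with_lf(lf[100:])
        ev_trim = proc.LiftEvents(lf_onset=0.0, gf_onset=0.2, liftoff=0.4)
        b1 = proc.binned_areas(gls_full, ev_full)
        b2 = proc.binned_areas(trimmed, ev_trim)
        np.testing.assert_allclose(b1.lf, b2.lf, atol=1e-12)

    def test_short_tail_rejected(self):
        gls = self._gls_with_lf(np.ones(400))
        ev = proc.LiftEvents(lf_onset=0.0, gf_onset=0.1, liftoff=0.3)
        with pytest.raises(ValueError, match="after GF onset"):
            proc.binned_areas(gls, ev)


class TestKinematics:
    @staticmethod
    def _trace_with_reach(cfg):
        rec = synth_lift_trial(cfg)
        gls = proc.grip_load(rec.trace)
        ev = proc.detect_events(gls, cfg.cube_weight)
        return rec, ev

    def test_straight_reach_zero_curvature_and_path(self):
        cfg = LiftSimConfig(noise_sd=0.0, visual_delay=0.0)
        rec, ev = self._trace_with_reach(cfg)
        kin = proc.kinematics(rec.trace, ev)
        assert kin.curvature == pytest.approx(0.0, abs=1e-9)
        start_idx = int(round(kin.movement_start / DT))
        contact_idx = int(round(ev.gf_onset / DT))
        straight = np.linalg.norm(
            rec.trace.thumb_pos[contact_idx] - rec.trace.thumb_pos[start_idx]
        )
        assert kin.path_length == pytest.approx(straight, abs=1e-9)

    def test_min_jerk_peak_velocity(self):
        cfg = LiftSimConfig(noise_sd=0.0, reach_amplitude=200.0, reach_duration=0.8)
        rec, ev = self._trace_with_reach(cfg)
        kin = proc.kinematics(rec.trace, ev)
        assert kin.peak_velocity == pytest.approx(1.875 * 200.0 / 0.8, rel=1e-3)

    def test_delay_increases_curvature_and_contact_position(self):
        rec0, ev0 = self._trace_with_reach(
            LiftSimConfig(noise_sd=0.0, visual_delay=0.0))
        rec200, ev200 = self._trace_with_reach(
            LiftSimConfig(noise_sd=0.0, visual_delay=200.0, hold_duration=1.2))
        kin0 = proc.kinematics(rec0.trace, ev0)
        kin200 = proc.kinematics(rec200.trace, ev200)
        assert kin200.curvature > kin0.curvature
        assert kin200.path_length > kin0.path_length
        assert kin200.contact_position_index > kin0.contact_position_index

    def test_requires_positions(self):
        gls_trace = make_trace(thumb_vertical=np.linspace(0, 4, 1000))
        ev = proc.LiftEvents(lf_onset=0.1, gf_onset=0.5, liftoff=0.9)
        with pytest.raises(ValueError, match="positions"):
            proc.kinematics(gls_trace, ev)


class TestScreenTrials:
    @staticmethod
    def _item(lf, weight=1.962, **kw):
        trace = make_trace(n=lf.size, thumb_vertical=lf, thumb_normal=2 * lf)
        gls = proc.grip_load(trace)
        ev = proc.detect_events(gls, weight)
        return proc.ScreenInput(
            trial_id=kw.pop("trial_id", "t0"), gls=gls, events=ev,
            cube_weight=weight, **kw,
        )

    @staticmethod
    def _clean_lf(n=1500, weight=1.962):
        t = np.arange(n) * DT
        lf = np.minimum(t * 4.0, weight + 0.5)
        return lf

    def test_clean_trial_kept(self):
        report = proc.screen_trials([self._item(self._clean_lf())])
        assert report.loc[0, "keep"]
        assert report.loc[0, "reason"] == "none"

    def test_mid_hold_dip_is_drop(self):
        lf = self._clean_lf()
        lf[900:1500] = 0.3 * 1.962  # falls and stays below half weight
        report = proc.screen_trials([self._item(lf)])
        assert report.loc[0, "reason"] == "drop"

    def test_recovering_dip_is_multiple_lift(self):
        lf = self._clean_lf()
        lf[900:1000] = 1.0  # below weight - 0.1, then recovers
        report = proc.screen_trials([self._item(lf)])
        assert report.loc[0, "reason"] == "multiple_lift"

    def test_start_offset_excludes_kinematics_only(self):
        item = self._item(self._clean_lf(), start_offset_mm=20.0)
        report = proc.screen_trials([item])
        assert report.loc[0, "keep"]  # retained for force analysis
        assert not report.loc[0, "kinematics_ok"]

    def test_failure_reason_passthrough(self):
        item = proc.ScreenInput(
            trial_id="bad", gls=None, events=None, cube_weight=1.0,
            failure="technical",
        )
        report = proc.screen_trials([item])
        assert not report.loc[0, "keep"]
        assert report.loc[0, "reason"] == "technical"

    def test_every_trial_appears_once(self):
        items = [
            self._item(self._clean_lf(), trial_id=f"t{i}") for i in range(5)
        ]
        report = proc.screen_trials(items)
        assert sorted(report["trial_id"]) == [f"t{i}" for i in range(5)]


class TestAverageCurves:
    @staticmethod
    def _synthetic_gls(d, noise=0.0, seed=0):
        cfg = LiftSimConfig(noise_sd=noise, true_duration_d=d, seed=seed)
        rec = synth_lift_trial(cfg)
        gls = proc.grip_load(rec.trace)
        ev = proc.detect_events(gls, cfg.cube_weight)
        return gls, ev, cfg.cube_weight

    def test_mean_of_copies_is_identity(self):
        gls, ev, _ = self._synthetic_gls(0.4)
        avg = proc.average_curves([gls] * 3, [ev] * 3)
        i0 = int(round(ev.gf_onset / DT))
        np.testing.assert_allclose(avg.lf, gls.lf[i0 : i0 + avg.lf.size], atol=1e-12)

    def test_alignment_at_onset(self):
        g1, e1, w = self._synthetic_gls(0.4)
        g2, e2, _ = self._synthetic_gls(0.42)
        avg = proc.average_curves([g1, g2], [e1, e2])
        assert avg.time[0] == 0.0
        dt = avg.time[1] - avg.time[0]
        gls = proc.GripLoadSeries(
            time=avg.time, gf=avg.gf, lf=avg.lf,
            gfr=np.gradient(avg.gf, dt), lfr=np.gradient(avg.lf, dt),
        )
        ev = proc.detect_events(gls, w)
        assert ev.gf_onset == pytest.approx(0.0, abs=dt)

    def test_mean_liftoff_between_individual_liftoffs(self):
        g1, e1, w = self._synthetic_gls(0.38)
        g2, e2, _ = self._synthetic_gls(0.42)
        avg = proc.average_curves([g1, g2], [e1, e2])
        dt = avg.time[1] - avg.time[0]
        gls = proc.GripLoadSeries(
            time=avg.time, gf=avg.gf, lf=avg.lf,
            gfr=np.gradient(avg.gf, dt), lfr=np.gradient(avg.lf, dt),
        )
        ev = proc.detect_events(gls, w)
        assert 0.38 - dt <= ev.liftoff <= 0.42 + dt

    def test_empty_condition_rejected(self):
        with pytest.raises(ValueError, match="no trials"):
            proc.average_curves([], [])
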