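import numpy as np
import pytest

from clsense.errors import AnalysisError, ValidationError
from clsense.events import (
    Direction,
    WindowSpec,
    build_effects_table,
    detect_transient,
    quantify_bath_effect,
)
from clsense.preprocess import RatioTrace
from clsense.trace_model import Condition, Event, EventKind, SliceRecording

from conftest import make_trace


def make_ratio(r, dt=5.0, slice_id="s1", roi_id="r1", condition=None):
    r = np.asarray(r, dtype=float)
    if condition is None:
        condition = Condition("AVP", "day", "bicarbonate")
    return RatioTrace(
        slice_id=slice_id,
        roi_id=roi_id,
        time_s=np.arange(r.size) * dt,
        r_cl=r,
        exposure500_ms=100.0,
        corrections_applied=["background", "ratio", "drift"],
        condition=condition,
    )


def step_trace(n=320, dt=5.0, onset=600.0, baseline=1.1, step=0.24,
               noise_sd=0.0, rng=None, **kw):
    t = np.arange(n) * dt
    r = np.where(t >= onset, baseline + step, baseline)
    if noise_sd > 0:
        r = r + rng.normal(0, noise_sd, n)
    return make_ratio(r, dt=dt, **kw)


VU = Event(EventKind.BATH_VU, 600.0)


class TestWindowSpec:
    def test_defaults_are_valid(self):
        spec = WindowSpec()
        assert spec.baseline_window == (-180.0, -10.0)
        assert spec.response_window == (600.0, 900.0)

    def test_baseline_must_precede_onset(self):
        with pytest.raises(ValidationError):
            WindowSpec(baseline_window=(-10.0, 20.0))

    def test_response_must_follow_onset(self):
        with pytest.raises(ValidationError):
            WindowSpec(response_window=(-50.0, 100.0))

    def test_unknown_summary_rejected(self):
        with pytest.raises(ValidationError):
            WindowSpec(summary="mode")


class TestQuantifyBathEffect:
    def test_flat_trace_gives_zero(self):
        rec = quantify_bath_effect(step_trace(step=0.0), VU)
        assert rec.delta_r == pytest.approx(0.0, abs=1e-12)

    def test_step_recovered_with_noise(self, rng):
        rec = quantify_bath_effect(
            step_trace(step=0.24, noise_sd=0.01, rng=rng), VU
        )
        assert rec.delta_r == pytest.approx(0.24, abs=0.01)

    def test_negative_step_recovered(self, rng):
        rec = quantify_bath_effect(
            step_trace(step=-0.04, noise_sd=0.01, rng=rng), VU
        )
        assert rec.delta_r == pytest.approx(-0.04, abs=0.01)

    def test_windows_not_covered_rejected(self):
        with pytest.raises(AnalysisError, match="window"):
            quantify_bath_effect(step_trace(n=100), VU)  # trace ends at 495 s

    def test_missing_samples_flag_low_confidence(self):
        trace = step_trace()
        sel = (trace.time_s >= 1200) & (trace.time_s <= 1500)
        r = trace.r_cl.copy()
        idx = np.where(sel)[0]
        r[idx[: int(0.4 * idx.size)]] = np.nan
        rec = quantify_bath_effect(trace.copy_with(r_cl=r), VU)
        assert rec.low_confidence

    def test_delta_invariant_to_constant_offset(self, rng):
        trace = step_trace(step=0.24, noise_sd=0.005, rng=rng)
        shifted = trace.copy_with(r_cl=trace.r_cl + 0.7)
        a = quantify_bath_effect(trace, VU)
        b = quantify_bath_effect(shifted, VU)
        assert a.delta_r == pytest.approx(b.delta_r, abs=1e-12)

    def test_median_summary(self, rng):
        spec = WindowSpec(summary="median")
        rec = quantify_bath_effect(
            step_trace(step=0.24, noise_sd=0.01, rng=rng), VU, spec
        )
        assert rec.delta_r == pytest.approx(0.24, abs=0.01)


def transient_trace(amplitude=0.10, decay_tau=120.0, rise_tau=10.0,
                    onset=600.0, n=400, dt=5.0, noise_sd=0.0, rng=None):
    t = np.arange(n) * dt
    dtm = t - onset
    shape = np.where(
        dtm >= 0,
        (1 - np.exp(-np.maximum(dtm, 0) / rise_tau))
        * np.exp(-np.maximum(dtm, 0) / decay_tau),
        0.0,
    )
    t_peak = rise_tau * np.log1p(decay_tau / rise_tau)
    peak = (1 - np.exp(-t_peak / rise_tau)) * np.exp(-t_peak / decay_tau)
    r = 1.1 + amplitude * shape / peak
    if noise_sd > 0:
        r = r + rng.normal(0, noise_sd, n)
    return make_ratio(r, dt=dt)


PUFF = Event(EventKind.PUFF_ISOGUVACINE, 600.0)


class TestDetectTransient:
    def test_flat_noisy_trace_no_transient(self, rng):
        trace = make_ratio(1.1 + rng.normal(0, 0.01, 400))
        out = detect_transient(trace, PUFF)
        assert not out.detected

    def test_influx_transient_detected(self, rng):
        trace = transient_trace(amplitude=0.10, noise_sd=0.003, rng=rng)
        out = detect_transient(trace, PUFF)
        assert out.detected
        assert out.direction is Direction.INFLUX
        assert out.amplitude == pytest.approx(0.10, abs=0.01)
        # recovery takes minutes (decay tau 120 s)
        assert out.recovered and 60.0 <= out.recovery_time_s <= 900.0
        assert out.recovery_time_s >= out.time_to_peak_s

    def test_negative_transient_is_efflux(self, rng):
        trace = transient_trace(amplitude=-0.08, noise_sd=0.003, rng=rng)
        out = detect_transient(trace, PUFF)
        assert out.detected
        assert out.direction is Direction.EFFLUX

    def test_short_post_window_rejected(self):
        trace = make_ratio(np.full(50, 1.1))
        with pytest.raises(AnalysisError, match="post-onset"):
            detect_transient(trace, Event(EventKind.PUFF_ISOGUVACINE, 200.0))

    def test_transient_invariant_to_drift_after_correction(self, rng, sensor,
                                                           avp_day):
        """Drift + transient composition: amplitude unbiased post-correction."""
        from clsense.preprocess import preprocess_recording
        from clsense.synthetic_data import (
            DriftSpec, TruthSpec, render_background, render_fluorescence,
            simulate_cl_trajectory,
        )

        t = np.arange(400) * 5.0
        truth = TruthSpec(transient_amplitude_r=0.10,
                          default_baseline_r=1.13, day_night_offset_r=0.0)
        cl = simulate_cl_trajectory(truth, [PUFF], t, avp_day, sensor)
        drift = DriftSpec(amplitude_per_100ms=0.015,
                          exposure_residual_slope=0.0)
        trace = render_fluorescence(cl, t, "s1", "r1", sensor, drift=drift,
                                    noise=None)
        bg = render_background(t, "s1", None, 100.0)
        rec = SliceRecording("s1", avp_day, traces=[trace, bg], events=[PUFF])
        (ratio,) = preprocess_recording(rec)
        out = detect_transient(ratio, PUFF)
        assert out.detected
        assert out.amplitude == pytest.approx(0.10, abs=0.01)


class TestBuildEffectsTable:
    def _dataset(self, n_slices=3, n_rois=5, with_event=True):
        cond = Condition("AVP", "day", "bicarbonate")
        recordings, ratios = [], []
        for s in range(n_slices):
            sid = f"s{s}"
            events = [VU] if with_event or s > 0 else []
            traces = [
                make_trace(slice_id=sid, roi_id=f"r{i}", n=300)
                for i in range(n_rois)
            ]
            traces.append(make_trace(slice_id=sid, roi_id="bg", n=300,
                                     is_background=True))
            recordings.append(
                SliceRecording(sid, cond, traces=traces, events=events)
            )
            for i in range(n_rois):
                ratios.append(
                    step_trace(slice_id=sid, roi_id=f"r{i}", condition=cond)
                )
        return recordings, ratios

    def test_counts_annotation(self):
        recordings, ratios = self._dataset(n_slices=3, n_rois=5)
        table = build_effects_table(recordings, ratios, EventKind.BATH_VU)
        assert len(table.records) == 15
        assert table.format_counts() == {"AVP day": "3 (15)"}
        assert table.skipped_slices == []

    def test_missing_event_slice_reported(self):
        recordings, ratios = self._dataset(n_slices=3, n_rois=5,
                                           with_event=False)
        table = build_effects_table(recordings, ratios, EventKind.BATH_VU)
        assert len(table.records) == 10
        assert table.skipped_slices == ["s0"]

    def test_per_condition_recovery_within_2se(self, rng):
        cond = Condition("VIP", "night", "bicarbonate")
        true_delta = 0.27
        recordings, ratios = [], []
        for s in range(6):
            sid = f"s{s}"
            traces = [make_trace(slice_id=sid, roi_id="r0", n=300),
                      make_trace(slice_id=sid, roi_id="bg", n=300,
                                 is_background=True)]
            recordings.append(
                SliceRecording(sid, cond, traces=traces, events=[VU])
            )
            slice_fx = rng.normal(0, 0.02)
            for i in range(4):
                ratios.append(
                    step_trace(
                        slice_id=sid, roi_id=f"r{i}", condition=cond,
                        baseline=1.1 + slice_fx, step=true_delta,
                        noise_sd=0.01, rng=rng,
                    )
                )
        table = build_effects_table(recordings, ratios, EventKind.BATH_VU)
        deltas = np.array([r.delta_r for r in table.records])
        se = deltas.std(ddof=1) / np.sqrt(deltas.size)
        assert abs(deltas.mean() - true_delta) < 2 * se * 3  # generous guard
        assert table.format_counts() == {"VIP night": "6 (24)"}
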