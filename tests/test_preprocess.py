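import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clsense.errors import AnalysisError, IdentifiabilityError
from clsense.preprocess import (
    DriftModel,
    ExposureAdjustment,
    RatioTrace,
    apply_exposure_adjustment,
    compute_ratio,
    correct_drift,
    fit_drift,
    fit_exposure_adjustment,
    mask_from_events,
    preprocess_recording,
    subtract_background,
)
from clsense.synthetic_data import (
    DEFAULT_SENSOR,
    NoiseSpec,
    render_background,
    render_fluorescence,
)
from clsense.trace_model import Event, EventKind

from conftest import make_trace


def make_ratio(r, dt=5.0, slice_id="s1", roi_id="r1", exposure=100.0,
               condition=None):
    r = np.asarray(r, dtype=float)
    return RatioTrace(
        slice_id=slice_id,
        roi_id=roi_id,
        time_s=np.arange(r.size) * dt,
        r_cl=r,
        exposure500_ms=exposure,
        corrections_applied=["background", "ratio"],
        condition=condition,
    )


class TestSubtractBackground:
    def test_trace_equal_to_background_flags_everything(self):
        bg = make_trace(roi_id="bg", is_background=True)
        trace = make_trace(f436=bg.f436.copy(), f500=bg.f500.copy())
        out = subtract_background(trace, bg)
        # zero-intensity channels survive subtraction; the ratio step then
        # flags every sample because the denominator is not positive
        assert np.all(out.f436 == 0) and np.all(out.f500 == 0)
        ratio = compute_ratio(out)
        assert ratio.n_flagged == ratio.r_cl.size

    def test_constant_offset_subtraction(self):
        trace = make_trace(f500=500.0)
        bg = make_trace(roi_id="bg", f500=100.0, is_background=True)
        out = subtract_background(trace, bg)
        np.testing.assert_array_equal(out.f500, 400.0)

    def test_negative_results_become_missing(self):
        trace = make_trace(f436=100.0)
        bg = make_trace(roi_id="bg", f436=150.0, is_background=True)
        out = subtract_background(trace, bg)
        assert np.all(np.isnan(out.f436))

    def test_non_background_trace_rejected(self):
        with pytest.raises(AnalysisError, match="is_background"):
            subtract_background(make_trace(), make_trace(roi_id="x"))

    def test_mismatched_time_base_rejected(self):
        bg = make_trace(roi_id="bg", n=50, is_background=True)
        with pytest.raises(AnalysisError, match="time base"):
            subtract_background(make_trace(n=100), bg)

    def test_generator_offset_recovered_exactly(self, sensor, rng):
        # noise-free rendering with nonzero background pedestal: subtracting
        # the rendered background recovers the pre-offset signal exactly
        noise = NoiseSpec(channel_noise_a=0.0, channel_noise_b=0.0,
                          background_f436=60.0, background_f500=90.0)
        t = np.arange(100) * 5.0
        cl = np.full(100, 30.0)
        trace = render_fluorescence(cl, t, "s1", "r1", sensor, drift=None,
                                    noise=noise, rng=rng)
        bg = render_background(t, "s1", noise, 100.0, rng)
        clean = render_fluorescence(cl, t, "s1", "r1", sensor, drift=None,
                                    noise=None)
        out = subtract_background(trace, bg)
        np.testing.assert_allclose(out.f436, clean.f436, rtol=1e-12)
        np.testing.assert_allclose(out.f500, clean.f500, rtol=1e-12)


class TestComputeRatio:
    def test_equal_channels_give_unity(self):
        ratio = compute_ratio(make_trace(f436=500.0, f500=500.0))
        np.testing.assert_array_equal(ratio.r_cl, 1.0)

    def test_operating_band_value(self):
        # 600/500 = 1.2, inside the 1.0-1.3 operating band
        ratio = compute_ratio(make_trace(f436=600.0, f500=500.0))
        np.testing.assert_array_equal(ratio.r_cl, 1.2)
        assert np.all((ratio.r_cl >= 1.0) & (ratio.r_cl <= 1.3))

    def test_zero_denominator_flags_single_sample(self):
        f500 = np.full(50, 500.0)
        f500[7] = 0.0
        ratio = compute_ratio(make_trace(n=50, f500=f500))
        assert np.isnan(ratio.r_cl[7])
        assert ratio.n_flagged == 1
        assert np.all(np.isfinite(np.delete(ratio.r_cl, 7)))

    def test_corrections_tagged(self):
        ratio = compute_ratio(make_trace())
        assert ratio.corrections_applied == ["background", "ratio"]


def drift_curve(t, a=0.05, tau=300.0, b=1.05):
    return b + a * (1.0 - np.exp(-t / tau))


class TestFitDrift:
    def test_flat_trace(self):
        ratio = make_ratio(np.full(200, 1.1))
        model = fit_drift(ratio)
        assert abs(model.amplitude_a) < 1e-6
        assert abs(model.offset_b - 1.1) < 1e-6

    def test_pure_drift_recovered(self):
        t = np.arange(300) * 5.0
        ratio = make_ratio(drift_curve(t))
        model = fit_drift(ratio)
        np.testing.assert_allclose(
            [model.amplitude_a, model.tau_s, model.offset_b],
            [0.05, 300.0, 1.05],
            rtol=1e-6,
        )

    def test_drift_with_masked_step(self):
        t = np.arange(300) * 5.0
        r = drift_curve(t)
        r[t >= 600] += 0.24  # drug step
        ratio = make_ratio(r)
        mask = mask_from_events(t, [Event(EventKind.BATH_VU, 600.0)])
        model = fit_drift(ratio, mask)
        np.testing.assert_allclose(
            [model.amplitude_a, model.tau_s, model.offset_b],
            [0.05, 300.0, 1.05],
            rtol=1e-3,
        )

    def test_too_few_unmasked_samples(self):
        ratio = make_ratio(np.full(40, 1.1))
        mask = [(0.0, 150.0)]  # leaves 9 samples
        with pytest.raises(IdentifiabilityError, match="unmasked"):
            fit_drift(ratio, mask)


class TestCorrectDrift:
    def test_zero_amplitude_is_identity(self):
        ratio = make_ratio(np.linspace(1.0, 1.2, 100))
        model = DriftModel(0.0, 300.0, 1.1, [], 0.0)
        out = correct_drift(ratio, model)
        np.testing.assert_array_equal(out.r_cl, ratio.r_cl)
        assert out.corrections_applied[-1] == "drift"

    def test_pure_drift_flattened(self):
        t = np.arange(300) * 5.0
        ratio = make_ratio(drift_curve(t))
        out = correct_drift(ratio, fit_drift(ratio))
        slope = stats.linregress(t, out.r_cl).slope
        assert abs(slope) < 1e-6

    def test_step_preserved_through_correction(self):
        t = np.arange(300) * 5.0
        r = drift_curve(t)
        step = t >= 600
        r[step] += 0.24
        ratio = make_ratio(r)
        mask = mask_from_events(t, [Event(EventKind.BATH_VU, 600.0)])
        out = correct_drift(ratio, fit_drift(ratio, mask))
        measured = np.mean(out.r_cl[t >= 900]) - np.mean(out.r_cl[t < 540])
        assert abs(measured - 0.24) < 0.005

    def test_model_trace_mismatch_rejected(self):
        ratio = make_ratio(np.full(100, 1.1))
        model = DriftModel(0.0, 300.0, 1.1, [], 0.0,
                           slice_id="other", roi_id="r9")
        with pytest.raises(AnalysisError, match="other"):
            correct_drift(ratio, model)


class TestExposureAdjustment:
    def _baselines(self, slope, cond="AVP day", rng=None, sd=0.0,
                   exposures=(20, 50, 100, 150, 200), n_rep=6):
        rows = []
        for e in exposures:
            for _ in range(n_rep):
                noise = rng.normal(0, sd) if rng is not None else 0.0
                rows.append({
                    "condition": cond,
                    "exposure500_ms": float(e),
                    "steady_r": 1.1 + slope * (e - 100.0) + noise,
                })
        return pd.DataFrame(rows)

    def test_identical_exposures_error(self):
        df = self._baselines(0.0, exposures=(100,))
        with pytest.raises(IdentifiabilityError, match="identical"):
            fit_exposure_adjustment(df)

    def test_identical_exposures_identity_opt_in(self):
        df = self._baselines(0.0, exposures=(100,))
        adj = fit_exposure_adjustment(df, allow_identity=True)["AVP day"]
        assert adj.slope_per_ms == 0.0

    def test_slope_recovered_within_2se(self, rng):
        df = self._baselines(5e-4, rng=rng, sd=0.02)
        adj = fit_exposure_adjustment(df)["AVP day"]
        assert abs(adj.slope_per_ms - 5e-4) < 2 * adj.slope_stderr

    def test_two_conditions_fit_independently(self, rng):
        df = pd.concat([
            self._baselines(5e-4, cond="AVP day", rng=rng, sd=0.01),
            self._baselines(-2e-4, cond="VIP day", rng=rng, sd=0.01),
        ])
        adjs = fit_exposure_adjustment(df)
        assert abs(adjs["AVP day"].slope_per_ms - 5e-4) < 2 * adjs["AVP day"].slope_stderr
        assert abs(adjs["VIP day"].slope_per_ms + 2e-4) < 2 * adjs["VIP day"].slope_stderr

    def test_reference_exposure_is_identity(self):
        ratio = make_ratio(np.full(50, 1.15), exposure=100.0)
        adj = ExposureAdjustment("AVP day", slope_per_ms=5e-4)
        out = apply_exposure_adjustment(ratio, adj)
        np.testing.assert_array_equal(out.r_cl, ratio.r_cl)
        assert out.corrections_applied[-1] == "exposure"

    def test_adjustment_arithmetic(self):
        ratio = make_ratio(np.full(50, 1.15), exposure=200.0)
        adj = ExposureAdjustment("AVP day", slope_per_ms=5e-4)
        out = apply_exposure_adjustment(ratio, adj)
        np.testing.assert_allclose(out.r_cl, ratio.r_cl - 0.05)

    def test_residual_trend_removed(self, rng):
        slope = 5e-4
        df = self._baselines(slope, rng=rng, sd=0.02)
        adj = fit_exposure_adjustment(df)["AVP day"]
        adjusted = df["steady_r"] - adj.slope_per_ms * (df["exposure500_ms"] - 100.0)
        res = stats.linregress(df["exposure500_ms"], adjusted)
        ci = 1.96 * res.stderr
        assert abs(res.slope) < ci + 1e-12

    def test_condition_mismatch_rejected(self, avp_day):
        ratio = make_ratio(np.full(50, 1.15), condition=avp_day)
        adj = ExposureAdjustment("VIP night", slope_per_ms=5e-4)
        with pytest.raises(AnalysisError, match="VIP night"):
            apply_exposure_adjustment(ratio, adj)


class TestFullChain:
    def test_identity_on_clean_input(self, sensor, avp_day):
        """Drift-free, noise-free input passes through the chain unchanged."""
        from clsense.trace_model import SliceRecording

        t = np.arange(200) * 5.0
        cl = np.full(t.size, 40.0)
        r_expected = sensor.forward(40.0)
        trace = render_fluorescence(cl, t, "s1", "r1", sensor, drift=None,
                                    noise=None)
        bg = render_background(t, "s1", None, 100.0)
        rec = SliceRecording("s1", avp_day, traces=[trace, bg])
        (out,) = preprocess_recording(rec)
        np.testing.assert_allclose(out.r_cl, r_expected, rtol=1e-9)
        assert out.corrections_applied == ["background", "ratio", "drift"]

    def test_step_bias_below_two_percent(self, sensor, avp_day):
        """Step signals survive drift correction with <2% amplitude bias."""
        from clsense.synthetic_data import DriftSpec
        from clsense.trace_model import SliceRecording

        t = np.arange(300) * 5.0
        onset = 600.0
        r0, step = 1.10, 0.24
        cl = np.where(
            t >= onset,
            DEFAULT_SENSOR.inverse(r0 + step),
            DEFAULT_SENSOR.inverse(r0),
        )
        # multiplicative drift inflates a step by ~step * asymptotic loss, so
        # the <2% bias bound holds for losses up to ~0.015 per 100 ms
        drift = DriftSpec(amplitude_per_100ms=0.015, tau_s=300.0,
                          exposure_residual_slope=0.0)
        trace = render_fluorescence(cl, t, "s1", "r1", sensor, drift=drift,
                                    noise=None)
        bg = render_background(t, "s1", None, 100.0)
        event = Event(EventKind.BATH_VU, onset)
        rec = SliceRecording("s1", avp_day, traces=[trace, bg], events=[event])
        (out,) = preprocess_recording(rec)
        measured = np.mean(out.r_cl[t >= 1200]) - np.mean(out.r_cl[t < 540])
        assert abs(measured - step) / step < 0.02
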