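"""Raw two-channel ROI traces -> corrected ratio time series.

The correction chain is fixed in order: background subtraction per wavelength,
ratio computation, single-exponential drift correction, and exposure
normalization to the 100 ms reference. Each stage appends its tag to
``corrections_applied`` so downstream code can verify order.

Drift model: slow photoinactivation produces a saturating rise of the ratio,

    R(t) = B + A * (1 - exp(-t / tau))

The time-dependent component A*(1 - exp(-t/tau)) is subtracted; the offset B
is retained so the absolute ratio level is preserved. Event windows are masked
during the fit so drug responses do not bias the drift estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy import stats

from .errors import AnalysisError, FitError, IdentifiabilityError, ValidationError
from .trace_model import Condition, Event, ROITrace, SliceRecording

__all__ = [
    "RatioTrace",
    "DriftModel",
    "ExposureAdjustment",
    "subtract_background",
    "compute_ratio",
    "mask_from_events",
    "fit_drift",
    "correct_drift",
    "fit_exposure_adjustment",
    "apply_exposure_adjustment",
    "preprocess_recording",
    "REFERENCE_EXPOSURE_MS",
    "DEFAULT_GUARD_BEFORE_S",
    "DEFAULT_GUARD_AFTER_S",
]

log = logging.getLogger(__name__)

REFERENCE_EXPOSURE_MS = 100.0
DEFAULT_GUARD_BEFORE_S = 60.0
DEFAULT_GUARD_AFTER_S = 600.0


@dataclass
class RatioTrace:
    """Corrected ratio time series for one ROI (NaN = flagged missing)."""

    slice_id: str
    roi_id: str
    time_s: np.ndarray
    r_cl: np.ndarray
    exposure500_ms: float
    corrections_applied: list[str] = field(default_factory=list)
    condition: Condition | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.r_cl = np.asarray(self.r_cl, dtype=float)
        if self.time_s.size != self.r_cl.size:
            raise ValidationError(
                f"slice {self.slice_id} roi {self.roi_id}: r_cl length "
                f"{self.r_cl.size} != time length {self.time_s.size}"
            )

    @property
    def n_flagged(self) -> int:
        return int(np.sum(~np.isfinite(self.r_cl)))

    def copy_with(self, **kwargs) -> "RatioTrace":
        return replace(self, **kwargs)


@dataclass
class DriftModel:
    """Single-exponential photoinactivation drift, B + A*(1 - exp(-t/tau))."""

    amplitude_a: float
    tau_s: float
    offset_b: float
    fit_window: list[tuple[float, float]]
    residual_rms: float
    slice_id: str = ""
    roi_id: str = ""

    def __post_init__(self) -> None:
        if not self.tau_s > 0:
            raise ValidationError(f"tau_s must be > 0, got {self.tau_s}")

    def trend(self, t: np.ndarray) -> np.ndarray:
        """The time-dependent component removed by correction."""
        return self.amplitude_a * (1.0 - np.exp(-np.asarray(t, float) / self.tau_s))

    def predict(self, t: np.ndarray) -> np.ndarray:
        return self.offset_b + self.trend(t)


@dataclass
class ExposureAdjustment:
    """Additive-linear map from any 500 nm exposure to the 100 ms reference."""

    condition: Hashable
    slope_per_ms: float
    reference_ms: float = REFERENCE_EXPOSURE_MS
    slope_stderr: float = float("nan")
    n_points: int = 0


def subtract_background(trace: ROITrace, background: ROITrace) -> ROITrace:
    """Subtract the background ROI from both channels, pointwise.

    Samples that go negative after subtraction are clamped to NaN (missing)
    rather than zero — a ratio of garbage is worse than a gap.
    """
    if not background.is_background:
        raise AnalysisError(
            f"slice {trace.slice_id}: supplied background trace "
            f"{background.roi_id} is not flagged is_background"
        )
    if background.time_s.size != trace.time_s.size or not np.allclose(
        background.time_s, trace.time_s
    ):
        raise AnalysisError(
            f"slice {trace.slice_id} roi {trace.roi_id}: background time base "
            "does not match trace"
        )
    f436 = trace.f436 - background.f436
    f500 = trace.f500 - background.f500
    f436 = np.where(f436 < 0, np.nan, f436)
    f500 = np.where(f500 < 0, np.nan, f500)
    return trace.copy_with(f436=f436, f500=f500)


def compute_ratio(trace: ROITrace, condition: Condition | None = None) -> RatioTrace:
    """Ratio of 436 nm-excited over 500 nm-excited emission.

    Samples with non-positive or missing denominator become NaN; the count is
    available as ``RatioTrace.n_flagged``.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(trace.f500 > 0, trace.f436 / trace.f500, np.nan)
    out = RatioTrace(
        slice_id=trace.slice_id,
        roi_id=trace.roi_id,
        time_s=trace.time_s.copy(),
        r_cl=r,
        exposure500_ms=trace.exposure500_ms,
        corrections_applied=["background", "ratio"],
        condition=condition,
    )
    if out.n_flagged:
        log.info(
            "slice %s roi %s: %d sample(s) flagged missing in ratio",
            trace.slice_id,
            trace.roi_id,
            out.n_flagged,
        )
    return out


def mask_from_events(
    time_s: np.ndarray,
    events: Iterable[Event],
    guard_before_s: float = DEFAULT_GUARD_BEFORE_S,
    guard_after_s: float = DEFAULT_GUARD_AFTER_S,
) -> list[tuple[float, float]]:
    """Time intervals to exclude from drift fitting around each event."""
    intervals = []
    tmax = float(time_s[-1]) if len(time_s) else 0.0
    for ev in events:
        end = ev.offset_s if ev.offset_s is not None else tmax
        if ev.kind.is_bath:
            end = tmax  # bath drugs persist to the end of the recording
        intervals.append((ev.onset_s - guard_before_s, end + guard_after_s))
    return intervals


def _unmasked(time_s: np.ndarray, intervals: Sequence[tuple[float, float]]):
    keep = np.ones(time_s.size, dtype=bool)
    for lo, hi in intervals:
        keep &= ~((time_s >= lo) & (time_s <= hi))
    return keep


def _drift_func(t, a, tau, b):
    return b + a * (1.0 - np.exp(-t / tau))


def fit_drift(
    ratio: RatioTrace,
    mask_intervals: Sequence[tuple[float, float]] = (),
    min_unmasked: int = 30,
    n_restarts: int = 4,
) -> DriftModel:
    """Least-squares fit of the saturating-rise drift over unmasked samples."""
    keep = _unmasked(ratio.time_s, mask_intervals) & np.isfinite(ratio.r_cl)
    if int(keep.sum()) < min_unmasked:
        raise IdentifiabilityError(
            f"slice {ratio.slice_id} roi {ratio.roi_id}: only {int(keep.sum())} "
            f"unmasked samples, need >= {min_unmasked} for drift fit"
        )
    t = ratio.time_s[keep]
    r = ratio.r_cl[keep]
    span = float(t[-1] - t[0]) or 1.0

    a0 = float(r[-1] - r[0])
    b0 = float(r[0])
    tau0 = span / 3.0
    lo = [-5.0, 1e-3, -10.0]
    hi = [5.0, 100.0 * span, 10.0]
    p0 = np.clip([a0, tau0, b0], lo, hi)

    rng = np.random.default_rng(0)
    last_err: Exception | None = None
    for attempt in range(n_restarts + 1):
        start = p0 if attempt == 0 else np.clip(
            p0 * np.exp(rng.normal(0, 0.3, 3)) + rng.normal(0, [0.01, 0, 0.01]),
            lo,
            hi,
        )
        try:
            popt, _ = curve_fit(
                _drift_func, t, r, p0=start, bounds=(lo, hi), maxfev=20000
            )
        except (RuntimeError, ValueError) as exc:
            last_err = exc
            continue
        resid = r - _drift_func(t, *popt)
        model = DriftModel(
            amplitude_a=float(popt[0]),
            tau_s=float(popt[1]),
            offset_b=float(popt[2]),
            fit_window=list(mask_intervals),
            residual_rms=float(np.sqrt(np.mean(resid**2))),
            slice_id=ratio.slice_id,
            roi_id=ratio.roi_id,
        )
        log.info(
            "slice %s roi %s: drift fit A=%.4g tau=%.4g B=%.4g rms=%.3g",
            ratio.slice_id,
            ratio.roi_id,
            model.amplitude_a,
            model.tau_s,
            model.offset_b,
            model.residual_rms,
        )
        return model
    raise FitError(
        f"slice {ratio.slice_id} roi {ratio.roi_id}: drift fit did not "
        f"converge after {n_restarts + 1} starts: {last_err}"
    )


def correct_drift(ratio: RatioTrace, model: DriftModel) -> RatioTrace:
    """Subtract the fitted time-dependent component, keeping the offset."""
    if model.slice_id and model.roi_id and (
        model.slice_id != ratio.slice_id or model.roi_id != ratio.roi_id
    ):
        raise AnalysisError(
            f"drift model fitted on {model.slice_id}/{model.roi_id} applied to "
            f"{ratio.slice_id}/{ratio.roi_id}"
        )
    corrected = ratio.r_cl - model.trend(ratio.time_s)
    return ratio.copy_with(
        r_cl=corrected,
        corrections_applied=ratio.corrections_applied + ["drift"],
    )


def fit_exposure_adjustment(
    baselines: pd.DataFrame,
    allow_identity: bool = False,
) -> dict[Hashable, ExposureAdjustment]:
    """Per-condition linear regression of steady-state ratio on exposure.

    ``baselines`` needs columns exposure500_ms, steady_r, condition (any
    hashable condition key). Each condition is fitted independently and needs
    >= 3 distinct exposures; identical exposures are unidentifiable and raise
    unless ``allow_identity`` opts in to a zero-slope adjustment.
    """
    required = {"exposure500_ms", "steady_r", "condition"}
    if not required <= set(baselines.columns):
        raise IdentifiabilityError(
            f"baseline table needs columns {sorted(required)}"
        )
    out: dict[Hashable, ExposureAdjustment] = {}
    for cond, cdf in baselines.groupby("condition", sort=False):
        x = cdf["exposure500_ms"].to_numpy(dtype=float)
        y = cdf["steady_r"].to_numpy(dtype=float)
        n_distinct = np.unique(x).size
        if n_distinct == 1:
            if allow_identity:
                log.warning(
                    "condition %s: all baselines at %.0f ms; exposure "
                    "adjustment is identity",
                    cond,
                    x[0],
                )
                out[cond] = ExposureAdjustment(
                    condition=cond, slope_per_ms=0.0, n_points=int(x.size)
                )
                continue
            raise IdentifiabilityError(
                f"condition {cond}: all exposures identical ({x[0]} ms); "
                "slope unidentifiable"
            )
        if n_distinct < 3:
            raise IdentifiabilityError(
                f"condition {cond}: need >= 3 distinct exposures, got {n_distinct}"
            )
        res = stats.linregress(x, y)
        out[cond] = ExposureAdjustment(
            condition=cond,
            slope_per_ms=float(res.slope),
            slope_stderr=float(res.stderr),
            n_points=int(x.size),
        )
    return out


def apply_exposure_adjustment(
    ratio: RatioTrace, adj: ExposureAdjustment
) -> RatioTrace:
    """Shift the trace to the 100 ms exposure reference."""
    if (
        ratio.condition is not None
        and isinstance(adj.condition, str)
        and adj.condition != ratio.condition.label
    ):
        raise AnalysisError(
            f"slice {ratio.slice_id} roi {ratio.roi_id}: adjustment for "
            f"condition {adj.condition!r} applied to {ratio.condition.label!r}"
        )
    shift = adj.slope_per_ms * (ratio.exposure500_ms - adj.reference_ms)
    return ratio.copy_with(
        r_cl=ratio.r_cl - shift,
        corrections_applied=ratio.corrections_applied + ["exposure"],
    )


def preprocess_recording(
    recording: SliceRecording,
    adjustments: Mapping[Hashable, ExposureAdjustment] | None = None,
    guard_before_s: float = DEFAULT_GUARD_BEFORE_S,
    guard_after_s: float = DEFAULT_GUARD_AFTER_S,
    min_unmasked: int = 30,
) -> list[RatioTrace]:
    """Full correction chain for every signal ROI in a slice recording.

    Applies background -> ratio -> drift (event-masked) and, when an
    adjustment for the slice's condition is supplied, exposure normalization.
    """
    background = recording.background
    mask = None
    out: list[RatioTrace] = []
    for trace in recording.signal_traces:
        sub = subtract_background(trace, background)
        ratio = compute_ratio(sub, condition=recording.condition)
        if mask is None:
            mask = mask_from_events(
                ratio.time_s, recording.events, guard_before_s, guard_after_s
            )
        model = fit_drift(ratio, mask, min_unmasked=min_unmasked)
        ratio = correct_drift(ratio, model)
        if adjustments is not None and recording.condition is not None:
            key = recording.condition.label
            if key in adjustments:
                ratio = apply_exposure_adjustment(ratio, adjustments[key])
        out.append(ratio)
    return out
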