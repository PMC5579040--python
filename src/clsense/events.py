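"""Quantify drug-induced ratio changes from corrected traces.

Bath drugs (persistent effects) are summarized as the difference between a
post-wash-in window and a pre-onset baseline window. Focal puffs (transient
effects) are summarized by peak amplitude, time to peak and recovery time.

Window defaults — baseline [-180 s, -10 s] and bath response [+600 s, +900 s]
relative to onset — assume a wash-in on the order of minutes; both are
configurable and are echoed in every sidecar so the choice is auditable.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import AnalysisError, ValidationError
from .preprocess import RatioTrace
from .trace_model import EffectRecord, Event, EventKind, SliceRecording

__all__ = [
    "WindowSpec",
    "Direction",
    "TransientSummary",
    "EffectsTable",
    "quantify_bath_effect",
    "detect_transient",
    "build_effects_table",
]


class Direction(str, enum.Enum):
    INFLUX = "influx"   # ratio up = chloride entering
    EFFLUX = "efflux"   # ratio down = chloride leaving


@dataclass(frozen=True)
class WindowSpec:
    """Baseline/response windows in seconds relative to event onset."""

    baseline_window: tuple[float, float] = (-180.0, -10.0)
    response_window: tuple[float, float] = (600.0, 900.0)
    summary: str = "mean"
    max_missing_frac: float = 0.2

    def __post_init__(self) -> None:
        b0, b1 = self.baseline_window
        r0, r1 = self.response_window
        if not (b0 < b1 <= 0):
            raise ValidationError(
                f"baseline_window {self.baseline_window} must lie entirely "
                "before onset"
            )
        if not (0 <= r0 < r1):
            raise ValidationError(
                f"response_window {self.response_window} must lie after onset"
            )
        if self.summary not in ("mean", "median"):
            raise ValidationError(f"unknown summary {self.summary!r}")

    def summarize(self, values: np.ndarray) -> float:
        fn = np.nanmean if self.summary == "mean" else np.nanmedian
        return float(fn(values))

    def to_dict(self) -> dict:
        return {
            "baseline_window": list(self.baseline_window),
            "response_window": list(self.response_window),
            "summary": self.summary,
            "max_missing_frac": self.max_missing_frac,
        }


@dataclass
class TransientSummary:
    """Peak description of a puff-evoked ratio transient."""

    detected: bool
    amplitude: float = float("nan")
    time_to_peak_s: float = float("nan")
    recovery_time_s: float | None = None
    direction: Direction | None = None
    baseline_r: float = float("nan")
    noise_sd: float = float("nan")

    def __post_init__(self) -> None:
        if self.detected and self.direction is not None:
            if self.direction is Direction.INFLUX and not self.amplitude > 0:
                raise ValidationError("influx transient must have amplitude > 0")
            if self.direction is Direction.EFFLUX and not self.amplitude < 0:
                raise ValidationError("efflux transient must have amplitude < 0")

    @property
    def recovered(self) -> bool:
        return self.recovery_time_s is not None


def _window_values(
    trace: RatioTrace, lo_s: float, hi_s: float
) -> np.ndarray:
    t = trace.time_s
    if lo_s < t[0] - 1e-9 or hi_s > t[-1] + 1e-9:
        raise AnalysisError(
            f"slice {trace.slice_id} roi {trace.roi_id}: window "
            f"[{lo_s:.1f}, {hi_s:.1f}]s not covered by trace "
            f"[{t[0]:.1f}, {t[-1]:.1f}]s"
        )
    sel = (t >= lo_s) & (t <= hi_s)
    if not np.any(sel):
        raise AnalysisError(
            f"slice {trace.slice_id} roi {trace.roi_id}: window "
            f"[{lo_s:.1f}, {hi_s:.1f}]s contains no samples"
        )
    return trace.r_cl[sel]


def quantify_bath_effect(
    ratio: RatioTrace,
    event: Event,
    spec: WindowSpec = WindowSpec(),
) -> EffectRecord:
    """Persistent ratio change: response-window summary minus baseline summary.

    Records with more than ``spec.max_missing_frac`` missing samples in either
    window are kept but flagged ``low_confidence``.
    """
    if ratio.condition is None:
        raise AnalysisError(
            f"slice {ratio.slice_id} roi {ratio.roi_id}: condition required to "
            "build an effect record"
        )
    base = _window_values(
        ratio, event.onset_s + spec.baseline_window[0],
        event.onset_s + spec.baseline_window[1],
    )
    post = _window_values(
        ratio, event.onset_s + spec.response_window[0],
        event.onset_s + spec.response_window[1],
    )
    low_conf = any(
        np.mean(~np.isfinite(w)) > spec.max_missing_frac for w in (base, post)
    )
    baseline_r = spec.summarize(base)
    post_r = spec.summarize(post)
    return EffectRecord(
        slice_id=ratio.slice_id,
        roi_id=ratio.roi_id,
        condition=ratio.condition,
        drug=event.kind,
        baseline_r=baseline_r,
        post_r=post_r,
        delta_r=post_r - baseline_r,
        low_confidence=low_conf,
    )


def detect_transient(
    ratio: RatioTrace,
    event: Event,
    baseline_span_s: float = 180.0,
    min_post_s: float = 120.0,
    threshold_sd: float = 3.0,
    recovery_frac: float = 0.1,
    sustain_samples: int = 3,
) -> TransientSummary:
    """Find a puff-evoked transient after ``event.onset_s``.

    The extremum of (R - pre-onset baseline) in the post window is the
    amplitude; it must exceed ``threshold_sd`` times the baseline noise SD,
    otherwise a "no transient detected" summary is returned. Recovery is the
    first re-entry into baseline +/- ``recovery_frac``*|amplitude| sustained
    for ``sustain_samples`` samples after the peak.
    """
    t = ratio.time_s
    if t[-1] - event.onset_s < min_post_s:
        raise AnalysisError(
            f"slice {ratio.slice_id} roi {ratio.roi_id}: only "
            f"{t[-1] - event.onset_s:.0f}s of post-onset trace, need >= "
            f"{min_post_s:.0f}s"
        )
    pre = (t >= event.onset_s - baseline_span_s) & (t < event.onset_s)
    if not np.any(pre & np.isfinite(ratio.r_cl)):
        raise AnalysisError(
            f"slice {ratio.slice_id} roi {ratio.roi_id}: no finite pre-onset "
            "samples for baseline"
        )
    baseline = float(np.nanmean(ratio.r_cl[pre]))
    noise_sd = float(np.nanstd(ratio.r_cl[pre], ddof=1)) if pre.sum() > 1 else 0.0

    post = t >= event.onset_s
    dev_raw = ratio.r_cl[post] - baseline
    t_post = t[post]
    if not np.any(np.isfinite(dev_raw)):
        return TransientSummary(detected=False, baseline_r=baseline, noise_sd=noise_sd)
    # peak search on a short moving average: single-sample noise extremes in a
    # minutes-long transient would otherwise trip the 3-sigma threshold
    dev = (
        pd.Series(dev_raw)
        .rolling(5, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    i_peak = int(np.nanargmax(np.abs(dev)))
    amplitude = float(dev[i_peak])
    if noise_sd > 0 and abs(amplitude) <= threshold_sd * noise_sd:
        return TransientSummary(detected=False, baseline_r=baseline, noise_sd=noise_sd)

    direction = Direction.INFLUX if amplitude > 0 else Direction.EFFLUX
    time_to_peak = float(t_post[i_peak] - event.onset_s)

    band = recovery_frac * abs(amplitude)
    recovery: float | None = None
    inside = np.abs(dev) <= band
    run = 0
    for j in range(i_peak + 1, dev.size):
        if not np.isfinite(dev[j]):
            run = 0
            continue
        run = run + 1 if inside[j] else 0
        if run >= sustain_samples:
            recovery = float(t_post[j - sustain_samples + 1] - event.onset_s)
            break
    return TransientSummary(
        detected=True,
        amplitude=amplitude,
        time_to_peak_s=time_to_peak,
        recovery_time_s=recovery,
        direction=direction,
        baseline_r=baseline,
        noise_sd=noise_sd,
    )


@dataclass
class EffectsTable:
    """Effect records plus the per-condition slice/ROI counts the figures list."""

    records: list[EffectRecord]
    counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    skipped_slices: list[str] = field(default_factory=list)

    def format_counts(self) -> dict[str, str]:
        """Counts rendered as 'n_slices (n_rois)', e.g. '3 (15)'."""
        return {k: f"{ns} ({nr})" for k, (ns, nr) in self.counts.items()}

    def sidecar(self, spec: WindowSpec) -> dict:
        return {
            "windows": spec.to_dict(),
            "counts": self.format_counts(),
            "skipped_slices": self.skipped_slices,
        }

    def write_sidecar(self, spec: WindowSpec, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.sidecar(spec), indent=2, sort_keys=True) + "\n")
        return path


def build_effects_table(
    recordings: Sequence[SliceRecording],
    ratios: Iterable[RatioTrace],
    event_kind: EventKind,
    spec: WindowSpec = WindowSpec(),
) -> EffectsTable:
    """One EffectRecord per (ROI, event) for the named bath event.

    Slices lacking the event are reported in ``skipped_slices`` rather than
    silently dropped. Counts per condition label mirror the "n (N)" figure
    annotation: number of slices, total ROIs in parentheses.
    """
    event_kind = EventKind(event_kind)
    by_slice: dict[str, list[RatioTrace]] = {}
    for r in ratios:
        by_slice.setdefault(r.slice_id, []).append(r)

    records: list[EffectRecord] = []
    skipped: list[str] = []
    slice_sets: dict[str, set[str]] = {}
    roi_counts: dict[str, int] = {}
    for rec in recordings:
        event = next((e for e in rec.events if e.kind is event_kind), None)
        if event is None:
            skipped.append(rec.slice_id)
            continue
        for ratio in by_slice.get(rec.slice_id, []):
            records.append(quantify_bath_effect(ratio, event, spec))
            label = ratio.condition.label if ratio.condition else "unknown"
            slice_sets.setdefault(label, set()).add(rec.slice_id)
            roi_counts[label] = roi_counts.get(label, 0) + 1
    counts = {
        label: (len(slice_sets[label]), roi_counts[label]) for label in slice_sets
    }
    return EffectsTable(records=records, counts=counts, skipped_slices=skipped)
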