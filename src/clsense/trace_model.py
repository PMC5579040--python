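"""Data model for recordings, conditions and effect tables, plus strict CSV I/O.

The interchange format is tidy long CSV: one row per ROI per time point for
traces, one row per (ROI, intervention) for effects. A JSON manifest carries
per-slice condition labels and event timings. All floats are written with 17
significant digits so write -> read -> write is byte-identical.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "NeuronType",
    "Phase",
    "Buffer",
    "EventKind",
    "Condition",
    "ROITrace",
    "Event",
    "SliceRecording",
    "EffectRecord",
    "phase_from_zt",
    "read_traces",
    "write_traces",
    "read_effects",
    "write_effects",
    "effects_to_frame",
    "load_manifest",
    "save_manifest",
    "TRACE_COLUMNS",
    "EFFECT_COLUMNS",
]

TRACE_COLUMNS = [
    "slice_id",
    "roi_id",
    "time_s",
    "f436",
    "f500",
    "exposure500_ms",
    "is_background",
]

EFFECT_COLUMNS = [
    "slice_id",
    "roi_id",
    "neuron_type",
    "phase",
    "buffer",
    "drug",
    "baseline_r",
    "post_r",
    "delta_r",
    "low_confidence",
]

_FLOAT_FMT = "%.17g"


class NeuronType(str, enum.Enum):
    AVP = "AVP"
    VIP = "VIP"


class Phase(str, enum.Enum):
    DAY = "day"
    NIGHT = "night"


class Buffer(str, enum.Enum):
    BICARBONATE = "bicarbonate"
    HEPES = "HEPES"


class EventKind(str, enum.Enum):
    PUFF_ISOGUVACINE = "puff_isoguvacine"
    BATH_VU = "bath_VU"
    BATH_BUMETANIDE = "bath_bumetanide"

    @property
    def is_bath(self) -> bool:
        return self in (EventKind.BATH_VU, EventKind.BATH_BUMETANIDE)


def phase_from_zt(zt_h: float) -> Phase:
    """Map a zeitgeber time (hours) onto the categorical recording phase.

    Day recordings fall in ZT 2-8 and night recordings in ZT 12-18; times
    outside either window are rejected because the phase label would be
    ambiguous.
    """
    if 2.0 <= zt_h <= 8.0:
        return Phase.DAY
    if 12.0 <= zt_h <= 18.0:
        return Phase.NIGHT
    raise ValidationError(
        f"ZT {zt_h} is outside the day (2-8) and night (12-18) windows"
    )


@dataclass(frozen=True)
class Condition:
    """Experimental condition of one slice recording."""

    neuron_type: NeuronType
    phase: Phase
    buffer: Buffer

    def __post_init__(self) -> None:
        object.__setattr__(self, "neuron_type", NeuronType(self.neuron_type))
        object.__setattr__(self, "phase", Phase(self.phase))
        object.__setattr__(self, "buffer", Buffer(self.buffer))

    @property
    def label(self) -> str:
        """Neuron-type x phase label, the grouping used for per-condition fits."""
        return f"{self.neuron_type.value} {self.phase.value}"

    def to_dict(self) -> dict:
        return {
            "neuron_type": self.neuron_type.value,
            "phase": self.phase.value,
            "buffer": self.buffer.value,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Condition":
        try:
            return cls(d["neuron_type"], d["phase"], d["buffer"])
        except KeyError as exc:
            raise SchemaError(f"condition is missing field {exc}") from exc


@dataclass
class ROITrace:
    """Two-channel fluorescence time series for one ROI.

    ``f436``/``f500`` are emission intensities after 436 nm and 500 nm
    excitation respectively (arbitrary camera units). NaN marks samples
    flagged as missing by upstream corrections.
    """

    slice_id: str
    roi_id: str
    time_s: np.ndarray
    f436: np.ndarray
    f500: np.ndarray
    exposure500_ms: float
    is_background: bool = False

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.f436 = np.asarray(self.f436, dtype=float)
        self.f500 = np.asarray(self.f500, dtype=float)
        n = self.time_s.size
        if self.f436.size != n or self.f500.size != n:
            raise ValidationError(
                f"slice {self.slice_id} roi {self.roi_id}: channel lengths "
                f"({self.f436.size}, {self.f500.size}) do not match time axis ({n})"
            )
        if n >= 2:
            dt = np.diff(self.time_s)
            if np.any(dt <= 0):
                i = int(np.argmax(dt <= 0))
                raise ValidationError(
                    f"slice {self.slice_id} roi {self.roi_id}: time not strictly "
                    f"increasing at row {i + 1} (t={self.time_s[i + 1]})"
                )
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValidationError(
                    f"slice {self.slice_id} roi {self.roi_id}: sampling interval "
                    "is not constant"
                )
        if not self.exposure500_ms > 0:
            raise ValidationError(
                f"slice {self.slice_id} roi {self.roi_id}: exposure500_ms must be "
                f"positive, got {self.exposure500_ms}"
            )

    @property
    def n_samples(self) -> int:
        return int(self.time_s.size)

    @property
    def dt_s(self) -> float:
        if self.time_s.size < 2:
            raise ValidationError(
                f"slice {self.slice_id} roi {self.roi_id}: trace too short for dt"
            )
        return float(self.time_s[1] - self.time_s[0])

    def copy_with(self, **kwargs) -> "ROITrace":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Event:
    """Drug application epoch. Bath events persist to the end of the trace."""

    kind: EventKind
    onset_s: float
    offset_s: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", EventKind(self.kind))
        if self.offset_s is not None and self.offset_s <= self.onset_s:
            raise ValidationError(
                f"event {self.kind.value}: offset {self.offset_s} <= onset {self.onset_s}"
            )

    def to_dict(self) -> dict:
        return {
            "kind": self.kind.value,
            "onset_s": self.onset_s,
            "offset_s": self.offset_s,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Event":
        return cls(d["kind"], d["onset_s"], d.get("offset_s"))


@dataclass
class SliceRecording:
    """All ROI traces acquired from one slice, plus its condition and events."""

    slice_id: str
    condition: Condition | None
    traces: list[ROITrace] = field(default_factory=list)
    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        n_bg = sum(t.is_background for t in self.traces)
        if self.traces and n_bg != 1:
            raise ValidationError(
                f"slice {self.slice_id}: expected exactly one background ROI, "
                f"found {n_bg}"
            )
        ref = self.traces[0].time_s if self.traces else None
        for t in self.traces:
            if t.slice_id != self.slice_id:
                raise ValidationError(
                    f"slice {self.slice_id}: trace {t.roi_id} carries slice_id "
                    f"{t.slice_id}"
                )
            if ref is not None and (
                t.time_s.size != ref.size or not np.allclose(t.time_s, ref)
            ):
                raise ValidationError(
                    f"slice {self.slice_id} roi {t.roi_id}: time base differs from "
                    "other traces in the slice"
                )
        tmax = float(ref[-1]) if ref is not None and ref.size else np.inf
        for ev in self.events:
            if not (0 <= ev.onset_s <= tmax):
                raise ValidationError(
                    f"slice {self.slice_id}: event {ev.kind.value} onset "
                    f"{ev.onset_s}s outside trace range [0, {tmax}]"
                )

    @property
    def background(self) -> ROITrace:
        for t in self.traces:
            if t.is_background:
                return t
        raise ValidationError(f"slice {self.slice_id}: no background ROI")

    @property
    def signal_traces(self) -> list[ROITrace]:
        return [t for t in self.traces if not t.is_background]


@dataclass
class EffectRecord:
    """One ROI's ratio change for one intervention, with clustering labels."""

    slice_id: str
    roi_id: str
    condition: Condition
    drug: EventKind
    baseline_r: float
    post_r: float
    delta_r: float
    low_confidence: bool = False

    def __post_init__(self) -> None:
        self.drug = EventKind(self.drug)
        if not np.isclose(self.delta_r, self.post_r - self.baseline_r,
                          rtol=0, atol=1e-9):
            raise ValidationError(
                f"slice {self.slice_id} roi {self.roi_id}: delta_r "
                f"{self.delta_r} != post_r - baseline_r "
                f"{self.post_r - self.baseline_r}"
            )


# ---------------------------------------------------------------------------
# manifest


def save_manifest(recordings: Iterable[SliceRecording], path: str | Path) -> Path:
    """Write the slice_id -> (condition, events) map as JSON."""
    out = {
        "slices": {
            rec.slice_id: {
                "condition": rec.condition.to_dict() if rec.condition else None,
                "events": [ev.to_dict() for ev in rec.events],
            }
            for rec in recordings
        }
    }
    path = Path(path)
    path.write_text(json.dumps(out, indent=2, sort_keys=True) + "\n")
    return path


def load_manifest(path: str | Path) -> dict[str, tuple[Condition | None, list[Event]]]:
    raw = json.loads(Path(path).read_text())
    if "slices" not in raw:
        raise SchemaError(f"manifest {path}: missing top-level 'slices' key")
    out: dict[str, tuple[Condition | None, list[Event]]] = {}
    for slice_id, entry in raw["slices"].items():
        cond = entry.get("condition")
        condition = Condition.from_dict(cond) if cond else None
        events = [Event.from_dict(e) for e in entry.get("events", [])]
        out[slice_id] = (condition, events)
    return out


# ---------------------------------------------------------------------------
# trace CSV I/O


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_traces(
    path: str | Path,
    manifest: str | Path | Mapping | None = None,
) -> list[SliceRecording]:
    """Load a tidy trace CSV (and optional manifest) into SliceRecordings.

    Rows are grouped by (slice_id, roi_id); row order within an ROI must be
    ordered by time. Duplicate (slice, roi, time) rows, non-monotone time and
    varying per-ROI exposure are all rejected with messages naming the
    offending slice/ROI.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, TRACE_COLUMNS, path)

    if isinstance(manifest, (str, Path)):
        manifest = load_manifest(manifest)

    recordings: list[SliceRecording] = []
    for slice_id, sdf in df.groupby("slice_id", sort=False):
        traces = []
        for roi_id, rdf in sdf.groupby("roi_id", sort=False):
            times = rdf["time_s"].to_numpy(dtype=float)
            if np.unique(times).size != times.size:
                raise ValidationError(
                    f"{path}: duplicated (slice, roi, time) row in slice "
                    f"{slice_id} roi {roi_id}"
                )
            exposures = rdf["exposure500_ms"].unique()
            if exposures.size != 1:
                raise ValidationError(
                    f"{path}: slice {slice_id} roi {roi_id} has varying "
                    f"exposure500_ms {sorted(exposures)}"
                )
            bg_vals = rdf["is_background"].astype(bool).unique()
            if bg_vals.size != 1:
                raise ValidationError(
                    f"{path}: slice {slice_id} roi {roi_id} has inconsistent "
                    "is_background flags"
                )
            f436 = rdf["f436"].to_numpy(dtype=float)
            f500 = rdf["f500"].to_numpy(dtype=float)
            for name, arr in (("f436", f436), ("f500", f500)):
                neg = arr[np.isfinite(arr)] < 0
                if np.any(neg):
                    raise ValidationError(
                        f"{path}: slice {slice_id} roi {roi_id} has negative "
                        f"{name} intensity"
                    )
            traces.append(
                ROITrace(
                    slice_id=str(slice_id),
                    roi_id=str(roi_id),
                    time_s=times,
                    f436=f436,
                    f500=f500,
                    exposure500_ms=float(exposures[0]),
                    is_background=bool(bg_vals[0]),
                )
            )
        condition, events = (None, [])
        if manifest is not None:
            if slice_id not in manifest:
                raise ValidationError(
                    f"{path}: slice {slice_id} absent from manifest"
                )
            condition, events = manifest[str(slice_id)]
        recordings.append(
            SliceRecording(
                slice_id=str(slice_id),
                condition=condition,
                traces=traces,
                events=list(events),
            )
        )
    return recordings


def write_traces(recordings: Iterable[SliceRecording], path: str | Path) -> Path:
    """Write recordings as tidy long CSV, lossless for all numeric fields."""
    rows = []
    for rec in recordings:
        for t in rec.traces:
            rows.append(
                pd.DataFrame(
                    {
                        "slice_id": t.slice_id,
                        "roi_id": t.roi_id,
                        "time_s": t.time_s,
                        "f436": t.f436,
                        "f500": t.f500,
                        "exposure500_ms": t.exposure500_ms,
                        "is_background": t.is_background,
                    }
                )
            )
    if rows:
        df = pd.concat(rows, ignore_index=True)
    else:
        df = pd.DataFrame(columns=TRACE_COLUMNS)
    path = Path(path)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


# ---------------------------------------------------------------------------
# effects CSV I/O


def effects_to_frame(effects: Iterable[EffectRecord]) -> pd.DataFrame:
    rows = [
        {
            "slice_id": e.slice_id,
            "roi_id": e.roi_id,
            "neuron_type": e.condition.neuron_type.value,
            "phase": e.condition.phase.value,
            "buffer": e.condition.buffer.value,
            "drug": e.drug.value,
            "baseline_r": e.baseline_r,
            "post_r": e.post_r,
            "delta_r": e.delta_r,
            "low_confidence": e.low_confidence,
        }
        for e in effects
    ]
    if not rows:
        return pd.DataFrame(columns=EFFECT_COLUMNS)
    return pd.DataFrame(rows, columns=EFFECT_COLUMNS)


def write_effects(effects: Iterable[EffectRecord], path: str | Path) -> Path:
    path = Path(path)
    effects_to_frame(effects).to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_effects(path: str | Path) -> list[EffectRecord]:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, EFFECT_COLUMNS, path)
    out = []
    for i, row in df.iterrows():
        out.append(
            EffectRecord(
                slice_id=str(row["slice_id"]),
                roi_id=str(row["roi_id"]),
                condition=Condition(row["neuron_type"], row["phase"], row["buffer"]),
                drug=EventKind(row["drug"]),
                baseline_r=float(row["baseline_r"]),
                post_r=float(row["post_r"]),
                delta_r=float(row["delta_r"]),
                low_confidence=bool(row["low_confidence"]),
            )
        )
    return out
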