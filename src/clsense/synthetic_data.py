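"""Synthetic generators for every input the pipeline consumes.

Everything is generated with known ground truth and a deterministic seed
hierarchy (dataset -> slice -> ROI), so that each pipeline stage can be tested
either by exact comparison (all corruption terms off) or by statistical
recovery. Drug effects are specified in ratio units — the reporting currency
of the analysis — and routed through the inverse calibration to build the
underlying chloride trajectory.

Photoinactivation drift is applied multiplicatively to the 500 nm channel
only (the chloride-sensitive moiety accumulates in an inactivated state),
which raises the measured ratio over time; its amplitude scales with the
assigned exposure. A small additive exposure-linked ratio offset survives
drift correction, emulating the residual exposure trend that the per-condition
exposure adjustment is designed to remove.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .calibration import CalibrationFit, CalibrationPoint, forward_model, inverse_model
from .errors import AnalysisError, ValidationError
from .egaba import RampPair
from .trace_model import (
    Buffer,
    Condition,
    Event,
    EventKind,
    NeuronType,
    Phase,
    ROITrace,
    SliceRecording,
    save_manifest,
    write_traces,
)

__all__ = [
    "DEFAULT_SENSOR",
    "TruthSpec",
    "NoiseSpec",
    "DriftSpec",
    "SimConfig",
    "SimulatedDataset",
    "simulate_cl_trajectory",
    "render_fluorescence",
    "render_background",
    "simulate_dataset",
    "simulate_calibration",
    "simulate_ramp",
    "default_conditions",
]

# Default sensor constants place the operating band for resting ratios at
# roughly 1.0-1.3, with half-saturation near 109 mM.
DEFAULT_SENSOR = CalibrationFit(
    kd_mM=108.8, r_min=0.98, r_max=2.92, hill_p=2.91
)


def default_conditions(buffer: Buffer = Buffer.BICARBONATE) -> list[Condition]:
    return [
        Condition(nt, ph, buffer)
        for nt in (NeuronType.AVP, NeuronType.VIP)
        for ph in (Phase.DAY, Phase.NIGHT)
    ]


@dataclass
class TruthSpec:
    """Ground-truth parameters injected into simulated recordings.

    ``baseline_r`` maps condition labels ("AVP day", ...) to resting ratios;
    missing labels fall back to ``default_baseline_r`` plus
    ``day_night_offset_r`` for day-phase conditions. ``drug_delta_r`` maps
    event kind -> neuron type -> persistent ratio step.
    """

    default_baseline_r: float = 1.10
    day_night_offset_r: float = 0.03
    baseline_r: dict[str, float] = field(default_factory=dict)
    drug_delta_r: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            EventKind.BATH_VU.value: {"AVP": 0.18, "VIP": 0.27},
            EventKind.BATH_BUMETANIDE.value: {"AVP": 0.04, "VIP": -0.04},
        }
    )
    washin_tau_s: float = 180.0
    transient_amplitude_r: float = 0.10
    transient_rise_tau_s: float = 10.0
    transient_decay_tau_s: float = 120.0
    # second bath drug's amplitude multiplier when a KCC blocker follows an
    # NKCC1 blocker (occlusion scenario)
    occlusion_factor: float = 0.0
    slice_random_effect_sd: float = 0.03
    egaba_true_mV: float = -60.0
    egaba_shift_mV: float = 23.0

    def baseline_for(self, condition: Condition) -> float:
        if condition.label in self.baseline_r:
            return self.baseline_r[condition.label]
        r = self.default_baseline_r
        if condition.phase is Phase.DAY:
            r += self.day_night_offset_r
        return r

    def delta_for(self, kind: EventKind, neuron_type: NeuronType) -> float:
        by_neuron = self.drug_delta_r.get(EventKind(kind).value, {})
        return by_neuron.get(NeuronType(neuron_type).value, 0.0)


@dataclass
class NoiseSpec:
    """Shot-noise-like channel noise, SD = a + b*sqrt(intensity)."""

    channel_noise_a: float = 1.0
    channel_noise_b: float = 0.15
    background_f436: float = 60.0
    background_f500: float = 90.0
    ramp_current_noise_pA: float = 5.0

    def channel_sd(self, intensity: np.ndarray) -> np.ndarray:
        return self.channel_noise_a + self.channel_noise_b * np.sqrt(
            np.maximum(intensity, 0.0)
        )


@dataclass
class DriftSpec:
    """Photoinactivation drift of the 500 nm channel.

    ``amplitude_per_100ms`` is the asymptotic fractional loss of the 500 nm
    signal for a 100 ms exposure; the loss scales linearly with exposure.
    ``exposure_residual_slope`` is the additive ratio-per-ms trend that
    remains after drift correction.
    """

    amplitude_per_100ms: float = 0.03
    tau_s: float = 300.0
    exposure_set_ms: tuple[float, ...] = (50.0, 100.0, 200.0)
    exposure_residual_slope: float = 5e-4

    def loss(self, time_s: np.ndarray, exposure_ms: float) -> np.ndarray:
        amp = self.amplitude_per_100ms * exposure_ms / 100.0
        return amp * (1.0 - np.exp(-np.asarray(time_s, float) / self.tau_s))


@dataclass
class SimConfig:
    """Deterministic recipe for a full simulated imaging dataset."""

    seed: int = 0
    n_slices_per_condition: int = 3
    rois_per_slice: int = 4
    sampling_interval_s: float = 5.0
    duration_s: float = 1500.0
    conditions: list[Condition] = field(default_factory=default_conditions)
    events: list[Event] = field(
        default_factory=lambda: [Event(EventKind.BATH_VU, 300.0)]
    )
    truth: TruthSpec = field(default_factory=TruthSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    drift: DriftSpec = field(default_factory=DriftSpec)
    calibration: CalibrationFit = field(
        default_factory=lambda: DEFAULT_SENSOR
    )

    def __post_init__(self) -> None:
        # accept plain dicts (e.g. parsed from a YAML/JSON config file)
        if isinstance(self.truth, dict):
            self.truth = TruthSpec(**self.truth)
        if isinstance(self.noise, dict):
            self.noise = NoiseSpec(**self.noise)
        if isinstance(self.drift, dict):
            drift = dict(self.drift)
            if "exposure_set_ms" in drift:
                drift["exposure_set_ms"] = tuple(drift["exposure_set_ms"])
            self.drift = DriftSpec(**drift)
        if isinstance(self.calibration, dict):
            self.calibration = CalibrationFit(**self.calibration)
        self.conditions = [
            Condition.from_dict(c) if isinstance(c, dict) else c
            for c in self.conditions
        ]
        self.events = [
            Event.from_dict(e) if isinstance(e, dict) else e
            for e in self.events
        ]
        if self.sampling_interval_s <= 0 or self.duration_s <= 0:
            raise ValidationError("sampling interval and duration must be positive")

    def time_base(self) -> np.ndarray:
        return np.arange(0.0, self.duration_s + 1e-9, self.sampling_interval_s)


@dataclass
class SimulatedDataset:
    recordings: list[SliceRecording]
    truth: dict
    config: SimConfig


def _transient_shape(dt: np.ndarray, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Unit-peak rise-and-decay shape for puff transients."""
    s = (1.0 - np.exp(-dt / rise_tau)) * np.exp(-dt / decay_tau)
    t_peak = rise_tau * np.log1p(decay_tau / rise_tau)
    peak = (1.0 - np.exp(-t_peak / rise_tau)) * np.exp(-t_peak / decay_tau)
    return s / peak


def simulate_cl_trajectory(
    truth: TruthSpec,
    events: Sequence[Event],
    time_s: np.ndarray,
    condition: Condition,
    calibration: CalibrationFit = DEFAULT_SENSOR,
) -> np.ndarray:
    """Ground-truth chloride concentration over time for one ROI.

    The trajectory is built in ratio space (baseline plus exponential wash-in
    steps for bath drugs, normalized rise/decay pulses for puffs) and mapped
    to concentration through the inverse calibration. When a KCC-blocker bath
    event follows an NKCC1-blocker bath event, its amplitude is multiplied by
    ``truth.occlusion_factor``.
    """
    time_s = np.asarray(time_s, dtype=float)
    events = sorted(events, key=lambda e: e.onset_s)
    bath = [e for e in events if e.kind.is_bath]
    for a, b in zip(bath, bath[1:]):
        if b.onset_s <= a.onset_s:
            raise AnalysisError(
                f"overlapping bath events at {a.onset_s}s and {b.onset_s}s"
            )
    if any(e.onset_s > time_s[-1] or e.onset_s < time_s[0] for e in events):
        raise AnalysisError("event onset outside the time base")

    r = np.full(time_s.shape, truth.baseline_for(condition))
    seen_bath: list[EventKind] = []
    for ev in events:
        dt = time_s - ev.onset_s
        active = dt >= 0
        if ev.kind.is_bath:
            amp = truth.delta_for(ev.kind, condition.neuron_type)
            if (
                ev.kind is EventKind.BATH_VU
                and EventKind.BATH_BUMETANIDE in seen_bath
            ):
                amp *= truth.occlusion_factor
            r[active] += amp * (1.0 - np.exp(-dt[active] / truth.washin_tau_s))
            seen_bath.append(ev.kind)
        else:
            r[active] += truth.transient_amplitude_r * _transient_shape(
                dt[active], truth.transient_rise_tau_s, truth.transient_decay_tau_s
            )
    if np.any(r <= calibration.r_min) or np.any(r >= calibration.r_max):
        raise AnalysisError(
            "simulated ratio trajectory leaves the calibratable range "
            f"({calibration.r_min:.3g}, {calibration.r_max:.3g})"
        )
    return inverse_model(calibration, r)


def render_fluorescence(
    cl_mM: np.ndarray,
    time_s: np.ndarray,
    slice_id: str,
    roi_id: str,
    calibration: CalibrationFit = DEFAULT_SENSOR,
    drift: DriftSpec | None = None,
    noise: NoiseSpec | None = None,
    exposure_ms: float = 100.0,
    rng: np.random.Generator | None = None,
    slice_effect_r: float = 0.0,
    base_f500: float = 2000.0,
) -> ROITrace:
    """Render a chloride trajectory as a raw two-channel ROI trace.

    The drift-free channels satisfy f436/f500 = forward_model(cl) exactly
    (plus the slice random effect and residual exposure offset in ratio
    space); drift then attenuates the 500 nm channel, background pedestals
    are added, and channel noise is drawn from ``rng``.
    """
    cl_mM = np.asarray(cl_mM, dtype=float)
    time_s = np.asarray(time_s, dtype=float)
    r_true = forward_model(calibration, cl_mM) + slice_effect_r
    if drift is not None:
        r_true = r_true + drift.exposure_residual_slope * (exposure_ms - 100.0)

    f500 = np.full(time_s.shape, base_f500 * exposure_ms / 100.0)
    f436 = r_true * f500
    if drift is not None:
        f500 = f500 * (1.0 - drift.loss(time_s, exposure_ms))
    if noise is not None:
        f436 = f436 + noise.background_f436
        f500 = f500 + noise.background_f500
        if rng is None:
            raise AnalysisError("rng required when noise is enabled")
        f436 = f436 + rng.normal(0.0, noise.channel_sd(f436))
        f500 = f500 + rng.normal(0.0, noise.channel_sd(f500))
        f436 = np.maximum(f436, 0.0)
        f500 = np.maximum(f500, 0.0)
    return ROITrace(
        slice_id=slice_id,
        roi_id=roi_id,
        time_s=time_s,
        f436=f436,
        f500=f500,
        exposure500_ms=exposure_ms,
        is_background=False,
    )


def render_background(
    time_s: np.ndarray,
    slice_id: str,
    noise: NoiseSpec | None,
    exposure_ms: float,
    rng: np.random.Generator | None = None,
    roi_id: str = "bg",
) -> ROITrace:
    """Dim-field background ROI: pedestal plus channel noise."""
    time_s = np.asarray(time_s, dtype=float)
    b436 = noise.background_f436 if noise is not None else 0.0
    b500 = noise.background_f500 if noise is not None else 0.0
    f436 = np.full(time_s.shape, float(b436))
    f500 = np.full(time_s.shape, float(b500))
    if noise is not None and rng is not None:
        f436 = np.maximum(f436 + rng.normal(0.0, noise.channel_sd(f436)), 0.0)
        f500 = np.maximum(f500 + rng.normal(0.0, noise.channel_sd(f500)), 0.0)
    return ROITrace(
        slice_id=slice_id,
        roi_id=roi_id,
        time_s=time_s,
        f436=f436,
        f500=f500,
        exposure500_ms=exposure_ms,
        is_background=True,
    )


def _slice_rng(seed: int, c: int, s: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(c, s)))


def _roi_rng(seed: int, c: int, s: int, r: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(c, s, r)))


def simulate_dataset(
    config: SimConfig,
    out_dir: str | Path | None = None,
) -> SimulatedDataset:
    """Generate a full clustered imaging dataset with a ground-truth sidecar.

    Deterministic given ``config.seed``: RNG streams are split hierarchically
    (dataset -> slice -> ROI), so adding ROIs or slices never perturbs
    existing ones. When ``out_dir`` is given, writes ``traces.csv``,
    ``manifest.json`` and ``truth.json``.
    """
    time_s = config.time_base()
    recordings: list[SliceRecording] = []
    truth_slices: dict[str, dict] = {}
    for c, cond in enumerate(config.conditions):
        for s in range(config.n_slices_per_condition):
            slice_id = f"{cond.neuron_type.value}-{cond.phase.value}-{cond.buffer.value}-s{s:02d}"
            srng = _slice_rng(config.seed, c, s)
            slice_effect = float(
                srng.normal(0.0, config.truth.slice_random_effect_sd)
            )
            exposure = float(
                config.drift.exposure_set_ms[
                    s % len(config.drift.exposure_set_ms)
                ]
            )
            traces: list[ROITrace] = []
            roi_truth: dict[str, dict] = {}
            for r in range(config.rois_per_slice):
                roi_id = f"roi{r:02d}"
                rng = _roi_rng(config.seed, c, s, r)
                cl = simulate_cl_trajectory(
                    config.truth, config.events, time_s, cond, config.calibration
                )
                trace = render_fluorescence(
                    cl,
                    time_s,
                    slice_id=slice_id,
                    roi_id=roi_id,
                    calibration=config.calibration,
                    drift=config.drift,
                    noise=config.noise,
                    exposure_ms=exposure,
                    rng=rng,
                    slice_effect_r=slice_effect,
                )
                traces.append(trace)
                roi_truth[roi_id] = {
                    "baseline_r": config.truth.baseline_for(cond) + slice_effect,
                }
            bg_rng = _roi_rng(config.seed, c, s, 10_000)
            traces.append(
                render_background(
                    time_s, slice_id, config.noise, exposure, bg_rng
                )
            )
            recordings.append(
                SliceRecording(
                    slice_id=slice_id,
                    condition=cond,
                    traces=traces,
                    events=list(config.events),
                )
            )
            truth_slices[slice_id] = {
                "condition": cond.to_dict(),
                "slice_effect_r": slice_effect,
                "exposure500_ms": exposure,
                "rois": roi_truth,
            }

    truth = {
        "seed": config.seed,
        "truth_spec": asdict(config.truth),
        "drift_spec": asdict(config.drift),
        "noise_spec": asdict(config.noise),
        "calibration": {
            "kd_mM": config.calibration.kd_mM,
            "r_min": config.calibration.r_min,
            "r_max": config.calibration.r_max,
            "hill_p": config.calibration.hill_p,
        },
        "events": [ev.to_dict() for ev in config.events],
        "slices": truth_slices,
    }
    ds = SimulatedDataset(recordings=recordings, truth=truth, config=config)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_traces(recordings, out_dir / "traces.csv")
        save_manifest(recordings, out_dir / "manifest.json")
        (out_dir / "truth.json").write_text(
            json.dumps(truth, indent=2, sort_keys=True) + "\n"
        )
    return ds


def simulate_calibration(
    fit_params: CalibrationFit,
    cl_levels: Iterable[float] = (0.0, 4.0, 20.0, 40.0, 60.0, 80.0, 123.0),
    noise_sd: float = 0.0,
    n_slices: int = 1,
    rng: np.random.Generator | None = None,
) -> list[CalibrationPoint]:
    """Steady-state calibration points on (or noisily around) the sigmoid."""
    levels = np.asarray(list(cl_levels), dtype=float)
    if levels.size < 5:
        raise AnalysisError("calibration simulation needs >= 5 levels")
    if noise_sd > 0 and rng is None:
        raise AnalysisError("rng required when noise_sd > 0")
    points: list[CalibrationPoint] = []
    for s in range(n_slices):
        r = forward_model(fit_params, levels)
        if noise_sd > 0:
            r = r + rng.normal(0.0, noise_sd, size=levels.size)
        for cl, rv in zip(levels, r):
            points.append(
                CalibrationPoint(cl_mM=float(cl), steady_r=float(rv),
                                 slice_id=f"cal{s:02d}")
            )
    return points


def simulate_ramp(
    egaba_true_mV: float,
    conductance_nS: float = 1.5,
    leak_conductance_nS: float = 2.0,
    leak_reversal_mV: float = -65.0,
    noise_pA: float = 0.0,
    rng: np.random.Generator | None = None,
    v_start_mV: float = -80.0,
    v_stop_mV: float = -20.0,
    n_samples: int = 400,
    sweep_id: str = "",
) -> RampPair:
    """Linear agonist + leak currents along a voltage ramp.

    i_gaba = g*(V - E) + leak(V) + noise, i_control = leak(V) + noise, with
    independent noise draws per trace. The true reversal must lie inside the
    command span.
    """
    lo, hi = min(v_start_mV, v_stop_mV), max(v_start_mV, v_stop_mV)
    if not (lo < egaba_true_mV < hi):
        raise AnalysisError(
            f"true reversal {egaba_true_mV} mV outside command span "
            f"[{lo}, {hi}] mV"
        )
    if noise_pA > 0 and rng is None:
        raise AnalysisError("rng required when noise_pA > 0")
    v = np.linspace(v_start_mV, v_stop_mV, n_samples)
    leak = leak_conductance_nS * (v - leak_reversal_mV)
    i_gaba = conductance_nS * (v - egaba_true_mV) + leak
    i_control = leak.copy()
    if noise_pA > 0:
        i_gaba = i_gaba + rng.normal(0.0, noise_pA, size=v.size)
        i_control = i_control + rng.normal(0.0, noise_pA, size=v.size)
    return RampPair(
        command_mV=v, i_gaba_pA=i_gaba, i_control_pA=i_control, sweep_id=sweep_id
    )
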