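"""Reversal-potential estimation from voltage-ramp current pairs, plus
Nernst / passive-distribution utilities for the chloride ion.

The agonist-evoked current is isolated by subtracting a control ramp from a
ramp recorded during agonist application; the reversal potential is the
x-intercept of a local linear fit to the difference I-V around its zero
crossing. No series-resistance or junction-potential correction is applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .errors import (
    AnalysisError,
    MultipleCrossingsError,
    NoCrossingError,
    ValidationError,
)

__all__ = [
    "RampPair",
    "EgabaEstimate",
    "NernstParams",
    "subtract_ramp",
    "estimate_egaba",
    "estimate_from_pair",
    "nernst_cl",
    "passive_cl",
    "GAS_CONSTANT",
    "FARADAY",
]

GAS_CONSTANT = 8.314462618  # J / (mol K), CODATA
FARADAY = 96485.33212  # C / mol, CODATA
DEFAULT_TEMPERATURE_C = 34.0


@dataclass
class RampPair:
    """Currents along one voltage ramp, with and without agonist."""

    command_mV: np.ndarray
    i_gaba_pA: np.ndarray
    i_control_pA: np.ndarray
    sweep_id: str = ""

    def __post_init__(self) -> None:
        self.command_mV = np.asarray(self.command_mV, dtype=float)
        self.i_gaba_pA = np.asarray(self.i_gaba_pA, dtype=float)
        self.i_control_pA = np.asarray(self.i_control_pA, dtype=float)
        n = self.command_mV.size
        if self.i_gaba_pA.size != n or self.i_control_pA.size != n:
            raise ValidationError(
                f"ramp {self.sweep_id or '<unnamed>'}: current lengths "
                f"({self.i_gaba_pA.size}, {self.i_control_pA.size}) do not "
                f"match command length ({n})"
            )
        dv = np.diff(self.command_mV)
        if n >= 2 and not (np.all(dv > 0) or np.all(dv < 0)):
            raise ValidationError(
                f"ramp {self.sweep_id or '<unnamed>'}: command voltage must be "
                "strictly monotone"
            )


@dataclass
class EgabaEstimate:
    """x-intercept of the subtracted I-V and its local linear fit."""

    e_gaba_mV: float
    slope_nS: float
    fit_window_mV: tuple[float, float]
    r_squared: float
    sweep_id: str = ""

    def to_dict(self) -> dict:
        return {
            "sweep_id": self.sweep_id,
            "e_gaba_mV": self.e_gaba_mV,
            "slope_nS": self.slope_nS,
            "fit_window_mV": list(self.fit_window_mV),
            "r_squared": self.r_squared,
        }


@dataclass(frozen=True)
class NernstParams:
    cl_out_mM: float
    cl_in_mM: float
    temperature_C: float = DEFAULT_TEMPERATURE_C

    def __post_init__(self) -> None:
        if self.cl_out_mM <= 0 or self.cl_in_mM <= 0:
            raise ValueError("chloride concentrations must be positive")


def subtract_ramp(pair: RampPair) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise agonist-minus-control current against command voltage."""
    return pair.command_mV.copy(), pair.i_gaba_pA - pair.i_control_pA


def _coarse_crossing(v: np.ndarray, di: np.ndarray, smooth_points: int,
                     cluster_mV: float) -> float:
    """Locate the zero crossing of a moving-average-smoothed difference I-V.

    The averaging window is at least ``smooth_points`` samples and at least
    ``cluster_mV`` of command voltage, so that densely sampled ramps are
    smoothed over a meaningful voltage span. Crossings within ``cluster_mV``
    of each other are treated as one (noise flicker around the true
    reversal); genuinely distinct crossings raise.
    """
    dv = float(np.median(np.abs(np.diff(v)))) or 1.0
    k = max(smooth_points, int(np.ceil(cluster_mV / dv)))
    k = min(k, di.size)
    kernel = np.ones(k) / k
    sm = np.convolve(di, kernel, mode="valid")
    v_sm = np.convolve(v, kernel, mode="valid")
    sign = np.sign(sm)
    nz = sign != 0
    idx = np.where(np.diff(sign[nz]) != 0)[0]
    v_nz = v_sm[nz]
    crossings = []
    for i in idx:
        v_lo, v_hi = v_nz[i], v_nz[i + 1]
        # linear interpolation of the smoothed curve between the two samples
        s_lo, s_hi = sm[nz][i], sm[nz][i + 1]
        crossings.append(float(v_lo + (v_hi - v_lo) * (-s_lo) / (s_hi - s_lo)))
    if not crossings:
        raise NoCrossingError("reversal outside ramp: difference I-V never crosses zero")
    clusters: list[list[float]] = [[crossings[0]]]
    for c in crossings[1:]:
        if abs(c - clusters[-1][-1]) <= cluster_mV:
            clusters[-1].append(c)
        else:
            clusters.append([c])
    if len(clusters) > 1:
        centers = [float(np.mean(c)) for c in clusters]
        raise MultipleCrossingsError(
            f"difference I-V crosses zero {len(clusters)} times near "
            f"{[round(c, 1) for c in centers]} mV"
        )
    return float(np.mean(clusters[0]))


def estimate_egaba(
    command_mV: np.ndarray,
    diff_pA: np.ndarray,
    window_mV: float = 10.0,
    smooth_points: int = 5,
    sweep_id: str = "",
) -> EgabaEstimate:
    """Reversal potential as the x-intercept of a local linear fit.

    A coarse crossing is located on a ``smooth_points``-sample moving average
    (to avoid noise-triggered false crossings), then the raw difference
    current within +/- ``window_mV`` of it is fitted by least squares;
    E = -intercept/slope. With currents in pA and voltages in mV, the fitted
    slope is the chord conductance in nS.
    """
    v = np.asarray(command_mV, dtype=float)
    di = np.asarray(diff_pA, dtype=float)
    if v.size != di.size:
        raise ValidationError("command and difference current lengths differ")
    if v.size < smooth_points + 2:
        raise AnalysisError("too few ramp samples for reversal estimation")
    v0 = _coarse_crossing(v, di, smooth_points, cluster_mV=window_mV)
    sel = np.abs(v - v0) <= window_mV
    if sel.sum() < 3:
        raise AnalysisError(
            f"fewer than 3 samples within +/-{window_mV} mV of coarse "
            f"crossing {v0:.1f} mV"
        )
    slope, intercept = np.polyfit(v[sel], di[sel], 1)
    if slope == 0:
        raise AnalysisError("zero slope in fit window; conductance unresolvable")
    e_gaba = -intercept / slope
    pred = slope * v[sel] + intercept
    ss_res = float(np.sum((di[sel] - pred) ** 2))
    ss_tot = float(np.sum((di[sel] - np.mean(di[sel])) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if not (min(v) - 1e-9 <= e_gaba <= max(v) + 1e-9):
        raise AnalysisError(
            f"fitted reversal {e_gaba:.1f} mV falls outside the command range"
        )
    return EgabaEstimate(
        e_gaba_mV=float(e_gaba),
        slope_nS=float(slope),
        fit_window_mV=(float(v0 - window_mV), float(v0 + window_mV)),
        r_squared=r2,
        sweep_id=sweep_id,
    )


def estimate_from_pair(pair: RampPair, window_mV: float = 10.0,
                       smooth_points: int = 5) -> EgabaEstimate:
    v, di = subtract_ramp(pair)
    return estimate_egaba(v, di, window_mV=window_mV,
                          smooth_points=smooth_points, sweep_id=pair.sweep_id)


def write_estimates(estimates: Iterable[EgabaEstimate], path: str | Path,
                    extra: dict | None = None) -> Path:
    payload: dict = {"estimates": [e.to_dict() for e in estimates]}
    if extra:
        payload.update(extra)
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path


def nernst_cl(params: NernstParams) -> float:
    """Chloride equilibrium potential in mV.

    For the monovalent anion, E_Cl = (RT/F) * ln([Cl]_in / [Cl]_out).
    """
    t_kelvin = params.temperature_C + 273.15
    rt_over_f_mV = GAS_CONSTANT * t_kelvin / FARADAY * 1000.0
    return float(rt_over_f_mV * np.log(params.cl_in_mM / params.cl_out_mM))


def passive_cl(cl_out_mM: float, vm_mV: float,
               temperature_C: float = DEFAULT_TEMPERATURE_C) -> float:
    """Internal chloride (mM) if passively distributed at membrane potential
    ``vm_mV`` — the inverse of :func:`nernst_cl` for cl_in."""
    if cl_out_mM <= 0:
        raise ValueError("cl_out_mM must be positive")
    t_kelvin = temperature_C + 273.15
    rt_over_f_mV = GAS_CONSTANT * t_kelvin / FARADAY * 1000.0
    return float(cl_out_mM * np.exp(vm_mV / rt_over_f_mV))
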