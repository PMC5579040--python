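"""Four-parameter sigmoid calibration between chloride concentration and ratio.

Model
-----
The steady-state ratio R as a function of chloride concentration C (mM) is

    R(C) = r_max + (r_min - r_max) / (1 + (C / kd)^p)

which satisfies R(0) = r_min, R(inf) = r_max and is strictly increasing for
p > 0 and r_max > r_min (chloride quenches the 500 nm-excited emission, so the
436/500 ratio rises with concentration). The exact algebraic inverse is

    C(R) = kd * ((r_min - R) / (R - r_max))^(1/p)

for r_min < R < r_max. Ratios at or below r_min are floored to 0 mM; ratios at
or above r_max are unresolvable and map to NaN.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy import stats

from .errors import FitError, IdentifiabilityError

__all__ = [
    "CalibrationPoint",
    "CalibrationFit",
    "forward_model",
    "inverse_model",
    "inverse_flags",
    "fit_calibration",
    "delta_cl",
    "concentration_sensitivity",
]

# bounds for (kd, r_min, r_max, p) used by the fitter
_BOUNDS_LO = np.array([1e-3, 1e-6, 1e-6, 0.5])
_BOUNDS_HI = np.array([1e4, 10.0, 10.0, 10.0])


@dataclass(frozen=True)
class CalibrationPoint:
    """One steady-state measurement at a known chloride concentration."""

    cl_mM: float
    steady_r: float
    slice_id: str = ""

    def __post_init__(self) -> None:
        if self.cl_mM < 0:
            raise ValueError(f"cl_mM must be >= 0, got {self.cl_mM}")
        if not self.steady_r > 0:
            raise ValueError(f"steady_r must be > 0, got {self.steady_r}")


@dataclass
class CalibrationFit:
    """Fitted sigmoid parameters with optional covariance diagnostics."""

    kd_mM: float
    r_min: float
    r_max: float
    hill_p: float
    covariance: np.ndarray | None = None
    n_points: int = 0
    rss: float | None = None

    def __post_init__(self) -> None:
        if not self.kd_mM > 0:
            raise ValueError(f"kd_mM must be > 0, got {self.kd_mM}")
        if not self.hill_p > 0:
            raise ValueError(f"hill_p must be > 0, got {self.hill_p}")
        if not self.r_max > self.r_min:
            raise ValueError(
                f"r_max ({self.r_max}) must exceed r_min ({self.r_min})"
            )
        if self.covariance is not None:
            self.covariance = np.asarray(self.covariance, dtype=float)
            if self.covariance.shape != (4, 4):
                raise ValueError("covariance must be 4x4 (kd, r_min, r_max, p)")

    @property
    def params(self) -> np.ndarray:
        return np.array([self.kd_mM, self.r_min, self.r_max, self.hill_p])

    def stderr(self) -> np.ndarray | None:
        if self.covariance is None:
            return None
        return np.sqrt(np.diag(self.covariance))

    def ci95(self) -> np.ndarray | None:
        """Wald 95% intervals, rows (lo, hi) per parameter."""
        se = self.stderr()
        if se is None:
            return None
        dof = max(self.n_points - 4, 1)
        half = stats.t.ppf(0.975, dof) * se
        return np.column_stack([self.params - half, self.params + half])

    def forward(self, cl_mM):
        return forward_model(self, cl_mM)

    def inverse(self, r_cl):
        return inverse_model(self, r_cl)

    def to_json(self, path: str | Path) -> Path:
        payload = {
            "kd_mM": self.kd_mM,
            "r_min": self.r_min,
            "r_max": self.r_max,
            "hill_p": self.hill_p,
            "covariance": None
            if self.covariance is None
            else self.covariance.tolist(),
            "n_points": self.n_points,
            "rss": self.rss,
        }
        path = Path(path)
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationFit":
        d = json.loads(Path(path).read_text())
        return cls(
            kd_mM=d["kd_mM"],
            r_min=d["r_min"],
            r_max=d["r_max"],
            hill_p=d["hill_p"],
            covariance=d.get("covariance"),
            n_points=d.get("n_points", 0),
            rss=d.get("rss"),
        )


def _sigmoid(cl, kd, r_min, r_max, p):
    # algebraically r_max + (r_min - r_max)/(1 + x) with x = (cl/kd)^p, but
    # evaluated piecewise to avoid cancellation at both asymptotes
    cl = np.asarray(cl, dtype=float)
    with np.errstate(over="ignore"):
        x = (cl / kd) ** p
    frac = np.where(x < 1.0, x / (1.0 + x), 1.0 - 1.0 / (1.0 + x))
    return r_min + (r_max - r_min) * frac


def forward_model(fit: CalibrationFit, cl_mM):
    """Predicted ratio at concentration ``cl_mM`` (scalar or array)."""
    cl = np.asarray(cl_mM, dtype=float)
    if np.any(cl < 0):
        raise ValueError("chloride concentration must be non-negative")
    out = _sigmoid(cl, fit.kd_mM, fit.r_min, fit.r_max, fit.hill_p)
    return float(out) if np.isscalar(cl_mM) else out


def inverse_model(fit: CalibrationFit, r_cl):
    """Concentration (mM) at ratio ``r_cl``.

    Values at or below r_min floor to 0 mM; values at or above r_max are NaN.
    Use :func:`inverse_flags` to recover which samples were clipped.
    """
    r = np.asarray(r_cl, dtype=float)
    out = np.full(r.shape, np.nan)
    ok = (r > fit.r_min) & (r < fit.r_max)
    with np.errstate(invalid="ignore"):
        out[ok] = fit.kd_mM * (
            (fit.r_min - r[ok]) / (r[ok] - fit.r_max)
        ) ** (1.0 / fit.hill_p)
    out[r <= fit.r_min] = 0.0
    return float(out) if np.isscalar(r_cl) else out


def inverse_flags(fit: CalibrationFit, r_cl) -> np.ndarray:
    """Per-sample status of the inverse mapping: 'ok', 'floor' or 'ceiling'."""
    r = np.atleast_1d(np.asarray(r_cl, dtype=float))
    flags = np.where(
        r <= fit.r_min, "floor", np.where(r >= fit.r_max, "ceiling", "ok")
    )
    return flags


def concentration_sensitivity(fit: CalibrationFit, r_cl) -> float | np.ndarray:
    """d[Cl]/dR at ratio ``r_cl`` — diverges as R approaches r_min.

    Reported with fits so that downstream users can propagate the
    baseline-dependent uncertainty of concentration estimates.
    """
    r = np.asarray(r_cl, dtype=float)
    num = fit.r_min - r
    den = r - fit.r_max
    ratio = num / den
    with np.errstate(divide="ignore", invalid="ignore"):
        dCdR = (
            fit.kd_mM
            / fit.hill_p
            * ratio ** (1.0 / fit.hill_p - 1.0)
            * (fit.r_max - fit.r_min)
            / den**2
        )
    return float(dCdR) if np.isscalar(r_cl) else dCdR


def _as_arrays(points) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(points, pd.DataFrame):
        if not {"cl_mM", "steady_r"} <= set(points.columns):
            raise IdentifiabilityError(
                "calibration table needs columns cl_mM and steady_r"
            )
        return (
            points["cl_mM"].to_numpy(dtype=float),
            points["steady_r"].to_numpy(dtype=float),
        )
    pts = list(points)
    return (
        np.array([p.cl_mM for p in pts], dtype=float),
        np.array([p.steady_r for p in pts], dtype=float),
    )


def fit_calibration(
    points: Iterable[CalibrationPoint] | pd.DataFrame,
    init: Sequence[float] | None = None,
    n_restarts: int = 8,
) -> CalibrationFit:
    """Nonlinear least-squares fit of the sigmoid to (cl_mM, steady_r) points.

    Initialisation takes r_min/r_max from the observed ratio range, kd from
    the concentration closest to mid-range ratio, and p = 1; up to
    ``n_restarts`` deterministic jittered restarts are tried before declaring
    failure. Requires >= 5 distinct concentrations for identifiability.
    """
    cl, r = _as_arrays(points)
    if np.unique(cl).size < 5:
        raise IdentifiabilityError(
            f"need >= 5 distinct concentrations, got {np.unique(cl).size}"
        )

    if init is not None:
        p0 = np.asarray(init, dtype=float)
    else:
        r_lo, r_hi = float(np.min(r)), float(np.max(r))
        mid = 0.5 * (r_lo + r_hi)
        pos = cl[cl > 0]
        kd0 = float(pos[np.argmin(np.abs(r[cl > 0] - mid))]) if pos.size else 50.0
        p0 = np.array([kd0, max(r_lo, 1e-3), max(r_hi, r_lo + 0.1), 1.0])
    p0 = np.clip(p0, _BOUNDS_LO, _BOUNDS_HI)

    rng = np.random.default_rng(0)  # deterministic restart jitter
    last_err: Exception | None = None
    for attempt in range(n_restarts + 1):
        start = p0 if attempt == 0 else np.clip(
            p0 * np.exp(rng.normal(0, 0.3, size=4)), _BOUNDS_LO, _BOUNDS_HI
        )
        try:
            popt, pcov = curve_fit(
                _sigmoid,
                cl,
                r,
                p0=start,
                bounds=(_BOUNDS_LO, _BOUNDS_HI),
                maxfev=20000,
            )
        except (RuntimeError, ValueError) as exc:
            last_err = exc
            continue
        kd, r_min, r_max, p = popt
        if r_max <= r_min:
            last_err = FitError("fit collapsed: r_max <= r_min")
            continue
        resid = r - _sigmoid(cl, *popt)
        return CalibrationFit(
            kd_mM=float(kd),
            r_min=float(r_min),
            r_max=float(r_max),
            hill_p=float(p),
            covariance=pcov,
            n_points=int(cl.size),
            rss=float(np.sum(resid**2)),
        )
    raise FitError(
        f"calibration fit failed after {n_restarts + 1} starts: {last_err}"
    )


def delta_cl(fit: CalibrationFit, baseline_r: float, delta_r: float) -> float:
    """Concentration change (mM) implied by a ratio step from ``baseline_r``.

    Both endpoints must lie strictly inside (r_min, r_max); otherwise NaN is
    returned (flagged missing) because the sigmoid cannot resolve them.
    """
    lo, hi = baseline_r, baseline_r + delta_r
    for endpoint in (lo, hi):
        if not (fit.r_min < endpoint < fit.r_max):
            return float("nan")
    return float(inverse_model(fit, hi) - inverse_model(fit, lo))
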