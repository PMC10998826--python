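"""Time-activity-curve kinetics: effective half-life, back-extrapolation,
and time-integrated disintegration counts.

The regional kinetics are mono-exponential.  A linear model is fitted to the
log-transformed TAC values; the effective decay constant is defined
non-negative, ``lambda_e = -slope``, so ``Te = ln2/lambda_e > 0`` and the
back-extrapolation ``A1 = A4 * exp(+lambda_e * dt)`` scales the late
background-corrected activity up to the first acquisition.  The total number
of disintegrations is

    N = A1 * (t1/2 + 1/lambda_e)        (times in seconds)

i.e. a linear-uptake triangle from injection to the first acquisition plus an
exponential tail anchored at A1 at t1.  When the data do not support the
exponential fit (non-negative slope, poor r^2, or too few positive points),
N falls back to trapezoidal integration over the acquisition window plus a
physical-decay tail anchored at the last point.

Public interfaces take hours; everything internal is in seconds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .nucdata import DecayData, physical_decay_constant

__all__ = [
    "TimeActivityCurve",
    "KineticFit",
    "DisintegrationCount",
    "UnusableFitError",
    "fit_effective_halflife",
    "back_extrapolate_A1",
    "integrate_disintegrations",
    "integrate_disintegrations_trapezoid",
]

_H_TO_S = 3600.0


class UnusableFitError(RuntimeError):
    """The log-linear fit is unusable; use the trapezoid fallback."""


@dataclass
class TimeActivityCurve:
    """Activity (Bq) or mean concentration (Bq/ml) at successive time points."""

    times_h: np.ndarray
    values: np.ndarray
    value_kind: str = "activity_bq"  # or "concentration_bq_ml"
    censored: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_h.shape != self.values.shape:
            raise ValueError("times and values must align")
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("TAC values must be non-negative")
        if self.censored is None:
            self.censored = np.zeros(self.times_h.shape, dtype=bool)
        else:
            self.censored = np.asarray(self.censored, dtype=bool)

    def uncensored(self) -> tuple[np.ndarray, np.ndarray]:
        keep = ~self.censored
        return self.times_h[keep], self.values[keep]


@dataclass
class KineticFit:
    """Log-linear fit result: intercept, decay constant, effective half-life."""

    alpha: float  # intercept of ln(value) vs time (h)
    lambda_e_per_s: float  # >= 0 by convention; 0/negative slope => unusable
    Te_h: float  # ln2/lambda_e, inf when lambda_e == 0
    r_squared: float
    n_points: int
    usable: bool
    fallback_reason: str = field(default="")


def fit_effective_halflife(tac: TimeActivityCurve, min_r2: float = 0.5) -> KineticFit:
    """Ordinary least squares of ln(value) on time; ``lambda_e = -slope``.

    Non-positive values are excluded with a warning.  The fit is flagged
    unusable (triggering the trapezoid fallback) for a non-negative slope,
    ``r^2 < min_r2``, or fewer than 3 positive points.
    """
    t, v = tac.uncensored()
    pos = v > 0
    if np.any(~pos):
        warnings.warn("non-positive TAC values excluded from log-linear fit")
    t, v = t[pos], v[pos]
    if len(t) < 2:
        raise ValueError("fewer than 2 positive points: cannot fit")

    slope, alpha = np.polyfit(t, np.log(v), 1)
    pred = alpha + slope * t
    ss_res = float(np.sum((np.log(v) - pred) ** 2))
    ss_tot = float(np.sum((np.log(v) - np.log(v).mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)

    lam_h = -slope  # per hour
    if lam_h <= 1e-12:  # constant TACs fit with slope 0 up to round-off
        lam_h = 0.0
    usable, reason = True, ""
    if len(t) < 3:
        usable, reason = False, "fewer than 3 positive points"
    elif lam_h <= 0:
        usable, reason = False, "non-negative log-TAC slope"
    elif r2 < min_r2:
        usable, reason = False, f"r^2 = {r2:.3f} below {min_r2}"

    lam_s = max(lam_h, 0.0) / _H_TO_S
    te = math.log(2.0) / lam_s / _H_TO_S if lam_s > 0 else math.inf
    return KineticFit(
        alpha=float(alpha), lambda_e_per_s=lam_s, Te_h=te,
        r_squared=r2, n_points=len(t), usable=usable, fallback_reason=reason,
    )


@dataclass
class DisintegrationCount:
    """Time-integrated activity as a dimensionless disintegration count."""

    N: float
    method: str  # "closed_form" | "trapezoid_tail"
    A1_used_bq: float

    def __post_init__(self) -> None:
        if self.A1_used_bq > 0 and not self.N > 0:
            raise ValueError("N must be positive when A1 > 0")


def back_extrapolate_A1(A4_bq: float, fit: KineticFit, delta_t_h: float) -> float:
    """Activity at the first acquisition, ``A1 = A4 * exp(lambda_e * dt)``."""
    if not fit.usable:
        raise UnusableFitError(
            f"fit unusable ({fit.fallback_reason}); use the trapezoid fallback"
        )
    if delta_t_h < 0:
        raise ValueError("delta_t must be non-negative")
    return float(A4_bq * math.exp(fit.lambda_e_per_s * delta_t_h * _H_TO_S))


def integrate_disintegrations(A1_bq: float, fit: KineticFit,
                              t1_h: float) -> DisintegrationCount:
    """Closed-form N = A1*(t1/2 + 1/lambda_e), times in seconds."""
    if not fit.usable or fit.lambda_e_per_s <= 0:
        raise UnusableFitError("non-positive decay constant; use the trapezoid fallback")
    if t1_h <= 0:
        raise ValueError("t1 must be positive")
    if A1_bq == 0:
        return DisintegrationCount(N=0.0, method="closed_form", A1_used_bq=0.0)
    t1_s = t1_h * _H_TO_S
    n = A1_bq * (t1_s / 2.0 + 1.0 / fit.lambda_e_per_s)
    return DisintegrationCount(N=float(n), method="closed_form", A1_used_bq=float(A1_bq))


def integrate_disintegrations_trapezoid(tac: TimeActivityCurve,
                                        decay: DecayData) -> DisintegrationCount:
    """Trapezoid over the acquisition window + physical-decay tail.

    N = A(t1)*t1/2  (uptake triangle, same convention as the closed form)
      + trapezoid of A over [t1, t_last]
      + A(t_last)/lambda_phys  (analytic tail with the physical half-life).
    """
    t, v = tac.uncensored()
    if len(t) < 2:
        raise ValueError("need at least 2 points for trapezoidal integration")
    t_s = t * _H_TO_S
    lam_phys = physical_decay_constant(decay)
    n = v[0] * t_s[0] / 2.0
    n += float(np.trapezoid(v, t_s))
    n += v[-1] / lam_phys
    return DisintegrationCount(N=float(n), method="trapezoid_tail", A1_used_bq=float(v[0]))
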