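"""Percent-intact-peptide quantification from radio-HPLC traces and per-arm
stability summaries.

A chromatogram is baseline-corrected (linear baseline between the trace
endpoints), segmented into peak regions at the valleys between detected
apexes, and the intact fraction is the integrated area of the peak whose apex
lies within a retention-time window divided by the total integrated area.
Degraded species need not form identifiable metabolite peaks; everything
outside the intact peak counts as bulk non-intact signal.

Summary conventions: median = midpoint (mean of the central pair for even n);
IQR = Q3 - Q1 with inclusive Tukey hinges; report-layer rounding is half-up
at the printed precision.  Non-evaluable entries are excluded, never imputed.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .phantom_sim import Chromatogram

__all__ = [
    "percent_intact",
    "stability_summary",
    "median_midpoint",
    "iqr_hinges",
    "round_half_up",
]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal rounding with ties away from zero (as printed tables round)."""
    q = 10.0**decimals
    return math.floor(abs(x) * q + 0.5) / q * (1 if x >= 0 else -1)


def median_midpoint(values) -> float:
    """Median with the midpoint convention (mean of central pair for even n)."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("median of empty cell")
    return float(np.median(v))


def iqr_hinges(values) -> float:
    """Q3 - Q1 using inclusive Tukey hinges (halves include the median if odd n)."""
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n == 0:
        raise ValueError("IQR of empty cell")
    if n == 1:
        return 0.0
    half = (n + 1) // 2
    lower, upper = v[:half], v[n - half:]
    return float(np.median(upper) - np.median(lower))


def percent_intact(c: Chromatogram, intact_rt_min: float,
                   tolerance_min: float = 0.5,
                   min_prominence_frac: float = 0.02) -> float:
    """Percent of total integrated signal in the intact-peptide peak.

    The trace is linear-baseline corrected between its endpoints, peaks are
    detected with a relative prominence floor, and peak regions are bounded
    by the valleys between adjacent apexes.  Returns
    ``100 * area(intact peak region) / total area`` (trapezoidal integration).
    A missing intact peak returns 0 with a warning; a zero total area is an
    error.
    """
    rt = np.asarray(c.retention_time_min, dtype=float)
    y = np.asarray(c.counts, dtype=float)
    if not (rt[0] <= intact_rt_min <= rt[-1]):
        raise ValueError("intact retention time outside the trace grid")
    baseline = np.interp(rt, [rt[0], rt[-1]], [y[0], y[-1]])
    y = np.clip(y - baseline, 0.0, None)
    total = float(np.trapezoid(y, rt))
    if total <= 0:
        raise ValueError("total integrated area is zero: percentage undefined")

    apexes, _ = find_peaks(y, prominence=min_prominence_frac * y.max())
    if apexes.size == 0:
        warnings.warn("no peaks detected in chromatogram")
        return 0.0
    in_window = np.abs(rt[apexes] - intact_rt_min) <= tolerance_min
    if not in_window.any():
        warnings.warn("no peak apex within the intact retention-time window")
        return 0.0
    # tallest apex inside the window is the intact peak
    intact_apex = apexes[in_window][np.argmax(y[apexes[in_window]])]

    # peak region: from the valley (argmin) before the apex to the one after
    order = np.sort(apexes)
    pos = int(np.searchsorted(order, intact_apex))
    lo = 0 if pos == 0 else order[pos - 1] + int(np.argmin(y[order[pos - 1]:intact_apex + 1]))
    if pos == len(order) - 1:
        hi = len(rt) - 1
    else:
        hi = intact_apex + int(np.argmin(y[intact_apex:order[pos + 1] + 1]))
    area = float(np.trapezoid(y[lo:hi + 1], rt[lo:hi + 1]))
    return 100.0 * area / total


def stability_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-(arm, time) medians/IQRs over evaluable patients, plus folds.

    Expects the packaged stability schema
    ``(patient, arm, time_min, percent_intact, evaluable)``.  Returns one row
    per time point with both arms' median and IQR, the with/without fold of
    raw medians, and the fold of medians rounded to one decimal (the printed
    convention).
    """
    ev = table[table["evaluable"]]
    rows = []
    for t in sorted(ev["time_min"].unique()):
        cell = {}
        for arm in ("without", "with"):
            v = ev.loc[(ev["arm"] == arm) & (ev["time_min"] == t), "percent_intact"]
            v = v.dropna().to_numpy()
            if v.size == 0:
                cell[arm] = (math.nan, math.nan, 0)
            else:
                cell[arm] = (median_midpoint(v), iqr_hinges(v), v.size)
        med_wo, iqr_wo, n_wo = cell["without"]
        med_w, iqr_w, n_w = cell["with"]
        fold = med_w / med_wo if n_wo and n_w else math.nan
        fold_rounded = (
            round_half_up(med_w, 1) / round_half_up(med_wo, 1)
            if n_wo and n_w else math.nan
        )
        rows.append({
            "time_min": t,
            "median_without": med_wo, "iqr_without": iqr_wo, "n_without": n_wo,
            "median_with": med_w, "iqr_with": iqr_w, "n_with": n_w,
            "fold": fold, "fold_of_rounded_medians": fold_rounded,
        })
    return pd.DataFrame(rows)
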