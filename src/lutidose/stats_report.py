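"""Paired with/without-premedication statistics and summary reports.

The paired comparison is Wilcoxon's signed-rank test with the classic
conventions: zero differences dropped, midranks for tied absolute
differences, and an exact two-sided p-value ``2 * min(tail)`` capped at 1.
The exact null distribution of W+ (conditional on the observed |differences|
when ties exist) is computed by convolution over the 2^n equiprobable sign
assignments — equivalent to full enumeration but feasible to n = 25; larger n
falls back to the normal approximation with continuity correction, flagged in
the result.

Endpoint summaries use the same median/IQR conventions as the stability
module; reported folds are ratios of medians rounded at the printed
precision (rounding happens only at the report layer — raw values are kept
everywhere else).  No multiple-testing correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .phantom_sim import load_clinical_tables, load_printed_summaries
from .stability import iqr_hinges, median_midpoint, round_half_up, stability_summary

__all__ = [
    "TestResult",
    "wilcoxon_signed_rank_exact",
    "summarize_endpoint",
    "assemble_paired_tables",
    "build_report",
    "ratio_consistency",
]

def _decimals_of(printed: float) -> int:
    """Number of decimals a printed value carries (0.2 -> 1, 0.28 -> 2)."""
    text = repr(float(printed))
    return len(text.split(".")[1].rstrip("0")) if "." in text else 0


def _matches_printed(computed: float, printed: float) -> bool:
    """Half-up rounding of the computed value at the printed precision."""
    return round_half_up(computed, _decimals_of(printed)) == printed


DOSE_ENDPOINTS = ("tumor_dose", "kidney_dose", "stomach_dose", "marrow_dose")
RATIO_ENDPOINTS = ("ratio_kidney", "ratio_stomach", "ratio_marrow")
_MAX_EXACT_N = 25


@dataclass
class TestResult:
    """Wilcoxon signed-rank result on paired with/without values."""

    n_effective: int  # pairs remaining after zero-difference removal
    W_plus: float
    W_minus: float
    p_two_sided: float
    method: str  # "exact" | "normal_approx" | "degenerate"

    def __post_init__(self) -> None:
        if not (0.0 < self.p_two_sided <= 1.0):
            raise ValueError("p-value must be in (0, 1]")


def _exact_wplus_distribution(ranks: np.ndarray) -> tuple[np.ndarray, int]:
    """Probability mass of W+ over all 2^n sign assignments.

    Ranks are midranks; doubling makes them integers, so the distribution is
    built by dynamic-programming convolution on the doubled-rank sum scale.
    Returns (pmf, scale) where W+ = support_index / scale with scale = 2.
    """
    doubled = np.rint(2.0 * ranks).astype(int)
    total = int(doubled.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: total + 1 - r]
        pmf = 0.5 * (pmf + shifted)
    return pmf, 2


def wilcoxon_signed_rank_exact(values_without, values_with) -> TestResult:
    """Exact matched-pairs Wilcoxon signed-rank test (two-sided).

    Differences are ``with - without``; zero differences are dropped, absolute
    differences are midranked, and the two-sided p is twice the smaller exact
    tail probability, capped at 1.
    """
    wo = np.asarray(values_without, dtype=float)
    w = np.asarray(values_with, dtype=float)
    if wo.shape != w.shape or wo.size == 0:
        raise ValueError("paired arrays must align and be non-empty")
    d = w - wo
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult(n_effective=0, W_plus=0.0, W_minus=0.0,
                          p_two_sided=1.0, method="degenerate")
    ranks = rankdata(np.abs(d))  # midranks for ties
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())

    if n <= _MAX_EXACT_N:
        pmf, scale = _exact_wplus_distribution(ranks)
        k = int(round(w_plus * scale))
        p_low = float(pmf[: k + 1].sum())
        p_high = float(pmf[k:].sum())
        p = min(1.0, 2.0 * min(p_low, p_high))
        return TestResult(n_effective=n, W_plus=w_plus, W_minus=w_minus,
                          p_two_sided=p, method="exact")

    # normal approximation with continuity correction and tie correction
    mean = n * (n + 1) / 4.0
    tie_term = float(np.sum([(c**3 - c) for c in
                             np.unique(ranks, return_counts=True)[1]]))
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term / 48.0
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / math.sqrt(var)
    p = min(1.0, 2.0 * float(norm.sf(abs(z))))
    return TestResult(n_effective=n, W_plus=w_plus, W_minus=w_minus,
                      p_two_sided=max(p, np.finfo(float).tiny),
                      method="normal_approx")


def summarize_endpoint(pairs: pd.DataFrame, decimals: int = 2) -> dict:
    """Medians/IQRs per arm, folds, and the exact test for one endpoint.

    ``pairs`` needs columns ``value_without`` and ``value_with`` (one row per
    unit).  ``decimals`` is the printed precision used for the report-layer
    fold of rounded medians.
    """
    if pairs.empty:
        raise ValueError("empty endpoint")
    wo = pairs["value_without"].to_numpy(dtype=float)
    w = pairs["value_with"].to_numpy(dtype=float)
    med_wo, med_w = median_midpoint(wo), median_midpoint(w)
    res = {
        "n_pairs": len(pairs),
        "median_without": med_wo,
        "median_with": med_w,
        "iqr_without": iqr_hinges(wo),
        "iqr_with": iqr_hinges(w),
        "fold": med_w / med_wo if med_wo > 0 else math.inf,
        "fold_of_rounded_medians": (
            round_half_up(med_w, decimals) / round_half_up(med_wo, decimals)
            if round_half_up(med_wo, decimals) > 0 else math.inf
        ),
        "test": wilcoxon_signed_rank_exact(wo, w),
    }
    return res


def assemble_paired_tables(doses: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-endpoint paired tables from the packaged dose table.

    Tumor doses and ratios are paired per lesion (6 evaluable lesions);
    organ doses are paired per patient (8 patients — the second-lesion rows
    repeat each patient's organ doses and are dropped for organ endpoints).
    """
    out: dict[str, pd.DataFrame] = {}
    wide = doses.pivot_table(index=["patient", "lesion"], columns="arm",
                             sort=True, observed=True)
    for ep in ("tumor_dose",) + RATIO_ENDPOINTS:
        sub = wide[ep].dropna()
        out[ep] = pd.DataFrame({
            "unit_id": [f"p{p}l{l}" for p, l in sub.index],
            "value_without": sub["without"].to_numpy(),
            "value_with": sub["with"].to_numpy(),
        })
    per_patient = doses[doses["lesion"] == 1]
    pw = per_patient.pivot_table(index="patient", columns="arm", observed=True)
    for ep in ("kidney_dose", "stomach_dose", "marrow_dose"):
        sub = pw[ep].dropna()
        out[ep] = pd.DataFrame({
            "unit_id": [f"p{p}" for p in sub.index],
            "value_without": sub["without"].to_numpy(),
            "value_with": sub["with"].to_numpy(),
        })
    return out


def ratio_consistency(doses: pd.DataFrame) -> pd.DataFrame:
    """Check each printed tumor-to-organ ratio against the printed doses.

    Doses are printed at two decimals and ratios at one, so the recomputed
    ratio is only determined up to the rounding intervals: a printed ratio is
    consistent when its own half-ulp interval overlaps the interval of ratios
    attainable from the printed-dose rounding intervals.
    """
    organ_of = {"ratio_kidney": "kidney_dose", "ratio_stomach": "stomach_dose",
                "ratio_marrow": "marrow_dose"}
    rows = []
    for _, row in doses.dropna(subset=["tumor_dose"]).iterrows():
        for ep, organ in organ_of.items():
            printed = row[ep]
            if pd.isna(printed):
                continue
            t, o = row["tumor_dose"], row[organ]
            lo = (t - 0.005) / (o + 0.005)
            hi = (t + 0.005) / max(o - 0.005, 1e-9)
            ok = (printed + 0.05 >= lo) and (printed - 0.05 <= hi)
            rows.append({
                "patient": row["patient"], "lesion": row["lesion"],
                "arm": row["arm"], "endpoint": ep,
                "ratio_printed": printed, "ratio_recomputed": t / o,
                "consistent": bool(ok),
            })
    return pd.DataFrame(rows)


def build_report(source: str = "fixtures",
                 tables: tuple[pd.DataFrame, pd.DataFrame] | None = None) -> dict:
    """Assemble the full computed-vs-printed summary report.

    ``source='fixtures'`` loads the packaged clinical tables (or accepts them
    via ``tables``) and reproduces the dose/ratio and stability summary rows,
    attaching the printed values and match flags.  Returns a dict with
    DataFrames ``dose_summary``, ``stability_summary``, ``ratio_consistency``.
    """
    if source != "fixtures":
        raise ValueError("only the fixtures source is built in; for phantom runs "
                         "use the pipeline functions directly")
    stab, doses = tables if tables is not None else load_clinical_tables()
    if stab.empty or doses.empty:
        raise ValueError("empty input tables")
    printed = load_printed_summaries()

    paired = assemble_paired_tables(doses)
    rows = []
    for ep in DOSE_ENDPOINTS + RATIO_ENDPOINTS:
        decimals = 1 if ep.startswith("ratio") else 2
        s = summarize_endpoint(paired[ep], decimals=decimals)
        ref = printed["dose_endpoints"][ep]
        row = {
            "endpoint": ep, "n_pairs": s["n_pairs"],
            "median_without": s["median_without"], "median_with": s["median_with"],
            "iqr_without": s["iqr_without"], "iqr_with": s["iqr_with"],
            "fold": s["fold"],
            "fold_reported": round_half_up(s["fold_of_rounded_medians"], 1),
            "p_exact": s["test"].p_two_sided,
            "printed_median_without": ref["median_without"],
            "printed_median_with": ref["median_with"],
            "printed_p": ref["p"],
        }
        row["median_match"] = (
            _matches_printed(s["median_without"], ref["median_without"])
            and _matches_printed(s["median_with"], ref["median_with"])
        )
        row["p_match"] = round_half_up(s["test"].p_two_sided, 2) == ref["p"]
        rows.append(row)
    dose_summary = pd.DataFrame(rows)

    ss = stability_summary(stab)
    ss["printed_median_without"] = [
        printed["stability"][str(int(t))]["median_without"] for t in ss["time_min"]
    ]
    ss["printed_median_with"] = [
        printed["stability"][str(int(t))]["median_with"] for t in ss["time_min"]
    ]
    ss["printed_fold"] = [
        printed["stability"][str(int(t))]["fold"] for t in ss["time_min"]
    ]
    ss["median_match"] = [
        _matches_printed(m, p) for m, p in
        zip(ss["median_without"], ss["printed_median_without"])
    ]
    ss["fold_match"] = [
        round_half_up(f, 1) == p for f, p in zip(ss["fold"], ss["printed_fold"])
    ]
    return {
        "dose_summary": dose_summary,
        "stability_summary": ss,
        "ratio_consistency": ratio_consistency(doses),
    }
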