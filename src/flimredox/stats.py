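"""Group comparison statistics and chemical redox-ratio arithmetic.

The two-group comparison follows the test-selection convention of
GraphPad-style analyses: Shapiro–Wilk normality on each group, then
either the nonparametric Mann–Whitney U test (if normality is rejected
in either group), or — for normal data — Levene's median-centred test
for homogeneity of variances deciding between the ordinary unpaired
t-test and Welch's modified t-test.  All tests are two-sided.
Significance labels use the GraphPad convention: ns p>0.05, * p<=0.05,
** p<=0.01, *** p<=0.001, **** p<=0.0001.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    EmptyGroupError,
    InsufficientSampleError,
    ParameterError,
    UndefinedRatioError,
)

__all__ = [
    "GroupSummary",
    "ComparisonResult",
    "p_to_stars",
    "choose_and_run_test",
    "mann_whitney",
    "summarize_group",
    "compute_redox_ratios",
]

QUANTITIES = ("tau_mean", "a1_over_a2", "tau_bound")


@dataclass(frozen=True)
class GroupSummary:
    """Mean ± sample SD of one per-cell quantity over one group."""

    label: str
    n: int
    mean: float
    sd: float
    sd_defined: bool = True  # False when n == 1 (SD reported as 0 with flag)


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of the two-group test-selection decision tree."""

    test_name: str  # mann_whitney | t_unpaired | t_welch
    statistic: float
    p_value: float
    stars: str
    n_a: int
    n_b: int
    normality_p: tuple[float, float] | None = None
    levene_p: float | None = None


def p_to_stars(p: float) -> str:
    """GraphPad significance labels: ns, *, **, ***, ****."""
    if not 0.0 <= p <= 1.0:
        raise ParameterError(f"p-value out of [0, 1]: {p}")
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 1e-2:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U statistic and p-value.

    Exact enumeration for tie-free samples with both n <= 20; normal
    approximation with tie correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    if max(len(a), len(b)) <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def choose_and_run_test(
    group_a: Sequence[float], group_b: Sequence[float], alpha: float = 0.05
) -> ComparisonResult:
    """Compare two samples with the normality/homogeneity decision tree.

    Shapiro–Wilk on each group at ``alpha``: if either rejects (or a
    group is constant, where normality testing is undefined), a
    two-sided Mann–Whitney U test is used.  Otherwise Levene's
    median-centred test at ``alpha`` chooses between the unpaired
    t-test (variances homogeneous) and Welch's t-test.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise InsufficientSampleError(
            f"both groups need n >= 3 (got {len(a)} and {len(b)})"
        )

    constant = np.ptp(a) == 0 or np.ptp(b) == 0
    if constant:
        warnings.warn(
            "constant-valued group: normality test skipped, Mann-Whitney used",
            stacklevel=2,
        )
        normality_p = None
        normal = False
    else:
        pa = float(sps.shapiro(a).pvalue)
        pb = float(sps.shapiro(b).pvalue)
        normality_p = (pa, pb)
        normal = pa > alpha and pb > alpha

    if not normal:
        stat, p = mann_whitney(a, b)
        return ComparisonResult(
            "mann_whitney", stat, p, p_to_stars(p), len(a), len(b), normality_p, None
        )

    lev_p = float(sps.levene(a, b, center="median").pvalue)
    equal_var = lev_p > alpha
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    name = "t_unpaired" if equal_var else "t_welch"
    p = float(res.pvalue)
    return ComparisonResult(
        name, float(res.statistic), p, p_to_stars(p), len(a), len(b), normality_p, lev_p
    )


def _extract(records: Iterable, quantity: str) -> np.ndarray:
    if quantity not in QUANTITIES:
        raise ParameterError(f"quantity must be one of {QUANTITIES}, got {quantity!r}")
    values = []
    for rec in records:
        fit = getattr(rec, "fit", rec)  # accept CellRecord or bare FitResult
        if fit is None or not fit.converged:
            continue
        values.append(getattr(fit, quantity))
    return np.asarray(values, dtype=float)


def summarize_group(records: Iterable, quantity: str, label: str = "") -> GroupSummary:
    """Mean and sample SD (n-1) of a fitted quantity over converged records.

    ``quantity`` is one of tau_mean, a1_over_a2, tau_bound; a1/a2 is
    computed per cell and then averaged (per-cell philosophy, matching
    per-cell violin summaries), not as a ratio of group means.
    """
    v = _extract(records, quantity)
    if len(v) == 0:
        raise EmptyGroupError("no converged records to summarise")
    if len(v) == 1:
        return GroupSummary(label, 1, float(v[0]), 0.0, sd_defined=False)
    return GroupSummary(label, len(v), float(v.mean()), float(v.std(ddof=1)))


def compute_redox_ratios(
    table: pd.DataFrame, pooled: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-replicate cofactor ratios and their per-sample mean ± SD.

    ``table`` needs columns sample, replicate, nadh, nad, nadph, nadp
    (concentrations in any common unit).  Computes NADH/NAD+ and
    NADPH/NADP+ per replicate, and the combined NAD(P)H/NAD(P)+ ratio —
    by default the pooled-sum convention (NADH+NADPH)/(NAD+ + NADP+);
    ``pooled=False`` averages the two pair ratios instead.

    Returns
    -------
    (per_replicate, summary) : DataFrames; summary has mean and sd per
    sample for each of the three ratios.
    """
    required = {"sample", "replicate", "nadh", "nad", "nadph", "nadp"}
    missing = required - set(table.columns)
    if missing:
        raise ParameterError(f"concentration table missing columns: {sorted(missing)}")
    conc = table[["nadh", "nad", "nadph", "nadp"]].to_numpy(dtype=float)
    if np.any(conc < 0):
        raise ParameterError("concentrations must be >= 0")
    if np.any(table["nad"] == 0) or np.any(table["nadp"] == 0):
        raise UndefinedRatioError("zero NAD+ or NADP+ concentration in a replicate")
    out = table[["sample", "replicate"]].copy()
    out["nadh_nad"] = table["nadh"] / table["nad"]
    out["nadph_nadp"] = table["nadph"] / table["nadp"]
    if pooled:
        denom = table["nad"] + table["nadp"]
        if np.any(denom == 0):
            raise UndefinedRatioError("zero pooled NAD(P)+ concentration")
        out["nadph_pool"] = (table["nadh"] + table["nadph"]) / denom
    else:
        out["nadph_pool"] = 0.5 * (out["nadh_nad"] + out["nadph_nadp"])
    summary = (
        out.groupby("sample")[["nadh_nad", "nadph_nadp", "nadph_pool"]]
        .agg(["mean", "std", "count"])
        .rename(columns={"std": "sd", "count": "n"})
    )
    return out, summary
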