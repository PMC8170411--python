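"""Non-parametric statistics helpers.

All group comparisons in the pipeline are non-parametric (Mann-Whitney U,
two-sample Kolmogorov-Smirnov, Wilcoxon signed-rank) with Benjamini-Hochberg
false-discovery-rate adjustment applied within an explicit comparison family.

Tie handling follows scipy.stats conventions: ``mannwhitneyu`` uses the
normal approximation with tie correction when ties are present (exact
enumeration otherwise for small samples), ``wilcoxon`` drops zero
differences (Wilcoxon's original treatment) and raises when all differences
are zero.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats as sps

from .core import StatResult

__all__ = ["bh_adjust", "mann_whitney", "ks_two_sample", "wilcoxon_signed",
           "adjust_family", "significance_glyph"]


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    For sorted raw p-values ``p_(1) <= ... <= p_(m)`` the adjusted value is
    ``min_{j >= i} (m / j) * p_(j)``, clipped at 1; output order matches the
    input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out


def _check_group(x, name: str, min_n: int = 2) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.size < min_n:
        raise ValueError(f"{name} needs at least {min_n} observations")
    return arr


def mann_whitney(group_a, group_b, comparison: str = "") -> StatResult:
    """Two-sided Mann-Whitney U test for two independent samples.

    The reported statistic is U for ``group_a`` over ``group_b``.
    """
    a = _check_group(group_a, "group_a")
    b = _check_group(group_b, "group_b")
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return StatResult("mann_whitney_u", float(res.statistic), float(res.pvalue),
                      comparison, a.size, b.size)


def ks_two_sample(group_a, group_b, comparison: str = "") -> StatResult:
    """Two-sided two-sample Kolmogorov-Smirnov test."""
    a = _check_group(group_a, "group_a")
    b = _check_group(group_b, "group_b")
    res = sps.ks_2samp(a, b, alternative="two-sided")
    return StatResult("ks_2samp", float(res.statistic), float(res.pvalue),
                      comparison, a.size, b.size)


def wilcoxon_signed(x, y=None, comparison: str = "") -> StatResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped (``zero_method='wilcox'``); if every
    difference is zero there is no evidence against the null and p = 1 is
    returned with statistic 0.
    """
    a = _check_group(x, "x")
    if y is not None:
        b = _check_group(y, "y")
        if a.size != b.size:
            raise ValueError("paired samples must have equal length")
        diffs = a - b
    else:
        diffs = a
    if np.all(diffs == 0):
        return StatResult("wilcoxon", 0.0, 1.0, comparison, a.size,
                          a.size if y is not None else 0)
    res = sps.wilcoxon(diffs, zero_method="wilcox", alternative="two-sided")
    return StatResult("wilcoxon", float(res.statistic), float(res.pvalue),
                      comparison, a.size, a.size if y is not None else 0)


def adjust_family(results: Sequence[StatResult]) -> list[StatResult]:
    """BH-adjust a family of comparisons in place and return it.

    The family is explicit: whatever list is passed is treated as one
    multiple-comparison family, mirroring per-figure adjustment.
    """
    results = list(results)
    if not results:
        return results
    adj = bh_adjust([r.p_raw for r in results])
    for r, q in zip(results, adj):
        r.p_adjusted = float(q)
    return results


def significance_glyph(p: float | None) -> str:
    """Conventional significance glyph on an adjusted p-value."""
    if p is None or np.isnan(p):
        return "NA"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
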