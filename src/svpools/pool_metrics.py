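"""Recycled-pool fractions, group summaries, subsets, and correlation analyses.

The central quantity is the *recycled pool fraction* of a synapse section:
the number of photoconverted (PC+, recycled) vesicles divided by the total
vesicle count.  Group-level descriptives are reported as mean +/- SEM with
the sample SD (n-1 denominator); "potentiated" synapses are those whose
fraction strictly exceeds the control mean + 2 SD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .model import SynapseSection


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    sd: float
    sem: float

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "GroupSummary":
        return group_summary(values)


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    dof: Optional[Tuple[float, ...]] = None


@dataclass(frozen=True)
class QuartileBins:
    """Per-bin (n, mean, sem) for 4 ordered 25% bins of fractions."""

    bins: Tuple[GroupSummary, ...]

    def __post_init__(self) -> None:
        if len(self.bins) != 4:
            raise ValueError("expected exactly 4 bins")


# ---------------------------------------------------------------------------
# per-synapse and group descriptives


def recycled_fraction(section: SynapseSection) -> float:
    """Proportion of recycled (PC+) vesicles among all vesicles of a section."""
    if section.n_vesicles == 0:
        raise ValueError(f"section {section.id!r} has no vesicles")
    return section.n_recycled / section.n_vesicles


def group_summary(values: Sequence[float]) -> GroupSummary:
    """Mean, sample SD (n-1 denominator) and SEM = SD/sqrt(n) of a sample."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("group summary requires at least 2 values")
    sd = float(arr.std(ddof=1))
    return GroupSummary(
        n=int(arr.size),
        mean=float(arr.mean()),
        sd=sd,
        sem=sd / math.sqrt(arr.size),
    )


def potentiated_threshold(control: GroupSummary) -> float:
    """Fraction threshold for the potentiated subset: control mean + 2 SD."""
    return control.mean + 2.0 * control.sd


def classify_potentiated(
    fractions: Sequence[float], threshold: float
) -> Tuple[np.ndarray, float]:
    """Boolean mask of fractions strictly above ``threshold`` + its proportion."""
    arr = np.asarray(fractions, dtype=float)
    mask = arr > threshold
    return mask, float(mask.mean()) if arr.size else 0.0


# ---------------------------------------------------------------------------
# ordered subsets


def quartile_bin_means(fractions: Sequence[float]) -> QuartileBins:
    """Split fractions into 4 ordered contiguous 25% bins (ascending).

    When n is not divisible by 4 the remainder is distributed to the upper
    bins, so bin sizes differ by at most one and the top bin is never the
    smallest (n = 7 -> sizes (1, 2, 2, 2)).
    """
    arr = np.sort(np.asarray(fractions, dtype=float))
    n = arr.size
    if n < 4:
        raise ValueError("quartile bins require at least 4 values")
    base, rem = divmod(n, 4)
    sizes = [base] * (4 - rem) + [base + 1] * rem
    bins = []
    start = 0
    for size in sizes:
        chunk = arr[start : start + size]
        start += size
        sd = float(chunk.std(ddof=1)) if size > 1 else 0.0
        bins.append(
            GroupSummary(
                n=size,
                mean=float(chunk.mean()),
                sd=sd,
                sem=sd / math.sqrt(size) if size > 1 else 0.0,
            )
        )
    return QuartileBins(bins=tuple(bins))


def top_fraction_subset(fractions: Sequence[float], q: float = 0.25) -> GroupSummary:
    """Summary of the highest ``ceil(q * n)`` fractions."""
    arr = np.sort(np.asarray(fractions, dtype=float))
    if arr.size < 4:
        raise ValueError("top-fraction subset requires at least 4 values")
    k = math.ceil(q * arr.size)
    return group_summary(arr[-k:])


def high_fraction_matched_subset(
    control_fractions: Sequence[float], target_mean: float
) -> Tuple[np.ndarray, GroupSummary]:
    """Largest-fraction control subset whose mean best matches ``target_mean``.

    Sorts the control fractions descending and picks the prefix of length
    k >= 2 minimizing ``|mean(prefix) - target_mean|``; ties break toward
    larger k.  Returns indices into the original array plus the subset
    summary.
    """
    arr = np.asarray(control_fractions, dtype=float)
    if arr.size < 2:
        raise ValueError("matched subset requires at least 2 control values")
    order = np.argsort(-arr, kind="stable")
    prefix_means = np.cumsum(arr[order]) / np.arange(1, arr.size + 1)
    best_k = 2
    best_diff = abs(prefix_means[1] - target_mean)
    for k in range(3, arr.size + 1):
        diff = abs(prefix_means[k - 1] - target_mean)
        if diff <= best_diff:
            best_diff = diff
            best_k = k
    idx = order[:best_k]
    return idx, group_summary(arr[idx])


# ---------------------------------------------------------------------------
# correlations and group tests


def spearman_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation (average ranks for ties, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("Spearman correlation requires n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(rho=float(rho), p_value=float(p), n=int(x.size))


def corrected_fraction_correlation(
    control_sections: Sequence[SynapseSection],
    test_sections: Sequence[SynapseSection],
) -> CorrelationResult:
    """Size-fraction correlation after removing the control-group trend.

    Fits an ordinary least-squares line of recycled fraction on total vesicle
    count in the control group, computes test-group residuals from that line,
    and returns the Spearman correlation of residuals against total vesicle
    count.  A persistent negative correlation means small synapses carry
    disproportionately large recycled fractions beyond what the control trend
    predicts.
    """
    c_counts = np.array([s.n_vesicles for s in control_sections], dtype=float)
    c_fracs = np.array([recycled_fraction(s) for s in control_sections])
    if c_counts.size < 3:
        raise ValueError("control group must have n >= 3")
    if np.ptp(c_counts) == 0:
        raise ValueError("degenerate control fit: all vesicle counts equal")
    slope, intercept = np.polyfit(c_counts, c_fracs, 1)
    t_counts = np.array([s.n_vesicles for s in test_sections], dtype=float)
    t_fracs = np.array([recycled_fraction(s) for s in test_sections])
    residuals = t_fracs - (slope * t_counts + intercept)
    return spearman_correlation(t_counts, residuals)


def compare_groups(a: Sequence[float], b: Sequence[float]) -> dict:
    """Two-tailed unpaired t test on means and F test on variances.

    The F statistic places the larger sample variance in the numerator; its
    two-sided p-value is ``min(1, 2 * sf(F))``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("both groups have zero variance")
    t_stat, t_p = stats.ttest_ind(a, b)
    if va >= vb:
        f_stat, dfn, dfd = va / vb if vb > 0 else math.inf, a.size - 1, b.size - 1
    else:
        f_stat, dfn, dfd = vb / va, b.size - 1, a.size - 1
    f_p = min(1.0, 2.0 * stats.f.sf(f_stat, dfn, dfd)) if math.isfinite(f_stat) else 0.0
    return {
        "t_test": TestResult("t_test", float(t_stat), float(t_p), (float(a.size + b.size - 2),)),
        "f_test": TestResult("f_test", float(f_stat), float(f_p), (float(dfn), float(dfd))),
    }
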