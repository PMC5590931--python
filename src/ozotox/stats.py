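"""Group summaries and two-sample comparisons.

The comparisons mirror common genotoxicity-reporting practice: Student's
pooled-variance t-test for viability and micronucleus data, Mann-Whitney
for the skewed per-cell comet measurements, with significance stars at
p < 0.05 / 0.005 / 0.0005 (strict inequalities).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "ComparisonResult",
    "summarize_group",
    "compare_groups",
    "percent_change",
    "significance_stars",
    "STAR_THRESHOLDS",
]

#: Star thresholds, strictly decreasing; a p-value exactly at a threshold
#: earns no star (strict "<").
STAR_THRESHOLDS = (0.05, 0.005, 0.0005)

#: Largest combined sample size for which the Mann-Whitney p-value is
#: computed by exact permutation enumeration.
EXACT_MW_LIMIT = 10


@dataclass(frozen=True)
class GroupSummary:
    """Mean, standard error and size of one measurement group."""

    mean: float
    se: float | None  # None for n = 1, where the SE is undefined
    n: int


@dataclass(frozen=True)
class ComparisonResult:
    test_name: Literal["t_test", "mann_whitney"]
    statistic: float
    p_value: float
    stars: str
    group_sizes: tuple[int, int]

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        if self.stars != significance_stars(self.p_value):
            raise ValueError("stars inconsistent with thresholds")


def significance_stars(p: float, thresholds: Sequence[float] = STAR_THRESHOLDS) -> str:
    """Map a p-value to its star annotation with strict thresholds."""
    stars = ""
    for i, thr in enumerate(thresholds, start=1):
        if p < thr:
            stars = "*" * i
    return stars


def summarize_group(values: Sequence[float]) -> GroupSummary:
    """Mean and standard error (sd / sqrt(n)) of a measurement vector.

    For a single observation the SE is undefined and reported as None.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) == 0:
        raise ValueError("values must be a non-empty 1-d vector")
    n = len(v)
    mean = float(np.mean(v))
    se = None if n == 1 else float(np.std(v, ddof=1) / math.sqrt(n))
    return GroupSummary(mean=mean, se=se, n=n)


def _exact_mann_whitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided exact Mann-Whitney by full permutation enumeration.

    Enumerates every assignment of the pooled observations' ranks to the
    first group and compares the observed U statistic against the exact
    permutation distribution (tie-safe: midranks are enumerated as-is).
    Two-sided p doubles the smaller tail, capped at 1.
    """
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # midranks under ties
    r1_obs = ranks[:n1].sum()
    u_obs = r1_obs - n1 * (n1 + 1) / 2.0

    idx = range(n1 + n2)
    total = 0
    le = 0  # assignments with U <= observed
    ge = 0  # assignments with U >= observed
    eps = 1e-9
    for comb in combinations(idx, n1):
        u = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2.0
        total += 1
        if u <= u_obs + eps:
            le += 1
        if u >= u_obs - eps:
            ge += 1
    p = min(1.0, 2.0 * min(le, ge) / total)
    return float(u_obs), p


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    test: Literal["t_test", "mann_whitney"] = "t_test",
) -> ComparisonResult:
    """Two-sided comparison of two measurement groups.

    ``t_test`` is Student's pooled-variance t-test (n >= 2 per group and
    non-zero pooled variance required).  ``mann_whitney`` uses the exact
    permutation distribution of the rank sum when the combined size is at
    most 10 and the tie- and continuity-corrected normal approximation
    above that.
    """
    av = np.asarray(a, dtype=float)
    bv = np.asarray(b, dtype=float)
    sizes = (len(av), len(bv))
    if test == "t_test":
        if min(sizes) < 2:
            raise ValueError("t-test requires at least 2 observations per group")
        if np.ptp(av) == 0 and np.ptp(bv) == 0:
            raise ValueError(
                "t-test undefined: both groups have zero variance "
                "(no within-group variability to estimate error from)"
            )
        stat, p = sps.ttest_ind(av, bv, equal_var=True)
        stat, p = float(stat), float(p)
    elif test == "mann_whitney":
        if min(sizes) < 1:
            raise ValueError("Mann-Whitney requires non-empty groups")
        if sum(sizes) <= EXACT_MW_LIMIT:
            stat, p = _exact_mann_whitney(av, bv)
        else:
            res = sps.mannwhitneyu(
                av, bv, alternative="two-sided", use_continuity=True,
                method="asymptotic",
            )
            stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    return ComparisonResult(
        test_name=test,
        statistic=stat,
        p_value=p,
        stars=significance_stars(p),
        group_sizes=sizes,
    )


def percent_change(treated: GroupSummary | float, control: GroupSummary | float) -> float:
    """Signed percent change of treated relative to control,
    (treated - control) / control x 100."""
    t = treated.mean if isinstance(treated, GroupSummary) else float(treated)
    c = control.mean if isinstance(control, GroupSummary) else float(control)
    if c == 0:
        raise ValueError("percent change undefined for zero control mean")
    return (t - c) / c * 100.0
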