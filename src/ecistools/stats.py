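"""Replicate-level group comparison: one-way ANOVA and Tukey-Kramer
pairwise multiple comparisons (studentized range with the unequal-n
correction).  Significance threshold defaults to 0.01.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps

from .errors import DataError, DomainError

__all__ = [
    "GroupSample",
    "PairwiseComparison",
    "ComparisonReport",
    "one_way_anova",
    "tukey_kramer",
]


@dataclass
class GroupSample:
    """Replicate-level scalars for one group (one value per well)."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise DataError("group values must be one-dimensional")
        if self.values.size < 2:
            raise DataError(
                f"group {self.label!r} needs n >= 2 for variance estimation")
        if not np.all(np.isfinite(self.values)):
            raise DataError(f"group {self.label!r} contains non-finite values")

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    mean_diff: float
    p_adjusted: float
    ci_low: float
    ci_high: float
    significant: bool


@dataclass
class ComparisonReport:
    f_statistic: float
    p_overall: float
    df_between: int
    df_within: int
    alpha: float
    pairs: list[PairwiseComparison] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "f_statistic": self.f_statistic,
            "p_overall": round(self.p_overall, 4),
            "df": [self.df_between, self.df_within],
            "alpha": self.alpha,
            "pairs": [
                {
                    "groups": [p.group_a, p.group_b],
                    "mean_diff": p.mean_diff,
                    "p_adjusted": round(p.p_adjusted, 4),
                    "ci": [p.ci_low, p.ci_high],
                    "significant": p.significant,
                }
                for p in self.pairs
            ],
        }


def _check_groups(groups) -> list[GroupSample]:
    gs = [g if isinstance(g, GroupSample) else GroupSample(*g) for g in groups]
    if len(gs) < 2:
        raise DomainError("need at least two groups")
    return gs


def one_way_anova(groups) -> tuple[float, float]:
    """Classical between/within mean-square F test.

    Returns ``(F, p)`` with ``(k-1, N-k)`` degrees of freedom.  Identical
    constant groups give ``F = 0, p = 1``.
    """
    gs = _check_groups(groups)
    k = len(gs)
    all_values = np.concatenate([g.values for g in gs])
    n_total = all_values.size
    grand = all_values.mean()
    ss_between = sum(g.n * (g.values.mean() - grand) ** 2 for g in gs)
    ss_within = sum(float(np.sum((g.values - g.values.mean()) ** 2)) for g in gs)
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0.0:
        if ss_between == 0.0:
            return 0.0, 1.0
        return math.inf, 0.0
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return float(f), p


def tukey_kramer(groups, alpha: float = 0.01) -> ComparisonReport:
    """Studentized-range pairwise comparisons with the Kramer unequal-n
    correction, plus the overall one-way ANOVA.

    For each pair (i, j): ``q = |mi - mj| / sqrt(MSW/2 (1/ni + 1/nj))``;
    the adjusted p is the studentized-range survival function with k groups
    and N-k error df, and the simultaneous ``1-alpha`` confidence interval
    is ``diff +- q_crit * SE``.
    """
    gs = _check_groups(groups)
    if not (0 < alpha < 1):
        raise DomainError("alpha must lie in (0, 1)")
    k = len(gs)
    n_total = sum(g.n for g in gs)
    df_w = n_total - k
    ss_within = sum(float(np.sum((g.values - g.values.mean()) ** 2)) for g in gs)
    msw = ss_within / df_w
    f, p = one_way_anova(gs)
    report = ComparisonReport(f, p, k - 1, df_w, alpha)
    q_crit = float(sps.studentized_range.ppf(1.0 - alpha, k, df_w))
    for ga, gb in combinations(gs, 2):
        diff = float(ga.values.mean() - gb.values.mean())
        se = math.sqrt(msw / 2.0 * (1.0 / ga.n + 1.0 / gb.n))
        if se == 0.0:
            p_adj = 1.0 if diff == 0.0 else 0.0
            ci = (diff, diff)
        else:
            q = abs(diff) / se
            p_adj = float(sps.studentized_range.sf(q, k, df_w))
            p_adj = min(max(p_adj, 0.0), 1.0)
            ci = (diff - q_crit * se, diff + q_crit * se)
        report.pairs.append(PairwiseComparison(
            ga.label, gb.label, diff, p_adj, ci[0], ci[1],
            significant=p_adj < alpha))
    return report
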