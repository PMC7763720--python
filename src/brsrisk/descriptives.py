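"""Group-comparison descriptive statistics for the high- vs low-risk groups.

Binary variables: counts/percentages compared with Fisher's exact test
(two-sided by summation of hypergeometric probabilities not exceeding that of
the observed table). Continuous variables: median (q1-q3) compared with the
Wilcoxon rank-sum (Mann-Whitney) test; Kruskal-Wallis is provided for >= 2
groups. Percentages are rounded half-up to integers; quartiles use linear
interpolation between order statistics (numpy's default, "type 7").
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
from scipy import stats

from ._base import DegenerateTableError, DomainError
from .association import TwoByTwo
from .cohort import Cohort

__all__ = [
    "GroupSummary",
    "fisher_exact_2x2",
    "rank_sum_test",
    "kruskal_wallis",
    "summarize_table1",
    "format_summaries",
]

logger = logging.getLogger(__name__)

#: Variables summarized as count (%) with Fisher's exact test. ``sex`` counts
#: males; ``pvs_positive`` is restricted to subjects with PVS performed.
BINARY_VARIABLES = (
    "sex",
    "icd",
    "syncope",
    "initial_type1",
    "af",
    "pvs_performed",
    "pvs_positive",
    "vtvf",
)

DEFAULT_TABLE1_VARIABLES = (
    "sex",
    "age_years",
    "icd",
    "syncope",
    "initial_type1",
    "af",
    "pvs_performed",
    "pvs_positive",
    "qrs_ms",
    "qtc_ms",
)


def round_half_up(x: float) -> int:
    """68.5 -> 69, unlike banker's rounding."""
    return int(math.floor(x + 0.5))


def fisher_exact_2x2(table: Union[TwoByTwo, Sequence[Sequence[int]]]) -> float:
    """Two-sided Fisher's exact p-value for a 2x2 table.

    The p-value sums the hypergeometric probabilities of all tables with the
    observed margins whose probability does not exceed the observed table's
    (the probability-mass rule, not doubling of the one-sided p).
    """
    if isinstance(table, TwoByTwo):
        arr = table.as_array()
    else:
        arr = np.asarray(table, dtype=int)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise DomainError("need a 2x2 table of nonnegative integers")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DegenerateTableError("2x2 table has an empty margin")
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def rank_sum_test(
    x: Sequence[float],
    y: Sequence[float],
    continuity: bool = True,
) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney U) test, two-sided.

    Exact null enumeration when the pooled sample has <= 12 values and no
    ties; otherwise the normal approximation with mid-rank tie correction and
    (by default) continuity correction. Returns ``(U statistic, p)`` where U
    counts pairs in which x exceeds y (ties as 1/2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DomainError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        # every observation tied: no evidence either way
        return float(x.size * y.size / 2.0), 1.0
    ties = np.unique(pooled).size < pooled.size
    if x.size + y.size <= 12 and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x,
        y,
        alternative="two-sided",
        method=method,
        use_continuity=continuity,
    )
    p = min(float(res.pvalue), 1.0)
    return float(res.statistic), p


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with a chi-square p on k-1 df.

    All observations identical across groups is treated as the 0/0 limit of
    the tie correction: H = 0, p = 1. For two groups the p agrees with the
    no-continuity-correction rank-sum test to within a few thousandths.
    """
    if len(groups) < 2:
        raise DomainError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise DomainError("all groups must be nonempty")
    pooled = np.concatenate(arrays)
    if np.unique(pooled).size == 1:
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


@dataclass(frozen=True)
class GroupSummary:
    """One variable's row of the group-comparison table."""

    variable: str
    kind: str  # "binary" | "continuous"
    # binary: (count, percent, group size); continuous: (median, q1, q3)
    group_pos: tuple
    group_neg: tuple
    p_value: float
    test: str  # "fisher_exact" | "rank_sum" | "kruskal_wallis"

    def formatted(self) -> tuple[str, str]:
        """Render like the printed table: '22 (69)' or '108 (98-114)'."""
        if self.kind == "binary":
            (c1, pct1, _), (c0, pct0, _) = self.group_pos, self.group_neg
            return f"{c1} ({pct1})", f"{c0} ({pct0})"
        (m1, q1a, q1b), (m0, q0a, q0b) = self.group_pos, self.group_neg
        fmt = lambda v: f"{v:g}"
        return (
            f"{fmt(m1)} ({fmt(q1a)}–{fmt(q1b)})",
            f"{fmt(m0)} ({fmt(q0a)}–{fmt(q0b)})",
        )


def _binary_positive(df, var):
    """0/1 indicator for the 'counted' level of a binary variable."""
    if var == "sex":
        return (df[var] == "male").astype(float)
    return df[var].astype(float)


def summarize_table1(
    cohort: Cohort,
    variables: Sequence[str] = DEFAULT_TABLE1_VARIABLES,
    quantile_method: str = "linear",
) -> list[GroupSummary]:
    """Compare the spontaneous VT/VF group against the rest, per variable.

    Binary variables get count (percent, rounded half-up) per group and a
    Fisher exact p; continuous variables get median (q1-q3) and a rank-sum p.
    Records missing a variable are excluded from that variable's row only,
    with a logged count.
    """
    df = cohort.to_frame()
    out: list[GroupSummary] = []
    for var in variables:
        if var not in df.columns:
            raise DomainError(f"unknown variable {var!r}")
        sub = df[[var, "vtvf"]].dropna()
        n_excluded = len(df) - len(sub)
        if n_excluded:
            logger.info(
                "summarize_table1: %s excludes %d records with missing values",
                var,
                n_excluded,
            )
        pos = sub[sub["vtvf"] == 1]
        neg = sub[sub["vtvf"] == 0]
        if var in BINARY_VARIABLES:
            x_pos = _binary_positive(pos, var)
            x_neg = _binary_positive(neg, var)
            a, b = int(x_pos.sum()), int(x_neg.sum())
            n1, n0 = len(pos), len(neg)
            table = TwoByTwo(a=a, b=b, c=n1 - a, d=n0 - b)
            try:
                p = fisher_exact_2x2(table)
            except DegenerateTableError:
                p = 1.0
            out.append(
                GroupSummary(
                    variable=var,
                    kind="binary",
                    group_pos=(a, round_half_up(100 * a / n1) if n1 else 0, n1),
                    group_neg=(b, round_half_up(100 * b / n0) if n0 else 0, n0),
                    p_value=p,
                    test="fisher_exact",
                )
            )
        else:
            xp = pos[var].astype(float).to_numpy()
            xn = neg[var].astype(float).to_numpy()
            _, p = rank_sum_test(xp, xn)
            q = lambda a: tuple(
                np.percentile(a, [50, 25, 75], method=quantile_method)
            )
            mp, q1p, q3p = q(xp)
            mn, q1n, q3n = q(xn)
            out.append(
                GroupSummary(
                    variable=var,
                    kind="continuous",
                    group_pos=(mp, q1p, q3p),
                    group_neg=(mn, q1n, q3n),
                    p_value=p,
                    test="rank_sum",
                )
            )
    return out


def format_summaries(summaries: Sequence[GroupSummary]) -> str:
    """TSV rendering mirroring the printed group-comparison table."""
    lines = ["variable\tvtvf_group\tno_vtvf_group\tp_value\ttest"]
    for s in summaries:
        pos, neg = s.formatted()
        lines.append(f"{s.variable}\t{pos}\t{neg}\t{s.p_value:.4g}\t{s.test}")
    return "\n".join(lines) + "\n"
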