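"""Group comparisons for ratio results: Welch ANOVA, Games-Howell, Welch t.

All three tests allow unequal group variances, using Welch-Satterthwaite
approximate degrees of freedom; Games-Howell converts the Welch pairwise
statistic to a studentized-range scale so that its p values are family-wise
adjusted for k groups.  The intended inputs are per-repeat
periplasmic/total ratios (typically n = 3 per condition, a deliberately
low-powered design mirrored from the experiments), but any per-cell or
per-repeat samples work.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "GroupSample",
    "welch_anova",
    "games_howell",
    "welch_ttest",
    "significance_stars",
]

log = logging.getLogger(__name__)


@dataclass
class GroupSample:
    """One condition's sample (per-repeat ratios or per-cell ipv values)."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) < 2:
            raise ValueError(f"group {self.label!r} needs n >= 2")

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def var(self) -> float:
        return float(self.values.var(ddof=1))


def significance_stars(p: float) -> str:
    """The study's convention: *** p<0.001, ** p<0.01, * p<0.05, else ns."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def welch_anova(groups: list[GroupSample]) -> tuple[float, float, float, float]:
    """Welch's heteroscedastic one-way ANOVA.

    Returns (F, df1, df2, p).  With every group variance zero and equal
    means the test is vacuous and p = 1 is returned by convention (logged);
    zero variances with unequal means give F = inf, p = 0.
    """
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    n = np.array([g.n for g in groups], dtype=float)
    m = np.array([g.mean for g in groups])
    v = np.array([g.var for g in groups])

    if np.all(v == 0):
        if np.all(m == m[0]):
            log.warning("all groups have zero variance and equal means; p = 1")
            return 0.0, float(k - 1), math.inf, 1.0
        return math.inf, float(k - 1), math.inf, 0.0

    w = n / np.where(v > 0, v, np.finfo(float).tiny)
    W = w.sum()
    mw = (w * m).sum() / W
    num = (w * (m - mw) ** 2).sum() / (k - 1)
    tmp = ((1.0 - w / W) ** 2 / (n - 1.0)).sum()
    den = 1.0 + 2.0 * (k - 2.0) / (k * k - 1.0) * tmp
    F = num / den
    df1 = float(k - 1)
    df2 = (k * k - 1.0) / (3.0 * tmp)
    p = float(sstats.f.sf(F, df1, df2))
    return float(F), df1, float(df2), p


def welch_ttest(
    a,
    b,
    two_sided: bool = True,
) -> tuple[float, float, float]:
    """Welch's unequal-variance t test.  Returns (t, df, p).

    Accepts GroupSamples or plain value arrays.  Two groups with zero
    variance and equal means return p = 1 by convention.
    """
    ga = a if isinstance(a, GroupSample) else GroupSample("a", a)
    gb = b if isinstance(b, GroupSample) else GroupSample("b", b)
    se2 = ga.var / ga.n + gb.var / gb.n
    if se2 == 0:
        if ga.mean == gb.mean:
            log.warning("zero variance in both groups with equal means; p = 1")
            return 0.0, math.inf, 1.0
        return math.copysign(math.inf, ga.mean - gb.mean), math.inf, 0.0
    t = (ga.mean - gb.mean) / math.sqrt(se2)
    df = _welch_satterthwaite(ga, gb)
    p = float(sstats.t.sf(abs(t), df))
    if two_sided:
        p *= 2.0
    return float(t), float(df), min(p, 1.0)


def games_howell(groups: list[GroupSample], alpha: float = 0.05) -> pd.DataFrame:
    """Games-Howell post-hoc pairwise comparisons.

    For each pair the Welch standard error and Welch-Satterthwaite df are
    combined with the studentized-range distribution at k = number of
    groups, giving family-wise adjusted p values; confidence intervals use
    the same critical value.  Returns a table with columns
    group_a, group_b, diff, se, df, q, p, ci_lo, ci_hi, stars.
    """
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    rows = []
    for ga, gb in itertools.combinations(groups, 2):
        diff = ga.mean - gb.mean
        se2 = ga.var / ga.n + gb.var / gb.n
        if se2 == 0:
            if diff == 0:
                log.warning("pair %s/%s has zero variance and equal means; p = 1",
                            ga.label, gb.label)
                rows.append((ga.label, gb.label, 0.0, 0.0, math.inf, 0.0, 1.0,
                             0.0, 0.0, "ns"))
            else:
                rows.append((ga.label, gb.label, diff, 0.0, math.inf, math.inf,
                             0.0, diff, diff, "***"))
            continue
        se = math.sqrt(se2)
        df = _welch_satterthwaite(ga, gb)
        q = abs(diff) / se * math.sqrt(2.0)
        p = float(sstats.studentized_range.sf(q, k, df))
        qcrit = float(sstats.studentized_range.ppf(1 - alpha, k, df))
        half = qcrit / math.sqrt(2.0) * se
        rows.append((ga.label, gb.label, diff, se, df, q, p,
                     diff - half, diff + half, significance_stars(p)))
    return pd.DataFrame(
        rows,
        columns=["group_a", "group_b", "diff", "se", "df", "q", "p",
                 "ci_lo", "ci_hi", "stars"],
    )


def _welch_satterthwaite(ga: GroupSample, gb: GroupSample) -> float:
    va, vb = ga.var / ga.n, gb.var / gb.n
    num = (va + vb) ** 2
    den = va * va / (ga.n - 1) + vb * vb / (gb.n - 1)
    if den == 0:
        return math.inf
    return num / den
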