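"""Group comparisons: unpaired t-tests and one-way ANOVA with Bonferroni.

Both tests accept either raw replicate values or (mean, SD, n) summaries —
published tables report only summaries, and for these tests the two paths
are algebraically identical.  Significance stars follow the usual figure
conventions: ns P > 0.05, * P <= 0.05, ** P <= 0.01, *** P <= 0.001,
**** P < 0.0001 (adjusted P where a Bonferroni family is declared).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class GroupSummary:
    label: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n < 2:
            raise ValueError("n must be at least 2")

    @classmethod
    def from_values(cls, label: str, values: Iterable[float]) -> "GroupSummary":
        arr = np.asarray(list(values), dtype=float)
        return cls(label=label, mean=float(arr.mean()), sd=float(arr.std(ddof=1)), n=arr.size)


@dataclass(frozen=True)
class ComparisonResult:
    pair: tuple[str, str]
    statistic: float
    df: float
    p_raw: float
    p_adjusted: float
    stars: str
    degenerate: bool = False

    def to_row(self) -> dict:
        return {
            "label_a": self.pair[0],
            "label_b": self.pair[1],
            "statistic": self.statistic,
            "df": self.df,
            "p_raw": self.p_raw,
            "p_adjusted": self.p_adjusted,
            "stars": self.stars,
        }


def stars(p_adjusted: float) -> str:
    """Significance label at the conventional thresholds."""
    if not 0 <= p_adjusted <= 1:
        raise ValueError("p must lie in [0, 1]")
    if p_adjusted > 0.05:
        return "ns"
    if p_adjusted > 0.01:
        return "*"
    if p_adjusted > 0.001:
        return "**"
    if p_adjusted >= 0.0001:
        return "***"
    return "****"


def _as_summary(group: GroupSummary | Sequence[float], label: str) -> GroupSummary:
    if isinstance(group, GroupSummary):
        return group
    return GroupSummary.from_values(label, group)


def ttest_unpaired(
    a: GroupSummary | Sequence[float],
    b: GroupSummary | Sequence[float],
    variant: str = "student",
) -> ComparisonResult:
    """Two-sided unpaired t-test from raw values or summaries.

    ``student`` pools the variances (df = nA + nB - 2); ``welch`` uses the
    Welch-Satterthwaite approximation.
    """
    if variant not in ("student", "welch"):
        raise ValueError("variant must be 'student' or 'welch'")
    sa = _as_summary(a, "a")
    sb = _as_summary(b, "b")
    if sa.sd == 0 and sb.sd == 0:
        if sa.mean == sb.mean:
            return ComparisonResult((sa.label, sb.label), 0.0, sa.n + sb.n - 2, 1.0, 1.0, "ns")
        return ComparisonResult(
            (sa.label, sb.label), np.inf, sa.n + sb.n - 2, 0.0, 0.0, "****", degenerate=True
        )
    res = sps.ttest_ind_from_stats(
        sa.mean, sa.sd, sa.n, sb.mean, sb.sd, sb.n, equal_var=(variant == "student")
    )
    if variant == "student":
        df = sa.n + sb.n - 2.0
    else:
        va, vb = sa.sd**2 / sa.n, sb.sd**2 / sb.n
        df = (va + vb) ** 2 / (va**2 / (sa.n - 1) + vb**2 / (sb.n - 1))
    p = float(res.pvalue)
    return ComparisonResult(
        pair=(sa.label, sb.label),
        statistic=float(res.statistic),
        df=float(df),
        p_raw=p,
        p_adjusted=p,
        stars=stars(p),
    )


def anova_oneway(groups: Sequence[GroupSummary]) -> tuple[float, float, float, float]:
    """One-way ANOVA from summaries: (F, df_between, df_within, p).

    Between/within sums of squares are computable from (mean, SD, n) alone.
    """
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two groups")
    ns = np.array([g.n for g in groups], dtype=float)
    means = np.array([g.mean for g in groups])
    sds = np.array([g.sd for g in groups])
    big_n = ns.sum()
    grand = (ns * means).sum() / big_n
    ssb = (ns * (means - grand) ** 2).sum()
    ssw = ((ns - 1) * sds**2).sum()
    df_b, df_w = k - 1, big_n - k
    if ssw == 0:
        f = np.inf if ssb > 0 else 0.0
        p = 0.0 if ssb > 0 else 1.0
        return f, df_b, df_w, p
    f = (ssb / df_b) / (ssw / df_w)
    return float(f), float(df_b), float(df_w), float(sps.f.sf(f, df_b, df_w))


def anova_bonferroni(
    groups: Sequence[GroupSummary | Sequence[float]],
    comparisons: Sequence[tuple[str, str]] | str = "all",
    labels: Sequence[str] | None = None,
) -> list[ComparisonResult]:
    """One-way ANOVA with Bonferroni-adjusted pairwise posttests.

    Each posttest uses the pooled within-group mean square with
    df = N - k; p_adjusted = min(1, m * p_raw) where m is the number of
    comparisons in the declared family (``"all"`` = every pair).
    """
    summaries = []
    for i, g in enumerate(groups):
        label = labels[i] if labels is not None else None
        if isinstance(g, GroupSummary):
            summaries.append(g if label is None else GroupSummary(label, g.mean, g.sd, g.n))
        else:
            summaries.append(GroupSummary.from_values(label or f"group{i}", g))
    by_label = {g.label: g for g in summaries}
    if len(by_label) != len(summaries):
        raise ValueError("group labels must be unique")

    if comparisons == "all":
        pairs = list(combinations(by_label, 2))
    else:
        pairs = [tuple(p) for p in comparisons]
        for a, b in pairs:
            if a not in by_label or b not in by_label:
                raise ValueError(f"comparison ({a!r}, {b!r}) names an unknown group")

    _, _, df_w, _ = anova_oneway(summaries)
    msw = sum((g.n - 1) * g.sd**2 for g in summaries) / df_w
    m = len(pairs)

    results = []
    for a, b in pairs:
        ga, gb = by_label[a], by_label[b]
        se = np.sqrt(msw * (1.0 / ga.n + 1.0 / gb.n))
        if se == 0:
            degenerate = ga.mean != gb.mean
            p = 0.0 if degenerate else 1.0
            t = np.inf if degenerate else 0.0
        else:
            t = (ga.mean - gb.mean) / se
            p = float(2.0 * sps.t.sf(abs(t), df_w))
            degenerate = False
        p_adj = min(1.0, m * p)
        results.append(
            ComparisonResult(
                pair=(a, b),
                statistic=float(t),
                df=float(df_w),
                p_raw=p,
                p_adjusted=p_adj,
                stars=stars(p_adj),
                degenerate=degenerate,
            )
        )
    return results


def comparisons_table(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in results])
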