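"""Group-comparison decision tree and significance annotation.

The comparison protocol for experimental groups (moduli per velocity,
transport quantities per pressure) is:

1. Shapiro–Wilk normality test per group, then Bartlett's test for variance
   homogeneity across groups;
2. two groups — independent Student's t-test, Welch-corrected when Bartlett
   rejects homogeneity;
3. more than two groups — one-way ANOVA with Tukey's HSD post hoc under
   homogeneity, otherwise Welch's ANOVA with the Games–Howell post hoc;
4. significance stars: * p < 0.05, ** p < 0.01, *** p < 0.001 (strict
   inequalities).

A normality violation does not reroute the analysis (no nonparametric
fallback is defined for this protocol); it is flagged on the result so the
caller can judge.  Welch's ANOVA and Games–Howell are implemented here in
their standard Welch–Satterthwaite / studentized-range formulation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupData",
    "GroupComparison",
    "star_annotation",
    "welch_anova",
    "games_howell",
    "decide_and_compare",
]

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass(frozen=True)
class GroupData:
    """One experimental group: a label and its measured values."""

    label: str
    values: np.ndarray
    unit: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class GroupComparison:
    """Outcome of the decision tree for one set of groups."""

    chosen_test: str
    normality_p: dict
    variance_homogeneity_p: float
    omnibus_p: float
    pairwise_p: dict
    stars: dict
    normality_violated: bool = False
    flags: tuple = ()

    @property
    def any_significant(self) -> bool:
        return any(s != "" for s in self.stars.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"group_a": a, "group_b": b, "p_value": p, "stars": self.stars[(a, b)]}
            for (a, b), p in self.pairwise_p.items()
        ]
        df = pd.DataFrame(rows)
        df["test"] = self.chosen_test
        return df


def star_annotation(p: float) -> str:
    """Significance stars for a p-value: *** <0.001, ** <0.01, * <0.05, else ''."""
    if not 0 <= p <= 1:
        raise ValueError(f"p-value must lie in [0, 1], got {p}")
    for threshold, stars in STAR_THRESHOLDS:
        if p < threshold:
            return stars
    return ""


def welch_anova(groups: Sequence[GroupData]) -> tuple[float, float, float, float]:
    """Welch's heteroscedastic one-way ANOVA.

    Returns (F, df1, df2, p) with df2 from the Welch–Satterthwaite
    approximation.
    """
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two groups")
    n = np.array([g.n for g in groups], dtype=float)
    m = np.array([g.values.mean() for g in groups])
    v = np.array([g.values.var(ddof=1) for g in groups])
    if np.any(v <= 0):
        raise ValueError("Welch's ANOVA requires positive within-group variance")
    w = n / v
    w_sum = w.sum()
    m_w = (w * m).sum() / w_sum
    a = (w * (m - m_w) ** 2).sum() / (k - 1)
    r = ((1 - w / w_sum) ** 2 / (n - 1)).sum()
    b = 1 + 2 * (k - 2) / (k**2 - 1) * r
    f_stat = a / b
    df1 = k - 1
    df2 = (k**2 - 1) / (3 * r)
    p = float(sps.f.sf(f_stat, df1, df2))
    return float(f_stat), float(df1), float(df2), p


def games_howell(groups: Sequence[GroupData]) -> dict[tuple[str, str], float]:
    """Games–Howell pairwise post hoc for unequal variances.

    For each pair the statistic q = |Δmean| / √(s²ᵢ/nᵢ + s²ⱼ/nⱼ) · √2 is
    referred to the studentized-range distribution with k groups and
    Welch–Satterthwaite degrees of freedom.
    """
    k = len(groups)
    out: dict[tuple[str, str], float] = {}
    for gi, gj in itertools.combinations(groups, 2):
        vi, vj = gi.values.var(ddof=1), gj.values.var(ddof=1)
        sei, sej = vi / gi.n, vj / gj.n
        se2 = sei + sej
        if se2 <= 0:
            raise ValueError("zero variance in both groups; comparison is degenerate")
        t = abs(gi.values.mean() - gj.values.mean()) / np.sqrt(se2)
        df = se2**2 / (sei**2 / (gi.n - 1) + sej**2 / (gj.n - 1))
        p = float(sps.studentized_range.sf(t * np.sqrt(2.0), k, df))
        out[(gi.label, gj.label)] = min(1.0, p)
    return out


def _tukey(groups: Sequence[GroupData]) -> dict[tuple[str, str], float]:
    res = sps.tukey_hsd(*[g.values for g in groups])
    out = {}
    for i, j in itertools.combinations(range(len(groups)), 2):
        out[(groups[i].label, groups[j].label)] = float(res.pvalue[i, j])
    return out


def decide_and_compare(groups: Sequence[GroupData], alpha: float = 0.05) -> GroupComparison:
    """Run the full decision tree on ≥ 2 groups.

    Groups with fewer than 3 values, or degenerate (constant) data, flag the
    comparison as skipped (``chosen_test='none'``) rather than raising, so a
    cohort report can carry partial results.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    flags: list[str] = []
    small = [g.label for g in groups if g.n < 3]
    if small:
        return GroupComparison(
            chosen_test="none",
            normality_p={},
            variance_homogeneity_p=float("nan"),
            omnibus_p=float("nan"),
            pairwise_p={},
            stars={},
            flags=(f"groups with n < 3 skip the comparison: {', '.join(small)}",),
        )
    constant = [g.label for g in groups if np.ptp(g.values) == 0]
    if constant:
        return GroupComparison(
            chosen_test="none",
            normality_p={},
            variance_homogeneity_p=float("nan"),
            omnibus_p=float("nan"),
            pairwise_p={},
            stars={},
            flags=(f"degenerate constant groups: {', '.join(constant)}",),
        )

    normality_p = {g.label: float(sps.shapiro(g.values).pvalue) for g in groups}
    normality_violated = any(p < alpha for p in normality_p.values())
    if normality_violated:
        flags.append("Shapiro-Wilk rejected normality for at least one group")
    bartlett_p = float(sps.bartlett(*[g.values for g in groups]).pvalue)
    homogeneous = bartlett_p >= alpha

    if len(groups) == 2:
        a, b = groups
        res = sps.ttest_ind(a.values, b.values, equal_var=homogeneous)
        chosen = "student_t" if homogeneous else "welch_t"
        omnibus_p = float(res.pvalue)
        pairwise = {(a.label, b.label): omnibus_p}
    elif homogeneous:
        chosen = "anova_tukey"
        omnibus_p = float(sps.f_oneway(*[g.values for g in groups]).pvalue)
        pairwise = _tukey(groups)
    else:
        chosen = "welch_anova_games_howell"
        omnibus_p = welch_anova(groups)[3]
        pairwise = games_howell(groups)

    stars = {pair: star_annotation(p) for pair, p in pairwise.items()}
    return GroupComparison(
        chosen_test=chosen,
        normality_p=normality_p,
        variance_homogeneity_p=bartlett_p,
        omnibus_p=omnibus_p,
        pairwise_p=pairwise,
        stars=stars,
        normality_violated=normality_violated,
        flags=tuple(flags),
    )
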