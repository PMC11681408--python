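"""Nonparametric comparison of 10-year WMH volume change across score categories.

A Kruskal-Wallis rank test (tie-corrected, chi-square reference) asks whether
volume change differs across the prescreen severity categories; planned post
hoc contrasts then compare each elevated category (mild, moderate, severe)
against the "none" category with rank-sum tests, Bonferroni-adjusted over
the planned contrasts. An all-pairwise variant is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = ["GroupComparisonResult", "PostHocContrast", "kruskal_wallis_by_category"]


@dataclass(frozen=True)
class PostHocContrast:
    group_a: str
    group_b: str
    statistic: float
    p_raw: float
    p_adjusted: float


@dataclass(frozen=True)
class GroupComparisonResult:
    """Omnibus Kruskal-Wallis result plus planned post hoc contrasts."""

    h_statistic: float
    p_value: float
    group_sizes: Mapping[str, int]
    group_medians: Mapping[str, float]
    contrasts: tuple[PostHocContrast, ...] = field(default_factory=tuple)
    degenerate: bool = False  # all observations identical

    @property
    def n(self) -> int:
        return sum(self.group_sizes.values())

    def to_dict(self) -> dict:
        return {
            "h_statistic": self.h_statistic,
            "p_value": self.p_value,
            "degenerate": self.degenerate,
            "group_sizes": dict(self.group_sizes),
            "group_medians": dict(self.group_medians),
            "contrasts": [
                {"a": c.group_a, "b": c.group_b, "statistic": c.statistic,
                 "p_raw": c.p_raw, "p_adjusted": c.p_adjusted}
                for c in self.contrasts
            ],
        }


def _rank_sum_contrast(a: Sequence[float], b: Sequence[float],
                       name_a: str, name_b: str) -> tuple[float, float, str, str]:
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(stat), float(p), name_a, name_b


def kruskal_wallis_by_category(
    groups: Mapping[str, Sequence[float]],
    *,
    reference: str = "none",
    post_hoc: Literal["vs_reference", "all_pairwise", "none"] = "vs_reference",
    alpha: float = 0.05,
) -> GroupComparisonResult:
    """Tie-corrected Kruskal-Wallis H across groups, with post hoc contrasts.

    ``groups`` maps category label -> volume changes. Needs at least two
    nonempty groups. When every observation is identical the omnibus test is
    degenerate: H = 0, p = 1, flagged via ``degenerate``. Post hoc contrasts
    are two-sided rank-sum (Mann-Whitney) tests, Bonferroni-adjusted over the
    contrasts actually performed.
    """
    clean = {k: np.asarray(v, dtype=float) for k, v in groups.items() if len(v)}
    if len(clean) < 2:
        raise ValueError("need >= 2 nonempty groups for a Kruskal-Wallis test")

    pooled = np.concatenate(list(clean.values()))
    sizes = {k: int(len(v)) for k, v in clean.items()}
    medians = {k: float(np.median(v)) for k, v in clean.items()}

    if np.unique(pooled).size < 2:
        return GroupComparisonResult(
            h_statistic=0.0, p_value=1.0, group_sizes=sizes,
            group_medians=medians, degenerate=True)

    h, p = stats.kruskal(*clean.values())

    contrasts: list[PostHocContrast] = []
    if post_hoc == "vs_reference":
        if reference not in clean:
            raise ValueError(f"reference group {reference!r} absent or empty")
        pairs = [(reference, k) for k in clean if k != reference]
    elif post_hoc == "all_pairwise":
        pairs = list(combinations(clean, 2))
    elif post_hoc == "none":
        pairs = []
    else:
        raise ValueError(f"unknown post hoc method {post_hoc!r}")

    m = len(pairs)
    for a, b in pairs:
        stat, p_raw, _, _ = _rank_sum_contrast(clean[a], clean[b], a, b)
        contrasts.append(PostHocContrast(
            group_a=a, group_b=b, statistic=stat, p_raw=p_raw,
            p_adjusted=min(1.0, p_raw * m)))

    return GroupComparisonResult(
        h_statistic=float(h), p_value=float(p), group_sizes=sizes,
        group_medians=medians, contrasts=tuple(contrasts))
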