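"""Per-gel aggregation, nonparametric comparison, and stiffness categories.

Conditions (gel formulations) are summarised as mean +/- sample SD of their
per-curve modulus estimates, compared pairwise with the two-sided
Mann-Whitney U test, and merged into stiffness categories by single-linkage
grouping of conditions that are *not* significantly different at the chosen
alpha — the operational counterpart of merging formulations with overlapping
stiffness ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "GelCondition",
    "StiffnessCategory",
    "aggregate_condition",
    "mann_whitney_u",
    "merge_stiffness_categories",
    "compare_conditions",
    "GroupComparison",
]


@dataclass
class GelCondition:
    """One gel formulation with its per-curve modulus estimates (Pa)."""

    label: str
    estimates: np.ndarray
    alginate_pct: float | None = None
    cacl2_molarity: float | None = None
    n_maps: int = 1

    def __post_init__(self) -> None:
        self.estimates = np.asarray(self.estimates, dtype=float)
        if self.estimates.size < 1:
            raise ValueError("a condition needs at least one retained estimate")
        if self.n_maps < 1:
            raise ValueError("n_maps must be >= 1")


@dataclass
class StiffnessCategory:
    """A merged stiffness range covering one or more indistinguishable gels."""

    label: str
    range_pa: tuple[float, float]
    members: list = field(default_factory=list)


def aggregate_condition(estimates) -> tuple[float, float, int]:
    """Mean, sample SD (n-1 denominator) and n of a set of modulus estimates."""
    e = np.asarray(estimates, dtype=float)
    if e.size < 2:
        raise ValueError("need at least 2 estimates for a mean +/- SD summary")
    return float(e.mean()), float(e.std(ddof=1)), int(e.size)


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test with midrank tie handling.

    Returns ``(U, p)`` where U is the statistic of the first sample. The
    p-value is exact (full enumeration of rank assignments) when
    n*m <= 400 and the pooled data are tie-free; otherwise the normal
    approximation with tie and continuity corrections is used. Two samples
    with all values identical yield p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return a.size * b.size / 2.0, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if a.size * b.size <= 400 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"  # scipy applies tie and continuity corrections
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def merge_stiffness_categories(
    conditions: list[GelCondition],
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> list[StiffnessCategory]:
    """Group conditions whose moduli are statistically indistinguishable.

    Single-linkage merging: conditions i and j join the same category when
    their pairwise two-sided Mann-Whitney p >= alpha (optionally Bonferroni-
    adjusted across the pairwise tests). Each category is labelled by the
    min-max envelope of its members' mean +/- SD, in kPa. The result is
    sorted by mean stiffness and independent of input order.
    """
    if len(conditions) < 2:
        raise ValueError("need at least two conditions to merge")
    n = len(conditions)
    n_tests = n * (n - 1) // 2
    thr = alpha / n_tests if bonferroni else alpha
    # order-independence: work on a canonical ordering by mean
    order = sorted(range(n), key=lambda i: float(np.mean(conditions[i].estimates)))
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for ii in range(n):
        for jj in range(ii + 1, n):
            i, j = order[ii], order[jj]
            _, p = mann_whitney_u(conditions[i].estimates, conditions[j].estimates)
            if p >= thr:
                parent[find(order[ii])] = find(order[jj])

    groups: dict[int, list[int]] = {}
    for ii in range(n):
        groups.setdefault(find(ii), []).append(order[ii])

    cats = []
    for members_idx in groups.values():
        members = [conditions[i] for i in members_idx]
        lo = min(np.mean(c.estimates) - np.std(c.estimates, ddof=1) for c in members)
        hi = max(np.mean(c.estimates) + np.std(c.estimates, ddof=1) for c in members)
        label = f"{lo / 1e3:.0f}-{hi / 1e3:.0f} kPa"
        cats.append(StiffnessCategory(label=label, range_pa=(float(lo), float(hi)), members=[c.label for c in members]))
    cats.sort(key=lambda c: c.range_pa[0])
    return cats


@dataclass
class GroupComparison:
    """Results container for a multi-condition stiffness comparison."""

    summaries: "pd.DataFrame"
    pairwise: "pd.DataFrame"
    categories: list
    alpha: float

    def summary(self) -> str:
        lines = ["Gel stiffness comparison", "=" * 60]
        for _, r in self.summaries.iterrows():
            lines.append(
                f"{r['label']:<24s} E = {r['mean_kPa']:9.1f} +/- {r['sd_kPa']:7.1f} kPa"
                f"  (n={int(r['n'])})"
            )
        lines.append("-" * 60)
        lines.append(f"Mann-Whitney two-sided, alpha = {self.alpha}")
        for _, r in self.pairwise.iterrows():
            mark = "*" if r["p"] < self.alpha else "ns"
            lines.append(f"{r['a']:<20s} vs {r['b']:<20s} U={r['U']:.0f} p={r['p']:.3g} {mark}")
        lines.append("-" * 60)
        lines.append(f"{len(self.categories)} stiffness categories:")
        for c in self.categories:
            lines.append(f"  {c.label:<18s} <- {', '.join(c.members)}")
        return "\n".join(lines)


def compare_conditions(conditions: list[GelCondition], alpha: float = 0.05) -> GroupComparison:
    """Aggregate, test pairwise and categorise a set of gel conditions."""
    import pandas as pd

    rows = []
    for c in conditions:
        mean, sd, n = aggregate_condition(c.estimates)
        rows.append(
            {"label": c.label, "mean_kPa": mean / 1e3, "sd_kPa": sd / 1e3, "n": n,
             "alginate_pct": c.alginate_pct, "cacl2_M": c.cacl2_molarity}
        )
    summaries = pd.DataFrame(rows)
    pw = []
    for i in range(len(conditions)):
        for j in range(i + 1, len(conditions)):
            u, p = mann_whitney_u(conditions[i].estimates, conditions[j].estimates)
            pw.append({"a": conditions[i].label, "b": conditions[j].label, "U": u, "p": p,
                       "significant": p < alpha})
    pairwise = pd.DataFrame(pw)
    cats = merge_stiffness_categories(conditions, alpha=alpha) if len(conditions) >= 2 else []
    return GroupComparison(summaries=summaries, pairwise=pairwise, categories=cats, alpha=alpha)
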