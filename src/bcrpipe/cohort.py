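"""Group-level comparisons of per-donor repertoire summaries.

A thin contract layer: nonparametric tests come from scipy (Mann-Whitney U for
two independent groups, Wilcoxon signed-rank for two paired groups,
Kruskal-Wallis for three or more, always two-tailed); Dunn's post-hoc test and
Holm-Šídák step-down adjustment are implemented here.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class GroupComparison:
    test_name: str
    statistic: float
    p_value: float
    groups: dict[str, np.ndarray]
    posthoc: Optional[pd.DataFrame] = None


def _validate(values_by_group: dict[str, Sequence[float]]) -> dict[str, np.ndarray]:
    groups = {}
    for name, values in values_by_group.items():
        arr = np.asarray(values, dtype=float)
        if arr.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
        groups[name] = arr
    return groups


def compare_groups(
    values_by_group: dict[str, Sequence[float]],
    design: str = "independent",
) -> GroupComparison:
    """Two-tailed nonparametric comparison across donor groups.

    Two independent groups: Mann-Whitney U (exact when both n <= 8 and no
    ties). Two paired groups: Wilcoxon signed-rank. Three or more independent
    groups: Kruskal-Wallis with a Dunn post-hoc table (Holm-Šídák adjusted).
    """
    groups = _validate(values_by_group)
    names = list(groups)
    if design not in ("independent", "paired"):
        raise ValueError(f"unknown design {design!r}")
    if len(names) < 2:
        raise ValueError("need at least 2 groups")

    if len(names) == 2:
        a, b = groups[names[0]], groups[names[1]]
        if design == "paired":
            if a.size != b.size:
                raise ValueError("paired design requires equal group lengths")
            res = sps.wilcoxon(a, b, alternative="two-sided")
            return GroupComparison("wilcoxon", float(res.statistic),
                                   float(res.pvalue), groups)
        pooled = np.concatenate([a, b])
        exact = a.size <= 8 and b.size <= 8 and np.unique(pooled).size == pooled.size
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
        )
        return GroupComparison("mann-whitney", float(res.statistic),
                               float(res.pvalue), groups)

    if design == "paired":
        raise ValueError("paired designs support exactly 2 groups")
    res = sps.kruskal(*groups.values())
    posthoc = dunn_posthoc(groups)
    return GroupComparison("kruskal-wallis", float(res.statistic),
                           float(res.pvalue), groups, posthoc)


def dunn_posthoc(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's pairwise rank-sum z tests after Kruskal-Wallis, tie-corrected,
    two-tailed, with Holm-Šídák adjusted p-values."""
    names = list(groups)
    pooled = np.concatenate([groups[n] for n in names])
    ranks = sps.rankdata(pooled)
    n_total = pooled.size
    mean_ranks = {}
    start = 0
    for name in names:
        size = groups[name].size
        mean_ranks[name] = ranks[start : start + size].mean()
        start += size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1)))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt(var_base * (1.0 / groups[a].size + 1.0 / groups[b].size))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": float(z), "p_value": float(p)})
    table = pd.DataFrame(rows)
    table["p_adjusted"] = adjust_pvalues(table["p_value"].to_numpy())
    return table


def adjust_pvalues(pvals: Sequence[float]) -> np.ndarray:
    """Holm-Šídák step-down adjustment.

    With p-values sorted ascending, the i-th adjusted value (1-based) is
    max over j <= i of 1 - (1 - p_(j))^(m - j + 1), clipped to 1; the result
    is monotone nondecreasing along the sorted order and returned in the input
    order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    m = p.size
    stepwise = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adjusted_sorted = np.minimum(np.maximum.accumulate(stepwise), 1.0)
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out


def paired_correlation(x: Sequence[float], y: Sequence[float]) -> Optional[float]:
    """Squared Pearson correlation of paired per-donor summaries; None when
    either vector has zero variance."""
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("paired correlation requires equal lengths >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return None
    r, _ = sps.pearsonr(a, b)
    return float(r * r)
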