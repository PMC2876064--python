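"""Group-level statistics: which pathways and descriptors shift between groups.

Two families of tests mirror the two questions of the analysis:

* per-pathway: does a pathway's frequency (fraction of taxa possessing it),
  connectivity (degree, strength) or centrality (closeness, betweenness,
  weighted betweenness) differ between two groups of taxa? Frequency uses
  Fisher's exact test on presence/absence counts; the other scores use the
  two-sided Mann-Whitney U test on per-taxon values restricted to taxa that
  possess the pathway (absence is already captured by the frequency score).
  All (pathway x score) p-values of a contrast form one Benjamini-Hochberg
  family, and results are medianized per functional category.
* per-descriptor: is a NIP descriptor's value the same across groups?
  Mann-Whitney for two groups, Kruskal-Wallis for three or more, with
  Bonferroni correction over the 52 descriptors.

Amplitudes are differences of group medians (frequency: difference of
frequencies), signed group_b minus group_a.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .descriptors import betweenness, closeness
from .errors import ValidationError
from .nip_core import NIP

logger = logging.getLogger(__name__)

__all__ = [
    "SCORES",
    "GroupComparison",
    "CategorySummary",
    "pathway_scores",
    "pathway_frequency",
    "fisher_exact",
    "mann_whitney",
    "kruskal_wallis",
    "adjust_pvalues",
    "compare_pathways",
    "compare_descriptors",
]

SCORES = ("frequency", "degree", "strength", "closeness", "betweenness", "weighted_betweenness")

# exact Mann-Whitney distribution is used up to this product of sample sizes
_MW_EXACT_LIMIT = 400


def pathway_scores(nip: NIP) -> pd.DataFrame:
    """Connectivity and centrality of every pathway in one NIP.

    Columns: degree, strength (weighted degree), harmonic closeness, and the
    unweighted and weighted vertex betweenness.
    """
    nodes = nip.nodes()
    deg = dict(nip.graph.degree)
    strength = dict(nip.graph.degree(weight="weight"))
    clo = closeness(nip)
    btw = betweenness(nip, "vertex", weighted=False)
    wbtw = betweenness(nip, "vertex", weighted=True)
    return pd.DataFrame(
        {
            "degree": [deg[v] for v in nodes],
            "strength": [strength[v] for v in nodes],
            "closeness": [clo[v] for v in nodes],
            "betweenness": [btw[v] for v in nodes],
            "weighted_betweenness": [wbtw[v] for v in nodes],
        },
        index=pd.Index(nodes, name="pathway_id"),
    )


def pathway_frequency(group: Mapping[str, Iterable[str]] | Sequence[NIP], pathway_id: str) -> float:
    """Fraction of taxa in a group that possess a pathway."""
    if isinstance(group, Mapping):
        memberships = [set(p) for p in group.values()]
    else:
        memberships = [set(nip.graph.nodes) for nip in group]
    if not memberships:
        raise ValueError("group must contain at least one taxon")
    return sum(pathway_id in m for m in memberships) / len(memberships)


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact p-value for a 2x2 count table."""
    t = np.asarray(table)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be a 2x2 array of non-negative counts")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Uses the exact null distribution when there are no ties and
    ``len(x) * len(y) <= 400``; otherwise the normal approximation with
    midranks and tie correction. Returns (U of the first sample, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):  # zero variance: no shift by definition
        return float(len(x) * len(y) / 2.0), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    if not has_ties and len(x) * len(y) <= _MW_EXACT_LIMIT:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=False
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def kruskal_wallis(samples: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H test with tie correction; chi-square p on k-1 df.

    All observations identical yields (H=0, p=1) rather than an error.
    """
    samples = [np.asarray(s, dtype=float) for s in samples]
    if len(samples) < 2 or any(len(s) == 0 for s in samples):
        raise ValueError("need at least 2 non-empty samples")
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def adjust_pvalues(p: Sequence[float], method: str = "bh") -> list[float]:
    """Multiple-testing adjustment preserving input order.

    ``bonferroni``: min(1, m*p); ``bh``: Benjamini-Hochberg step-up adjusted
    values with enforced monotonicity.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return []
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    key = {"bh": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValueError(f"method must be 'bh' or 'bonferroni', got {method!r}")
    return list(map(float, multipletests(p, method=key)[1]))


@dataclass
class GroupComparison:
    """Result of one (pathway, score) test between two taxa groups."""

    pathway_id: str
    score_name: str
    group_a: str
    group_b: str
    amplitude: float  # signed, group_b minus group_a
    p_value: float
    fdr: float = float("nan")


@dataclass
class CategorySummary:
    """Median amplitude and FDR of one score over a functional category."""

    category: str
    score_name: str
    median_amplitude: float
    median_fdr: float
    direction: str  # increase | decrease | none


def compare_pathways(
    nips_by_group: Mapping[str, Sequence[NIP]],
    categories: Mapping[str, str] | None = None,
    scores: Sequence[str] = SCORES,
) -> tuple[list[GroupComparison], list[CategorySummary]]:
    """Per-pathway frequency/connectivity/centrality shifts between two groups.

    For each pathway present in at least one taxon: the frequency score is
    tested with Fisher's exact test on presence counts; each other score
    with Mann-Whitney on the per-taxon values of taxa possessing the pathway
    (skipped, with a log entry, when either group has fewer than 2 such
    taxa). BH correction is applied jointly across all (pathway, score)
    tests of the contrast. Category summaries take per-category medians of
    amplitude and FDR; direction is the sign of the median amplitude.
    """
    if len(nips_by_group) != 2:
        raise ValidationError("compare_pathways requires exactly two groups")
    (label_a, nips_a), (label_b, nips_b) = nips_by_group.items()
    if len(nips_a) < 2 or len(nips_b) < 2:
        raise ValidationError("each group needs at least 2 taxa")
    categories = categories or {}
    unknown = [s for s in scores if s not in SCORES]
    if unknown:
        raise ValueError(f"unknown scores: {unknown}")

    tables = {label_a: [pathway_scores(n) for n in nips_a],
              label_b: [pathway_scores(n) for n in nips_b]}
    all_pathways = sorted(
        set().union(*(set(t.index) for ts in tables.values() for t in ts))
    )

    comparisons: list[GroupComparison] = []
    for pid in all_pathways:
        present_a = [t for t in tables[label_a] if pid in t.index]
        present_b = [t for t in tables[label_b] if pid in t.index]
        if not present_a and not present_b:
            logger.info("pathway %r absent from both groups; skipped", pid)
            continue
        if "frequency" in scores:
            n_a, n_b = len(tables[label_a]), len(tables[label_b])
            k_a, k_b = len(present_a), len(present_b)
            p = fisher_exact([[k_a, n_a - k_a], [k_b, n_b - k_b]])
            comparisons.append(
                GroupComparison(pid, "frequency", label_a, label_b, k_b / n_b - k_a / n_a, p)
            )
        for score in scores:
            if score == "frequency":
                continue
            vals_a = np.array([t.loc[pid, score] for t in present_a], dtype=float)
            vals_b = np.array([t.loc[pid, score] for t in present_b], dtype=float)
            if len(vals_a) < 2 or len(vals_b) < 2:
                logger.info(
                    "pathway %r, score %r: fewer than 2 taxa per group; test skipped",
                    pid,
                    score,
                )
                continue
            _, p = mann_whitney(vals_a, vals_b)
            amp = float(np.median(vals_b) - np.median(vals_a))
            comparisons.append(GroupComparison(pid, score, label_a, label_b, amp, p))

    fdrs = adjust_pvalues([c.p_value for c in comparisons], "bh")
    for c, f in zip(comparisons, fdrs):
        c.fdr = f

    summaries: list[CategorySummary] = []
    frame = pd.DataFrame(
        {
            "category": [categories.get(c.pathway_id, "uncategorized") for c in comparisons],
            "score": [c.score_name for c in comparisons],
            "amplitude": [c.amplitude for c in comparisons],
            "fdr": [c.fdr for c in comparisons],
        }
    )
    for (cat, score), sub in frame.groupby(["category", "score"], sort=True):
        med_amp = float(sub["amplitude"].median())
        direction = "increase" if med_amp > 0 else "decrease" if med_amp < 0 else "none"
        summaries.append(
            CategorySummary(cat, score, med_amp, float(sub["fdr"].median()), direction)
        )
    return comparisons, summaries


def compare_descriptors(descriptors: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Per-descriptor group tests with Bonferroni correction.

    Mann-Whitney for two groups, Kruskal-Wallis for three or more. Returns a
    table with the test statistic, raw and Bonferroni-corrected p-values and
    per-group mean and standard deviation for every descriptor column.
    """
    labels = labels.reindex(descriptors.index).dropna()
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValidationError("compare_descriptors needs at least 2 groups")
    rows = []
    for col in descriptors.columns:
        samples = [
            descriptors.loc[labels[labels == g].index, col].dropna().values for g in groups
        ]
        row: dict = {"descriptor": col}
        if any(len(s) == 0 for s in samples):
            degenerate = True
        else:
            pooled = np.concatenate(samples)
            degenerate = bool(np.all(pooled == pooled[0]))
        if degenerate:
            stat, p = np.nan, 1.0
        elif len(groups) == 2:
            stat, p = mann_whitney(samples[0], samples[1])
        else:
            stat, p = kruskal_wallis(samples)
        row["statistic"] = stat
        row["p_value"] = p
        for g, s in zip(groups, samples):
            row[f"mean_{g}"] = float(np.mean(s)) if len(s) else np.nan
            row[f"sd_{g}"] = float(np.std(s, ddof=1)) if len(s) > 1 else np.nan
        rows.append(row)
    out = pd.DataFrame(rows).set_index("descriptor")
    out["p_bonferroni"] = adjust_pvalues(out["p_value"].tolist(), "bonferroni")
    return out
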