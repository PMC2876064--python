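import itertools
import math

import numpy as np
import pandas as pd
import pytest

from nipevo.errors import ValidationError
from nipevo.nip_core import build_nip
from nipevo.pathway_importance import (
    adjust_pvalues,
    compare_descriptors,
    compare_pathways,
    fisher_exact,
    kruskal_wallis,
    mann_whitney,
    pathway_frequency,
    pathway_scores,
)

from conftest import make_nip


class TestPathwayFrequency:
    def test_fraction(self):
        group = {"t1": {"P1"}, "t2": {"P1"}, "t3": {"P1"}, "t4": {"P2"}}
        assert pathway_frequency(group, "P1") == 0.75

    def test_absent_and_ubiquitous(self):
        group = {"t1": {"P1"}, "t2": {"P1"}}
        assert pathway_frequency(group, "P9") == 0.0
        assert pathway_frequency(group, "P1") == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            pathway_frequency({}, "P1")


def hypergeom_two_sided(table):
    """Exact enumeration over all tables with the observed margins."""
    from math import comb

    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
            return 0.0
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    return sum(prob(x) for x in range(0, c1 + 1) if prob(x) <= p_obs * (1 + 1e-9))


class TestFisherExact:
    @pytest.mark.parametrize(
        "table",
        [
            [[2, 0], [0, 2]],
            [[10, 0], [0, 10]],
            [[3, 5], [7, 2]],
            [[1, 9], [8, 2]],
        ],
    )
    def test_matches_hypergeometric_enumeration(self, table):
        assert fisher_exact(table) == pytest.approx(hypergeom_two_sided(table), abs=1e-9)

    def test_diagonal_2x2_is_one_third(self):
        assert fisher_exact([[2, 0], [0, 2]]) == pytest.approx(1 / 3)

    def test_no_association_is_one(self):
        assert fisher_exact([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, -1], [0, 2]])


def mw_permutation_p(x, y):
    """Exact permutation null of the U statistic by full enumeration."""
    pooled = list(x) + list(y)
    nx = len(x)

    def u_stat(xs, ys):
        return sum(1 for xi in xs for yi in ys if xi > yi) + 0.5 * sum(
            1 for xi in xs for yi in ys if xi == yi
        )

    u_obs = u_stat(x, y)
    mu = len(x) * len(y) / 2
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), nx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u_stat(xs, ys) - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_disjoint_samples_enumeration(self):
        u, p = mann_whitney([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1 / 3)

    def test_identical_samples_p_one(self):
        _, p = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_matches_permutation_oracle(self, rng):
        for _ in range(5):
            x = rng.normal(size=5).round(2)
            y = rng.normal(0.5, 1, size=5).round(2)
            if len(np.unique(np.concatenate([x, y]))) < 10:
                continue  # oracle below assumes no ties
            _, p = mann_whitney(x, y)
            assert p == pytest.approx(mw_permutation_p(list(x), list(y)), abs=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestKruskalWallis:
    def test_identical_samples_no_effect(self):
        h, p = kruskal_wallis([[1, 1], [1, 1], [1, 1]])
        assert h == 0.0
        assert p == 1.0

    def test_hand_ranked_formula(self):
        samples = [[1, 2], [3, 4], [5, 6]]
        h, p = kruskal_wallis(samples)
        # ranks 1..6, no ties: H = 12/(N(N+1)) * sum n_i (rbar_i - rbar)^2
        rbar = [1.5, 3.5, 5.5]
        h_hand = 12 / (6 * 7) * sum(2 * (r - 3.5) ** 2 for r in rbar)
        assert h == pytest.approx(h_hand)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2]])


class TestAdjustPvalues:
    def test_bh_step_up_by_hand(self):
        assert adjust_pvalues([0.01, 0.02, 0.03, 0.04], "bh") == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_bonferroni_single_test(self):
        assert adjust_pvalues([0.03], "bonferroni") == pytest.approx([0.03])

    def test_bh_dominated_by_bonferroni(self, rng):
        p = rng.uniform(size=30)
        bh = np.array(adjust_pvalues(p, "bh"))
        bonf = np.array(adjust_pvalues(p, "bonferroni"))
        assert (bh >= p - 1e-12).all()
        assert (bh <= bonf + 1e-12).all()
        assert (bonf <= 1 + 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.2], "bh")


def _group_of_nips(rng, n_taxa, pathways, boost_pathways=(), boost=0):
    """Taxa sharing a pathway universe; boosted pathways get extra metabolites."""
    nips = []
    for t in range(n_taxa):
        annotation = {}
        for pid in pathways:
            mets = {f"m{k}" for k in rng.integers(0, 20, size=6)}
            if pid in boost_pathways:
                mets |= {f"m{k}" for k in rng.integers(0, 20, size=boost)}
            annotation[pid] = mets
        nips.append(build_nip(annotation, taxon_id=f"t{t}"))
    return nips


class TestComparePathways:
    def test_planted_category_flagged_with_direction(self, rng):
        pathways = [f"P{i:02d}" for i in range(12)]
        categories = {p: ("lipid" if i < 4 else "other") for i, p in enumerate(pathways)}
        group_a = _group_of_nips(rng, 12, pathways)
        group_b = _group_of_nips(rng, 12, pathways, boost_pathways=pathways[:4], boost=12)
        comparisons, summaries = compare_pathways(
            {"a": group_a, "b": group_b}, categories, scores=("strength", "degree")
        )
        lipid_strength = next(
            s for s in summaries if s.category == "lipid" and s.score_name == "strength"
        )
        assert lipid_strength.direction == "increase"
        assert lipid_strength.median_fdr < 0.05

    def test_identical_groups_are_null(self, rng):
        pathways = [f"P{i:02d}" for i in range(8)]
        group = _group_of_nips(rng, 10, pathways)
        _, summaries = compare_pathways({"a": group, "b": list(group)}, {})
        assert all(s.median_fdr >= 0.9 for s in summaries)
        assert all(s.direction == "none" for s in summaries)

    def test_rare_pathway_gets_fisher_but_not_mann_whitney(self, rng):
        pathways = [f"P{i:02d}" for i in range(5)]
        group_a = _group_of_nips(rng, 4, pathways)
        group_b = _group_of_nips(rng, 4, pathways)
        # pathway present in exactly one taxon overall
        group_a[0].graph.add_node("RARE", category="other")
        comparisons, _ = compare_pathways({"a": group_a, "b": group_b}, {})
        rare = [c for c in comparisons if c.pathway_id == "RARE"]
        assert [c.score_name for c in rare] == ["frequency"]

    def test_amplitude_antisymmetry(self, rng):
        pathways = [f"P{i:02d}" for i in range(6)]
        group_a = _group_of_nips(rng, 6, pathways)
        group_b = _group_of_nips(rng, 6, pathways, boost_pathways=pathways[:2], boost=8)
        fwd, _ = compare_pathways({"a": group_a, "b": group_b}, {})
        rev, _ = compare_pathways({"b": group_b, "a": group_a}, {})
        fwd_map = {(c.pathway_id, c.score_name): c for c in fwd}
        for c in rev:
            mirror = fwd_map[(c.pathway_id, c.score_name)]
            assert c.amplitude == pytest.approx(-mirror.amplitude, abs=1e-12)
            assert c.p_value == pytest.approx(mirror.p_value, abs=1e-12)

    def test_needs_two_groups_of_two(self, rng):
        group = _group_of_nips(rng, 2, ["P1"])
        with pytest.raises(ValidationError):
            compare_pathways({"a": group}, {})


class TestCompareDescriptors:
    def test_planted_shift_detected(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 10)), columns=[f"d{i}" for i in range(10)])
        labels = pd.Series(["a"] * 30 + ["b"] * 30, index=X.index)
        X.loc[labels == "b", "d3"] += 5.0  # 5 sd shift
        out = compare_descriptors(X, labels)
        assert out.loc["d3", "p_bonferroni"] < 0.01
        assert out.loc["d3", "mean_b"] - out.loc["d3", "mean_a"] == pytest.approx(5.0, abs=1.0)

    def test_identical_groups_show_no_difference(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("wxyz"))
        stacked = pd.concat([X, X], ignore_index=True)
        labels = pd.Series(["a"] * 20 + ["b"] * 20)
        out = compare_descriptors(stacked, labels)
        assert (out["p_value"] > 0.9).all()

    def test_three_groups_use_kruskal_wallis(self, rng):
        X = pd.DataFrame({"d0": rng.normal(size=30)})
        labels = pd.Series(["a"] * 10 + ["b"] * 10 + ["c"] * 10, index=X.index)
        out = compare_descriptors(X, labels)
        assert math.isfinite(out.loc["d0", "statistic"])
        assert 0 <= out.loc["d0", "p_value"] <= 1


def test_pathway_scores_columns(rng):
    nip = make_nip(5, [(0, 1, 2), (1, 2, 1), (3, 4, 3)])
    scores = pathway_scores(nip)
    assert list(scores.columns) == [
        "degree",
        "strength",
        "closeness",
        "betweenness",
        "weighted_betweenness",
    ]
    assert scores.loc["v01", "degree"] == 2
    assert scores.loc["v01", "strength"] == 3
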