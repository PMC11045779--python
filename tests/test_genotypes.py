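"""Cross-genotype heterogeneity, conservation, bootstrap and category stats."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epmkit.genotypes import (AnalysisConfig, bootstrap_percentages,
                              category_comparison, classify_heterogeneity,
                              cluster_genotype_profiles, compare_observed_predicted,
                              epm_conservation, fisher_intersection)


class TestHeterogeneity:
    def test_constant_probabilities_homogeneous(self):
        rec = classify_heterogeneity("g", {"a": 0.6, "b": 0.6, "c": 0.6})
        assert rec.variance == 0.0 and rec.heterogeneity == "homogeneous"

    def test_two_spread_probabilities_differential(self):
        rec = classify_heterogeneity("g", {"a": 0.2, "b": 0.9})
        assert rec.variance == pytest.approx(0.1225)  # population variance
        assert rec.heterogeneity == "differential"

    def test_boundary_probability_is_low_class(self):
        rec = classify_heterogeneity("g", {"a": 0.5, "b": 0.9})
        assert rec.class_by_genotype["a"] == "low"
        assert rec.class_by_genotype["b"] == "high"

    def test_call_invariant_to_genotype_order(self):
        probs = {"a": 0.1, "b": 0.8, "c": 0.4}
        r1 = classify_heterogeneity("g", probs)
        r2 = classify_heterogeneity("g", dict(reversed(list(probs.items()))))
        assert r1.variance == pytest.approx(r2.variance)
        assert r1.heterogeneity == r2.heterogeneity

    def test_single_genotype_homogeneous(self):
        rec = classify_heterogeneity("g", {"a": 0.7})
        assert rec.variance == 0.0 and rec.heterogeneity == "homogeneous"


class TestConservation:
    def test_present_everywhere_conserved(self):
        presence = {f"g{i}": True for i in range(15)}
        presence["ref"] = True
        assert epm_conservation(presence, "ref") == "conserved"

    def test_missing_in_one_genotype_mutated(self):
        presence = {f"g{i}": True for i in range(14)}
        presence["ref"] = True
        presence["g3"] = False
        assert epm_conservation(presence, "ref") == "mutated"

    def test_absent_from_reference_not_mutated(self):
        presence = {"ref": False, "g1": True, "g2": False}
        assert epm_conservation(presence, "ref") == "absent"

    def test_statuses_mutually_exclusive(self):
        for pattern in ([True, True], [True, False], [False, True], [False, False]):
            presence = {"ref": pattern[0], "g1": pattern[1]}
            assert epm_conservation(presence, "ref") in {"conserved", "mutated", "absent"}

    def test_unscanned_reference_rejected(self):
        with pytest.raises(KeyError):
            epm_conservation({"g1": True}, "ref")


class TestBootstrap:
    def test_all_conserved_always_hundred_percent(self):
        out = bootstrap_percentages(["conserved"] * 30,
                                    AnalysisConfig(bootstrap_reps=100, seed=1))
        assert np.all(out["pct_conserved"] == 100.0)
        assert np.all(out["pct_mutated"] == 0.0)

    def test_mean_close_to_true_fraction(self):
        statuses = ["conserved"] * 70 + ["mutated"] * 30
        cfg = AnalysisConfig(bootstrap_pool=100, bootstrap_reps=1000, seed=2)
        out = bootstrap_percentages(statuses, cfg)
        se = math.sqrt(0.7 * 0.3 / 100) * 100
        assert abs(out["pct_conserved"].mean() - 70.0) < 3 * se

    def test_seeded_reproducibility(self):
        statuses = ["conserved"] * 10 + ["mutated"] * 5
        cfg = AnalysisConfig(seed=7)
        a = bootstrap_percentages(statuses, cfg)
        b = bootstrap_percentages(statuses, cfg)
        assert np.array_equal(a["pct_conserved"], b["pct_conserved"])


def fisher_oracle(n11, n10, n01, n00):
    """Two-sided Fisher p by hypergeometric summation with log-factorials."""
    from math import lgamma, exp

    def lchoose(n, k):
        return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)

    r1, r2 = n11 + n10, n01 + n00
    c1 = n11 + n01
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    logp = {k: lchoose(r1, k) + lchoose(r2, c1 - k) - lchoose(n, c1)
            for k in range(lo, hi + 1)}
    obs = logp[n11]
    return sum(exp(v) for v in logp.values() if v <= obs + 1e-9)


class TestFisherIntersection:
    def test_matches_hypergeometric_oracle(self, rng):
        universe = [f"g{i}" for i in range(60)]
        for _ in range(20):
            a = set(rng.choice(universe, size=int(rng.integers(5, 30)), replace=False))
            b = set(rng.choice(universe, size=int(rng.integers(5, 30)), replace=False))
            out = fisher_intersection(a, b, universe)
            (n11, n10), (n01, n00) = out["table"]
            assert out["p"] == pytest.approx(fisher_oracle(n11, n10, n01, n00),
                                             rel=1e-9, abs=1e-12)

    def test_perfect_overlap_highly_significant(self):
        universe = [f"g{i}" for i in range(100)]
        half = set(universe[:50])
        assert fisher_intersection(half, half, universe)["p"] < 1e-3

    def test_degenerate_tiny_universe_no_crash(self):
        out = fisher_intersection({"a"}, {"b"}, {"a", "b"})
        assert 0.0 <= out["p"] <= 1.0

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            fisher_intersection(set(), set(), set())


class TestGenotypeClustering:
    def test_identical_genotypes_merge_at_zero(self, rng):
        probs = rng.random(20)
        df = pd.DataFrame({"a": probs, "b": probs, "c": probs + 0.5})
        newick, Z = cluster_genotype_profiles(df)
        assert Z[0, 2] == pytest.approx(0.0)

    def test_shared_edit_genotypes_are_siblings(self, rng):
        base = rng.random(30)
        df = pd.DataFrame({"ref": base,
                           "edit1": base + 0.3 * (np.arange(30) < 10),
                           "edit2": base + 0.3 * (np.arange(30) < 10) + 0.01})
        newick, Z = cluster_genotype_profiles(df)
        from skbio import TreeNode
        from io import StringIO
        tree = TreeNode.read(StringIO(newick))
        tips = {t.name for t in tree.tips()}
        assert tips == {"ref", "edit1", "edit2"}
        # edit1/edit2 must share their immediate parent
        e1 = tree.find("edit1")
        assert {t.name for t in e1.parent.tips()} == {"edit1", "edit2"}

    def test_single_genotype_rejected(self, rng):
        with pytest.raises(ValueError):
            cluster_genotype_profiles(pd.DataFrame({"a": rng.random(5)}))


def ranksum_oracle(x, y):
    """Normal-approximation rank-sum p (no continuity correction)."""
    allv = np.concatenate([x, y])
    order = np.argsort(allv, kind="mergesort")
    ranks = np.empty(len(allv))
    sv = allv[order]
    i = 0
    pos = 0
    while i < len(sv):
        j = i
        while j < len(sv) and sv[j] == sv[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2
        i = j
    n1, n2 = len(x), len(y)
    T = ranks[:n1].sum()
    mu = n1 * (n1 + n2 + 1) / 2
    sigma = math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
    z = (T - mu) / sigma
    return 2 * stats.norm.sf(abs(z))


def bh_oracle(ps):
    m = len(ps)
    order = np.argsort(ps)
    q = np.empty(m)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        prev = min(prev, ps[idx] * m / rank)
        q[idx] = prev
    return q


class TestCategoryComparison:
    def test_expression_only_in_species_a_scales_to_minus_one(self):
        cats = {f"g{i}": "cat" for i in range(10)}
        va = {f"g{i}": 1.0 for i in range(10)}
        vb = {f"g{i}": 0.0 for i in range(10)}
        out = category_comparison(cats, va, vb)
        assert out[0].scaled_obs_diff == pytest.approx(-1.0)

    def test_identical_distributions_no_shift(self, rng):
        vals = {f"g{i}": float(v) for i, v in enumerate(rng.random(40))}
        cats = {g: "cat" for g in vals}
        out = category_comparison(cats, vals, vals)
        assert out[0].scaled_obs_diff == 0.0
        assert out[0].obs_p > 0.9

    def test_small_categories_skipped(self):
        cats = {"g1": "tiny", "g2": "tiny"}
        va = {"g1": 1.0, "g2": 0.5}
        assert category_comparison(cats, va, va, min_n=5) == []

    def test_pvalues_and_fdr_match_independent_oracle(self, rng):
        cats, va, vb = {}, {}, {}
        for c in range(50):
            for i in range(8):
                g = f"g{c}_{i}"
                cats[g] = f"cat{c:02d}"
                va[g] = float(rng.random())
                vb[g] = float(rng.random() + 0.2 * (c % 3))
        out = category_comparison(cats, va, vb)
        ps = []
        for comp in out:
            genes = [g for g, c in cats.items() if c == comp.category_id]
            x = np.array([vb[g] for g in genes])
            y = np.array([va[g] for g in genes])
            expect = ranksum_oracle(x, y)
            assert comp.obs_p == pytest.approx(expect, abs=1e-9)
            ps.append(comp.obs_p)
        qs = bh_oracle(np.array(ps))
        for comp, q in zip(out, qs):
            assert comp.obs_fdr == pytest.approx(q, abs=1e-9)
            assert comp.obs_fdr >= comp.obs_p - 1e-12

    def test_observed_predicted_merge_reports_rank_correlation(self, rng):
        cats, oa, ob, pa, pb = {}, {}, {}, {}, {}
        for c in range(6):
            for i in range(6):
                g = f"g{c}_{i}"
                cats[g] = f"cat{c}"
                oa[g] = float(c % 2)
                ob[g] = float((c + 1) % 2)
                pa[g] = oa[g] * 0.8 + 0.1
                pb[g] = ob[g] * 0.8 + 0.1
        merged, corr = compare_observed_predicted(cats, oa, ob, pa, pb)
        assert len(merged) == 6
        assert corr == pytest.approx(1.0)
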