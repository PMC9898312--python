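"""Enrichment primitives against independent oracles."""

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pathnet.annotations import CandidateGeneList, Pathway, PathwayCollection
from pathnet.enrichment import (
    CompetitiveEnrichment,
    PermutationConfig,
    PermutationNullCache,
    SelfContainedEnrichment,
    adjust_bh,
    adjust_bonferroni,
    consensus_pathways,
    empirical_pvalue,
    enrichment_score,
    hypergeometric_pvalue,
    normalize_es,
    permutation_null,
)
from pathnet.gene_scores import GeneScoreTable


def exact_tail(L, M, S, g):
    """Fraction-arithmetic hypergeometric upper tail, the oracle."""
    total = Fraction(0)
    for x in range(g, min(S, M) + 1):
        total += Fraction(comb(S, x) * comb(L - S, M - x), comb(L, M))
    return total


class TestHypergeometric:
    def test_g_zero_is_one(self):
        assert hypergeometric_pvalue(100, 10, 5, 0) == 1.0

    def test_draw_enumeration_oracle(self):
        """Count actual draws: all C(20,5) candidate choices, overlap >= 2
        with a 4-gene pathway."""
        L, M, S, g = 20, 5, 4, 2
        pathway = set(range(S))
        hits = sum(1 for draw in combinations(range(L), M)
                   if len(pathway & set(draw)) >= g)
        expected = hits / comb(L, M)
        assert hypergeometric_pvalue(L, M, S, g) == pytest.approx(
            expected, abs=1e-12)
        assert expected == pytest.approx(0.2487, abs=5e-4)

    def test_tail_monotone_in_overlap(self):
        L, M, S = 50, 12, 9
        ps = [hypergeometric_pvalue(L, M, S, g) for g in range(min(S, M) + 1)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    @pytest.mark.parametrize("L", [5, 11, 17])
    def test_matches_exact_fraction_tail(self, L):
        for M in range(L + 1):
            for S in range(L + 1):
                for g in range(min(S, M) + 1):
                    assert hypergeometric_pvalue(L, M, S, g) == pytest.approx(
                        float(exact_tail(L, M, S, g)), abs=1e-12)

    def test_infeasible_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_pvalue(10, 12, 5, 1)
        with pytest.raises(ValueError):
            hypergeometric_pvalue(10, 5, 12, 1)
        with pytest.raises(ValueError):
            hypergeometric_pvalue(10, 5, 4, 5)


class TestEnrichmentScore:
    def test_sum_and_sum_of_squares(self):
        assert enrichment_score([1.0, 2.0, 3.0], "sumstat") == 6.0
        assert enrichment_score([1.0, 2.0, 3.0], "sumsq") == 14.0
        assert enrichment_score([0.0, 0.0], "sumstat") == 0.0
        assert enrichment_score([0.0, 0.0], "sumsq") == 0.0

    def test_empty_membership_rejected(self):
        with pytest.raises(ValueError):
            enrichment_score([], "sumstat")


class TestPermutationNull:
    def test_constant_universe_gives_constant_null(self):
        table = GeneScoreTable("x", [f"g{i}" for i in range(20)],
                               [0.1] * 20)
        null = permutation_null(table, 3, "sumstat",
                                PermutationConfig(B=200, seed=1))
        np.testing.assert_allclose(null, 3 * -np.log10(0.1))

    def test_small_universe_matches_exact_enumeration(self):
        """5 scores, subsets of 2: the null must converge to the uniform
        law over the C(5,2)=10 subset sums."""
        p = [0.5, 0.1, 0.02, 0.3, 0.9]
        table = GeneScoreTable("x", [f"g{i}" for i in range(5)], p)
        scores = table.scores
        exact = sorted(scores[i] + scores[j]
                       for i, j in combinations(range(5), 2))
        null = permutation_null(table, 2, "sumstat",
                                PermutationConfig(B=10_000, seed=3))
        for value in exact:
            freq = np.mean(np.isclose(null, value))
            assert freq == pytest.approx(0.1, abs=0.02)

    def test_same_seed_reproduces_null(self):
        rng_scores = np.random.default_rng(0).uniform(size=100)
        table = GeneScoreTable("x", [f"g{i}" for i in range(100)],
                               rng_scores)
        cfg = PermutationConfig(B=500, seed=9)
        a = permutation_null(table, 7, "sumstat", cfg)
        b = permutation_null(table, 7, "sumstat",
                             PermutationConfig(B=500, seed=9))
        np.testing.assert_array_equal(a, b)

    def test_set_size_larger_than_universe_rejected(self):
        table = GeneScoreTable("x", ["a", "b"], [0.5, 0.5])
        with pytest.raises(ValueError):
            permutation_null(table, 3, "sumstat", PermutationConfig(B=100))


class TestEmpiricalPvalue:
    def test_direct_count(self):
        assert empirical_pvalue(6, list(range(1, 11))) == pytest.approx(6 / 11)

    def test_floor_and_ceiling(self):
        null = list(range(10))
        assert empirical_pvalue(100, null) == pytest.approx(1 / 11)
        assert empirical_pvalue(-1, null) == 1.0

    @given(st.permutations(list(range(12))))
    def test_invariant_under_null_reordering(self, perm):
        assert empirical_pvalue(5.5, perm) == empirical_pvalue(
            5.5, list(range(12)))


class TestNormalizeES:
    def test_zero_when_observed_equals_mean(self):
        z, _ = normalize_es(5.5, list(range(1, 11)))
        assert z == pytest.approx(0.0)

    def test_closed_form_example(self):
        # null 1..10: mean 5.5, sample sd 3.02765
        z, p = normalize_es(6.0, list(range(1, 11)))
        assert z == pytest.approx(0.5 / 3.0276503, abs=1e-6)
        assert z == pytest.approx(0.16514, abs=1e-5)
        assert 0 < p < 1

    def test_location_invariance(self):
        null = np.arange(1.0, 11.0)
        z1, _ = normalize_es(6.0, null)
        z2, _ = normalize_es(6.0 + 42, null + 42)
        assert z1 == pytest.approx(z2)

    def test_zero_variance_is_an_error(self):
        with pytest.raises(ValueError):
            normalize_es(1.0, [2.0, 2.0, 2.0])


class TestAdjustments:
    def test_bh_hand_computed(self):
        np.testing.assert_allclose(adjust_bh([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_bh_oracle_and_order_preservation(self):
        def bh_oracle(p):
            m = len(p)
            order = sorted(range(m), key=lambda i: p[i])
            adj = [0.0] * m
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                adj[i] = running
            return adj

        rng = np.random.default_rng(0)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 40))
            got = adjust_bh(p)
            np.testing.assert_allclose(got, bh_oracle(list(p)),
                                       atol=1e-12)
            # monotone transform of the raw ordering
            assert np.all(np.diff(got[np.argsort(p, kind="stable")]) >= -1e-15)

    def test_bonferroni(self):
        np.testing.assert_allclose(adjust_bonferroni([0.3, 0.4, 0.5]),
                                   [0.9, 1.0, 1.0])
        np.testing.assert_allclose(adjust_bonferroni([0.01]), [0.01])

    def test_single_p_identity_and_equal_ps(self):
        np.testing.assert_allclose(adjust_bh([0.37]), [0.37])
        np.testing.assert_allclose(adjust_bh([0.2, 0.2, 0.2]),
                                   [0.2, 0.2, 0.2])

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=50)
        assert np.all(adjust_bh(p) >= p - 1e-15)
        assert np.all(adjust_bonferroni(p) >= p - 1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.2])


class TestCompetitiveModel:
    def make_table(self, n):
        rng = np.random.default_rng(5)
        return GeneScoreTable("3h", [f"g{i}" for i in range(n)],
                              rng.uniform(size=n))

    def test_disjoint_pathway_p_one(self):
        table = self.make_table(50)
        coll = PathwayCollection([Pathway("PW:A", "a", genes=frozenset(
            {"g10", "g11"}))])
        cand = CandidateGeneList([("g0", 50.0), ("g1", 50.0)])
        res = CompetitiveEnrichment(table, coll, cand).fit()
        row = res.frame.iloc[0]
        assert row["N_FT"] == 0 and row["p_value"] == 1.0

    def test_pathway_equal_to_universe_p_one(self):
        table = self.make_table(20)
        coll = PathwayCollection([Pathway("PW:U", "u", genes=frozenset(
            table.universe))])
        cand = CandidateGeneList([("g0", 50.0), ("g1", 50.0)])
        res = CompetitiveEnrichment(table, coll, cand).fit()
        row = res.frame.iloc[0]
        assert row["N_FT"] == 2 and row["p_value"] == 1.0

    def test_seeded_overlap_ranks_first(self):
        """A pathway capturing 20 of 50 candidates in a 1000-gene universe
        must dominate 100 random pathways."""
        rng = np.random.default_rng(11)
        genes = [f"g{i}" for i in range(1000)]
        table = GeneScoreTable("3h", genes, rng.uniform(size=1000))
        cand_genes = [f"g{i}" for i in range(50)]
        cand = CandidateGeneList([(g, 50.0) for g in cand_genes])
        planted = frozenset(cand_genes[:20]) | frozenset(
            f"g{i}" for i in range(900, 920))
        pathways = [Pathway("PW:planted", "planted", genes=planted)]
        for j in range(100):
            members = rng.choice(1000, size=40, replace=False)
            pathways.append(Pathway(f"PW:{j}", "null", genes=frozenset(
                genes[i] for i in members)))
        res = CompetitiveEnrichment(table, PathwayCollection(pathways),
                                    cand).fit()
        ranked = res.ranked()
        assert ranked.iloc[0]["pathway_id"] == "PW:planted"
        assert ranked.iloc[0]["p_value"] < 1e-4


class TestSelfContainedModel:
    def test_pathway_equal_to_universe_degenerate(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(30)]
        table = GeneScoreTable("3h", genes, rng.uniform(size=30))
        coll = PathwayCollection([Pathway("PW:U", "u",
                                          genes=frozenset(genes))])
        res = SelfContainedEnrichment(
            table, coll, "sumstat", PermutationConfig(B=200, seed=0)).fit()
        row = res.frame.iloc[0]
        assert row["ES"] == pytest.approx(table.scores.sum())
        assert row["p_empirical"] == 1.0
        assert np.isnan(row["normalized_ES"])

    def test_shared_cache_consistency(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(200)]
        table = GeneScoreTable("3h", genes, rng.uniform(size=200))
        coll = PathwayCollection([
            Pathway("PW:A", "a", genes=frozenset(genes[:10])),
            Pathway("PW:B", "b", genes=frozenset(genes[50:60])),
        ])
        cfg = PermutationConfig(B=300, seed=4)
        cache = PermutationNullCache(table, cfg)
        with_cache = SelfContainedEnrichment(
            table, coll, "sumstat", cfg, null_cache=cache).fit()
        without = SelfContainedEnrichment(table, coll, "sumstat", cfg).fit()
        np.testing.assert_allclose(with_cache.frame["p_empirical"],
                                   without.frame["p_empirical"])


class TestConsensus:
    def make_results(self, rows):
        import pandas as pd
        from pathnet.enrichment import EnrichmentResults, RESULT_COLUMNS

        out = []
        for method, cond, pathway_p in rows:
            frame = pd.DataFrame(
                [(pid, pid, cond, method, 10, 1, np.nan, np.nan, np.nan,
                  np.nan, p) for pid, p in pathway_p.items()],
                columns=RESULT_COLUMNS[:11])
            out.append(EnrichmentResults(frame, method, cond, 100, 10))
        return out

    def test_require_all_conditions(self):
        rows = [("sumstat", c, {"PW:A": 1e-6 if c != "24h" else 0.5,
                                "PW:B": 1e-6})
                for c in ("3h", "6h", "12h", "24h")]
        cons = consensus_pathways(self.make_results(rows), 1e-4, True)
        assert cons.per_method["sumstat"] == ["PW:B"]
        cons_any = consensus_pathways(self.make_results(rows), 1e-4, False)
        assert cons_any.per_method["sumstat"] == ["PW:A", "PW:B"]

    def test_method_intersections(self):
        rows = [("sumstat", "3h", {"PW:A": 1e-6, "PW:B": 1e-6}),
                ("hypergeometric", "3h", {"PW:A": 1e-6, "PW:B": 0.2})]
        cons = consensus_pathways(self.make_results(rows), 1e-4, True)
        assert cons.intersections["hypergeometric&sumstat"] == ["PW:A"]
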