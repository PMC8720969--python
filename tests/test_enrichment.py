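"""Over-representation analysis and preranked GSEA."""

import itertools
import math

import numpy as np
import pytest

from herbnet import synthetic
from herbnet.enrichment import (
    GeneSet,
    gene_term_edges,
    gsea_preranked,
    hypergeom_tail,
    make_collection,
    ora,
    read_gmt,
    top_terms,
    write_gmt,
)


def tail_by_counting(k, N, K, n):
    """P(X >= k) from exact combinatorial counts."""
    total = math.comb(N, n)
    hits = sum(
        math.comb(K, i) * math.comb(N - K, n - i)
        for i in range(k, min(K, n) + 1)
        if n - i <= N - K
    )
    return hits / total


class TestHypergeometricTail:
    def test_matches_enumeration_for_all_small_configurations(self):
        for N in range(1, 26):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in (0, 1, min(K, n) // 2, min(K, n)):
                        assert hypergeom_tail(k, N, K, n) == pytest.approx(
                            tail_by_counting(k, N, K, n), abs=1e-12
                        )

    def test_matches_explicit_draw_enumeration(self):
        # literal enumeration over every C(12,6) draw of the query
        N, K, n, k = 12, 5, 6, 3
        universe = range(N)
        inside = set(range(K))
        count = sum(
            1
            for draw in itertools.combinations(universe, n)
            if len(inside.intersection(draw)) >= k
        )
        assert hypergeom_tail(k, N, K, n) == pytest.approx(count / math.comb(N, n))

    def test_monotone_decreasing_in_k(self):
        tails = [hypergeom_tail(k, 50, 12, 20) for k in range(13)]
        assert all(a >= b for a, b in zip(tails, tails[1:]))


class TestOra:
    def make_collection(self):
        return make_collection(
            [
                GeneSet("s1", "alpha", "custom", frozenset({"A", "B", "C"})),
                GeneSet("s2", "beta", "custom", frozenset({"D", "E"})),
                GeneSet("s3", "gamma", "custom", frozenset({"A", "D", "F", "G"})),
            ]
        )

    def test_disjoint_set_has_p_one(self):
        res = ora({"F", "G"}, self.make_collection(), keep_all=True)
        row = res[res["set_id"] == "s2"].iloc[0]
        assert row["k"] == 0
        assert row["p"] == 1.0

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            ora({"A"}, self.make_collection(), universe=set())

    def test_query_outside_universe_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="outside the universe"):
            res = ora({"A", "ZZZ"}, self.make_collection(), keep_all=True)
        assert (res["n"] == 1).all()

    def test_planted_sets_occupy_top_ranks(self):
        universe = [f"G{i:04d}" for i in range(400)]
        planted = universe[:25]
        collection, truth = synthetic.gen_genesets(
            universe, n_sets=30, set_size_range=(10, 30),
            planted_list=planted, n_enriched=3, seed=5
        )
        res = ora(set(planted), collection, universe=set(universe), keep_all=True)
        assert list(res["set_id"][:3].sort_values()) == sorted(truth.enriched_set_ids)

    def test_null_collection_rarely_significant(self):
        universe = [f"G{i:04d}" for i in range(300)]
        hits = 0
        for seed in range(20):
            collection, _ = synthetic.gen_genesets(
                universe, n_sets=20, set_size_range=(10, 30), n_enriched=0, seed=seed
            )
            res = ora(set(universe[:30]), collection, universe=set(universe))
            hits += len(res) > 0
        assert hits <= 1  # >= 95 % of seeds clean

    def test_bh_runs_within_category(self):
        sets = [
            GeneSet(f"b{i}", f"b{i}", "BP", frozenset({f"X{i}"})) for i in range(5)
        ] + [GeneSet("k0", "k0", "KEGG", frozenset({"X0"}))]
        res = ora({"X0"}, make_collection(sets), keep_all=True)
        bp0 = res[res["set_id"] == "b0"].iloc[0]
        kegg = res[res["set_id"] == "k0"].iloc[0]
        assert bp0["p"] == pytest.approx(kegg["p"])
        # the lone KEGG set pays no multiplicity penalty, the BP one does
        assert kegg["adjusted_p"] == pytest.approx(kegg["p"])
        assert bp0["adjusted_p"] >= bp0["p"]


class TestTopTermsAndEdges:
    def test_top_terms_per_category(self):
        universe = [f"G{i:04d}" for i in range(200)]
        collection, _ = synthetic.gen_genesets(
            universe, n_sets=25, set_size_range=(5, 20),
            planted_list=universe[:20], n_enriched=5, seed=1
        )
        res = ora(set(universe[:20]), collection, universe=set(universe), keep_all=True)
        top = top_terms(res, 10)
        assert len(top) == 10
        assert list(top["adjusted_p"]) == sorted(top["adjusted_p"])

    def test_fewer_than_n_returns_all(self):
        res = ora({"A"}, make_collection([GeneSet("s", "s", "custom", frozenset("A"))]), keep_all=True)
        assert len(top_terms(res, 10)) == 1

    def test_edge_count_equals_sum_of_overlaps(self):
        universe = [f"G{i:04d}" for i in range(100)]
        collection, _ = synthetic.gen_genesets(
            universe, n_sets=10, set_size_range=(5, 20),
            planted_list=universe[:15], n_enriched=2, seed=3
        )
        res = ora(set(universe[:15]), collection, universe=set(universe), keep_all=True)
        edges = gene_term_edges(res)
        assert len(edges) == int(res["k"].sum())
        # one set with two overlap genes contributes exactly two edges
        two = res[res["k"] == 2]
        if len(two):
            sid = two.iloc[0]["set_id"]
            assert sum(1 for s, _ in edges if s == sid) == 2


class TestGsea:
    def ranking(self):
        return [(f"g{i}", float(10 - i)) for i in range(10)]

    def test_single_hit_at_top_weight_zero_gives_es_one(self):
        res = gsea_preranked(self.ranking(), {"G0"}, weight=0, n_perm=20, seed=0)
        assert res.es == pytest.approx(1.0)
        assert res.leading_edge == ["G0"]

    def test_hand_enumerated_running_sum(self):
        # hits at ranks 1,2 with weight 0: +1/2, +1/2, then -1/8 each miss
        res = gsea_preranked(self.ranking(), {"G0", "G1"}, weight=0, n_perm=20, seed=0)
        running = [0.5, 1.0] + [1.0 - (i + 1) / 8 for i in range(8)]
        peak = max(running, key=abs)
        assert res.es == pytest.approx(peak)
        np.testing.assert_allclose(res.running_sum, running)

    def test_es_invariant_to_positive_rescaling_at_weight_zero(self):
        scaled = [(g, 3.7 * s) for g, s in self.ranking()]
        a = gsea_preranked(self.ranking(), {"G2", "G5"}, weight=0, n_perm=10, seed=1)
        b = gsea_preranked(scaled, {"G2", "G5"}, weight=0, n_perm=10, seed=1)
        assert a.es == pytest.approx(b.es)

    def test_reversed_ranking_negates_es_for_symmetric_scores(self):
        scores = [5.0, 4.0, 3.0, 2.0, 1.0, -1.0, -2.0, -3.0, -4.0, -5.0]
        fwd = [(f"g{i}", s) for i, s in enumerate(scores)]
        rev = [(f"g{9 - i}", s) for i, s in enumerate(scores)]
        a = gsea_preranked(fwd, {"G0", "G1"}, weight=0, n_perm=10, seed=1)
        b = gsea_preranked(rev, {"G0", "G1"}, weight=0, n_perm=10, seed=1)
        assert a.es == pytest.approx(-b.es)

    def test_permutation_p_uses_add_one_estimator(self):
        res = gsea_preranked(self.ranking(), {"G0"}, weight=0, n_perm=200, seed=3)
        assert res.p > 0
        assert res.p >= 1 / 201

    def test_null_p_roughly_uniform_across_seeds(self):
        rng = np.random.default_rng(9)
        ps = []
        for seed in range(40):
            scores = -np.sort(-rng.normal(size=30))
            ranking = [(f"g{i}", float(s)) for i, s in enumerate(scores)]
            members = {f"G{i}" for i in rng.choice(30, size=5, replace=False)}
            ps.append(gsea_preranked(ranking, members, n_perm=99, seed=seed).p)
        # mean of a uniform is 0.5; allow generous Monte-Carlo slack
        assert 0.3 < np.mean(ps) < 0.7

    def test_full_coverage_rejected(self):
        with pytest.raises(ValueError, match="whole ranking"):
            gsea_preranked(self.ranking(), {f"G{i}" for i in range(10)})

    def test_no_overlap_rejected(self):
        with pytest.raises(ValueError, match="not intersect"):
            gsea_preranked(self.ranking(), {"ZZ"})


class TestGmtIO:
    def test_round_trip(self, tmp_path):
        universe = [f"G{i:04d}" for i in range(60)]
        collection, _ = synthetic.gen_genesets(
            universe, n_sets=8, set_size_range=(5, 15),
            planted_list=universe[:10], n_enriched=2, seed=4
        )
        path = tmp_path / "c.gmt"
        write_gmt(collection, path)
        back = read_gmt(path)
        assert set(back) == set(collection)
        for sid in collection:
            assert back[sid].members == collection[sid].members
            assert back[sid].category == collection[sid].category

    def test_malformed_line_rejected(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("only_id\tdesc\n")
        with pytest.raises(ValueError, match="malformed"):
            read_gmt(path)
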