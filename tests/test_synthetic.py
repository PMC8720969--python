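"""Generator contracts: reproducibility, truth-ledger consistency, planted effects."""

import numpy as np
import pandas as pd
import pytest

from herbnet import synthetic as syn
from herbnet.deg import CASE, CONTROL


class TestReproducibility:
    def test_component_table_byte_identical(self, tmp_path):
        outs = []
        for run in range(2):
            table, _ = syn.gen_component_table(40, frac_passing=0.3, seed=13)
            p = tmp_path / f"t{run}.tsv"
            table.to_csv(p, sep="\t", index=False)
            outs.append(p.read_bytes())
        assert outs[0] == outs[1]

    def test_all_generators_reproducible(self):
        m1, t1 = syn.gen_expression(100, n_de=10, seed=3)
        m2, t2 = syn.gen_expression(100, n_de=10, seed=3)
        pd.testing.assert_frame_equal(m1.values, m2.values)
        assert t1.de_gene_ids_up == t2.de_gene_ids_up
        g1, _ = syn.gen_ppi(80, core_size=10, seed=3)
        g2, _ = syn.gen_ppi(80, core_size=10, seed=3)
        assert set(g1.edges()) == set(g2.edges())
        uni = [f"G{i}" for i in range(50)]
        c1, _ = syn.gen_genesets(uni, 5, (5, 10), uni[:8], 2, seed=3)
        c2, _ = syn.gen_genesets(uni, 5, (5, 10), uni[:8], 2, seed=3)
        assert {s.members for s in c1.values()} == {s.members for s in c2.values()}

    def test_streams_independent_of_seed_reuse(self):
        # same master seed drives different named streams: artifacts differ
        table, _ = syn.gen_component_table(10, frac_passing=0.5, seed=1)
        m, _ = syn.gen_expression(10, n_de=0, seed=1)
        assert not np.allclose(table["OB"][:5], m.values.iloc[0, :5])


class TestComponentGenerator:
    def test_empty_table(self):
        table, truth = syn.gen_component_table(0, frac_passing=0.5, seed=1)
        assert len(table) == 0
        assert not truth.passing_component_ids

    def test_exact_passing_count_with_strict_margins(self):
        table, truth = syn.gen_component_table(50, frac_passing=0.24, seed=1)
        passing = table[(table["OB"] >= 30) & (table["DL"] >= 0.18)]
        assert len(passing) == round(0.24 * 50) == 12
        assert set(passing["mol_id"]) == truth.passing_component_ids
        # passing strictly above both thresholds, failing strictly below one
        assert (passing["OB"] > 30).all() and (passing["DL"] > 0.18).all()
        failing = table[~table["mol_id"].isin(truth.passing_component_ids)]
        assert ((failing["OB"] < 30) | (failing["DL"] < 0.18)).all()

    def test_published_ranges_representable(self):
        # observed pivotal ranges: DL 0.21-0.29, OB 30.68-69.67
        table, _ = syn.gen_component_table(500, frac_passing=1.0, seed=2)
        assert table["DL"].min() < 0.21 and table["DL"].max() > 0.29
        assert table["OB"].min() < 30.68 and table["OB"].max() > 69.67

    def test_herb_membership_one_to_three(self):
        table, _ = syn.gen_component_table(100, frac_passing=0.5, seed=3)
        counts = table["herbs"].str.split(";").map(len)
        assert counts.between(1, 3).all()

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            syn.gen_component_table(-1, frac_passing=0.5, seed=1)


class TestExpressionGenerator:
    def test_null_model_empty_truth(self):
        _, truth = syn.gen_expression(100, n_de=0, seed=1)
        assert not truth.de_gene_ids_up and not truth.de_gene_ids_down

    def test_default_design_thirty_vs_nine(self):
        m, _ = syn.gen_expression(10, n_de=0, seed=1)
        assert len(m.samples_in(CASE)) == 30
        assert len(m.samples_in(CONTROL)) == 9

    def test_planted_shift_and_half_split(self):
        m, truth = syn.gen_expression(500, n_de=11, lfc=2.0, sigma=0.3, seed=5)
        assert len(truth.de_gene_ids_up) == 6  # odd count: extra up gene
        assert len(truth.de_gene_ids_down) == 5
        assert not truth.de_gene_ids_up & truth.de_gene_ids_down
        case, ctrl = m.samples_in(CASE), m.samples_in(CONTROL)
        for g in truth.de_gene_ids_up:
            diff = m.values.loc[g, case].mean() - m.values.loc[g, ctrl].mean()
            assert diff == pytest.approx(2.0, abs=0.5)

    def test_n_de_exceeding_n_genes_rejected(self):
        with pytest.raises(ValueError):
            syn.gen_expression(5, n_de=6, seed=1)


class TestPpiGenerator:
    def test_core_size_zero_is_pure_background(self):
        g, truth = syn.gen_ppi(100, core_size=0, seed=1)
        assert not truth.planted_core_nodes
        assert g.number_of_nodes() == 100

    def test_graph_simple_and_core_wired_in(self, planted_ppi):
        g, truth = planted_ppi
        assert not any(u == v for u, v in g.edges())
        for node in truth.planted_core_nodes:
            assert any(nb.startswith("BG") for nb in g[node])

    def test_core_nodes_rank_in_top_decile_by_degree(self, planted_ppi):
        g, truth = planted_ppi
        cut = int(np.ceil(0.1 * g.number_of_nodes()))
        top = {n for n, _ in sorted(g.degree(), key=lambda kv: -kv[1])[:cut]}
        assert truth.planted_core_nodes <= top

    def test_custom_core_labels(self):
        labels = [f"GENE{i}" for i in range(5)]
        g, truth = syn.gen_ppi(50, core_size=5, seed=2, core_labels=labels)
        assert truth.planted_core_nodes == set(labels)
        assert set(labels) <= set(g.nodes())

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            syn.gen_ppi(10, core_size=10, seed=1)
        with pytest.raises(ValueError):
            syn.gen_ppi(10, core_size=2, core_p=0.0, seed=1)


class TestGenesetGenerator:
    def test_empty_planted_list_valid(self):
        uni = [f"G{i}" for i in range(30)]
        coll, truth = syn.gen_genesets(uni, 5, (5, 10), [], 0, seed=1)
        assert len(coll) == 5
        assert not truth.enriched_set_ids

    def test_enriched_sets_draw_enough_planted_members(self):
        uni = [f"G{i}" for i in range(200)]
        planted = uni[:30]
        coll, truth = syn.gen_genesets(uni, 10, (10, 20), planted, 3, seed=2)
        assert len(truth.enriched_set_ids) == 3
        for sid in truth.enriched_set_ids:
            members = coll[sid].members
            frac = len(members & set(planted)) / len(members)
            assert frac >= 0.55  # >= 60 % by construction, minus rounding

    def test_planted_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            syn.gen_genesets(["A", "B"], 2, (1, 2), ["Z"], 1, seed=1)


class TestCoexprGenerator:
    def test_independence_at_rho_zero(self):
        m = syn.gen_coexpr_pairs({("A1", "B1"): 0.0}, n_samples=2000, seed=7)
        r = np.corrcoef(m.values.loc["A1"], m.values.loc["B1"])[0, 1]
        assert abs(r) < 3 / np.sqrt(2000)

    def test_strong_correlation_recovered(self):
        m = syn.gen_coexpr_pairs({("CDK1", "CCNB1"): 0.84}, n_samples=4000, seed=11)
        r = np.corrcoef(m.values.loc["CDK1"], m.values.loc["CCNB1"])[0, 1]
        assert r == pytest.approx(0.84, abs=0.03)

    def test_pairs_independent_of_each_other(self):
        m = syn.gen_coexpr_pairs(
            {("A1", "B1"): 0.8, ("A2", "B2"): -0.5}, n_samples=3000, seed=9
        )
        cross = np.corrcoef(m.values.loc["A1"], m.values.loc["A2"])[0, 1]
        assert abs(cross) < 0.06

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError):
            syn.gen_coexpr_pairs({("A", "B"): 1.0}, n_samples=10, seed=1)

    def test_gene_reuse_rejected(self):
        with pytest.raises(ValueError, match="reused"):
            syn.gen_coexpr_pairs({("A", "B"): 0.1, ("B", "C"): 0.1}, n_samples=10, seed=1)


class TestTruthLedger:
    def test_merge_and_json_round_trip(self, tmp_path):
        _, t1 = syn.gen_component_table(10, frac_passing=0.5, seed=1)
        _, t2 = syn.gen_expression(20, n_de=4, seed=1)
        merged = t1.merge(t2)
        assert merged.passing_component_ids == t1.passing_component_ids
        assert merged.de_gene_ids_up == t2.de_gene_ids_up
        path = tmp_path / "truth.json"
        merged.to_json(path)
        import json

        payload = json.loads(path.read_text())
        assert set(payload["passing_component_ids"]) == t1.passing_component_ids
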