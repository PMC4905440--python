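from math import comb

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from lncnet.coexpress import coexpressed_partner_sets, coexpression_edges
from lncnet.core import GeneSetCollection, LNCRNA, ValidationError
from lncnet.simulate import simulate_tf_gmt
from lncnet.tfnet import build_tripartite_network, hub_ranking, tf_enrichment


class TestTFEnrichment:
    def test_degenerate_saturation_not_accepted(self):
        genes = frozenset(f"G{i}" for i in range(10))
        coll = GeneSetCollection({"TF1": ("d", genes)})
        res = tf_enrichment({"L1": genes}, coll)
        row = res.iloc[0]
        assert row["p_value"] == 1.0 and not row["accepted"]

    def test_full_containment_matches_closed_form(self):
        universe = [f"G{i}" for i in range(1000)]
        targets = frozenset(universe[:10])
        coll = GeneSetCollection({
            "TF1": ("d", targets),
            "PAD": ("d", frozenset(universe)),  # pins M = 1000
        })
        res = tf_enrichment({"L1": targets}, coll).set_index("tf_id")
        expected = comb(10, 10) * comb(990, 0) / comb(1000, 10)
        assert res.loc["TF1", "p_value"] == pytest.approx(expected, rel=1e-9)

    def test_planted_pairs_accepted_no_decoys(self, module_sim):
        cfg, (matrix, ann, truth) = module_sim
        tf_sets = simulate_tf_gmt(cfg, truth)
        symbols = ann.symbol_map()
        lnc = ann.probes_of_class(LNCRNA)
        mrna = ann.probes_of_class("mRNA")
        edges = coexpression_edges(matrix, lnc, mrna, threshold=0.99)
        partners = coexpressed_partner_sets(edges, symbol_map=symbols)
        res = tf_enrichment(partners, tf_sets, universe=frozenset(symbols.values()))
        accepted = set(zip(
            res.loc[res["accepted"], "lncRNA_probe_id"],
            res.loc[res["accepted"], "tf_id"],
        ))
        planted = {
            (lnc_id, tf)
            for tf, module in truth.tf_match.items()
            for lnc_id in truth.module_members(module, LNCRNA)
        }
        assert planted <= accepted
        decoys = set(tf_sets.term_ids()) - set(truth.tf_match)
        assert not any(tf in decoys for _lnc, tf in accepted)

    def test_joint_fdr_never_accepts_more_than_raw_p(self, module_sim):
        cfg, (matrix, ann, truth) = module_sim
        tf_sets = simulate_tf_gmt(cfg, truth)
        symbols = ann.symbol_map()
        edges = coexpression_edges(
            matrix, ann.probes_of_class(LNCRNA), ann.probes_of_class("mRNA"), threshold=0.99
        )
        partners = coexpressed_partner_sets(edges, symbol_map=symbols)
        res = tf_enrichment(partners, tf_sets, universe=frozenset(symbols.values()))
        assert res["accepted"].sum() <= (res["p_value"] < 0.01).sum()

    def test_partner_outside_universe_skipped_with_warning(self):
        coll = GeneSetCollection({"TF1": ("d", frozenset({"A", "B"}))})
        with pytest.warns(UserWarning, match="L9"):
            res = tf_enrichment({"L9": frozenset({"ZZZ"})}, coll)
        assert res.empty

    def test_acceptance_monotone_in_overlap(self):
        # fixed K, M; growing the overlap with the query never raises p
        universe = frozenset(f"G{i}" for i in range(50))
        targets = frozenset(f"G{i}" for i in range(10))
        coll = GeneSetCollection({"TF1": ("d", targets), "PAD": ("d", universe)})
        prev = 1.1
        for k in range(1, 11):
            partners = frozenset(list(targets)[:k])
            res = tf_enrichment({"L1": partners}, coll).set_index("tf_id")
            p = res.loc["TF1", "p_value"]
            # n grows with k here; p still must not increase
            assert p <= prev + 1e-15
            prev = p


class TestTripartiteNetwork:
    @staticmethod
    def toy_inputs():
        edges = pd.DataFrame({
            "lncRNA_probe_id": ["L1", "L1", "L1"],
            "mRNA_probe_id": ["M1", "M2", "M3"],
            "r": [0.995, 0.996, 0.997],
        })
        tf_sets = GeneSetCollection({
            "TF1": ("d", frozenset({"M1", "M2", "M3", "M9"})),
        })
        assoc = pd.DataFrame({
            "lncRNA_probe_id": ["L1"], "tf_id": ["TF1"], "k": [3], "n": [3],
            "K": [4], "M": [100], "p_value": [1e-6], "fdr": [1e-5], "accepted": [True],
        })
        return assoc, edges, tf_sets

    def test_edge_counts_by_construction(self):
        assoc, edges, tf_sets = self.toy_inputs()
        g = build_tripartite_network(assoc, edges, tf_sets)
        kinds = [d["interaction"] for _u, _v, d in g.edges(data=True)]
        assert kinds.count("coexpressed") == 3
        assert kinds.count("regulates") == 4  # TF->lncRNA + 3 TF->mRNA
        assert g.nodes["TF1"]["node_class"] == "TF"
        assert hub_ranking(g) == [("TF1", 4)]

    def test_no_accepted_associations_gives_empty_network(self):
        assoc, edges, tf_sets = self.toy_inputs()
        assoc["accepted"] = False
        g = build_tripartite_network(assoc, edges, tf_sets)
        assert g.number_of_nodes() == 0

    def test_unknown_lncRNA_rejected(self):
        assoc, edges, tf_sets = self.toy_inputs()
        assoc["lncRNA_probe_id"] = ["L404"]
        with pytest.raises(ValidationError, match="L404"):
            build_tripartite_network(assoc, edges, tf_sets)

    def test_hub_ranking_follows_planted_module_sizes(self):
        """Three TFs whose target overlaps have distinct sizes rank by size."""
        edges = pd.DataFrame({
            "lncRNA_probe_id": ["L1"] * 6 + ["L2"] * 4 + ["L3"] * 2,
            "mRNA_probe_id": [f"M{i}" for i in range(6)]
            + [f"Q{i}" for i in range(4)] + [f"R{i}" for i in range(2)],
            "r": 0.999,
        })
        tf_sets = GeneSetCollection({
            "TFA": ("d", frozenset(f"M{i}" for i in range(6))),
            "TFB": ("d", frozenset(f"Q{i}" for i in range(4))),
            "TFC": ("d", frozenset(f"R{i}" for i in range(2))),
        })
        assoc = pd.DataFrame({
            "lncRNA_probe_id": ["L1", "L2", "L3"],
            "tf_id": ["TFA", "TFB", "TFC"],
            "k": [6, 4, 2], "n": [6, 4, 2], "K": [6, 4, 2], "M": 100,
            "p_value": 1e-9, "fdr": 1e-8, "accepted": True,
        })
        g = build_tripartite_network(assoc, edges, tf_sets)
        assert [tf for tf, _deg in hub_ranking(g)] == ["TFA", "TFB", "TFC"]

    def test_degrees_match_recount_after_graphml_round_trip(self, tmp_path, module_sim):
        from lncnet.io import write_network

        cfg, (matrix, ann, truth) = module_sim
        tf_sets = simulate_tf_gmt(cfg, truth)
        symbols = ann.symbol_map()
        edges = coexpression_edges(
            matrix, ann.probes_of_class(LNCRNA), ann.probes_of_class("mRNA"), threshold=0.99
        )
        partners = coexpressed_partner_sets(edges, symbol_map=symbols)
        assoc = tf_enrichment(partners, tf_sets, universe=frozenset(symbols.values()))
        g = build_tripartite_network(assoc, edges, tf_sets, symbol_map=symbols)
        out = tmp_path / "net.graphml"
        write_network(g, out, fmt="graphml")
        back = nx.read_graphml(out)
        assert back.number_of_nodes() > 0
        for node in back.nodes:
            assert int(back.nodes[node]["degree"]) == back.degree(node)
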