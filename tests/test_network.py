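"""Hypergeometric shared-miRNA test and ceRNA network assembly."""

import math

import networkx as nx
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ceranet as cn
from ceranet.io import InteractionSet
from ceranet.network import mirna_partner_subnetwork

from oracles import exact_hypergeom_tail


class TestHypergeomP:
    @pytest.mark.parametrize(
        "T,t,N,r,expected",
        [
            (10, 3, 3, 0, 1.0),  # empty tail sum is the whole distribution
            (10, 3, 3, 3, 1 / 120),  # C(3,3)C(7,0)/C(10,3)
            (4, 2, 2, 1, 5 / 6),  # 1 - C(2,0)C(2,2)/C(4,2)
            (20, 5, 5, 5, 1 / math.comb(20, 5)),
        ],
    )
    def test_known_values(self, T, t, N, r, expected):
        assert cn.hypergeom_p(T, t, N, r) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize(
        "T,t,N,r",
        [(10, 11, 3, 1), (10, 3, 11, 1), (10, 3, 3, 4), (10, -1, 3, 1), (10, 3, 3, -1)],
    )
    def test_domain_errors(self, T, t, N, r):
        with pytest.raises(ValueError):
            cn.hypergeom_p(T, t, N, r)

    @given(st.integers(1, 40), st.data())
    def test_matches_exact_enumeration(self, T, data):
        t = data.draw(st.integers(0, T))
        N = data.draw(st.integers(0, T))
        r = data.draw(st.integers(0, min(t, N)))
        exact = float(exact_hypergeom_tail(T, t, N, r))
        assert cn.hypergeom_p(T, t, N, r) == pytest.approx(exact, rel=1e-12, abs=1e-300)

    @given(st.integers(2, 50), st.data())
    def test_monotone_nonincreasing_in_r(self, T, data):
        t = data.draw(st.integers(1, T))
        N = data.draw(st.integers(1, T))
        probs = [cn.hypergeom_p(T, t, N, r) for r in range(min(t, N) + 1)]
        assert all(a >= b - 1e-15 for a, b in zip(probs, probs[1:]))


def _toy_interactions(rows):
    return InteractionSet(pd.DataFrame(rows, columns=["mirna_id", "target_id", "target_class"]))


class TestBuilder:
    def test_strong_shared_pair_retained(self):
        """One lncRNA and one mRNA sharing 5 DE miRNAs out of a universe of
        20 is kept at alpha=0.01 (p = 1/C(20,5) << 0.01)."""
        shared = [f"mir{i}" for i in range(5)]
        rows = [(m, "GENE", "mRNA") for m in shared] + [(m, "LNC", "lncRNA") for m in shared]
        # pad the universe with miRNAs wired elsewhere
        rows += [(f"bg{i}", f"OTHER{i}", "mRNA") for i in range(15)]
        iset = _toy_interactions(rows)
        de_mir = shared + [f"bg{i}" for i in range(15)]
        b = cn.CeRNANetworkBuilder(alpha=0.01).fit(
            iset, de_mir, ["GENE"] + [f"OTHER{i}" for i in range(15)], ["LNC"]
        )
        assert b.network_.has_edge("LNC", "GENE")
        edge = b.network_.edges["LNC", "GENE"]
        assert (edge["T"], edge["t"], edge["N"], edge["r"]) == (20, 5, 5, 5)
        assert edge["p_value"] == pytest.approx(1 / math.comb(20, 5), rel=1e-12)

    def test_zero_shared_pair_absent(self):
        rows = [("mir1", "GENE", "mRNA"), ("mir2", "LNC", "lncRNA")]
        b = cn.CeRNANetworkBuilder().fit(_toy_interactions(rows), ["mir1", "mir2"], ["GENE"], ["LNC"])
        assert b.network_.number_of_edges() == 0
        assert len(b.pairs_) == 0  # r = 0 pairs are never even candidates

    def test_empty_after_filter_warns_not_raises(self, caplog):
        rows = [("mir1", "GENE", "mRNA")]
        b = cn.CeRNANetworkBuilder().fit(_toy_interactions(rows), [], [], [])
        assert b.network_.number_of_edges() == 0

    def test_planted_pairs_recovered_and_match_brute_force(
        self, default_dataset, significant_features, cerna_builder
    ):
        """Retained edges contain every planted pair and equal an
        independent brute-force recomputation over all lncRNA x mRNA
        candidates."""
        net = cerna_builder.network_
        got = {
            (u, v) if net.nodes[u]["node_class"] == "lncRNA" else (v, u)
            for u, v in net.edges
        }
        assert set(map(tuple, default_dataset.truth.planted_pairs)) <= got

        # brute force: rebuild partner maps by hand from the raw edge table
        sig = significant_features
        edges = default_dataset.interactions.edges
        edges = edges[edges["mirna_id"].isin(sig["mirna"])]
        keep = (
            (edges["target_class"] == "mRNA") & edges["target_id"].isin(sig["mrna"])
        ) | ((edges["target_class"] == "lncRNA") & edges["target_id"].isin(sig["lncrna"]))
        edges = edges[keep]
        T = edges["mirna_id"].nunique()
        by_target = {
            (row.target_class, row.target_id): set()
            for row in edges.itertuples()
        }
        for row in edges.itertuples():
            by_target[(row.target_class, row.target_id)].add(row.mirna_id)
        expected = set()
        for (cls_l, lnc), lset in by_target.items():
            if cls_l != "lncRNA":
                continue
            for (cls_m, mrna), mset in by_target.items():
                if cls_m != "mRNA":
                    continue
                r = len(lset & mset)
                if r >= 1 and float(exact_hypergeom_tail(T, len(mset), len(lset), r)) < 0.01:
                    expected.add((lnc, mrna))
        assert got == expected

    def test_order_independent(self, default_dataset, significant_features):
        sig = significant_features
        shuffled = InteractionSet(
            default_dataset.interactions.edges.sample(frac=1, random_state=99)
        )
        a = cn.CeRNANetworkBuilder().fit(
            default_dataset.interactions, sig["mirna"], sig["mrna"], sig["lncrna"]
        )
        b = cn.CeRNANetworkBuilder().fit(shuffled, sig["mirna"], sig["mrna"], sig["lncrna"])
        assert set(a.network_.edges) == set(b.network_.edges)

    def test_alpha_one_keeps_every_candidate(self, default_dataset, significant_features):
        sig = significant_features
        b = cn.CeRNANetworkBuilder(alpha=1.0).fit(
            default_dataset.interactions, sig["mirna"], sig["mrna"], sig["lncrna"]
        )
        assert b.network_.number_of_edges() == len(b.pairs_)

    def test_edge_invariants(self, cerna_network):
        for u, v, d in cerna_network.edges(data=True):
            classes = {cerna_network.nodes[u]["node_class"], cerna_network.nodes[v]["node_class"]}
            assert classes == {"lncRNA", "mRNA"}
            assert d["r"] <= min(d["t"], d["N"]) <= max(d["t"], d["N"]) <= d["T"]
            assert len(d["shared_mirnas"]) == d["r"]
            assert 0 <= d["p_value"] < 0.01


class TestSubnetwork:
    def test_reference_lncrna_has_five_mirna_partners(self, reference_interactions):
        """The curated table gives RP11-96D1.10 exactly five miRNA
        partners, and its star sub-network restores them as nodes."""
        sub = mirna_partner_subnetwork(reference_interactions, "RP11-96D1.10")
        mirs = [n for n, d in sub.nodes(data=True) if d["node_class"] == "miRNA"]
        assert len(mirs) == 5
        assert sub.number_of_edges() == 5

    def test_triple_path_for_single_competitor(self):
        g = nx.Graph()
        g.add_node("LNC", node_class="lncRNA")
        g.add_node("GENE", node_class="mRNA")
        g.add_edge("LNC", "GENE", shared_mirnas=frozenset({"mirX"}))
        sub = cn.extract_subnetwork(g, "LNC")
        assert sorted(sub.nodes) == ["GENE", "LNC", "mirX"]
        assert sub.number_of_edges() == 2  # LNC-mirX-GENE path

    def test_unknown_lncrna_raises(self, cerna_network):
        with pytest.raises(KeyError):
            cn.extract_subnetwork(cerna_network, "NOT_A_NODE")

    def test_mirna_nodes_restored_from_annotations(self, cerna_network, default_dataset):
        lnc = default_dataset.truth.hub_lncrnas[0]
        sub = cn.extract_subnetwork(cerna_network, lnc)
        mirs = {n for n, d in sub.nodes(data=True) if d["node_class"] == "miRNA"}
        expected = set()
        for mrna in cerna_network.neighbors(lnc):
            expected |= set(cerna_network.edges[lnc, mrna]["shared_mirnas"])
        assert mirs == expected
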