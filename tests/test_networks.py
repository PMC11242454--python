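"""Network construction and topology: genus agglomeration, clr, the
three-way edge filter, modules, hubs and the Table-style metrics."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from rhizobiome import networks as nw
from rhizobiome.containers import FeatureTable

import oracles


def make_taxonomy(taxa, genus=None, order="Ord1"):
    genus = genus if genus is not None else list(taxa)
    return pd.DataFrame(
        {
            "domain": "Bacteria", "phylum": "Phy1", "class": "Cls1",
            "order": order, "family": "Fam1", "genus": genus,
        },
        index=pd.Index(taxa, name="taxon_id"),
    )


def graph_to_adj(g, weight="weight"):
    return {
        n: {v: float(d.get(weight, 1.0)) for v, d in g.adj[n].items()} for n in g.nodes
    }


class TestAgglomerateGenus:
    def test_same_genus_summed(self):
        t = FeatureTable(pd.DataFrame([[3, 5]], index=["s"], columns=["asv1", "asv2"]))
        tax = make_taxonomy(["asv1", "asv2"], genus=["Massilia", "Massilia"])
        out = nw.agglomerate_genus(t, tax)
        assert out.data.loc["s", "Massilia"] == 8

    def test_reads_conserved(self, dataset):
        out = nw.agglomerate_genus(dataset.table, dataset.taxonomy)
        np.testing.assert_allclose(
            out.data.sum(axis=1), dataset.table.data.sum(axis=1)
        )

    def test_unclassified_labelled_by_deepest_rank(self):
        t = FeatureTable(pd.DataFrame([[4]], index=["s"], columns=["asv1"]))
        tax = make_taxonomy(["asv1"], genus=[None], order="Vicinamibacterales")
        tax.loc["asv1", "family"] = None
        out = nw.agglomerate_genus(t, tax)
        assert out.taxon_ids == ["U. Vicinamibacterales"]

    def test_empty_lineage_rejected(self):
        t = FeatureTable(pd.DataFrame([[4]], index=["s"], columns=["asv1"]))
        tax = make_taxonomy(["asv1"]).map(lambda _: None)
        with pytest.raises(ValueError, match="empty lineage"):
            nw.agglomerate_genus(t, tax)


class TestClrTransform:
    def test_uniform_row_is_zero(self):
        t = FeatureTable(pd.DataFrame([[1, 1, 1, 1]], index=["s"]))
        np.testing.assert_allclose(nw.clr_transform(t).to_numpy(), 0.0)

    def test_rows_centred(self, rng):
        t = FeatureTable(pd.DataFrame(rng.integers(0, 100, size=(6, 9))))
        out = nw.clr_transform(t)
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-12)

    def test_two_part_hand_value(self):
        t = FeatureTable(pd.DataFrame([[9, 99]], index=["s"], columns=["a", "b"]))
        out = nw.clr_transform(t, pseudocount=1)
        assert out.loc["s", "a"] == pytest.approx(-1.1513, abs=1e-4)
        assert out.loc["s", "b"] == pytest.approx(+1.1513, abs=1e-4)


class TestCorrelationEdges:
    def test_collinear_pair_retained(self, rng):
        x = rng.normal(size=10)
        clr = pd.DataFrame({"a": x, "b": 2 * x, "c": rng.normal(size=10)})
        edges = nw.correlation_edges(clr, alpha=0.05, lfdr_max=1.0)
        pair = edges[(edges.source == "a") & (edges.target == "b")]
        assert len(pair) == 1
        assert pair.iloc[0].r == pytest.approx(1.0)

    def test_below_r_threshold_rejected_regardless_of_p(self, rng):
        # construct two columns with |r| just below 0.3 but huge n -> tiny p
        n = 5000
        x = rng.standard_normal(n)
        y = 0.25 * x + np.sqrt(1 - 0.25**2) * rng.standard_normal(n)
        r = np.corrcoef(x, y)[0, 1]
        y = y - (r - 0.25) * x  # nudge toward exactly 0.25
        clr = pd.DataFrame({"a": x, "b": y})
        edges = nw.correlation_edges(clr, r_min=0.3, alpha=0.5, lfdr_max=1.0)
        assert len(edges) == 0

    def test_planted_blocks_match_bruteforce(self, rng):
        """Two blocks of 10 genera: retained edges exactly the within-block
        pairs, verified against independent per-pair testing."""
        from scipy import stats as sps

        n = 40
        f1, f2 = rng.standard_normal(n), rng.standard_normal(n)
        cols = {}
        for j in range(10):
            cols[f"b1_{j}"] = 2.0 * f1 + 0.5 * rng.standard_normal(n)
        for j in range(10):
            cols[f"b2_{j}"] = 2.0 * f2 + 0.5 * rng.standard_normal(n)
        clr = pd.DataFrame(cols)
        edges = nw.correlation_edges(clr, r_min=0.3, alpha=1e-4, lfdr_max=1.0)
        got = {tuple(sorted(e)) for e in zip(edges.source, edges.target)}
        expected = set()
        names = list(cols)
        for i in range(20):
            for j in range(i + 1, 20):
                r, p = sps.pearsonr(clr[names[i]], clr[names[j]])
                if abs(r) >= 0.3 and p <= 1e-4:
                    expected.add(tuple(sorted((names[i], names[j]))))
        assert got == expected
        assert all(n1[:2] == n2[:2] for n1, n2 in got)  # within-block only

    def test_filter_is_monotone_conjunction(self, rng):
        clr = pd.DataFrame(rng.standard_normal((15, 8)))
        clr.columns = [f"g{j}" for j in range(8)]
        strict = nw.correlation_edges(clr, r_min=0.3, alpha=0.01, lfdr_max=0.2)
        for relaxed in (
            nw.correlation_edges(clr, r_min=0.0, alpha=0.01, lfdr_max=0.2),
            nw.correlation_edges(clr, r_min=0.3, alpha=1.0 - 1e-9, lfdr_max=0.2),
            nw.correlation_edges(clr, r_min=0.3, alpha=0.01, lfdr_max=1.0),
        ):
            strict_pairs = set(zip(strict.source, strict.target))
            relaxed_pairs = set(zip(relaxed.source, relaxed.target))
            assert strict_pairs <= relaxed_pairs

    def test_zero_variance_genus_excluded_with_warning(self, rng):
        clr = pd.DataFrame({"a": rng.normal(size=8), "flat": np.zeros(8)})
        with pytest.warns(UserWarning, match="zero-variance"):
            edges = nw.correlation_edges(clr, alpha=0.5, lfdr_max=1.0)
        assert "flat" not in set(edges.source) | set(edges.target)


class TestDetectModules:
    def test_two_disconnected_cliques(self):
        g = nx.Graph()
        for offset, names in ((0, "abcd"), (1, "wxyz")):
            for i, u in enumerate(names):
                for v in names[i + 1 :]:
                    g.add_edge(u, v, weight=1.0)
        modules, q = nw.detect_modules(g)
        assert len(set(modules.values())) == 2
        assert {frozenset(n for n, m in modules.items() if m == mid)
                for mid in set(modules.values())} == {frozenset("abcd"), frozenset("wxyz")}

    def test_barbell_matches_exhaustive_partition_search(self):
        g = nx.barbell_graph(3, 0)  # two triangles joined by one edge
        nx.set_edge_attributes(g, 1.0, "weight")
        modules, q = nw.detect_modules(g)
        q_best, part_best = oracles.best_partition_oracle(graph_to_adj(g))
        assert q == pytest.approx(q_best, abs=1e-12)
        found = {frozenset(n for n, m in modules.items() if m == mid)
                 for mid in set(modules.values())}
        assert found == {frozenset(p) for p in part_best}

    def test_empty_network_has_missing_q(self):
        modules, q = nw.detect_modules(nx.Graph())
        assert modules == {} and q is None


class TestHubTaxa:
    def test_star_centre_is_sole_hub(self):
        g = nx.star_graph(5)
        nx.set_edge_attributes(g, 1.0, "weight")
        assert nw.hub_taxa(g) == {0}

    def test_regular_ring_has_no_hubs(self):
        g = nx.cycle_graph(8)
        nx.set_edge_attributes(g, 1.0, "weight")
        assert nw.hub_taxa(g) == set()

    def test_planted_hub_matches_power_iteration(self, rng):
        g = nx.erdos_renyi_graph(20, 0.15, seed=7)
        hub = 0
        for v in range(1, 15):
            g.add_edge(hub, v)
        for u, v in g.edges:
            g[u][v]["weight"] = float(rng.uniform(0.5, 1.0))
        got = nw.hub_taxa(g, quantile=0.95)
        comp = max(nx.connected_components(g), key=len)
        cent = oracles.eigenvector_centrality_oracle(graph_to_adj(g.subgraph(comp)))
        values = np.array(list(cent.values()))
        cutoff = np.quantile(values, 0.95)
        expected = {n for n, s in cent.items() if s > cutoff}
        assert got == expected


class TestNaturalConnectivity:
    def test_edgeless_graph_zero(self):
        g = nx.empty_graph(5)
        assert nw.natural_connectivity(g, normalized=False) == 0.0

    def test_strictly_decreases_on_edge_deletion(self, rng):
        for seed in range(5):
            g = nx.gnm_random_graph(10, 20, seed=seed)
            if not nx.is_connected(g):
                continue
            base = nw.natural_connectivity(g, normalized=False)
            h = g.copy()
            edge = list(h.edges)[int(rng.integers(h.number_of_edges()))]
            h.remove_edge(*edge)
            assert nw.natural_connectivity(h, normalized=False) < base


class TestNetworkProperties:
    def _net(self, g, edges_df=None, universe=None):
        if edges_df is None:
            rows = [{"source": u, "target": v, "r": g[u][v].get("r", 1.0),
                     "p": 0.0, "lfdr": 0.0} for u, v in g.edges]
            edges_df = pd.DataFrame(rows, columns=["source", "target", "r", "p", "lfdr"])
        net = nw.AssociationNetwork(
            graph=g, edges=edges_df, node_universe=universe or list(g.nodes)
        )
        net.modules, net.modularity = nw.detect_modules(net)
        return net

    def test_complete_graph_closed_forms(self):
        g = nx.complete_graph(5)
        nx.set_edge_attributes(g, 1.0, "weight")
        props = nw.network_properties(self._net(g))
        assert props.clustering_coefficient == pytest.approx(1.0)
        assert props.edge_density == pytest.approx(1.0)
        assert props.average_path_length == pytest.approx(1.0)
        assert props.positive_edge_pct == pytest.approx(100.0)

    def test_path_graph_average_path_length(self):
        g = nx.path_graph(3)
        nx.set_edge_attributes(g, 1.0, "weight")
        props = nw.network_properties(self._net(g))
        assert props.average_path_length == pytest.approx(4.0 / 3.0)
        adj = {n: set(g.adj[n]) for n in g.nodes}
        assert props.average_path_length == pytest.approx(
            oracles.average_path_length_oracle(adj)
        )

    def test_components_counted_over_full_universe(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=1.0)
        universe = ["a", "b", "c", "d", "e"]
        props = nw.network_properties(self._net(g, universe=universe))
        assert props.n_components == 1 + 3  # one edge component + 3 isolated genera
        assert props.edge_density == pytest.approx(1 / 10)

    def test_invariant_to_node_relabeling(self, rng):
        g = nx.gnm_random_graph(8, 12, seed=3)
        nx.set_edge_attributes(g, 1.0, "weight")
        p1 = nw.network_properties(self._net(g.copy()))
        mapping = {n: f"node_{n}" for n in g.nodes}
        h = nx.relabel_nodes(g, mapping)
        p2 = nw.network_properties(self._net(h))
        for attr in ("n_components", "clustering_coefficient", "edge_density",
                     "robustness", "average_path_length", "n_modules"):
            assert getattr(p1, attr) == pytest.approx(getattr(p2, attr))


class TestCompareNetworks:
    def test_identical_tables_give_identical_networks(self, rng):
        n = 20
        f = rng.standard_normal(n)
        log_ab = np.tile(rng.normal(4, 0.3, 12), (n, 1))
        log_ab[:, :6] += 1.5 * f[:, None]
        log_ab += 0.3 * rng.standard_normal((n, 12))
        counts = np.round(np.exp(log_ab)).astype(int) + 1
        taxa = [f"g{j}" for j in range(12)]
        t = FeatureTable(pd.DataFrame(counts, index=[f"s{i}" for i in range(n)], columns=taxa))
        tax = make_taxonomy(taxa)
        cmp = nw.compare_networks({"g1": t, "g2": t.copy()}, tax, alpha=0.001)
        e1, e2 = cmp["networks"]["g1"].edges, cmp["networks"]["g2"].edges
        pd.testing.assert_frame_equal(e1, e2)
        assert cmp["core_hubs"] == cmp["networks"]["g1"].hubs
        assert all(len(s) == 0 for s in cmp["group_specific_hubs"].values())

    def test_small_group_skipped_with_warning(self, rng):
        taxa = [f"g{j}" for j in range(5)]
        big = FeatureTable(pd.DataFrame(
            rng.integers(1, 50, size=(10, 5)), index=[f"s{i}" for i in range(10)], columns=taxa))
        tiny = FeatureTable(pd.DataFrame(
            rng.integers(1, 50, size=(2, 5)), index=["x1", "x2"], columns=taxa))
        with pytest.warns(UserWarning, match="skipped"):
            cmp = nw.compare_networks({"big": big, "tiny": tiny}, make_taxonomy(taxa), alpha=0.5)
        assert "tiny" not in cmp["networks"]
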