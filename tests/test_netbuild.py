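"""Network assembly, differential merging, topology, ranking, augmentation."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from ppindiff import netbuild
from ppindiff.netbuild import (
    augment_for_flow,
    build_network,
    fit_power_law,
    merge_differential,
    rank_baits_by_rewiring,
    topology_metrics,
)


def interactions(rows):
    return pd.DataFrame(rows, columns=["bait", "prey", "mean_log2fc", "p_value"])


def calls(rows):
    return pd.DataFrame(rows, columns=["bait", "prey", "category"])


# ---------------------------------------------------------------- oracles
def brute_force_shortest_paths(g, s, t):
    """All shortest simple paths between s and t by exhaustive DFS."""
    paths = []
    stack = [(s, [s])]
    while stack:
        node, path = stack.pop()
        if node == t:
            paths.append(path)
            continue
        for nb in g.neighbors(node):
            if nb not in path:
                stack.append((nb, path + [nb]))
    if not paths:
        return []
    shortest = min(map(len, paths))
    return [p for p in paths if len(p) == shortest]


def brute_force_betweenness(g):
    n = g.number_of_nodes()
    if n < 3:
        return {v: 0.0 for v in g}
    scale = (n - 1) * (n - 2) / 2
    bc = {v: 0.0 for v in g}
    for s, t in itertools.combinations(g.nodes, 2):
        sps = brute_force_shortest_paths(g, s, t)
        if not sps:
            continue
        for v in g:
            if v in (s, t):
                continue
            through = sum(1 for p in sps if v in p)
            bc[v] += through / len(sps)
    return {v: x / scale for v, x in bc.items()}


def brute_force_clustering(g):
    out = {}
    for v in g:
        nbrs = list(g.neighbors(v))
        k = len(nbrs)
        if k < 2:
            out[v] = 0.0
            continue
        links = sum(1 for a, b in itertools.combinations(nbrs, 2) if g.has_edge(a, b))
        out[v] = 2 * links / (k * (k - 1))
    return out


# ------------------------------------------------------------------ tests
class TestBuild:
    def test_shared_prey_spoke_model(self):
        g = build_network(interactions([("B1", "P", 2.0, 0.01),
                                        ("B2", "P", 2.0, 0.01)]))
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 2
        assert g.nodes["P"]["type"] == "prey"

    def test_duplicates_keep_better_p(self):
        g = build_network(interactions([("B", "P", 1.0, 0.04),
                                        ("B", "P", 2.0, 0.001)]))
        assert g.number_of_edges() == 1
        assert g["B"]["P"]["p_value"] == 0.001
        assert g["B"]["P"]["mean_log2fc"] == 2.0

    def test_edge_count_conserved(self, recovery_screen):
        hi = recovery_screen["interactions"]["hi"]
        g = build_network(hi)
        assert g.number_of_edges() == len(hi.drop_duplicates(["bait", "prey"]))

    def test_empty_input_warns(self, caplog):
        with caplog.at_level("WARNING"):
            g = build_network(interactions([]))
        assert g.number_of_nodes() == 0


class TestMergeDifferential:
    def test_identical_networks_all_unchanged(self):
        rows = [("B", "P", 2.0, 0.01), ("B", "Q", 2.0, 0.01)]
        hi = build_network(interactions(rows))
        lo = build_network(interactions(rows))
        d = merge_differential(hi, lo, calls([("B", "P", "unchanged"),
                                              ("B", "Q", "unchanged")]))
        assert netbuild.category_counts(d) == {"unchanged": 2}

    def test_counts_partition_union(self, recovery_screen):
        hi = build_network(recovery_screen["interactions"]["hi"])
        lo = build_network(recovery_screen["interactions"]["lo"])
        d = merge_differential(hi, lo, recovery_screen["calls"])
        assert sum(netbuild.category_counts(d).values()) == d.number_of_edges()

    def test_uncovered_edge_raises(self):
        hi = build_network(interactions([("B", "P", 2.0, 0.01)]))
        with pytest.raises(ValueError, match="no rewiring call"):
            merge_differential(hi, nx.Graph(), calls([]))


class TestTopology:
    def test_triangle(self):
        g = nx.complete_graph(3)
        rep = topology_metrics(g)
        assert np.allclose(rep["nodes"]["clustering"], 1.0)
        assert np.allclose(rep["nodes"]["betweenness"], 0.0)

    def test_three_node_path_middle_betweenness(self):
        g = nx.path_graph(3)
        rep = topology_metrics(g)
        assert rep["nodes"].loc[1, "betweenness"] == pytest.approx(1.0)

    def test_star_graph(self):
        g = nx.star_graph(10)  # hub 0 plus 10 leaves
        rep = topology_metrics(g)
        assert rep["nodes"].loc[0, "degree"] == 10
        assert rep["nodes"].loc[0, "betweenness"] == pytest.approx(1.0)
        assert (rep["nodes"].loc[1:, "clustering"] == 0).all()
        assert rep["network"]["avg_path_length"] == pytest.approx(
            (10 * 1 + 45 * 2) / 55
        )

    def test_matches_brute_force_on_random_small_graphs(self):
        rng = np.random.default_rng(17)
        for _ in range(40):
            n = int(rng.integers(3, 9))
            g = nx.gnp_random_graph(n, 0.45, seed=int(rng.integers(1 << 30)))
            if g.number_of_edges() == 0:
                continue
            rep = topology_metrics(g)
            bc = brute_force_betweenness(g)
            cc = brute_force_clustering(g)
            for v in g:
                assert rep["nodes"].loc[v, "betweenness"] == pytest.approx(bc[v], abs=1e-9)
                assert rep["nodes"].loc[v, "clustering"] == pytest.approx(cc[v], abs=1e-9)

    def test_power_law_fit_on_exact_power_law_counts(self):
        # construct degree data whose log-log regression slope is exactly -2
        degrees = []
        for k in (1, 2, 4, 8):
            degrees.extend([k] * int(1024 / k**2))
        alpha, r2 = fit_power_law(degrees)
        assert alpha == pytest.approx(2.0, abs=1e-6)
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_single_node_network(self):
        g = nx.Graph()
        g.add_node("x")
        with pytest.warns(UserWarning):
            rep = topology_metrics(g)
        assert rep["network"]["avg_path_length"] == 0.0


class TestRanking:
    def diffnet(self, edge_cats):
        g = nx.Graph()
        for bait, prey, cat in edge_cats:
            g.add_node(bait, type="bait")
            g.add_node(prey, type="prey")
            g.add_edge(bait, prey, category=cat)
        return g

    def test_counts_and_order(self):
        g = self.diffnet(
            [("A", f"P{i}", "hi_only") for i in range(5)]
            + [("B", f"Q{i}", "lo_only") for i in range(3)]
            + [("C", "R0", "unchanged")]
        )
        out = rank_baits_by_rewiring(g, 3)
        assert list(out["bait"]) == ["A", "B", "C"]
        assert list(out["n_rewired"]) == [5, 3, 0]

    def test_no_rewiring_is_stable_lexicographic(self):
        g = self.diffnet([(b, f"P{b}", "unchanged") for b in "CAB"])
        out = rank_baits_by_rewiring(g, 3)
        assert list(out["bait"]) == ["A", "B", "C"]

    def test_hi_enhanced_mode_ignores_lo_categories(self):
        g = self.diffnet([("A", "P", "lo_only"), ("B", "Q", "shared_up_hi")])
        out = rank_baits_by_rewiring(g, 2, hi_enhanced_only=True)
        assert out.set_index("bait")["n_rewired"].to_dict() == {"A": 0, "B": 1}

    def test_k_larger_than_baits_warns_and_returns_all(self, caplog):
        g = self.diffnet([("A", "P", "hi_only")])
        with caplog.at_level("WARNING"):
            out = rank_baits_by_rewiring(g, 10)
        assert len(out) == 1


class TestAugment:
    def base(self):
        return build_network(interactions([("B1", "P1", 2.0, 0.01),
                                           ("B1", "P2", 2.0, 0.01)]))

    def test_empty_extras_identity(self):
        g = self.base()
        out = augment_for_flow(g, [])
        assert nx.utils.graphs_equal(out, g)

    def test_existing_edge_merges_provenance(self):
        out = augment_for_flow(self.base(), [("B1", "P1")])
        assert out.number_of_edges() == 2
        assert out["B1"]["P1"]["source"] == "apms+external"

    def test_new_triangle_raises_clustering(self):
        g = self.base()
        before = topology_metrics(g)["nodes"].loc["P1", "clustering"]
        out = augment_for_flow(g, [("P1", "P2")])
        after = topology_metrics(out)["nodes"].loc["P1", "clustering"]
        assert after > before

    def test_dangling_endpoint_raises(self):
        with pytest.raises(ValueError, match="unknown nodes"):
            augment_for_flow(self.base(), [("P1", "GHOST")])

    def test_extra_nodes_are_retained_even_if_isolated(self):
        out = augment_for_flow(self.base(), [], extra_nodes=["LONER"])
        assert "LONER" in out and out.degree("LONER") == 0
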