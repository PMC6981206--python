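"""Condition networks, the merged differential network, and topology.

Networks are undirected spoke-model graphs (bait connected to each retained
prey; AP-MS gives no edge direction and no prey-prey evidence), held as
:class:`networkx.Graph` with typed nodes and attributed edges.  Topology
metrics follow the conventions of standard network-analysis tools:
normalised Brandes betweenness, triangle-fraction clustering, average
shortest-path length over the largest component, and a degree-distribution
power-law exponent fit by least squares on log10 P(k) vs log10 k (a
maximum-likelihood fit is available as an alternative).
"""

from __future__ import annotations

import logging
import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def build_network(interactions: pd.DataFrame) -> nx.Graph:
    """Spoke-model graph from filtered interaction statistics.

    Duplicate (bait, prey) rows collapse to a single edge keeping the
    attributes of the row with the better P value.
    """
    g = nx.Graph()
    if interactions.empty:
        logger.warning("build_network: empty interaction set -> empty network")
        return g
    best = (
        interactions.sort_values("p_value", kind="stable")
        .drop_duplicates(["bait", "prey"], keep="first")
    )
    for row in best.itertuples(index=False):
        for node, role in ((row.bait, "bait"), (row.prey, "prey")):
            if node in g:
                if g.nodes[node]["type"] != role:
                    g.nodes[node]["type"] = "both"
            else:
                g.add_node(node, type=role)
        if row.bait != row.prey:
            g.add_edge(
                row.bait,
                row.prey,
                mean_log2fc=float(row.mean_log2fc),
                p_value=float(row.p_value),
                source="apms",
            )
    logger.info(
        "build_network: %d nodes, %d edges from %d interactions",
        g.number_of_nodes(),
        g.number_of_edges(),
        len(interactions),
    )
    return g


def merge_differential(
    net_hi: nx.Graph, net_lo: nx.Graph, calls: pd.DataFrame
) -> nx.Graph:
    """Union graph of the two condition networks with per-edge categories."""
    lookup = {
        (r.bait, r.prey): r.category for r in calls.itertuples(index=False)
    }
    merged = nx.Graph()
    for net, cond in ((net_hi, "hi"), (net_lo, "lo")):
        for node, data in net.nodes(data=True):
            if node in merged and merged.nodes[node]["type"] != data.get("type"):
                merged.nodes[node]["type"] = "both"
            elif node not in merged:
                merged.add_node(node, type=data.get("type", "prey"))
        for u, v, data in net.edges(data=True):
            key = (u, v) if (u, v) in lookup else (v, u)
            if key not in lookup:
                raise ValueError(f"edge {(u, v)} has no rewiring call")
            if merged.has_edge(u, v):
                merged[u][v]["presence"] = "both"
            else:
                merged.add_edge(
                    u,
                    v,
                    category=lookup[key],
                    presence=cond,
                    mean_log2fc=data.get("mean_log2fc", 0.0),
                )
    counts = category_counts(merged)
    logger.info("merge_differential: category counts %s", counts)
    return merged


def category_counts(diff_net: nx.Graph) -> dict:
    counts: dict = {}
    for _, _, data in diff_net.edges(data=True):
        counts[data["category"]] = counts.get(data["category"], 0) + 1
    return counts


def fit_power_law(degrees, method: str = "loglog"):
    """Degree-distribution scale-freeness fit.

    ``loglog`` (default) regresses log10 P(k) on log10 k over degrees >= 1
    with nonzero counts, returning (exponent, r_squared); ``mle`` returns
    the continuous maximum-likelihood (Hill) exponent with r_squared NaN.
    """
    k = np.asarray([d for d in degrees if d >= 1], dtype=float)
    if k.size == 0:
        return float("nan"), float("nan")
    if method == "mle":
        kmin = k.min()
        alpha = 1.0 + k.size / np.sum(np.log(k / (kmin - 0.5)))
        return float(alpha), float("nan")
    values, counts = np.unique(k, return_counts=True)
    pk = counts / counts.sum()
    if len(values) < 2:
        return float("nan"), float("nan")
    res = stats.linregress(np.log10(values), np.log10(pk))
    return float(-res.slope), float(res.rvalue**2)


def topology_metrics(net: nx.Graph) -> dict:
    """Node-level and network-level topology report.

    Returns ``{"nodes": DataFrame(degree, betweenness, clustering),
    "network": {...}}``.  Betweenness is normalised by (n-1)(n-2)/2;
    average path length is computed over the largest connected component;
    single-node networks report zero metrics with a warning.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("topology_metrics requires a non-empty network")
    if net.number_of_nodes() == 1:
        warnings.warn("single-node network: metrics defined as 0")
        node = next(iter(net.nodes))
        return {
            "nodes": pd.DataFrame(
                {"degree": [0], "betweenness": [0.0], "clustering": [0.0]},
                index=[node],
            ),
            "network": {
                "n_nodes": 1,
                "n_edges": 0,
                "n_components": 1,
                "avg_path_length": 0.0,
                "powerlaw_exponent": float("nan"),
                "powerlaw_r2": float("nan"),
            },
        }
    degree = dict(net.degree())
    bc = nx.betweenness_centrality(net, normalized=True)
    cc = nx.clustering(net)
    nodes = pd.DataFrame(
        {
            "degree": pd.Series(degree),
            "betweenness": pd.Series(bc),
            "clustering": pd.Series(cc),
        }
    )
    components = list(nx.connected_components(net))
    giant = net.subgraph(max(components, key=len))
    apl = (
        nx.average_shortest_path_length(giant)
        if giant.number_of_nodes() > 1
        else 0.0
    )
    exponent, r2 = fit_power_law(nodes["degree"].to_numpy())
    return {
        "nodes": nodes,
        "network": {
            "n_nodes": net.number_of_nodes(),
            "n_edges": net.number_of_edges(),
            "n_components": len(components),
            "avg_path_length": float(apl),
            "powerlaw_exponent": exponent,
            "powerlaw_r2": r2,
        },
    }


def rank_baits_by_rewiring(
    diff: nx.Graph, k: int, hi_enhanced_only: bool = False
) -> pd.DataFrame:
    """Baits ordered by their number of rewired incident edges.

    ``hi_enhanced_only`` counts only interactions gained or enhanced in the
    hi condition (hi_only, shared_up_hi).  Ties break lexicographically by
    bait identifier for reproducibility.
    """
    wanted = (
        {"hi_only", "shared_up_hi"}
        if hi_enhanced_only
        else {"hi_only", "lo_only", "shared_up_hi", "shared_up_lo"}
    )
    baits = [n for n, d in diff.nodes(data=True) if d.get("type") in ("bait", "both")]
    counts = {b: 0 for b in baits}
    for u, v, data in diff.edges(data=True):
        if data.get("category") in wanted:
            for node in (u, v):
                if node in counts:
                    counts[node] += 1
    table = pd.DataFrame(
        {"bait": list(counts), "n_rewired": list(counts.values())}
    ).sort_values(["n_rewired", "bait"], ascending=[False, True], kind="stable")
    if k > len(table):
        logger.warning(
            "rank_baits_by_rewiring: k=%d exceeds %d baits; returning all",
            k,
            len(table),
        )
        k = len(table)
    return table.head(k).reset_index(drop=True)


def augment_for_flow(
    net: nx.Graph, extra_edges, extra_nodes=()
) -> nx.Graph:
    """Union of the AP-MS network with external (e.g. prey-prey) edges.

    ``extra_edges`` is an iterable of (u, v) pairs; endpoints must exist in
    the network or in ``extra_nodes`` (dangling endpoints raise).  Existing
    edges get merged provenance rather than duplication; disconnected extra
    nodes are retained.
    """
    out = net.copy()
    allowed = set(out.nodes) | set(extra_nodes)
    edges = [tuple(e) for e in extra_edges]
    dangling = sorted(
        {n for e in edges for n in e if n not in allowed}
    )
    if dangling:
        raise ValueError(f"augmentation edges reference unknown nodes: {dangling[:10]}")
    for node in extra_nodes:
        if node not in out:
            out.add_node(node, type="external")
    for u, v in edges:
        if u == v:
            continue
        if out.has_edge(u, v):
            src = out[u][v].get("source", "apms")
            if "external" not in src:
                out[u][v]["source"] = src + "+external"
        else:
            out.add_edge(u, v, source="external")
    return out
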