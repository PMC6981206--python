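"""Channel-mode damped random-walk information flow.

A discrete-time random walk starts at a source node, survives each step
with probability ``damping`` (signal dissipation), moves to a uniformly
chosen neighbour (optionally weight-proportional), and is absorbed on
first arrival at any sink.  With ``P`` the row-stochastic transition
operator and ``Q = damping * P`` restricted to transient (non-sink) nodes,
the unconditioned expected visit counts from source ``s`` are row ``s`` of
``(I - Q)^-1``, and the probability of eventual absorption at any sink
before dissipation is the harmonic-like function

.. math:: h(v) = d\\,\\bigl(P_{v\\to\\text{sinks}}\\mathbf{1}
                 + \\sum_{u\\ \\text{transient}} P_{vu}\\,h(u)\\bigr).

The channel model conditions on absorption: the information-flow score of
a transient node is ``IFS(v) = visits(s -> v) * h(v) / h(s)`` (the
expected visits of walks that do reach a sink), and each sink's score is
its conditioned absorption mass, so sink scores sum to one.  The initial
placement at the source counts as one visit, hence ``IFS(source) >= 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve


@dataclass
class FlowConfig:
    """Source, sinks and per-step survival probability of the walk."""

    source: str
    sinks: list = field(default_factory=list)
    damping: float = 0.85
    weight: str | None = None  # edge attribute for weighted transitions

    def validate(self) -> None:
        if not self.sinks:
            raise ValueError("sinks must be non-empty")
        if self.source in self.sinks:
            raise ValueError("source must not be a sink")
        if not 0 < self.damping <= 1:
            raise ValueError("damping must be in (0, 1]")


def _transition_matrix(net: nx.Graph, nodes: list, weight: str | None):
    """Row-stochastic transition operator (rows of isolated nodes are zero)."""
    index = {n: i for i, n in enumerate(nodes)}
    rows, cols, vals = [], [], []
    for u in nodes:
        nbrs = list(net.neighbors(u))
        if not nbrs:
            continue
        if weight:
            w = np.array([net[u][v].get(weight, 1.0) for v in nbrs], dtype=float)
        else:
            w = np.ones(len(nbrs))
        w = w / w.sum()
        rows.extend([index[u]] * len(nbrs))
        cols.extend(index[v] for v in nbrs)
        vals.extend(w.tolist())
    n = len(nodes)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def ifs_scores(net: nx.Graph, cfg: FlowConfig) -> pd.DataFrame:
    """Information-flow scores for every node of one condition network.

    Returns a frame indexed by node with columns ``ifs`` (conditioned
    expected visits for transient nodes, conditioned absorption mass for
    sinks), ``ifs_normalized`` (share of total network flow, summing to 1),
    and ``is_sink``.  Deterministic; raises if any sink is unreachable
    from the source.
    """
    cfg.validate()
    missing = [n for n in [cfg.source, *cfg.sinks] if n not in net]
    if missing:
        raise ValueError(f"nodes absent from network: {missing}")
    reachable = nx.node_connected_component(net, cfg.source)
    unreachable = [t for t in cfg.sinks if t not in reachable]
    if unreachable:
        raise ValueError(f"sinks unreachable from source: {unreachable}")

    nodes = list(net.nodes)
    sinks = set(cfg.sinks)
    transient = [n for n in nodes if n not in sinks]
    t_index = {n: i for i, n in enumerate(transient)}
    d = cfg.damping

    P = _transition_matrix(net, nodes, cfg.weight)
    full_index = {n: i for i, n in enumerate(nodes)}
    t_rows = [full_index[n] for n in transient]
    s_rows = [full_index[n] for n in cfg.sinks]
    Ptt = P[t_rows, :][:, t_rows]
    Pts = P[t_rows, :][:, s_rows]

    nt = len(transient)
    A = sp.identity(nt, format="csc") - d * Ptt.tocsc()
    s = t_index[cfg.source]

    # expected visits from the source: row s of (I - Q)^-1
    e_s = np.zeros(nt)
    e_s[s] = 1.0
    visits = spsolve(A.T.tocsc(), e_s)

    # absorption probability before dissipation: (I - d Ptt) h = d Pts 1
    h = spsolve(A, d * np.asarray(Pts.sum(axis=1)).ravel())
    h_s = h[s]
    if h_s <= 0:
        raise ValueError("source cannot reach any sink before dissipation")

    ifs = {n: float(visits[i] * h[i] / h_s) for n, i in t_index.items()}
    # conditioned absorption mass per sink
    absorb = d * (visits @ Pts) / h_s
    for t, a in zip(cfg.sinks, absorb):
        ifs[t] = float(a)

    table = pd.DataFrame(
        {
            "ifs": pd.Series(ifs),
            "is_sink": pd.Series({n: n in sinks for n in nodes}),
        }
    ).loc[nodes]
    total = table["ifs"].sum()
    table["ifs_normalized"] = table["ifs"] / total if total > 0 else 0.0
    return table


def differential_ifs(
    table_hi: pd.DataFrame,
    table_lo: pd.DataFrame,
    node_fold: float = 2.0,
    tf_fold: float = 1.2,
) -> dict:
    """Compare normalised flow between two condition networks.

    Nodes present in both tables are flagged when their normalised-score
    ratio exceeds ``node_fold`` in either direction; sink nodes
    (transcription factors) are flagged separately at the laxer
    ``tf_fold``.  Nodes scored in only one network are listed as exclusive
    rather than folded; zero scores in one condition give infinite ratios
    with a flag.
    """
    shared = table_hi.index.intersection(table_lo.index)
    hi = table_hi.loc[shared, "ifs_normalized"].to_numpy(float)
    lo = table_lo.loc[shared, "ifs_normalized"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(lo > 0, hi / lo, np.inf)
        ratio = np.where((lo == 0) & (hi == 0), 1.0, ratio)
    report = pd.DataFrame(
        {
            "ifs_hi": hi,
            "ifs_lo": lo,
            "ratio_hi_vs_lo": ratio,
            "is_sink": table_hi.loc[shared, "is_sink"].to_numpy(bool),
        },
        index=shared,
    )
    report["infinite"] = ~np.isfinite(ratio)
    up = report["ratio_hi_vs_lo"] > node_fold
    down = report["ratio_hi_vs_lo"] < 1.0 / node_fold
    report["node_flag"] = up | down
    report["direction"] = np.where(up, "hi", np.where(down, "lo", ""))
    tf = report["is_sink"]
    report["tf_flag"] = tf & (
        (report["ratio_hi_vs_lo"] >= tf_fold)
        | (report["ratio_hi_vs_lo"] <= 1.0 / tf_fold)
    )
    return {
        "report": report,
        "flagged_nodes": report[report["node_flag"]],
        "flagged_tfs": report[report["tf_flag"]],
        "exclusive_hi": sorted(table_hi.index.difference(table_lo.index)),
        "exclusive_lo": sorted(table_lo.index.difference(table_hi.index)),
    }
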