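"""Monte-Carlo oracle for channel-mode information flow.

Simulates damped random walks step by step (survive with probability
``damping``, move to a uniform neighbour, absorb on arrival at a sink)
and estimates conditioned visit counts and absorption splits directly
from walk trajectories — fully independent of the linear-algebra
implementation it cross-checks.
"""

from __future__ import annotations

import numpy as np


def simulate_channel_walks(net, source, sinks, damping, n_walks, seed, chunk=200_000):
    """Empirical conditioned visit counts from ``n_walks`` damped walks.

    Returns ``(visit_means, absorbed_fraction)``: mean per-node visit
    counts among walks that reached a sink (the channel conditioning), and
    each sink's share of absorbed walks.
    """
    nodes = list(net.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    nbrs = [np.array([index[v] for v in net.neighbors(n)], dtype=np.int64) for n in nodes]
    sink_idx = np.array(sorted(index[t] for t in sinks), dtype=np.int64)
    sink_mask = np.zeros(len(nodes), dtype=bool)
    sink_mask[sink_idx] = True
    src = index[source]
    rng = np.random.default_rng(seed)

    total_counts = np.zeros(len(nodes))
    n_absorbed = 0
    sink_hits = np.zeros(len(nodes))
    done = 0
    while done < n_walks:
        m = min(chunk, n_walks - done)
        done += m
        cur = np.full(m, src, dtype=np.int64)
        alive = np.ones(m, dtype=bool)
        absorbed_at = np.full(m, -1, dtype=np.int64)
        counts = np.zeros((m, len(nodes)), dtype=np.int32)
        counts[:, src] = 1
        while alive.any():
            a = np.flatnonzero(alive)
            survive = rng.random(a.size) < damping
            alive[a[~survive]] = False
            a = a[survive]
            if a.size == 0:
                break
            curs = cur[a]
            for node in np.unique(curs):
                sel = a[curs == node]
                nb = nbrs[node]
                if nb.size == 0:
                    alive[sel] = False
                    continue
                cur[sel] = nb[rng.integers(0, nb.size, sel.size)]
            a = a[alive[a]]
            counts[a, cur[a]] += 1
            hit = sink_mask[cur[a]]
            hit_walkers = a[hit]
            absorbed_at[hit_walkers] = cur[hit_walkers]
            alive[hit_walkers] = False
        ok = absorbed_at >= 0
        n_absorbed += int(ok.sum())
        total_counts += counts[ok].sum(axis=0)
        np.add.at(sink_hits, absorbed_at[ok], 1)
    if n_absorbed == 0:
        raise RuntimeError("no walk reached a sink")
    visit_means = {n: total_counts[i] / n_absorbed for n, i in index.items()}
    absorbed_fraction = {
        n: sink_hits[index[n]] / n_absorbed for n in nodes if sink_mask[index[n]]
    }
    return visit_means, absorbed_fraction
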