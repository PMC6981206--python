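"""Hypergeometric enrichment and protein-complex coverage.

Enrichment of a property set (e.g. differentially abundant proteins)
within a focal set (e.g. network nodes) against an assayed background of
size N uses the exact upper-tail hypergeometric probability

.. math:: p(X \\ge k) = \\sum_{x=k}^{\\min(n, K)}
          \\frac{\\binom{K}{x}\\binom{N-K}{n-x}}{\\binom{N}{n}},

evaluated in log space for numerical stability.  Complex coverage reports,
per complex, the fraction of members present in a network and the
fraction of present members that are rewired preys.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentInput:
    """Counts of the 2x2 sampling design behind the hypergeometric test.

    N: assayed background; n: property-set size; K: focal-set size among
    the assayed; k: overlap of property and focal sets.
    """

    N: int
    n: int
    K: int
    k: int

    def validate(self) -> None:
        if not (0 <= self.n <= self.N and 0 <= self.K <= self.N):
            raise ValueError("require 0 <= n <= N and 0 <= K <= N")
        if not 0 <= self.k <= min(self.n, self.K):
            raise ValueError("require 0 <= k <= min(n, K)")
        if self.k < self.n + self.K - self.N:
            raise ValueError("k below the minimum possible overlap n + K - N")


def _log_binom(a, b):
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def hypergeom_upper(inp: EnrichmentInput) -> float:
    """Exact upper-tail probability p(X >= k), computed in log space."""
    inp.validate()
    N, n, K, k = inp.N, inp.n, inp.K, inp.k
    if k == 0:
        return 1.0
    x = np.arange(k, min(n, K) + 1)
    log_terms = _log_binom(K, x) + _log_binom(N - K, n - x) - _log_binom(N, n)
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def set_enrichment(background, property_set, focal_set):
    """Construct hypergeometric counts by set intersection and test.

    Elements of the property or focal sets outside the background are
    trimmed with a warning.  Returns ``(EnrichmentInput, p)``.
    """
    bg = set(background)
    if not bg:
        raise ValueError("background must be non-empty")
    prop, focal = set(property_set), set(focal_set)
    trimmed = (len(prop - bg), len(focal - bg))
    if any(trimmed):
        logger.warning(
            "set_enrichment: trimmed %d property / %d focal elements outside "
            "the background",
            *trimmed,
        )
    prop &= bg
    focal &= bg
    inp = EnrichmentInput(
        N=len(bg), n=len(prop), K=len(focal), k=len(prop & focal)
    )
    return inp, hypergeom_upper(inp)


def complex_coverage(
    complex_defs: dict,
    net: nx.Graph,
    rewired_preys,
    presence_min: float = 0.7,
    rewired_min: float = 0.6,
) -> pd.DataFrame:
    """Per-complex network presence and rewired-member fractions.

    ``presence_fraction`` = members present in the network / all members
    (flagged inclusively at ``presence_min``); ``rewired_fraction`` =
    rewired preys among *present* members (flagged strictly above
    ``rewired_min``).  Empty member lists are skipped with a warning.
    """
    rewired = set(rewired_preys)
    nodes = set(net.nodes)
    rows = []
    for name, members in complex_defs.items():
        members = list(dict.fromkeys(members))
        if not members:
            logger.warning("complex %s has no members; skipped", name)
            continue
        present = [m for m in members if m in nodes]
        presence = len(present) / len(members)
        rewired_frac = (
            len([m for m in present if m in rewired]) / len(present)
            if present
            else 0.0
        )
        rows.append(
            (
                name,
                len(members),
                presence,
                rewired_frac,
                presence >= presence_min,
                rewired_frac > rewired_min,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "complex",
            "n_members",
            "presence_fraction",
            "rewired_fraction",
            "present_flag",
            "rewired_flag",
        ],
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values for batch enrichment runs."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
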