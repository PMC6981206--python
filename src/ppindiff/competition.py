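"""Equilibrium competition of effectors for a single GTPase binding site.

Active KRAS presents one shared effector-binding interface, so effectors
with totals :math:`E_{i,T}` and dissociation constants :math:`K_i` compete
for a common pool :math:`R_T` of active KRAS.  At equilibrium the free
KRAS concentration :math:`r` is the unique root in :math:`(0, R_T]` of

.. math:: R_T = r \\Bigl(1 + \\sum_i \\frac{E_{i,T}}{K_i + r}\\Bigr),

and each complex is :math:`C_i = r\\,E_{i,T} / (K_i + r)`.  Effectors are
"high affinity" when :math:`K_i` is below the active-KRAS abundance and
"low affinity" above it; in the low-affinity regime :math:`C_i \\approx
r\\,E_{i,T}/K_i`, so raising KRAS dosage changes low-affinity complexes
proportionally more — the dose fold-change of bound fraction increases
with :math:`K_i`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass
class EffectorSpec:
    """One competing effector: totals and affinity in nM."""

    name: str
    total_conc: float  # nM
    kd: float  # nM
    pathway: str | None = None

    def validate(self) -> None:
        if self.total_conc <= 0 or self.kd <= 0:
            raise ValueError(f"effector {self.name}: total_conc and kd must be > 0")


@dataclass
class KrasContext:
    """Abundance of active KRAS (nM). Defaults: lo ~150 nM, hi ~400 nM."""

    r_total: float = 150.0

    def validate(self) -> None:
        if self.r_total <= 0:
            raise ValueError("r_total must be > 0")


LO_CONTEXT = KrasContext(150.0)
HI_CONTEXT = KrasContext(400.0)


@dataclass
class CompetitionResult:
    r_free: float
    complexes: dict = field(default_factory=dict)
    bound_fraction: dict = field(default_factory=dict)
    affinity_class: dict = field(default_factory=dict)


def solve_equilibrium(
    effectors: list[EffectorSpec], ctx: KrasContext, tol: float = 1e-12
) -> CompetitionResult:
    """Solve the single-site competition equilibrium by bracketed root finding.

    The conservation function is strictly increasing in the free
    concentration, so the root is bracketed in (0, r_total] and located
    with Brent's method, giving mass conservation to solver tolerance for
    KRAS and, by construction, exactly for each effector.
    """
    ctx.validate()
    for e in effectors:
        e.validate()
    if tol <= 0:
        raise ValueError("tol must be > 0")
    names = [e.name for e in effectors]
    et = np.array([e.total_conc for e in effectors], dtype=float)
    kd = np.array([e.kd for e in effectors], dtype=float)
    rt = ctx.r_total

    if not effectors:
        return CompetitionResult(r_free=rt)

    def conservation(r):
        return r * (1.0 + np.sum(et / (kd + r))) - rt

    lo = rt * 1e-16
    if conservation(lo) > 0:  # pathological only for absurd inputs
        lo = rt * 1e-308
    r_free = optimize.brentq(conservation, lo, rt, xtol=tol * rt, maxiter=500)
    residual = abs(conservation(r_free)) / rt
    if residual > max(1e-9, tol):
        raise RuntimeError(
            f"equilibrium solver did not converge: relative residual {residual:.3g}"
        )
    complexes = r_free * et / (kd + r_free)
    bound = complexes / et
    return CompetitionResult(
        r_free=float(r_free),
        complexes=dict(zip(names, complexes.tolist())),
        bound_fraction=dict(zip(names, bound.tolist())),
        affinity_class=classify_affinity(effectors, ctx),
    )


def classify_affinity(effectors: list[EffectorSpec], ctx: KrasContext) -> dict:
    """High affinity iff Kd < active-KRAS abundance (Kd == r_total -> low)."""
    ctx.validate()
    return {e.name: ("high" if e.kd < ctx.r_total else "low") for e in effectors}


def dose_fold_change(
    effectors: list[EffectorSpec], ctx_lo: KrasContext, ctx_hi: KrasContext
) -> pd.DataFrame:
    """Fold-change of each effector's bound fraction between two doses.

    Returns a frame with the fold-change, a dense descending rank, and a
    flag for undefined ratios (zero bound fraction at the low dose).
    """
    res_lo = solve_equilibrium(effectors, ctx_lo)
    res_hi = solve_equilibrium(effectors, ctx_hi)
    rows = []
    for e in effectors:
        b_lo = res_lo.bound_fraction[e.name]
        b_hi = res_hi.bound_fraction[e.name]
        if b_lo == 0:
            fc, undefined = float("inf"), True
        else:
            fc, undefined = b_hi / b_lo, False
        rows.append((e.name, e.pathway, e.kd, fc, undefined))
    out = pd.DataFrame(
        rows, columns=["effector", "pathway", "kd", "fold_change", "undefined"]
    )
    out["rank"] = out["fold_change"].rank(method="dense", ascending=False).astype(int)
    return out.sort_values("rank", kind="stable").reset_index(drop=True)


def dose_response_curve(
    effectors: list[EffectorSpec], r_grid
) -> pd.DataFrame:
    """Complex concentrations over a grid of active-KRAS abundances."""
    rows = []
    for r in r_grid:
        res = solve_equilibrium(effectors, KrasContext(float(r)))
        for name, c in res.complexes.items():
            rows.append((float(r), name, c, res.bound_fraction[name]))
    return pd.DataFrame(
        rows, columns=["r_total", "effector", "complex_nM", "bound_fraction"]
    )


def sensitivity_from_apms(
    diff_stats: pd.DataFrame, pathway_map: dict
) -> pd.DataFrame:
    """Dose sensitivity of effector pathways from AP-MS fold-changes.

    For each pathway, the score is the sum of hi-vs-lo log2 fold-changes
    over the measured preys of the pathway's bait complexes, normalised by
    the number of preys measured (i.e. their mean).  Pathways with no
    measured preys are omitted with a warning.
    """
    import logging

    logger = logging.getLogger(__name__)
    rows = []
    by_pathway: dict[str, list[str]] = {}
    for bait, pathway in pathway_map.items():
        by_pathway.setdefault(pathway, []).append(bait)
    for pathway, baits in by_pathway.items():
        sub = diff_stats[diff_stats["bait"].isin(baits)]
        if sub.empty:
            logger.warning("pathway %s has no measured preys; omitted", pathway)
            continue
        rows.append((pathway, float(sub["mean_log2fc"].sum() / len(sub)), len(sub)))
    return pd.DataFrame(rows, columns=["pathway", "score", "n_measured"])


def rank_agreement(model_fcs: dict, sensitivity_scores: pd.DataFrame):
    """Spearman correlation of model-predicted vs AP-MS sensitivity ranks.

    ``model_fcs`` maps pathway -> predicted bound-fraction fold-change.
    Requires at least three shared pathways.
    """
    shared = [
        p for p in sensitivity_scores["pathway"] if p in model_fcs
    ]
    if len(shared) < 3:
        raise ValueError(
            f"rank agreement needs >= 3 shared pathways, got {len(shared)}"
        )
    scores = sensitivity_scores.set_index("pathway").loc[shared, "score"]
    model = [model_fcs[p] for p in shared]
    rho, p = stats.spearmanr(model, scores.to_numpy())
    return float(rho), float(p)
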