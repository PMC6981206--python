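"""Ground-truth networks and simulated SILAC quantification tables.

The generator emulates the statistical structure of a two-condition
(``hi`` / ``lo``) differential AP-MS screen:

* a bait panel pulling down a shared prey namespace, with hub preys arising
  from preferential attachment;
* per-edge rewiring categories (gained, lost, abundance-shifted, unchanged)
  with planted log2 effect sizes;
* replicate-level log2 SILAC ratios (biological x technical replicates,
  label swap encoded as an orientation flag with sign-flipped raw values);
* a nonspecific "background" proteome quantified in every pulldown and in
  empty-vector controls, which is what makes median centring and
  percentile-based outlier statistics meaningful, plus a smaller pool of
  sticky contaminants that appear sporadically with mild enrichment;
* differentially abundant / phosphorylated protein tables with a
  controllable overlap with rewired preys.

Everything is driven by one seeded :class:`numpy.random.Generator` so a
given configuration is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

CATEGORIES = ("hi_only", "lo_only", "shared_up_hi", "shared_up_lo", "unchanged")

#: columns of the replicate-level quantification table dialect
QUANT_COLUMNS = [
    "bait",
    "prey",
    "condition",
    "replicate_id",
    "bio_rep",
    "tech_rep",
    "label_orientation",
    "log2_ratio",
]


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic two-condition AP-MS screen.

    Defaults emulate the scale of the study design this package targets:
    95 baits, ~33 true preys per bait (~3.1k edges per condition), three
    biological times two technical replicates with SILAC label swap, and
    rewiring fractions (of the edge union) matching the observed split of
    gained / lost / abundance-shifted interactions.
    """

    n_baits: int = 95
    mean_preys_per_bait: float = 33.0
    frac_hi_only: float = 0.14
    frac_lo_only: float = 0.09
    frac_shift: float = 0.07
    noise_sd: float = 0.3
    n_bio: int = 3
    n_tech: int = 2
    contaminant_rate: float = 0.05
    seed: int = 0

    # prey namespace / topology
    prey_share_prob: float = 0.35  # preferential re-use of an existing prey
    n_background: int = 300  # nonspecific binders quantified per pulldown
    n_contaminants: int = 30  # sticky frequent-flyer pool

    # planted effects (log2 units)
    gain_effect: float = 4.0  # hi_only edges (detection-limited ratio)
    loss_effect: float = -4.0  # lo_only edges
    shift_min: float = 2.0
    shift_max: float = 4.0
    min_effect: float = 2.0  # |effect| floor for any rewired category
    enrich_mean: float = 3.0  # pulldown-vs-control enrichment of true preys
    enrich_sd: float = 0.8
    enrich_min: float = 1.0
    contam_enrich_mean: float = 2.0
    contam_enrich_sd: float = 0.5
    run_offset_sd: float = 0.15  # per-MS-run global ratio offset
    missing_rate: float = 0.9  # P(absent edge emits no row in that condition)

    # rewiring concentration: hot baits carry `hot_weight`-fold rewiring odds
    n_hot_baits: int = 0
    hot_weight: float = 1.0

    # optional dose-response pathway design: baits listed here have all of
    # their rewiring as positive shared_up_hi shifts at the given per-bait
    # fraction, emulating graded sensitivity of effector pathways
    pathway_map: dict = field(default_factory=dict)  # bait -> pathway name
    pathway_shift_frac: dict = field(default_factory=dict)  # pathway -> frac
    pathway_shift_mag: float = 2.5

    def validate(self) -> None:
        if self.frac_hi_only < 0 or self.frac_lo_only < 0 or self.frac_shift < 0:
            raise ConfigurationError("rewiring fractions must be non-negative")
        if self.frac_hi_only + self.frac_lo_only + self.frac_shift > 1:
            raise ConfigurationError(
                "frac_hi_only + frac_lo_only + frac_shift must be <= 1"
            )
        for name in ("n_baits", "n_bio", "n_tech"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not 0 <= self.contaminant_rate <= 1:
            raise ConfigurationError("contaminant_rate must be in [0, 1]")
        if self.shift_min < self.min_effect:
            raise ConfigurationError("shift_min must be >= min_effect")
        for pw, f in self.pathway_shift_frac.items():
            if not 0 <= f <= 1:
                raise ConfigurationError(f"pathway_shift_frac[{pw!r}] not in [0,1]")


@dataclass
class TruthNetwork:
    """Planted ground truth: per-condition edge sets, categories, effects."""

    baits: list
    edges: dict  # {"hi": set[(bait, prey)], "lo": set[(bait, prey)]}
    category: dict  # (bait, prey) -> category
    effect_size: dict  # (bait, prey) -> planted log2 fold-change (hi vs lo)
    contaminants: set
    background: set
    config: SimulationConfig | None = None

    @property
    def union_edges(self) -> set:
        return self.edges["hi"] | self.edges["lo"]

    def rewired_edges(self) -> set:
        return {e for e, c in self.category.items() if c != "unchanged"}

    def rewired_preys(self) -> set:
        return {prey for (_, prey) in self.rewired_edges()}

    def preys(self) -> set:
        return {prey for (_, prey) in self.union_edges}

    def to_json(self, path) -> None:
        payload = {
            "baits": self.baits,
            "edges": {c: sorted(map(list, es)) for c, es in self.edges.items()},
            "category": {f"{b}\t{p}": c for (b, p), c in self.category.items()},
            "effect_size": {f"{b}\t{p}": v for (b, p), v in self.effect_size.items()},
            "contaminants": sorted(self.contaminants),
            "background": sorted(self.background),
            "config": asdict(self.config) if self.config else None,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthNetwork":
        with open(path) as fh:
            d = json.load(fh)
        split = lambda k: tuple(k.split("\t"))
        return cls(
            baits=d["baits"],
            edges={c: {tuple(e) for e in es} for c, es in d["edges"].items()},
            category={split(k): v for k, v in d["category"].items()},
            effect_size={split(k): v for k, v in d["effect_size"].items()},
            contaminants=set(d["contaminants"]),
            background=set(d["background"]),
            config=SimulationConfig(**d["config"]) if d.get("config") else None,
        )


def _assign_preys(cfg: SimulationConfig, rng: np.random.Generator):
    """Preferential-attachment prey assignment over a shared namespace."""
    prey_degree: dict[str, int] = {}
    bait_preys: dict[str, list[str]] = {}
    counter = 0
    baits = [f"B{i + 1:03d}" for i in range(cfg.n_baits)]
    # mean_preys_per_bait parameterises the hi-condition network scale;
    # lo-exclusive edges are drawn on top of it, so inflate the union mean
    union_mean = cfg.mean_preys_per_bait / max(0.1, 1.0 - cfg.frac_lo_only)
    for bait in baits:
        n_prey = max(1, rng.poisson(union_mean))
        chosen: list[str] = []
        for _ in range(n_prey):
            existing = [p for p in prey_degree if p not in chosen]
            if existing and rng.random() < cfg.prey_share_prob:
                weights = np.array([prey_degree[p] for p in existing], dtype=float)
                pick = existing[rng.choice(len(existing), p=weights / weights.sum())]
            else:
                counter += 1
                pick = f"P{counter:04d}"
                prey_degree[pick] = 0
            prey_degree[pick] += 1
            chosen.append(pick)
        bait_preys[bait] = chosen
    return baits, bait_preys


def generate_truth_network(config: SimulationConfig) -> TruthNetwork:
    """Draw a ground-truth differential network from the configuration.

    Edges are assigned to the five rewiring categories so that the expected
    category fractions (of the edge union) match the configured values, with
    optional concentration of rewiring on ``n_hot_baits`` baits and the
    pathway dose-response design overriding per-bait fractions.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    baits, bait_preys = _assign_preys(config, rng)

    hot = set(baits[: config.n_hot_baits])
    category: dict = {}
    effect: dict = {}
    edges_hi: set = set()
    edges_lo: set = set()

    weights = {b: (config.hot_weight if b in hot else 1.0) for b in baits}
    all_edges = [(b, p) for b in baits for p in bait_preys[b]]
    mean_w = float(np.mean([weights[b] for b, _ in all_edges])) or 1.0
    frac_total = config.frac_hi_only + config.frac_lo_only + config.frac_shift

    for bait, prey in all_edges:
        pathway = config.pathway_map.get(bait)
        if pathway is not None:
            # graded dose-response bait: rewiring is purely positive shifts
            f = config.pathway_shift_frac.get(pathway, 0.0)
            if rng.random() < f:
                cat = "shared_up_hi"
                es = config.pathway_shift_mag
            else:
                cat, es = "unchanged", 0.0
        else:
            p_rw = min(1.0, frac_total * weights[bait] / mean_w)
            if frac_total > 0 and rng.random() < p_rw:
                u = rng.random() * frac_total
                if u < config.frac_hi_only:
                    cat, es = "hi_only", config.gain_effect
                elif u < config.frac_hi_only + config.frac_lo_only:
                    cat, es = "lo_only", config.loss_effect
                else:
                    mag = rng.uniform(config.shift_min, config.shift_max)
                    if rng.random() < 0.5:
                        cat, es = "shared_up_hi", mag
                    else:
                        cat, es = "shared_up_lo", -mag
            else:
                cat, es = "unchanged", 0.0
        category[(bait, prey)] = cat
        effect[(bait, prey)] = float(es)
        if cat != "lo_only":
            edges_hi.add((bait, prey))
        if cat != "hi_only":
            edges_lo.add((bait, prey))

    contaminants = {f"C{i + 1:03d}" for i in range(config.n_contaminants)}
    background = {f"BG{i + 1:04d}" for i in range(config.n_background)}
    return TruthNetwork(
        baits=baits,
        edges={"hi": edges_hi, "lo": edges_lo},
        category=category,
        effect_size=effect,
        contaminants=contaminants,
        background=background,
        config=config,
    )


def _replicate_frame(rng, cfg, bait, condition, prey_means):
    """Emit replicate rows for one (bait, condition) experiment.

    ``prey_means`` maps prey -> true mean log2 ratio. Technical replicate 2
    of every biological replicate is label-swapped; raw stored ratios of
    reverse-orientation runs are sign-flipped, and every run carries a
    global additive offset that median centring must remove.
    """
    preys = list(prey_means)
    means = np.array([prey_means[p] for p in preys])
    rows = []
    for bio in range(1, cfg.n_bio + 1):
        for tech in range(1, cfg.n_tech + 1):
            orientation = "reverse" if tech == 2 else "forward"
            offset = rng.normal(0.0, cfg.run_offset_sd) if cfg.run_offset_sd else 0.0
            vals = means + offset + rng.normal(0.0, cfg.noise_sd, size=len(preys))
            raw = -vals if orientation == "reverse" else vals
            rows.append(
                pd.DataFrame(
                    {
                        "bait": bait,
                        "prey": preys,
                        "condition": condition,
                        "replicate_id": f"b{bio}t{tech}",
                        "bio_rep": bio,
                        "tech_rep": tech,
                        "label_orientation": orientation,
                        "log2_ratio": raw,
                    }
                )
            )
    return rows


def simulate_silac_experiment(truth: TruthNetwork, config: SimulationConfig | None = None):
    """Simulate replicate-level SILAC tables from a ground-truth network.

    Returns
    -------
    (pulldown, control, hi_vs_lo) : tuple of DataFrame
        ``pulldown``: bait-vs-empty-vector log2 ratios per condition
        (``condition`` in {"hi", "lo"}).  ``control``: empty-vector
        control-vs-control null ratios (``condition`` in {"control_hi",
        "control_lo"}, ``bait`` = "EV"), containing background binders and
        contaminants only — never planted true interactors.  ``hi_vs_lo``:
        direct condition-vs-condition ratios per bait whose per-edge means
        equal the planted effect sizes.
    """
    cfg = config or truth.config
    if cfg is None:
        raise ConfigurationError("no SimulationConfig available")
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 1])

    background = sorted(truth.background)
    contaminants = sorted(truth.contaminants)
    contam_enrich = {
        c: max(0.5, rng.normal(cfg.contam_enrich_mean, cfg.contam_enrich_sd))
        for c in contaminants
    }
    bait_preys: dict[str, list[str]] = {b: [] for b in truth.baits}
    for bait, prey in sorted(truth.union_edges):
        bait_preys[bait].append(prey)

    # base pulldown enrichment per edge (log2 pulldown/control where present)
    base_enrich = {
        e: max(cfg.enrich_min, rng.normal(cfg.enrich_mean, cfg.enrich_sd))
        for e in sorted(truth.union_edges)
    }

    pulldown_rows, hivslo_rows = [], []
    for bait in truth.baits:
        contam_here = [c for c in contaminants if rng.random() < cfg.contaminant_rate]
        # condition-vs-condition experiment: all quantified preys
        diff_means = {p: 0.0 for p in background}
        diff_means.update({c: 0.0 for c in contam_here})
        for cond in ("hi", "lo"):
            means = {p: 0.0 for p in background}
            means.update({c: contam_enrich[c] for c in contam_here})
            for prey in bait_preys[bait]:
                edge = (bait, prey)
                es = truth.effect_size[edge]
                present = edge in truth.edges[cond]
                if present:
                    enrich = base_enrich[edge]
                    if truth.category[edge] in ("shared_up_hi", "shared_up_lo"):
                        enrich += es / 2 if cond == "hi" else -es / 2
                    means[prey] = enrich
                elif rng.random() >= cfg.missing_rate:
                    means[prey] = rng.normal(0.0, cfg.noise_sd / 2)
                # else: stochastic non-detection, no row emitted
            pulldown_rows.extend(_replicate_frame(rng, cfg, bait, cond, means))
        for prey in bait_preys[bait]:
            diff_means[prey] = truth.effect_size[(bait, prey)]
        hivslo_rows.extend(
            _replicate_frame(rng, cfg, bait, "hi_vs_lo", diff_means)
        )

    control_rows = []
    for cond in ("control_hi", "control_lo"):
        contam_here = [c for c in contaminants if rng.random() < cfg.contaminant_rate]
        means = {p: 0.0 for p in background}
        means.update({c: 0.0 for c in contam_here})
        control_rows.extend(_replicate_frame(rng, cfg, "EV", cond, means))

    pulldown = pd.concat(pulldown_rows, ignore_index=True)[QUANT_COLUMNS]
    control = pd.concat(control_rows, ignore_index=True)[QUANT_COLUMNS]
    hi_vs_lo = pd.concat(hivslo_rows, ignore_index=True)[QUANT_COLUMNS]
    return pulldown, control, hi_vs_lo


def simulate_protein_tables(
    truth: TruthNetwork,
    n_de: int,
    n_dp: int,
    overlap_with_rewired: float,
    seed: int,
    n_proteins: int = 4685,
):
    """Simulate differential abundance and phosphorylation tables.

    ``overlap_with_rewired`` is the planted fraction of differential
    proteins drawn from preys of rewired edges; the remainder come from the
    rest of the assayed universe. Returns ``(abundance, phosphorylation)``
    DataFrames with columns protein / log2_fc / p_value / significant.
    """
    if not 0 <= overlap_with_rewired <= 1:
        raise ConfigurationError("overlap_with_rewired must be in [0, 1]")
    rng = np.random.default_rng([seed, 2])
    rewired = sorted(truth.rewired_preys())
    other = sorted((truth.preys() | truth.background | truth.contaminants) - set(rewired))
    n_fill = n_proteins - len(rewired) - len(other)
    filler = [f"X{i + 1:05d}" for i in range(max(0, n_fill))]
    universe = rewired + other + filler
    if len(universe) > n_proteins:
        universe = universe[:n_proteins]
        rewired = [p for p in rewired if p in set(universe)]
        other = [p for p in other + filler if p in set(universe) and p not in set(rewired)]
    else:
        other = other + filler

    def one_table(n_diff: int) -> pd.DataFrame:
        if n_diff > len(universe):
            raise ConfigurationError("n_diff exceeds available proteins")
        n_from_rw = min(len(rewired), int(round(n_diff * overlap_with_rewired)))
        n_from_other = n_diff - n_from_rw
        if n_from_other > len(other):
            raise ConfigurationError("n_diff exceeds available non-rewired proteins")
        diff = list(rng.choice(rewired, size=n_from_rw, replace=False)) + list(
            rng.choice(other, size=n_from_other, replace=False)
        )
        diff_set = set(diff)
        is_diff = np.array([p in diff_set for p in universe])
        fc = np.where(
            is_diff,
            rng.choice([-1, 1], size=len(universe)) * rng.normal(1.5, 0.4, len(universe)),
            rng.normal(0.0, 0.3, len(universe)),
        )
        p = np.where(
            is_diff,
            rng.uniform(1e-6, 0.05, len(universe)),
            rng.uniform(0.05, 1.0, len(universe)),
        )
        return pd.DataFrame(
            {"protein": universe, "log2_fc": fc, "p_value": p, "significant": is_diff}
        )

    return one_table(n_de), one_table(n_dp)


def simulate_prey_prey_edges(truth: TruthNetwork, n_edges: int, seed: int) -> pd.DataFrame:
    """Random prey-prey edges emulating a public interaction supplement."""
    rng = np.random.default_rng([seed, 3])
    preys = sorted(truth.preys())
    seen, rows = set(), []
    while len(rows) < n_edges and len(seen) < len(preys) * (len(preys) - 1) // 2:
        a, b = rng.choice(len(preys), size=2, replace=False)
        key = (min(a, b), max(a, b))
        if key in seen:
            continue
        seen.add(key)
        rows.append((preys[key[0]], preys[key[1]]))
    return pd.DataFrame(rows, columns=["node_a", "node_b"])


def simulate_complexes(
    truth: TruthNetwork,
    n_complexes: int = 60,
    size_range: tuple = (4, 20),
    in_network_bias: float = 0.7,
    seed: int = 0,
) -> dict:
    """Synthetic protein-complex definitions with tunable network coverage.

    Each complex draws members from network preys with probability
    ``in_network_bias`` and from outside proteins otherwise, so coverage
    fractions span the thresholding range downstream.
    """
    rng = np.random.default_rng([seed, 4])
    preys = sorted(truth.preys())
    outside = [f"OUT{i + 1:04d}" for i in range(200)]
    complexes = {}
    for i in range(n_complexes):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        members = []
        for _ in range(size):
            pool = preys if rng.random() < in_network_bias else outside
            members.append(pool[rng.integers(len(pool))])
        complexes[f"CPX{i + 1:03d}"] = sorted(set(members))
    return complexes
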