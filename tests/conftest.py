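"""Shared fixtures: simulated screens reused across the suite.

The expensive default-scale simulation (95 baits) and the 500-edge
recovery screen are run once per session; tests consume frozen views.
"""

from __future__ import annotations

import pandas as pd
import pytest

from ppindiff import netbuild
from ppindiff.silac_stats import (
    Thresholds,
    add_significance_a,
    classify_rewiring,
    compare_conditions,
    filter_true_interactors,
    normalize_ratios,
    test_enrichment,
)
from ppindiff.synthetic_data import (
    SimulationConfig,
    generate_truth_network,
    simulate_silac_experiment,
)


def run_screen(cfg: SimulationConfig):
    """Simulate one two-condition screen and run the scoring chain."""
    truth = generate_truth_network(cfg)
    pulldown, control, hi_vs_lo = simulate_silac_experiment(truth, cfg)
    pn = normalize_ratios(pulldown)
    cn = normalize_ratios(control)
    hn = normalize_ratios(hi_vs_lo)
    thr = Thresholds()
    interactions = {}
    for cond in ("hi", "lo"):
        stats = test_enrichment(
            pn[pn["condition"] == cond], cn[cn["condition"] == f"control_{cond}"]
        )
        stats = add_significance_a(stats, on_degenerate="saturate")
        interactions[cond] = filter_true_interactors(stats, thr, cfg.n_baits)
    diff_stats = compare_conditions(hn)
    calls = classify_rewiring(
        list(zip(interactions["hi"]["bait"], interactions["hi"]["prey"])),
        list(zip(interactions["lo"]["bait"], interactions["lo"]["prey"])),
        diff_stats,
        thr,
    )
    return {
        "truth": truth,
        "pulldown": pulldown,
        "control": control,
        "hi_vs_lo": hi_vs_lo,
        "interactions": interactions,
        "diff_stats": diff_stats,
        "calls": calls,
    }


@pytest.fixture(scope="session")
def recovery_screen():
    """~500-edge screen with rewiring concentrated on 3 hot baits."""
    cfg = SimulationConfig(
        seed=7,
        n_baits=20,
        mean_preys_per_bait=25,
        n_hot_baits=3,
        hot_weight=6.0,
    )
    return run_screen(cfg)


@pytest.fixture(scope="session")
def default_screen():
    """Full default-scale screen (95 baits, study-design defaults)."""
    return run_screen(SimulationConfig(seed=1))
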