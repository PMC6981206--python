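#!/usr/bin/env python
"""Score and filter high-confidence interactions per condition.

Normalizes the replicate tables (label-swap orientation, per-run median
centring), tests each prey's enrichment over the empty-vector control
(one-sided Welch t on biological replicates), attaches per-bait
significance A, and applies the two-step false-positive filter
(P <= 0.05 AND significance A <= 0.05, then the frequent-flyer cut).

Writes: results/interactions_{hi,lo}.tsv
"""

import argparse
from pathlib import Path

from ppindiff import io as pio
from ppindiff.pipeline import PipelineConfig
from ppindiff.silac_stats import (
    add_significance_a,
    filter_true_interactors,
    normalize_ratios,
    test_enrichment,
)
from ppindiff.synthetic_data import TruthNetwork

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=ROOT / "results")
    args = ap.parse_args()
    cfg = PipelineConfig.from_yaml(args.results / "run_config.yaml")
    data = args.results / "data"

    pulldown = normalize_ratios(pio.read_table(data / "quant_pulldown.tsv"))
    control = normalize_ratios(pio.read_table(data / "quant_control.tsv"))
    truth = TruthNetwork.from_json(data / "truth.json")

    for cond in ("hi", "lo"):
        stats = test_enrichment(
            pulldown[pulldown["condition"] == cond],
            control[control["condition"] == f"control_{cond}"],
        )
        stats = add_significance_a(stats, on_degenerate="saturate")
        retained = filter_true_interactors(
            stats, cfg.thresholds, cfg.simulation.n_baits
        )
        pio.write_table(retained, args.results / f"interactions_{cond}.tsv",
                        stage="filter")
        edges = set(zip(retained["bait"], retained["prey"]))
        tp = len(edges & truth.edges[cond])
        print(f"{cond}: {len(stats)} candidate pairs -> {len(edges)} retained "
              f"(precision vs planted truth {tp / len(edges):.3f}, "
              f"recall {tp / len(truth.edges[cond]):.3f})")


if __name__ == "__main__":
    main()
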