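#!/usr/bin/env python
"""Enrichment of differential proteins in the networks; complex coverage.

Simulates differential abundance/phosphorylation tables with a planted
over-representation among rewired preys, runs the exact hypergeometric
upper-tail tests (network membership and rewired-node enrichment), and
computes protein-complex coverage of both condition networks.

Writes: results/protein_{abundance,phosphorylation}.tsv,
enrichment_report.tsv, complex_coverage_{hi,lo}.tsv
"""

import argparse
from pathlib import Path

import pandas as pd

from ppindiff import io as pio
from ppindiff import netbuild
from ppindiff.enrichment import complex_coverage, set_enrichment
from ppindiff.pipeline import PipelineConfig
from ppindiff.synthetic_data import (
    TruthNetwork,
    simulate_complexes,
    simulate_protein_tables,
)

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=ROOT / "results")
    args = ap.parse_args()
    res = args.results
    cfg = PipelineConfig.from_yaml(res / "run_config.yaml")
    truth = TruthNetwork.from_json(res / "data" / "truth.json")

    abundance, phospho = simulate_protein_tables(
        truth, cfg.n_de, cfg.n_dp, cfg.overlap_with_rewired, cfg.seed,
        n_proteins=cfg.n_proteins_assayed,
    )
    pio.write_table(abundance, res / "protein_abundance.tsv", stage="simulate")
    pio.write_table(phospho, res / "protein_phosphorylation.tsv", stage="simulate")

    calls = pio.read_table(res / "rewiring_calls.tsv")
    rewired_preys = set(calls.loc[calls["category"] != "unchanged", "prey"])
    nodes = set(calls["bait"]) | set(calls["prey"])
    background = set(abundance["protein"])
    net_assayed = nodes & background

    rows = []
    for label, table in (("DE", abundance), ("DP", phospho)):
        diff = set(table.loc[table["significant"], "protein"])
        inp_net, p_net = set_enrichment(background, diff, net_assayed)
        inp_rw, p_rw = set_enrichment(net_assayed, diff & net_assayed,
                                      rewired_preys & net_assayed)
        rows += [
            (f"{label}_in_network", inp_net.N, inp_net.n, inp_net.K, inp_net.k, p_net),
            (f"{label}_in_rewired", inp_rw.N, inp_rw.n, inp_rw.K, inp_rw.k, p_rw),
        ]
        print(f"{label}: {inp_net.k} of {inp_net.n} differential proteins are "
              f"network nodes (p {p_net:.3g}); {inp_rw.k} of {inp_rw.n} "
              f"in-network differential proteins are rewired (p {p_rw:.3g})")
    report = pd.DataFrame(rows, columns=["test", "N", "n", "K", "k", "p"])
    pio.write_table(report, res / "enrichment_report.tsv", stage="enrich")

    complexes = simulate_complexes(truth, cfg.n_complexes, seed=cfg.seed)
    ints = {c: pio.read_table(res / f"interactions_{c}.tsv") for c in ("hi", "lo")}
    for cond in ("hi", "lo"):
        net = netbuild.build_network(ints[cond])
        cov = complex_coverage(complexes, net, rewired_preys)
        pio.write_table(cov, res / f"complex_coverage_{cond}.tsv", stage="enrich")
        print(f"{cond}: {int(cov['present_flag'].sum())} of {len(cov)} complexes "
              f"have >=70% members in the network; "
              f"{int((cov['present_flag'] & cov['rewired_flag']).sum())} of those "
              f"are >60% rewired")


if __name__ == "__main__":
    main()
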