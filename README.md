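# ppindiff

Differential analysis of protein–protein interaction networks (PPINs)
measured by SILAC-based AP-MS in two cellular conditions.

The motivating setting is a receptor signalling network (e.g. the EGFR
network in colorectal cancer cells) mapped with a panel of ~95 tagged
baits under a low and a high dosage of an oncogenic KRAS mutant. Each
bait pulldown yields replicate-level heavy/light log2 ratios against
empty-vector controls, plus a direct condition-vs-condition comparison.
The questions the pipeline answers:

* which bait–prey pairs are *bona fide* interactions in each condition;
* which interactions are **rewired** between conditions — gained, lost,
  or significantly shifted in prey abundance;
* how the two networks differ topologically and which baits concentrate
  the rewiring;
* whether the dose dependence of KRAS–effector complexes follows from
  equilibrium competition for KRAS's single effector-binding site;
* how signal flow from the receptor to transcription factors
  redistributes between the two networks;
* whether differentially expressed/phosphorylated proteins and known
  protein complexes are over-represented among rewired network nodes.

It is written for computational biologists who want the complete analysis
chain as a tested, reusable library with a synthetic-data generator, so
every stage can be exercised and validated without any downloads.

## Statistical core

**Interaction scoring.** After orienting label-swapped runs and median
centring each MS run, technical replicates are averaged into their
biological replicate. A prey is a high-confidence interactor when a
one-sided Welch t-test of pulldown vs empty-vector log2 ratios gives
*P* ≤ 0.05 **and** its significance *A* ≤ 0.05, followed by a
frequent-flyer contaminant filter. Significance *A* is the
percentile-based outlier statistic for a log-ratio *r*:

    z = (r − q50) / (q84.13 − q50)   if r ≥ q50
        (q50 − r) / (q50 − q15.87)   otherwise
    sig_A = erfc(z / √2) / 2

**Rewiring.** Every edge of the two-network union is classified from the
direct hi-vs-lo comparison (two-sided one-sample t against 0, plus
significance *A* per bait experiment): significant edges present in only
one network are `hi_only`/`lo_only`, significant shared edges are
`shared_up_hi`/`shared_up_lo` by the sign of the fold-change, and
everything else — including single-network edges that fail the test — is
`unchanged`.

**Competition model.** Effectors with totals E_i and dissociation
constants K_i compete for a single pool R_T of active KRAS; the free
concentration r solves

    R_T = r · (1 + Σ_i E_i / (K_i + r)),   C_i = r · E_i / (K_i + r).

Low-affinity effectors (K_i above the active-KRAS abundance) have
C_i ≈ r·E_i/K_i, so their bound fractions gain the most from a dose
increase — the model's testable ranking prediction.

**Information flow.** Damped random walks (survival probability 0.85 per
step) start at a source node and are absorbed at transcription-factor
sinks; the channel-mode score of a node is its expected visit count
conditioned on absorption, `IFS(v) = visits(s→v)·h(v)/h(s)`, computed by
sparse linear solves and cross-checked against simulated walks.

**Enrichment.** Exact hypergeometric upper tails
p(X ≥ k) = Σ C(K,x)·C(N−K,n−x)/C(N,n), evaluated in log space.

## Worked example

The numbered scripts under `analysis/` run the whole study on simulated
data (seed 1 by default) and write their tables under `results/`:

```
python analysis/01_simulate_screen.py --seed 1
python analysis/02_score_interactions.py
python analysis/03_classify_rewiring.py
python analysis/04_competition_model.py
python analysis/05_information_flow.py
python analysis/06_enrichment_analysis.py
```

Selected output of the run:

```
planted truth: 95 baits, 3085 hi / 2933 lo edges, 1017 rewired (874 rewired preys)
hi: 31738 candidate pairs -> 3334 retained (precision vs planted truth 0.923, recall 0.997)
union: 3721 edges; rewired: 1071 (433 hi-only, 269 lo-only, 369 shifted)
hi topology: 2227 nodes, 3334 edges, 1 component(s), avg path 4.70, power-law exponent 1.26 (R2 0.57)
  TIAM1    Kd   2500 nM (low  affinity): bound-fraction fold-change 3.44 (rank 1)
  RAF1     Kd     80 nM (high affinity): bound-fraction fold-change 1.94 (rank 7)
model vs AP-MS sensitivity rank agreement: Spearman rho 0.89 (p 0.00681, 7 pathways)
330 of 1980 shared nodes differ >2.0-fold in normalised flow; 10 sink TFs differ >= 1.2-fold
DE: 240 of 404 differential proteins are network nodes (p 1.31e-05); 147 of 240 in-network differential proteins are rewired (p 5.14e-13)
```

Reading this: the two-step filter recovers the planted interactions at
~92% precision and >99% recall; about 29% of the edge union is called
rewired, dominated by gains/losses; both condition networks are
single-component and heavy-tailed; the equilibrium model predicts larger
dose fold-changes for weaker binders, and the AP-MS-derived pathway
sensitivity scores recover that ranking (ρ = 0.89); flow and enrichment
statistics quantify the downstream consequences of the planted rewiring.

The same chain is available as one call (`ppindiff run --seed 1 --outdir
out/`) or stage-by-stage through the `ppindiff` subcommands
(`simulate`, `quant`, `rewire`, `net`, `topo`, `compete`, `flow`,
`flowdiff`, `enrich`, `validate`). `ppindiff validate` recomputes the
headline counts from externally supplied processed tables (e.g. a
published study's supplementary data converted to the TSV dialect) and
reports deltas against user-provided expected counts.

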