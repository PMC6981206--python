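# Methods

This note documents the models and procedures implemented in `ppindiff`,
the assumptions behind them, the parameters that matter, and the design
choices made where the design was genuinely open. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. The synthetic screen

The generator (`ppindiff.synthetic_data`) emulates the statistical
structure of a two-condition SILAC AP-MS screen, not its mass spectra.
Its defaults are the study-design conditions the package targets.

**Bait panel and prey namespace.** 95 baits draw preys from one shared
namespace with preferential attachment (`prey_share_prob = 0.35`): each
prey slot reuses an existing prey with probability 0.35, weighted by its
current degree, otherwise mints a new one. This produces the heavy-tailed
prey-degree distribution (shared hub preys) that makes the detected
networks single-component. `mean_preys_per_bait = 33` parameterises the
hi-condition network scale (~3.1k edges); the per-bait Poisson mean for
the edge union is inflated by 1/(1 − frac_lo_only) so lo-exclusive edges
do not deflate the hi network.

**Rewiring categories.** Each union edge is `hi_only` (planted log2
effect +4), `lo_only` (−4), `shared_up_hi/lo` (|shift| uniform in
[2, 4]), or `unchanged` (0), with union fractions 0.14 / 0.09 / 0.07 /
0.70 by default. Gains and losses are modelled as large finite log2
shifts rather than ±∞ because presence/absence in AP-MS manifests as
detection-limited ratios; this keeps one statistical machinery applicable
to all categories. An edge absent in a condition emits no row in that
condition's pulldown with probability 0.9 (stochastic peptide detection)
and a near-zero ratio otherwise. Optional concentration knobs
(`n_hot_baits`, `hot_weight`) multiply per-bait rewiring odds, emulating
the empirically non-uniform distribution of rewiring across bait
complexes.

**Background and contaminants.** Every pulldown also quantifies a shared
nonspecific background proteome (`n_background = 300` preys at ratio
≈ 0). This is deliberate and load-bearing: in real pulldowns true
interactors are a minority of quantified proteins, which is what makes
per-run median centring meaningful and keeps the percentile-based
significance-A statistic calibrated (its 84.13th-percentile spread
estimate must fall on the null part of the distribution). A smaller pool
of sticky contaminants (`n_contaminants = 30`) appears in any pulldown
with probability `contaminant_rate = 0.05` with a mild stable enrichment
(~2 log2) — these are the realistic, statistically indistinguishable
false positives that bound filter precision. The empty-vector control
tables contain background and contaminants only, never planted true
interactors.

**Replicates and label swap.** 3 biological × 2 technical replicates;
technical replicate 2 of each biological replicate is reverse-labelled
and stored with sign-flipped raw ratios, so naive averaging without
orientation correction cancels the signal. Each MS run carries a global
additive offset (sd 0.15 log2) that normalisation must remove; replicate
noise is Gaussian with `noise_sd = 0.3` log2 (a typical SILAC replicate
spread).

**Dose-response pathway design.** When enabled, the last seven baits are
assigned to effector pathways; their rewiring consists purely of positive
shared shifts at a per-bait fraction graded by the competition model's
predicted dose fold-change for the corresponding effector. This plants
the "low-affinity pathways respond more" signal that
`sensitivity_from_apms` and `rank_agreement` are meant to recover.

**What the generator does not emulate** — peptide-level effects (missed
cleavages, shared peptides, intensity-dependent missingness), ratio
compression, batch structure beyond per-run offsets, and correlated prey
co-detection within complexes. Passing recovery tests therefore shows the
statistical chain is correct and well-calibrated for this noise model,
not that it is robust to every pathology of real AP-MS data.

All draws flow from one seeded `numpy.random.Generator`; regenerating
with the same configuration is bit-identical, and the seed is recorded in
the truth JSON.

## 2. Interaction scoring

* **Normalisation** flips reverse-label rows and median-centres per
  (bait, condition, replicate) MS run. Each run is treated as one
  experiment's ratio set; per-run (rather than pooled per-bait) centring
  is chosen because the offsets it removes are per-run artefacts.
* **Technical replicates are averaged into their biological replicate
  before testing**; the test n is the biological replicate count,
  avoiding pseudo-replication.
* **Enrichment vs control** uses a one-sided Welch t-test. Preys without
  their own empty-vector measurements (the expected case for true
  interactors) are tested against the pooled control null distribution.
  Zero-variance degenerate sets resolve by the sign of the difference
  (identical → p = 0.5, positive → 0, negative → 1), which keeps the
  noise-free limit exact.
* **Significance A** uses the percentile robust-z construction, computed
  per bait experiment by default (config-switchable to pooled) over the
  per-prey mean log2 fold-changes. A zero one-sided spread raises by
  default; the condition-comparison path requests `saturate`, the correct
  noise-free limit (any off-median value is an infinitely strong
  outlier). With ≥ 10 values required, quantiles are linearly
  interpolated.
* **Two-step filter**: the joint P ≤ 0.05 AND significance A ≤ 0.05 gate
  (no multiple-testing correction — the conjunction of two orthogonal
  criteria is the operative false-positive control, applied at raw
  thresholds), then removal of preys retained for more than
  `contaminant_max_frequency = 0.5` of baits, plus an optional
  user-supplied exclusion list. The frequency step is a documented
  stand-in for pipeline-specific contaminant curation.
* **Rewiring classification**: an edge is rewired only if the direct
  hi-vs-lo comparison passes the joint gate; single-network edges failing
  it are `unchanged`. A significant shared edge with fold-change exactly
  0 (measure-zero) falls back to `unchanged`. The five categories
  partition the union, and relabelling hi↔lo mirrors the calls exactly.
* **Zero-variance hi-vs-lo sets** give p = 1 when the mean is 0 and p = 0
  otherwise (with a warning); a blanket p = 1 would misclassify planted
  effects in the noise-free limit.

## 3. Networks and topology

Graphs are undirected spoke models (bait–prey only); prey–prey
co-complex edges are never inferred from pulldowns, only imported during
flow augmentation. Duplicate rows collapse keeping the better P value;
bait-ranking ties break lexicographically for reproducibility.
Betweenness is normalised Brandes betweenness ((n−1)(n−2)/2 pairs),
clustering is the triangle fraction, and average path length is computed
over the largest component (disconnected augmented nodes are retained in
the graph but excluded from path statistics). The scale-freeness exponent
is fitted by least squares on log10 P(k) vs log10 k over degrees ≥ 1 with
nonzero counts — chosen for comparability with the widely used
network-analysis tools that report this fit — with a continuous
maximum-likelihood (Hill) alternative available.

## 4. Competition equilibrium

The single-site competition model is solved at its fixed point: the
conservation function f(r) = r(1 + Σ E_i/(K_i + r)) − R_T is strictly
increasing on (0, R_T] with f(0⁺) < 0 ≤ f(R_T), so the root is bracketed
and found with Brent's method (`xtol = 1e-12·R_T`); bracketing guarantees
convergence and Brent converges faster than the bisection+Newton scheme
it replaces. Effector mass conservation is exact by construction; KRAS
conservation holds to < 1e-9 relative (asserted). Affinity classes:
`high` iff Kd < active-KRAS abundance, boundary Kd = R_T labelled `low`
(documented convention). Dose fold-changes are ratios of bound fractions
between two solved contexts (defaults 150 and 400 nM); a zero bound
fraction at the low dose reports +∞ with a flag. Sensitivity scores
interpret "log fold-changes" as log2, consistent with the SILAC chain.
The default effector catalogue is synthetic (names, totals, Kd's chosen
to span the high/low boundary) and user-replaceable; no literature values
are embedded as ground truth.

## 5. Information flow

The channel model is implemented from its mathematical definition:
with P the row-stochastic transition operator and Q = d·P_tt on transient
nodes, expected visits from the source are row s of (I − Q)⁻¹ (one sparse
solve of the transpose system), the absorption probability h solves
(I − d·P_tt)h = d·P_ts·1, and conditioned scores are visits·h(v)/h(s);
per-sink scores are conditioned absorption splits, which sum to one
(asserted to 1e-9). Exact numerical agreement with any particular
published tool is not claimed; the correctness standard is a Monte-Carlo
oracle (simulated damped walks) agreeing within 2% on nodes carrying
non-negligible flow. Conventions: the initial placement at the source
counts as one visit (affects only the source's own score); edges are
unweighted by default (weighting by an edge attribute is available but
off, as no weighting scheme is canonical); multiple sinks form one
absorbing class with per-sink attribution from the splits. For
cross-network comparison, scores are normalised to share-of-total-flow
because the two networks differ in size; raw scores are also exported.
Differential thresholds: nodes > 2-fold (either direction), sink TFs
≥ 1.2-fold; nodes scored in only one network are listed as exclusive
rather than folded, and zero-score ratios report +∞ with a flag.

## 6. Enrichment

The upper-tail hypergeometric probability is summed in log space
(gammaln + logsumexp); the exhaustive-enumeration oracle in the test
suite checks every design with N ≤ 12. Backgrounds default to the
assayed-protein universe of the relevant table, never a whole proteome.
Complex coverage flags presence inclusively at ≥ 0.7 and rewiring
strictly at > 0.6; the rewired-fraction denominator is the members
*present in the network* (the conservative reading of "constituent
proteins that are rewired preys"); the all-members denominator is a
config switch. No multiple-testing correction is applied inside the
operation; a Benjamini–Hochberg utility is provided for batch runs.

## 7. Orchestration

`run_pipeline` executes simulate → normalise → enrichment test → filter →
networks → rewiring → topology → ranking → competition → flow →
enrichment from one `PipelineConfig` (YAML-loadable), logging row counts
at every stage and writing TSVs with `# stage` / `# config_hash` headers;
two runs with the same seed are byte-identical (the hash excludes the
output directory). For the flow stage on synthetic data the source is the
highest-degree bait (the receptor stand-in) and the sinks are the 19
highest-degree preys reachable in both networks.
`validate_against_supplementary` recomputes headline counts from
user-supplied processed tables and diffs them against user-provided
expected values; when no tables are given it reports "skipped".

## 8. Problem sizes and known limitations

The default simulated screen (95 baits, ~380k pulldown rows) runs the
full pipeline in about a minute on one CPU; the tests use a ~500-edge
screen for recovery checks and small graphs for the exhaustive oracles —
sizes chosen so the whole suite exercises every code path in a few
minutes while keeping Monte-Carlo standard errors well inside the
asserted tolerances. Limitations: the two-step filter's precision is
bounded by design by sticky contaminants that are statistically genuine
enrichments (~0.92 at default conditions); significance A assumes
differential values are a minority of each bait experiment's ratio
distribution and degrades when that fraction approaches the 84.13th
percentile; the equilibrium model ignores GTP/GDP cycling, GEF/GAP
dynamics and membrane localisation; the flow model treats edges as
undirected conduits with uniform transition probabilities.
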