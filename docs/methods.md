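# Methods

## Data model

The pipeline consumes RMA-style normalised log2 intensities: a genes ×
samples matrix (TSV, first column `gene_id`) and a sample metadata
sidecar (`sample_id`, `lineage`, `time_hours`, `is_control`). Exactly one
control sample (time 0, uninduced) is shared by both lineages. Gene
annotation arrives as a flat catalog TSV (`gene_id`, `symbol`, `go_ids`,
`interpro_ids`; multi-values semicolon-delimited, one row per gene — any
probe-set-to-gene collapsing happens upstream). Values must already be
log2; the loader rejects matrices whose maximum exceeds a plausible log2
range rather than guessing the scale, because silent conversion is a
correctness hazard.

## Transcription-factor universe and families

TFs are the catalog genes whose GO annotation intersects a flat
39-accession transcription-related term set that ships with the package
(GO release 2009-01-25 vintage; `lineagetf/data/go_tf_terms.txt`).
Matching is by exact accession — the term set is a flat list, so no
ontology-graph propagation to descendants is attempted. Families combine
an InterPro accession (bHLH = IPR001092) with an optional explicit member
list; explicit members missing from the catalog are ignored with a
warning.

## Behavior classification

For each lineage, r_g(t) = x_g(t) − x_g(0) on the log2 scale. Time point
t fires upward for gene g iff

    r_g(t) > f   or   r_g(t) > μ_t + k·σ_t

with fold threshold f = 1.0 (two-fold) and k = 3.0 by default;
downward firing is the mirror image (−f, μ_t − k·σ_t). μ_t and σ_t
(population sd, ddof = 0) are taken across **all catalog genes** at that
time point — an array-wide outlier criterion computable without
replicates. The reference population for the adaptive bound is a genuine
design choice (per-gene-across-time is the main alternative); the
array-wide convention was chosen because it needs no replication
structure and keeps the two criteria interpretable as "absolute fold OR
array-adaptive outlier". Callers can supply their own bounds to
`classify_gene` to change the convention.

Calls are existential over time points: ↑ if only upward firings exist,
↓ if only downward, ↑↓ if both (necessarily at distinct times), ≈ if
none. Inequalities are strict — a ratio of exactly 1.0 does not fire.
Consequences asserted by the property suite: calls are invariant under
time-point permutation; raising f never converts ≈ into ↑/↓; as k → ∞
the rule reduces to the pure ±f fold rule.

The cross-lineage 4×4 contingency table counts genes by (adipocyte call,
osteoblast call) in the fixed order ↑, ↓, ↑↓, ≈. "Changed" genes are the
grand total minus the (≈, ≈) cell. Switch candidates are genes with
exactly (↑ osteoblast, ↓ adipocyte) or the reverse — pure calls only,
↑↓ excluded — sorted by gene id.

## Phase structure

Phase windows are contiguous half-open intervals [start, end) covering
every sampling time (the last window is closed). Defaults:

* osteoblast — 1hr [0.5, 3), 6-24hr [3, 27), 30-48hr [27, 60),
  4-6d [60, 168), 8-14d [168, 336];
* adipocyte — 2d [1, 60), 4d [60, 120), 8d [120, 216), 10-14d [216, 336].

The adipocyte boundaries beyond the 2 d / 4 d / 10–14 d cluster labels
are a documented choice (the course is sampled sparsely there); the 2 d
window opens at 1 h so the windows cover the early 2 h sample required by
the coverage invariant. All windows are configurable.

Assignment: each fired direction of a regulated gene yields one
assignment — UP at the argmax of the raw ratio over up-fired time points
(earliest time wins ties), DOWN at the argmin over down-fired points; the
peak time selects the containing window. Assignment reads raw ratios, so
it is invariant to any profile standardisation used for display
clustering. ≈ genes yield nothing, ↑↓ genes exactly two assignments.

Window detection (auxiliary route): sample columns are clustered with
correlation distance and average linkage; the number of clusters
k ≤ max_phases is chosen at the largest jump in merge height (no jump ⇒
one window); the labelling is converted to contiguous-in-time runs, and
if a cut crosses non-adjacent times the most similar adjacent runs are
merged until at most max_phases remain. Boundaries fall halfway between
adjacent groups. Fixed windows plus peak assignment is the canonical
route; detection exists to check that the sample structure itself
supports the chosen windows.

Heat-map gene ordering: per-lineage profiles are z-scored per gene
(population sd; constant profiles map to zeros with a logged note),
concatenated across lineages, and clustered agglomeratively
(scipy.cluster.hierarchy; correlation distance, average linkage by
default — the standard choices for expression heat maps). The gene order
is the left-to-right leaf traversal; scipy's linkage on a condensed
distance matrix is deterministic for a fixed input order. Genes constant
in both lineages cannot enter correlation clustering and are appended
unclustered.

## Family enrichment

Per (phase, family) pair: a = |P∩F|, b = |P∖F|, c = |F∖P|,
d = |background ∖ (P∪F)|, with the background = all catalog genes (the
stand-in for the full array universe). The statistic is the uncorrected
Pearson chi-square at df = 1 (closed form N(ad−bc)²/∏marginals, verified
against Σ(O−E)²/E and scipy in tests); the p-value is the upper tail of
χ²(1). Yates correction and Bonferroni adjustment exist as flags, both
off by default. Pairs with a zero marginal (empty phase, empty family, or
a set spanning the whole background) are untestable and are skipped with
a logged note rather than aborting a run — empty phases are routine on
sparse courses.

## Synthetic data

`build_reference_fixture()` is deterministic and noiseless: 110 TFs, each
plateauing at +2.0 log2 across its curated osteoblast phase window and
sitting at baseline (8.0) elsewhere. The curated ↑↓ genes (Id1, Id2,
Npas4, Atoh8) add a −1.5 plateau over the last osteoblast window. On the
adipocyte grid the eleven bHLH genes realise their curated behavior
(±2.0 plateaus in the labelled cluster window, ±0.2 alternating wiggles
for the unchanged three); every other gene carries the same deterministic
sub-threshold ±0.2 wiggle rather than exact zeros, so the array-wide σ_t
never collapses at time points where nothing is regulated (exact zeros
would make the adaptive bound fire on the wiggle itself). Amplitude 2.0
(four-fold) satisfies both the log2 > 1 rule and the two-fold switch
criterion with margin, making noiseless recovery exact; 0.2 stays well
below every firing criterion.

`generate_dataset(config)` adds `n_background_genes` unchanged genes
(baselines uniform in [6, 12], per-sample offsets uniform within ±0.2),
tags the first `n_family_background` of them with the bHLH InterPro
accession (they carry no TF GO term, so they enlarge the family
background without entering classification), appends the fixture by
default, and finally adds Gaussian noise (`noise_sd_log2`, default 0) to
every measurement including the control. All randomness flows from one
integer seed; a fixed seed gives byte-identical output.

Default time grids: osteoblast 15 points (1, 3, 6, 12, 18, 24, 30, 36,
48, 96, 120, 144, 192, 240, 336 h), adipocyte 7 points (2, 24, 48, 96,
168, 240, 336 h), control at 0 h.

What passing tests on this generator do **not** show about real data:
the generator has no probe-level structure, no baseline-dependent
variance, no temporally correlated noise, and its regulated genes are
cleanly separated from the thresholds, so recovery rates here are upper
bounds on what thresholded classification achieves on real arrays.

Known limitation of the fixture: only the eleven curated bHLH genes are
family-tagged among the 110 (the full family annotation of the curated
lists is not machine-readable). Four of them peak in the second
osteoblast phase, so against a synthetic background the family tests
enriched in the second phase as well as the first; phase-specificity of
the enrichment depends on family/background counts that only the real
array provides.

## Pipeline and outputs

Stages: load/simulate → TF selection → ratios → classification →
contingency → switch candidates → phase assignment → heat-map ordering →
enrichment. Any stage error aborts with the stage name and removes
partial outputs; every default in effect is logged. Outputs:
`behavior_calls.tsv`, `contingency.tsv`/`.json`,
`phase_membership_<lineage>.tsv`, `enrichment.tsv`,
`switch_candidates.tsv`, `gene_order.txt`, `run_report.json`, and (for
simulated runs) the generated dataset. Reruns with the same config and
seed are byte-identical; the run report stores file names rather than
absolute paths for that reason.

## Problem sizes used in tests

The test suite and the reproduction script run the fixture (110 genes ×
23 samples), a 20,000-gene background for the enrichment computation, and
2,000-gene backgrounds across five seeds for the noise-robustness check
(noise sd 0.1 log2, ≥95 % of fixture genes must keep their noiseless
calls). These sizes match the study conditions the generator emulates
while keeping the whole suite fast.
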