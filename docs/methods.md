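# Methods

This note documents the models and procedures `crosstalknet` implements,
the parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical and design choices made where the design was
genuinely open.

## Study design being modeled

The pipeline targets factorial treatment transcriptomics: a cell line
profiled under a mock control and six treatment arms (three agents singly
and in all combinations, the default labels being Doxo, E2, TNFa and their
combinations), with the triple combination as the *focal* condition. Every
treatment is contrasted against mock. The quantities of interest are the
genes responding exclusively to the focal combination, the upstream
receptors best connected to them in a signed interaction network, the gene
sets those genes activate, and the normal tissue they are specific to.

## Rank-product differential expression

For a contrast with *t* treated and *c* control replicates, all *t·c*
replicate pairings form the ratio matrix (two-class all-pairs
construction). Per column, genes receive ranks 1..n (average ranks on
ties); the statistic is the geometric mean of rank/n over the *k* columns,
separately for the up direction (rank 1 = largest ratio) and down
(rank 1 = smallest). The per-gene log of the normalized ranks is summed in
sorted order so that genes with identical rank multisets receive
bit-identical statistics regardless of column order — this keeps the
permutation counting below exactly reproducible.

The percentage of false positives (pfp) is estimated from B permutations
that shuffle gene labels independently within each ratio column. With
genes ordered by ascending observed RP (position r), the expected
false-positive count at RP(g) is #{permuted RP ≤ RP(g)}/B, and
pfp(g) = E[FP](g)/r, forced monotone non-decreasing along the sorted order
by a cumulative maximum (finite-B rank inversions would otherwise produce
non-monotone pfp). B < 100 is rejected as unstable. A gene is called when
pfp < 0.05 and |log2FC| > 2, both strict; log2FC is the difference of
condition means on the log2 scale.

A paired (one-class) rank-product scheme is not implemented: the design
table carries no replicate pairing, and the two-class all-pairs form is
the standard construction for unpaired two-group comparisons.

## Context-specific DEGs and concordance

A CS-DEG is a gene called (in either direction) in the focal condition and
in no other compared condition. A direction-aware variant
(`direction_aware=True`) instead discards a gene only when another
condition calls it in the *same* direction. Exclusivity is assessed on
called sets, not on fold-change margins.

The concordance analysis fits, by OLS with intercept,

    fc_triple ~ fc_double_1 + fc_double_2

over genes called in any of the three contrasts, and reports coefficients,
t statistics, and sequential (type-I) ANOVA F values computed by explicit
nested refits (RSS decomposition). Sequential sums of squares were chosen
because the question is which double treatment is the *main component* of
an ordered model; with correlated predictors the order matters and is part
of the report. Fewer than four observations or a rank-deficient design is
an error.

## PLS-DA

X (samples × genes) is mean-centered and unit-variance scaled — constant
genes are rejected by name — and Y is the centered one-hot class
indicator. Components come from the NIPALS PLS2 iteration (w ← X'u
normalized, t ← Xw, q ← Y't/t't, u ← Yq/q'q) iterated to a score change
below 1e-10 or 500 iterations, deflating X and Y by each component.
Classification takes the class with the largest predicted indicator score.

Cross-validation is stratified k-fold (default 5 folds, 10 repeats,
components 1..10), reducing folds with a warning when the smallest class
is smaller than the fold count. The selected component count is the
smallest whose mean accuracy is within one standard error of the maximum —
a parsimony rule; the emulated analyses report only that the count was
chosen "from performance results", so the 1-SE rule is this package's
choice. Confidence ellipses use the χ²(2 df) quantile at level 0.954
applied to each class's 2-D score covariance eigen-decomposition; a
singular covariance is flagged degenerate rather than rejected.

Null-accuracy caveat: conditional on a single dataset, cross-validated
accuracy under label permutation can sit well away from 1/#classes because
chance dataset-level correlations generalize across folds of the same
data; null calibration must average over label permutations (the tests
do).

## Receptor-anchored network scoring (NAS)

Edge weights realize "information cost" as the self-information of a
uniform random out-step: w(u→v) = log2(outdeg(u)) bits. A path's cost is
then −log2 of its probability under a uniform random walk, so minimum-cost
paths are maximum-probability paths. This realization is a replaceable
strategy — any non-negative edge-weighting slots into the same shortest-
path machinery.

Receptors are scored by coverage/(1 + mean cost), with coverage the
fraction of molecules reachable by forward traversal and the mean over
reached molecules' minimum path costs; receptors reaching nothing are
excluded. Among equal-cost paths the lexicographically smallest node
sequence is kept (Dijkstra keyed on (cost, node sequence) — valid because
weights are non-negative and a path never sorts below its own prefix), so
subnetworks are deterministic. Subnetworks keep only nodes and edges lying
on a kept path. The top R receptors (default 3) are carried forward.

For a reference set P on analysis universe U (genes present in both the
expression matrix and the network, stated in the output metadata):

    nfc(g) = |log2FC(g)| / max over molecules |log2FC|
    NAS(P) = k · mean_nfc / |P ∩ U|,   k = |molecules ∩ P ∩ U|

NAS is 0 when k = 0, at most 1, invariant to rescaling all fold changes,
and strictly decreasing when a non-molecule gene joins P. The permutation
p value redraws |molecules| genes uniformly from U, reassigns the observed
nfc values, and uses the add-one estimator (1 + #{NAS_null ≥ NAS_obs})/(1 + B);
a hypergeometric upper-tail p with Benjamini–Hochberg adjustment across
sets accompanies it. BH was chosen because the emulated analyses report
"adjusted p" without naming a method.

Because |P ∩ U| is the NAS denominator, sets nearly disjoint from the
universe get unstable, inflated scores; the pipeline therefore drops sets
with fewer than `min_set_size` (default 10) genes on the universe before
scoring, the same guard gene-set enrichment tools apply. The library
function leaves the filter off by default.

## Integrated-network topology

The selected receptor subnetwork is expanded by one neighborhood: every
background node adjacent (either direction) to a subnetwork node joins,
with all induced signed edges. Betweenness (normalized by (n−1)(n−2) on
ordered pairs) and stress centrality (raw counts of shortest paths through
a node, σ_sv·σ_vt summed where d_sv + d_vt = d_st) are computed on the
directed graph with unit edge lengths by default; an undirected toggle is
provided because the mode of the original desktop computation is
unstated. The degree distribution is fit by least squares on
(log10 degree, log10 count) over total degrees with count ≥ 1, reporting
amplitude, exponent and the R² of the log-log line — the raw-count
convention of network-analyzer tools, not a maximum-likelihood exponent.
Individual scale-free graphs can draw ragged tails (singleton high-degree
bins) that depress R²; the slope sign is the robust diagnostic.

## Tissue DEG sets and query enrichment

The panel is zero-mean normalized per gene across all samples. Per tissue,
each gene gets a Welch (unequal-variance) two-sided t-test of that
tissue's samples versus all others — Welch because tissue variances
differ and the emulated method states only "two-sided t-test" — with logFC
the tissue-minus-rest mean difference on the normalized scale. BH runs
jointly over all gene × tissue tests (the family is not stated in the
emulated method; the joint family is the conservative choice). Membership
requires adjusted p ≤ 0.05 and |logFC| ≥ 0.58, both non-strict, with
direction from the logFC sign. Tissues with fewer than two samples are
skipped with a warning.

A directed query is tested against each tissue's up ∪ down set by a
one-sided hypergeometric test, BH across tissues; per tissue the report
includes the fraction of overlapping genes whose query direction matches
the tissue-set direction. Testing the union with a separate direction
report (rather than testing up and down sets separately) keeps one test
per tissue while still exposing the down-under-treatment /
up-in-normal-tissue pattern.

## Synthetic data: what it emulates and what it does not

The generator plants known structure so that every stage has a recovery
oracle:

- **Expression**: per-gene baseline log2 level uniform in
  `baseline_mean_range` (default 6–12), i.i.d. Gaussian replicate noise
  (`noise_sd`, default 0.25), planted shifts of ±`effect_size` (default
  3.0, above the |log2FC| > 2 calling threshold). Non-focal conditions
  draw nested prefixes of a shared DEG pool so they overlap; the focal
  condition adds `n_exclusive_focal` fresh genes (default 71), giving an
  exact planted CS-DEG set. The down-regulated fraction defaults to 43/71.
  Default replicate count is 3 per arm — a convention, as the emulated
  arrays do not state one.
- **Network**: a preferential-attachment skeleton with randomly oriented
  edges, signs inhibitory with probability 58/337 ≈ 0.172, receptors as
  extra nodes; module genes not already reachable from their assigned
  receptor get a direct activating edge, so receptor-module plantedness is
  a construction guarantee, not a probability. Default 300 nodes, 2 edges
  per node, 3 receptors of which 1 is wired.
- **Gene sets**: one enriched set per non-empty module carrying ≥ 70% of
  its module plus uniform background genes; decoys drawn uniformly.
- **Tissue panel**: 30 tissues with `n_panel_replicates` samples each
  (default 10 — multi-tissue reference panels are deeply sampled, unlike
  the 3-replicate treatment arms; with 3 samples a Welch test has ~2
  degrees of freedom and marker recovery collapses under the joint BH
  family). Each tissue's markers (default 10) are up-shifted by
  `effect_size` in that tissue only; marker assignments must not overlap.

All four generators are deterministic given the config seed, with
independent RNG streams so call order is irrelevant.

Not emulated: probe-level microarray structure, normalization artifacts,
batch effects, correlated noise, variance heterogeneity between genes,
partial or noisy network knowledge, and gene sets with antagonistic
(mixed-direction) signal. Passing recovery tests therefore demonstrates
the correctness of the machinery under the stated noise model, not its
power on real arrays, where effect sizes are smaller and noise is
structured.

## Pipeline and problem sizes

`run_all` executes deg → csdeg → plsda → nas → topology → tissue, each
stage reading only prior-stage outputs, and writes a JSON manifest with
the package version, the full config, per-stage seeds (derived from the
global seed by stable hashing of stage names, so stages are independently
reproducible) and SHA-256 digests of all inputs. All writers emit sorted
output; two runs of one config are byte-identical apart from the
absolute paths recorded in the manifest.

The bundled demo uses 1200 genes, a 300-node network, 20 gene sets, a
30-tissue panel, 200 permutations for pfp and 500 for NAS — sizes chosen
so a full run finishes in seconds on one CPU while keeping every planted
recovery comfortably powered. The acceptance script adds a null
calibration at 200 genes × 10 seeds × 100 permutations.

## Known limitations

- The pfp estimator shares one null distribution across genes (pooled
  permuted RP values), as in the standard rank-product formulation; very
  small gene counts make it coarse.
- Receptor scoring is purely topological; edge signs are carried through
  subnetworks and counted, but path signs do not enter the score.
- The power-law fit is descriptive (least squares on binned counts), not
  an estimator of the true degree exponent.
- The stress/betweenness implementation enumerates all-pairs BFS and is
  intended for integrated networks of up to a few thousand nodes.
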