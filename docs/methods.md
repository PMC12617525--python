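# Methods

This note documents the models, parameters, and numerical choices behind
`cofracnet`, and what its synthetic benchmarks do and do not demonstrate.

## The co-elution model and the synthetic generator

CF-MS infers physical association from co-elution: subunits of an intact
complex migrate together through size-exclusion chromatography, so their
abundance profiles across fractions share a peak. The generator plants
this structure directly. Each complex receives a Gaussian peak with apex
drawn uniformly inside the fraction range (a two-peak-width margin keeps
peaks off the edges) and width drawn from `peak_width_range`; each member
gets the common apex plus an individual jitter of at most ±0.25 fractions
and a log-normal amplitude around `abundance_scale`. Background proteins
and members of complexes absent from a genotype receive independent
apexes. Per engine, observed counts are negative-binomial draws around
the profile (variance μ + `count_noise`·μ²; `count_noise = 0` returns the
noise-free continuous profile), and `dropout_prob` zeroes cells
independently.

Defaults encode the emulated study design: 50 complexes of 3–8 subunits,
100 background proteins, 96 fractions, three engines, `count_noise` 0.1,
`dropout_prob` 0.2. The jitter bound and the width range (3–6 fractions)
are coupled: with widths ≥ 3 fractions a worst-case 0.5-fraction apex
offset keeps noise-free within-complex Pearson r above 0.99, which is the
regime the recovery tests assume. The noise defaults were set so that
classifier cross-validation lands in a realistic 0.8–0.95+ auROC band
rather than in a trivially separable one.

Genotype rewiring draws one action per baseline complex per mutant
genotype from configurable probabilities: *deleted* (members become
independent), *split* (two disjoint parts of size ≥ 2 with distinct
apexes), *apex_shifted* (membership intact, new apex), or *kept*. The
rewiring log plus the baseline catalog reproduce each genotype's catalog,
and deleted complexes contribute no co-elution edges — both are asserted
in tests. Co-complex members share a subcompartment label so that the
plausibility filter never vetoes planted ground-truth edges; background
proteins are labelled at random across the full vocabulary.

What the generator does **not** emulate: peptide-to-protein inference,
shared peptides, abundance-dependent detectability, correlated dropout
between co-eluting proteins, chimeric peaks from proteins in several
assemblies, and retention-time drift between replicates. Passing the
recovery benchmarks therefore shows the pipeline is correct and well
calibrated under the stated co-elution model, not that it attains any
particular sensitivity on real lysates.

## Preprocessing

Fixed order per condition: impute missing cells to zero → drop proteins
detected in ≤ 1 fraction → average engines → normalize. Engine matrices
are aligned by the union of their protein sets with zero fill, so a
protein missed by one of three engines contributes its value divided by
three; union preserves single-engine identifications. Whether to
normalize before or after engine averaging is genuinely open; the order
above is fixed, logged in the report, and idempotent for row mode.
Row normalization divides each nonzero row by its sum; column
normalization (the fraction-bias/injection correction) does the same per
column; `both` applies row then column. All-zero rows and columns are
left untouched, so the zero pattern is conserved exactly and no NaN can
appear. Intensities are assumed log2-scale upstream; `log2_transform`
applies log2(x+1) when they are raw.

## Similarity features

The registry provides 13 named metrics; the classifiers accept any
registered subset, and `register_metric` adds user metrics. Conventions
that matter:

- degenerate profiles (all-zero or zero-variance) make any
  correlation-type metric 0, keeping the feature table total;
- rank metrics use midranks (ties);
- mutual information uses 5 equal-width bins per profile's observed range
  and is divided by log 5 to land in [0, 1]; a zero range gives 0;
- `cross_correlation_max` is the best Pearson over relative shifts of up
  to 2 fractions; `apex_match` is 1/(1+|Δapex|) with apex = argmax;
- `co_peak_count` counts shared fractions above each profile's upper
  quartile, scaled by the smaller peak count.

`compute_features` uses vectorized equivalents of the scalar definitions
(verified against a naive double loop to 1e-9 in the tests) and emits
pairs canonically ordered with `protein_a < protein_b`.

## PPI learning

Positives are within-complex pairs of the reference catalog restricted to
detected proteins; negatives are a uniform, seeded sample of detected
cross-complex pairs that are within-complex nowhere, at a 1:1 ratio by
default. Folds are stratified by label at the pair level. Each labeled
pair's score comes from the fold that held it out (asserted structurally
in a test); unlabeled pairs are scored by models refit on all labeled
pairs. Hyperparameters are fixed and exposed, never tuned silently:
500-tree random forest; standardized logistic regression (≤ 2000
iterations); standardized RBF margin classifier with Platt-style
probability calibration. The ensemble is the unweighted mean of the three
probabilities — the simplest order-independent combination. The default
threshold rule is Youden's J on the pooled CV ROC, with `fixed:<v>` and
`fpr_at:<v>` available to reproduce externally chosen cutoffs; ROC-point
ties break toward the higher cutoff. The plausibility filter removes
edges joining OMM–matrix or IMS–matrix; unannotated endpoints pass but
are flagged.

## Complex detection

Cohesiveness f(V) = w_in/(w_in + w_bound + p·|V|) with per-node penalty
p = 2 by default (the penalty models unobserved edges; p → ∞ drives every
score to 0). Seeds are unused nodes in descending weighted-degree order;
growth takes the best strict single-node improvement (ε = 1e-12),
visiting candidates in sorted order for determinism. Candidate groups
with pairwise ω > o merge transitively; merged unions are re-grown so
that every reported group is locally optimal under single-node moves, and
the merge+regrow loop runs to a fixpoint, making the merge pass
idempotent. Filters apply after merging (order is fixed because it
affects results): size ≥ 3 and weighted internal density ≥ d. Evaluation
uses the standard clustering-wise Sn/PPV confusion matrix
(Acc = √(Sn·PPV)), MMR via an exact assignment solver on the ω matrix,
and Overlap = fraction of reference complexes matched at ω ≥ 0.25; grid
selection maximizes Acc + Overlap + MMR with ties toward higher d then
higher o. Exhaustive cohesiveness optimization is intentionally absent;
brute force serves only as a test oracle on ≤ 10-node graphs.

## Differential analyses

Intersection cells partition the edge union by exact presence pattern, so
cell counts sum to the union size (asserted on every run). "Lost" means
above threshold in the reference network and absent from every comparison
network; per-hub percentages count each lost edge at both endpoints and
therefore sum to 200 over involved proteins. The per-protein change
ranking is log2((Σb+ε)/(Σa+ε)) of summed abundances with ε = 1 (a
per-fraction mean-log-ratio variant is a config switch; neither is
asserted as canonical). GSEA uses the weighted Kolmogorov–Smirnov running
sum (weight exponent 1; 0 gives the classical KS statistic), a gene-label
permutation null (implemented as random same-size member sets, which is
equivalent and allows caching per set size), same-sign p-values with the
+1 correction, NES = ES over the mean |same-sign null ES|, and BH across
complexes. Minimal attainable p is 1/(1 + #same-sign nulls).

## Spatial DEG scoring

Spot selection is conjunctive: region label, soma flag, and every marker
count ≥ the floor; attrition is reported per criterion. Expression is
scaled per spot to a fixed 10,000-count total and log2(x+1)-transformed
before statistics. A fixed reference total (rather than a data-dependent
one such as the median spot total) was chosen so that multiplying all
counts by a constant provably changes nothing downstream — a property the
test suite checks exactly. The t-test is Welch by default (Student via
config); genes with zero variance in both groups get P = 1. In FCS the
pseudocount (ε = 1) enters the ratio only when either mean is zero, and
in SNS only when σ_HOM + σ_WT = 0, so the hand-checkable formula values
are exact (to 1e-12) away from those degeneracies. The top-20% rule uses
dense descending ranks on absolute scores (a signed mode exists), cutoff
⌈0.2·N⌉ per score, and both score criteria plus P < 0.05 must hold.

## Orchestration, determinism and problem sizes

Every stochastic stage derives a named sub-seed from the master seed via
SHA-256 (`stage_seed`), so no stage reads global randomness and runs are
reproducible end to end; floats are written at 6 significant digits and
all writers order rows deterministically, giving byte-identical outputs
across runs (the manifest's timestamps excepted). The acceptance script
and the heavier tests use the full default conditions for classifier
evaluation (50 complexes, 96 fractions, three engines) and smaller
planted instances elsewhere — 12 complexes for clustering recovery, 10
for differential soundness, 500 genes × 200 sets × 1000 permutations for
GSEA calibration, and a 6-complex, 2-engine configuration for the
double-run determinism check; these sizes are the package's benchmark
choices and are stated in the relevant functions' defaults.

## Known limitations

- The similarity registry is an explicit functional stand-in for the
  larger metric panels used by dedicated CF-MS scoring software; the
  count and identity of metrics are configurable, not canonical.
- Negative sampling treats all cross-complex pairs as true negatives;
  genuinely interacting pairs outside the reference catalog contaminate
  the negatives at a rate the synthetic benchmark does not model.
- The greedy cohesiveness search is locally, not globally, optimal.
- Complex-level GSEA on summed-abundance rankings cannot distinguish a
  complex whose subunits change abundance from one whose members merely
  redistribute across fractions; the per-fraction ranking switch probes
  the latter.
- Disease/ontology enrichment of genotype-exclusive assemblies is out of
  scope (database-dependent); the assembly sets it would consume are
  exported.
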