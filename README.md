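# cofracnet

Co-fractionation mass-spectrometry (CF-MS) interactome analysis for
multi-genotype study designs, plus a spot-level differential-expression
scoring arm for spatial transcriptomics. The package is aimed at
proteomics / systems-biology researchers who have per-search-engine
protein × fraction abundance matrices from size-exclusion chromatography
(SEC) of native lysates and want to go from elution profiles to predicted
protein–protein interactions (PPIs), protein complexes, and cross-genotype
differences — or who want to benchmark such a pipeline end to end on
synthetic data with planted ground truth.

## What it computes

**CF-MS arm.** For each (genotype, extract) condition the pipeline

1. preprocesses per-engine matrices: zero-imputation of missing cells,
   removal of proteins detected in only one fraction, engine averaging
   (union alignment, zero fill), then row- and column-wise normalization;
2. computes a per-pair vector of co-elution similarity features
   (Pearson/Spearman/Kendall, cosine, Jaccard/Dice co-detection,
   Bray–Curtis, distance similarities, apex matching, shift-tolerant
   cross-correlation, binned mutual information, co-peak counts);
3. trains three classifiers — random forest, logistic regression, and an
   RBF margin classifier with probability calibration — on within-complex
   pairs of a reference complex catalog (CORUM-style GMT) versus sampled
   cross-complex pairs, evaluates them by fivefold cross-validation
   (pooled auROC), and averages their probabilities into an ensemble;
4. thresholds the ensemble score (Youden J on the pooled CV ROC by
   default) and removes biologically implausible edges joining the outer
   membrane to the matrix or the intermembrane space to the matrix;
5. detects overlapping complexes by a cohesiveness-greedy local search
   (ClusterONE-style), where the cohesiveness of a node set V is

       f(V) = w_in / (w_in + w_bound + p·|V|),

   sweeping minimum density d ∈ [0.2, 0.45] and merge overlap
   o ∈ [0.5, 0.8] and keeping the grid cell maximizing the composite
   score Acc + Overlap + MMR against the reference catalog
   (ω(A,B) = |A∩B|²/(|A|·|B|), match at ω ≥ 0.25);
6. compares genotypes: exact presence-pattern intersection counts of the
   edge union, lost-interaction reports with per-hub attribution
   percentages, and GSEA of predicted complexes (as gene sets) against a
   per-protein co-elution change ranking with a gene-label permutation
   null and Benjamini–Hochberg adjustment.

**Spatial arm.** Spots are restricted to a region by dopaminergic marker
expression (Th, Dat, Vmat2) and soma presence; per-gene group statistics
(μ, σ, Welch t-test P) feed two ranking scores,

    FCS = log2(μ_HOM / μ_WT) · (−log10 P)
    SNS = ((μ_HOM − μ_WT) / (σ_HOM + σ_WT)) · (−log10 P)

and genes with P < 0.05 ranking in the top 20% by |FCS| **and** |SNS| are
called DEGs.

**Synthetic data.** `cofracnet.synth` plants complexes (Gaussian
co-elution peaks over 96 fractions, negative-binomial counts, dropout,
per-engine replicates), rewires them per genotype (delete / split /
apex-shift), and generates spot × gene count tables with planted DEGs —
so every stage above is testable against exact ground truth.

## Worked example

```python
import cofracnet as cf
from cofracnet.pipeline import stage_seed

cfg = cf.SimulationConfig(seed=stage_seed(20240901, "simulate"))  # 50 complexes, 96 fractions
truth = cf.generate_truth(cfg)
matrix, _ = cf.preprocess_condition(cf.simulate_elution(truth, cfg, "WT"))
features = cf.compute_features(matrix)
training = cf.build_training(truth.catalogs["WT"], matrix.proteins,
                             seed=stage_seed(20240901, "training"))
scores, report = cf.train_and_score(features, training,
                                    seed=stage_seed(20240901, "predict"))
for name, cv in report.per_model.items():
    print(name, round(cv.pooled_auroc, 4))
```

prints

```
rf 0.9858
glm 0.9856
svm 0.9843
ensemble 0.9861
```

i.e. on the default synthetic conditions each classifier separates
within-complex from cross-complex pairs with pooled CV auROC ≈ 0.99, and
the ensemble is at least as good as the best single model. Thresholding
with `cf.select_threshold(report)` and clustering the resulting network
with `cf.optimize_params(...)` then recovers the planted complexes (on
noise-free planted networks the composite score reaches 3.0 — perfect
accuracy, overlap and maximum matching ratio).

A complete synthetic run (simulate → preprocess → features → predict →
cluster → differential) is one call — `cf.run_pipeline(config, outdir,
master_seed)` — or one shell command:

```bash
cofracnet run-all --seed 7 --outdir out/
cofracnet spatial-deg --seed 7 --outdir out_spatial/
```

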