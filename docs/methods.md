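# Methods

`recurpath` reimplements, as a tested pipeline, a pathway-centric analysis of
tumor recurrence in paired primary/recurrent expression panels: digital-count
normalization, paired differential expression, gene-set over-representation,
network hub ranking, immune deconvolution, and — the core — per-pathway
pairwise convolutional classifiers whose Shapley-consensus features yield a
ranked recurrence signature evaluated against disease-free survival.

## Count-panel normalization

Digital count panels carry six positive spike-in controls on a 4-fold
concentration ladder, eight negative controls, and housekeeping probes.
Normalization runs in the conventional order — positive-control scaling,
background flagging, housekeeping normalization — with each step as follows.

* **Positive-control factor.** `factor_s` = (grand mean of per-sample
  positive-control geometric means) / (geometric mean in sample *s*).
  Applying the factors equalizes the control geomeans; the operation is
  idempotent.
* **Background threshold.** Mean of all pooled negative-control counts plus
  two sample (n−1) standard deviations. A lower bound is meaningless for
  background exclusion, so only the upper bound is used. A gene is excluded
  only when below threshold in *every* sample.
* **geNorm reference selection.** Stability `M_j` = mean over partners *k* of
  the SD of the pairwise log2 ratio `log2 x_j − log2 x_k`; the least stable
  candidate is iteratively removed until the target count (default 5)
  remains. Ties break on gene id. Counts are offset by +1 before logs in
  control and housekeeping computations because FFPE panels contain zeros.
* **Housekeeping normalization.** Samples are scaled so reference-gene
  geometric means are equal across samples.

The n−1 standard deviation is used throughout (small negative-control
samples; unbiased estimator).

## Paired differential expression

The design is a strict paired contrast over (by default) 7 patients. The
log2 fold change per gene is the mean of per-patient log2 differences
(recurrent − primary); significance is a two-sided paired t-test on those
differences. Degenerate genes: all-zero differences give p = 1; identical
non-zero differences give the smallest positive float (the t statistic
diverges), logged. Multiplicity is controlled with Benjamini–Hochberg
q-values; a single-λ Storey estimate (λ = 0.5) is available by config for
users who prefer a π₀-adaptive q-value, but BH is the deterministic default.
A gene is a DEG when q ≤ 0.05 and |linear fold change| ≥ 1.5, both bounds
inclusive.

## Enrichment and term curation

Over-representation uses the hypergeometric upper tail with the panel genes
surviving the background filter as the universe — for a ~760-gene panel the
genome-wide universe would overstate enrichment, and the panel universe is
the honest choice. BH adjustment is applied within each category (pathways
and GO biological processes are separate libraries). Two tiers:

* report tier: adjusted p < 0.001, top 10 per category;
* curation tier (feeds the classifiers): adjusted p < 0.05 with ≥ 5
  overlapping DEGs for pathways and ≥ 10 for GO terms.

Bridge genes are genes linked to ≥ 5 of the top-5 pathways plus top-5 GO
terms in the gene–term bipartite graph; "top" means smallest adjusted p
within each category.

## Network hubs

Maximal Clique Centrality: `MCC(v) = Σ_{maximal cliques C ∋ v} (|C|−1)!`,
with `MCC(v) = deg(v)` when v's neighborhood has no internal edge. Cliques
come from Bron–Kerbosch enumeration with pivoting (networkx); the
exponential worst case is guarded by a node bound (default 5,000, warning
above 500) — DEG-scale PPI subnetworks of ~160 nodes are tractable. Hub
ranking breaks MCC ties by degree, then gene id. The module consumes an edge
list already filtered at the user's confidence cutoff (0.4 "medium" is the
conventional choice).

## Immune deconvolution

Bulk expression is modelled as a non-negative mixture of 22 reference
cell-type profiles: fractions minimize ‖S·w − x‖₂ subject to w ≥ 0 (NNLS) on
the shared signature genes, then renormalize to sum to one. An optional
per-gene median-matching alignment of the signature to the mixture serves as
a lightweight cross-platform correction. Noiseless mixtures of full-rank
signatures are recovered to 1e−6; at 5% relative noise the median maximum
per-type error stays below 0.05. Paired group differences per cell type use
the exact two-sided Wilcoxon signed-rank test (n ≤ 25), with the usual
significance stars.

## Pairwise classifier

With hundreds of primary samples (study + augmentation cohorts) but few
recurrent ones, classification is pairwise: primary–primary (PP) pairs are
one class, primary–recurrent (PR) pairs the other, multiplying the instance
count and absorbing the class imbalance into pair construction.

* **Standardization.** Within each curated term, every sample's expression
  vector over the term's genes is scaled to mean 0 / population-SD 1. Models
  therefore see only relative expression patterns among pathway genes —
  cross-cohort level differences cancel. A consequence worth knowing: a
  shift planted on a *majority* of a term's genes is partly absorbed into
  the per-sample mean and re-expressed on the unshifted minority, so the
  discriminative unit is the term's pattern, not any single gene.
* **Architecture.** Input genes × 2; a 16-filter convolution with a 1 × 2
  kernel spans the two-sample axis (one learned contrast per gene, weights
  shared over genes), then dense layers of 32 and 16 rectified-linear units
  and a 2-way softmax. Cross-entropy loss, Adagrad optimizer. The network is
  implemented directly in numpy: models are tiny, and explicit passes are
  dependency-free and bit-reproducible from the seed.
* **Splitting.** Samples (not pairs) are partitioned 80/20, stratified by
  tissue class, before pairing; pairs form within each split so no sample
  leaks across the boundary. "Bootstrapping" is repeated random
  re-partitioning (10 iterations by default), not resampling with
  replacement.
* **Balance.** Each training epoch subsamples PP pairs to a 1:1 ratio with
  the PR pairs (reseeded per bootstrap). The *test* pair set is rebalanced
  the same way before scoring: against a PP-dominated test set the
  degenerate always-PP predictor scores far above 0.8 and the
  high-performer accuracy threshold loses its meaning.
* **Hyper-parameters.** Epochs 100, learning rate 0.05, batch 32 by default;
  all in config. These are convergence choices for tiny models, not tuned
  quantities.

## Shapley consensus and the discriminant score

Gene importance is the Shapley value of the gene (both pair-slots toggled
jointly) for the PR-class probability, estimated by permutation sampling
with background draws from the training pairs; the estimate satisfies
efficiency exactly against the mean background output. An exact 2^k
enumeration serves as the oracle for small gene counts. Per (gene, model)
the scalar importance is the mean absolute per-instance value — the common
sign-robust SHAP summary, since a scalar threshold is applied per feature
per model.

A bootstrap model is high-performing when test accuracy strictly exceeds
0.80. Within a term with H high performers, a gene is selected when its
importance is ≥ 0.01 in at least ⌈0.5·H⌉ of them (H = 8 → 4 of 8). The gene
discriminant score counts the terms (pathways + GO) selecting the gene; the
top 20 form the signature, with ties broken by mean importance then gene id.

For survival, a sample is "altered" when any signature gene's cohort
z-score (n−1 SD) strictly exceeds 2. Kaplan–Meier curves, group medians
(smallest time with survival ≤ 0.5; "not reached" otherwise) and the
two-group log-rank test come from lifelines.

## Synthetic data

The generators emulate the study conditions: 7 paired patients on a
760-gene panel (negative-binomial counts, log-normal gene dispersions,
patient random effects, library-size variation, 9:1 up:down planted fold
changes mirroring the strongly asymmetric DEG split); a 373-sample
primary-only augmentation cohort whose histology labels (8 + 3 + 2 excluded
categories) filter to 360, with deliberately shifted per-gene means so
cross-cohort models must rely on standardization; 40 random gene sets of
10–60 genes; a 22-type block-marker immune signature with Dirichlet mixture
fractions; exponential survival with a group hazard ratio.

What the generators do *not* emulate: real expression covariance between
genes, probe-level artifacts, platform-specific count distributions of the
augmentation cohort, or realistic immune signature collinearity. Passing
tests therefore demonstrate correctness of the computations and
recoverability under the modelled conditions, not performance on any real
cohort.

### Recovery benchmark

`simulate_recovery_benchmark` is the end-to-end test of the classifier +
consensus stages: 20 planted genes shifted 2 SD in recurrent samples, six
curated terms — three signal, three noise. Each planted gene belongs to two
of the three signal terms and is a minority (~40%) among term-specific
fillers, for two reasons: the standardization effect above (a planted
majority hands the contrast to the fillers), and the two-term membership
gives planted genes discriminant score 2 against 1 for any filler, so the
top-20 list isolates them. The benchmark cohort uses 50 primary and 16
recurrent samples: with very few recurrent samples the test split carries
only one or two PR samples and the Shapley estimates over test pairs become
too noisy to threshold reliably. At this size the benchmark recovers ≥ 90%
of planted genes per seed with signal-term accuracy ≈ 1.0 and null terms
near chance.

## Problem sizes and numerical choices

Default test-scale runs use: 10 bootstraps per term; 50 training epochs in
benchmark runs (signal is strong and converged); 18 Shapley permutations ×
18 test instances per bootstrap; 100–200 replicates for calibration checks;
500 replicates for log-rank null uniformity. Tolerances: 1e−12 relative for
closed-form oracles, 0.01 absolute for Monte-Carlo Shapley vs exact
enumeration, 1e−6 for noiseless deconvolution. Tie-breaks are deterministic
everywhere (documented per operation); all randomness flows from a single
integer seed.

## Known limitations

* The paired t-test stands in for the original platform software's
  unpublished test; DEG counts on real data may differ.
* The ν-SVR + batch-correction core of the reference deconvolution tool is
  proprietary; NNLS with optional median matching is a documented stand-in.
* "MCC" is implemented as Maximal Clique Centrality, the established hub
  statistic of that name; some sources expand the acronym differently.
* The train/test partition unit (samples) and ratio (80/20), the PP:PR
  balance ratio, and the SHAP aggregation (mean |value|) are design choices
  where the method description is silent; each is configurable.
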