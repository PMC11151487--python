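# recurpath

Pathway-centric pairwise deep-learning analysis of tumor recurrence in
expression panels.

## The problem

Hepatocellular carcinoma that recurs after resection or transplant is
profiled, at best, as a handful of paired primary/recurrent tumor samples on
a targeted count panel (~760 genes) — far too few samples to train a
classifier per pathway, and far too imbalanced once hundreds of public
primary-tissue samples are added for augmentation. `recurpath` implements a
complete analysis for this setting:

1. **Normalization** of digital count panels: positive-control scaling,
   negative-control background threshold (mean + 2 SD), geNorm selection of
   housekeeping references (stability statistic *M*), housekeeping
   normalization.
2. **Paired differential expression**: per-patient log2 differences, paired
   t-test, Benjamini–Hochberg q-values, DEGs at q ≤ 0.05 and |FC| ≥ 1.5.
3. **Enrichment**: hypergeometric over-representation of DEGs against
   pathway and GO collections, BH-adjusted per category; bridge genes linked
   to ≥ 5 of the top-5 terms per category.
4. **Network hubs**: Maximal Clique Centrality,
   MCC(v) = Σ_{cliques C ∋ v} (|C|−1)!, on a user-supplied PPI edge list.
5. **Immune deconvolution**: non-negative least squares against a 22-type
   signature matrix with sum-to-one fractions; paired Wilcoxon signed-rank
   comparisons.
6. **The core — pairwise classification**: for each curated term, samples
   are standardized per sample over the term's genes, all primary–primary
   and primary–recurrent sample pairs are formed, and a small convolutional
   network (16 filters with a 1×2 kernel across the pair axis, dense 32/16,
   softmax; Adagrad) is trained over 10 random train/test re-partitions.
   Gene importance is the Shapley value of each gene for the
   primary–recurrent output; a gene passes a term when its importance is
   ≥ 0.01 in at least half of the bootstraps exceeding 80% test accuracy.
   The **gene discriminant score** counts the terms selecting each gene; the
   top 20 genes form the recurrence signature, evaluated by Kaplan–Meier /
   log-rank comparison of "altered" samples (any signature gene with
   z-score > 2).

Every pipeline input can be generated synthetically with known ground truth
(`recurpath.synthetic`), so the full analysis is testable offline.

## Worked example

```python
from recurpath import PipelineConfig, RecurrenceSignatureModel
from recurpath.synthetic import simulate_recovery_benchmark

expr, meta, terms, planted = simulate_recovery_benchmark(seed=1)
cfg = PipelineConfig(n_bootstraps=10, epochs=50,
                     shap_permutations=18, shap_max_instances=18)
results = RecurrenceSignatureModel(expr, meta, terms, cfg).fit(seed=1)
print(results.summary())
```

prints (abridged):

```
Pathway-centric pairwise recurrence classifier
========================================================
terms: 6  bootstraps/term: 10  seed: 1
samples: 50 primary, 16 recurrent
pathway models: median accuracy 0.883, sensitivity 0.950, specificity 0.933
GO-term models: median accuracy 0.725, sensitivity 0.617, specificity 0.933
consensus-selected (term, gene) pairs: 114
top 20 signature genes by discriminant score:
 rank      gene  score  pathway_count  go_count
    1     sig14      2              1         1
    2     sig10      2              1         1
    3     sig16      2              1         1
  ...
   18     sig04      2              1         1
   19 noise1_29      1              1         0
   20 noise1_24      1              1         0
```

The benchmark plants 20 genes with a 2-SD shift in recurrent samples across
three signal terms alongside three pure-noise terms (the per-category
medians above mix signal and noise terms — each category holds some of
both). Signal-term models separate the pair classes nearly perfectly, noise
terms hover at chance, and the top-20 discriminant list recovers 18 of the
20 planted genes (`sig*`) at this seed. The full pipeline — simulation through survival — also runs
as a CLI:

```bash
recurpath --outdir run1 --seed 7 --stage all   # 9 stages + manifest.json
```

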