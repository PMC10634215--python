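# cfrna

Analysis toolkit for cell-free RNA (cfRNA) liquid biopsies in aggressive
B-cell lymphoma (DLBCL and PMBCL), covering four analyses that turn plasma
total-RNA sequencing counts into biomarkers:

1. **Absolute cfRNA concentration** from spike-in controls. With a known
   mass *m* of a synthetic spike added per sample, the concentration is
   estimated as `c = m · (N_endo / N_spike) / V` (ng RNA per mL plasma),
   where `N_endo` and `N_spike` are the deduplicated read counts mapping to
   the endogenous genome and to the spike, and `V` is the plasma volume.
2. **Differential abundance** between patient groups: count prefiltering
   (≥ 10 counts in at least half of one group; ≥ 4 back-splice junction
   counts for circRNAs), median-of-ratios normalization, and a per-gene
   negative-binomial Wald test (method-of-moments dispersion, log-link GLM
   fit by IRLS) with Benjamini–Hochberg correction; genes with q < 0.05 are
   called differentially abundant.
3. **Cell-of-origin (COO) classification** of DLBCL into GCB vs non-GCB
   from an oriented gene panel, by a normalized-rank score (difference of
   mean cross-cohort abundance percentiles between the two panel halves) or
   a standardized-abundance score (the same difference on per-gene z-scores
   of log₂ normalized counts), evaluated by ROC/AUC against
   immunohistochemistry (Hans) labels.
4. **Prognostic gene signatures**: per-gene univariate Cox screening
   (score-test p ≤ 0.01 and |β| above a configurable threshold), favorable/
   unfavorable orientation by the sign of β, average-linkage hierarchical
   clustering with an adaptive dendrogram cut, per-cluster signature scores
   (mean log₂ normalized expression), a multivariable Cox model jointly
   with the NCCN-IPI, maximally selected rank-statistic cutpoints, and
   Kaplan–Meier / log-rank risk stratification. The Cox engine
   (Newton–Raphson on the Breslow partial likelihood), Kaplan–Meier
   estimator, log-rank test and maxstat search are implemented from first
   principles and validated against independent oracles.

Gene-set overlap statistics (one-sided Fisher/hypergeometric test, odds
ratio, Jaccard index), direction-concordance counting for circRNA–host
pairs, Kruskal–Wallis/Wilcoxon group comparisons with Bonferroni–Holm
correction, Pearson correlation and ROC utilities round out the toolkit.

Because real plasma cohorts of this kind are controlled-access, the package
ships a **synthetic cohort generator** (`cfrna.simulate`) that emulates the
study design — three diagnostic groups plus healthy controls, planted
GCB/non-GCB effect genes, longitudinal responder trajectories, spike-in
reads, circRNA/host pairs, and survival outcomes generated from planted
gene-cluster expression — so every stage is testable end to end without any
download.

## Worked example

Simulate a cohort and run every stage from the shell:

```bash
cfrna --out-dir demo --seed 5 simulate --n-genes 500
cfrna --out-dir demo concentration --spikes demo/spikes.tsv --samples demo/samples.tsv
cfrna --out-dir demo da --counts demo/counts.tsv --samples demo/samples.tsv \
      --contrast group:control,DLBCL
cfrna --out-dir demo coo --counts demo/counts.tsv --samples demo/samples.tsv \
      --panel demo/panel.tsv
cfrna --out-dir demo survival --counts demo/counts.tsv --samples demo/samples.tsv \
      --endpoint pfs
```

which prints (panel built from the generator's planted COO genes):

```
cohort written to demo (500 genes x 77 samples)
Kruskal-Wallis p = 6.843e-11
160 significant genes -> demo/da_group_DLBCL_vs_control.tsv
rank: AUC=1.000 accuracy=1.000
z: AUC=1.000 accuracy=1.000
signature_0 (unfavorable, 8 genes): log-rank p = 2.9e-15
```

Reading the output: lymphoma samples carry twice the endogenous RNA mass of
controls by design, so the spike-based concentration comparison is strongly
significant; the differential-abundance stage recovers the planted disease
genes; the planted 64-gene panel separates GCB from non-GCB perfectly on
this separable cohort; and the survival screen finds an unfavorable
signature overlapping the planted 9-gene prognostic cluster, whose
high/low-risk split has the quoted log-rank p-value.

The same analyses are available as a library — estimator-style classes
(`CooClassifier`, `NBWaldTest`, `PrognosticPipeline`) with scikit-learn
`fit`/fitted-attribute conventions, and plain functions for the scalar
statistics (`jaccard`, `fisher_overlap`, `estimate_concentration`, ...).

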