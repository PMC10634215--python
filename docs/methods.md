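# Methods

This note documents the statistical models implemented in `cfrna`, their
assumptions, the defaults that matter, and the choices made where the
design was genuinely open. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Spike-in concentration estimation

A known mass `m` of a synthetic spike-in control is added to each plasma
sample before library preparation; the mass follows from the stock
concentration, the working-mix dilution factor and the volume added
(`m = stock × volume / dilution`; e.g. 2 µL of a 1/12,500 dilution of a
1 ng/µL stock is 1.6·10⁻⁴ ng). Because spike and endogenous molecules
share the capture and sequencing path, the endogenous/spike read ratio
estimates the mass ratio, giving

    c = m · (N_endo / N_spike) / V   [ng RNA / mL plasma].

The estimator is exactly invariant to common read scaling, linear in the
spike mass and inverse in the plasma volume. Assumptions: equal capture
efficiency for spike and endogenous RNA, and spike reads deep enough that
the Poisson relative error `1/√N_spike` is small. The spike used is the
most abundant control in the mix (configurable by name). A sample with
zero spike reads yields a flagged-undefined estimate, never a silent zero.
`N_endo` is taken as the deduplicated uniquely mapped endogenous count
supplied as an input column; the package never touches alignments, which
keeps the formula testable on counts alone. Whether the read counts in the
ratio are pre- or post-deduplication is a documented choice
(deduplicated), as the convention is not fixed by the estimator itself.

## Differential abundance

The prefilter keeps a gene when its count reaches 10 in at least
`⌈n/2⌉` samples of one of the two compared groups (the stricter ceiling
reading on odd group sizes); circRNA rows are filtered on back-splice
junction counts with threshold 4. Normalization uses median-of-ratios
size factors against the per-gene geometric mean, restricted to genes
expressed in every sample.

The per-gene test is an intentionally simple negative-binomial Wald test,
not a re-implementation of any full DA framework: variance `μ + φμ²` with
a per-gene method-of-moments dispersion (pooled within-group variance of
normalized counts, floored at 10⁻⁸), a log-link GLM with intercept and
group indicator fit by IRLS (the design is shared across genes, so the
weighted normal equations reduce to a closed-form 2×2 solve per gene,
vectorized over the matrix), a normal-reference Wald p-value for the group
coefficient, and Benjamini–Hochberg correction across tested genes.
There is no independent filtering and no fold-change shrinkage —
deliberately absent. Non-converged genes are flagged, get `p = NA`, and
are excluded from the BH denominator. The result schema (base mean,
log₂FC, SE, p, q, direction) is stable so an external engine could be
swapped in without touching downstream modules. Calibration under the
null and sign fidelity under planted effects are checked by simulation in
the test suite; note that median-of-ratios factors absorb part of a
strongly one-sided differential signal — a property shared by all
median-based normalizations.

## Overlap statistics

Overlap significance between two gene sets uses the one-sided
hypergeometric (Fisher) tail over an explicit universe — by convention the
union of genes tested in the two differential-abundance analyses — with
the unconditional sample odds ratio `ad/bc` (reported as infinite when
`bc = 0`), not the conditional MLE; the difference matters only at extreme
tables and the 2×2 table is included verbatim in every report since the
odds ratio depends on the universe size. The Jaccard index
`|A∩B| / |A∪B|` is defined 0 for two empty sets (logged). Group
comparisons use Kruskal–Wallis followed by pairwise Wilcoxon rank-sum
tests (exact permutation distribution when tie-free and n ≤ 40, normal
approximation otherwise) with Bonferroni–Holm correction. ROC analysis
computes AUC by the Mann–Whitney identity with ties counted ½, which
equals trapezoidal integration of the ROC curve.

## Cell-of-origin scoring

Both scores are **cohort-relative**. The normalized-rank score ranks each
panel gene's size-factor-normalized abundance across the scored cohort
(midranks for ties), maps rank r in 1..n to the percentile `(r−1)/n`, and
takes the mean percentile over the class-1 (GCB-up) genes minus the mean
over the class-2 genes; it is bounded by ±(n−1)/n and exactly invariant to
per-sample depth scaling. The standardized-abundance score z-scores
`log₂(normalized count + 1)` per gene across the cohort and takes the same
difference; zero-variance genes are dropped with a log entry. Positive
scores are evidence for class 1. Both scores negate exactly under a swap
of the two panel halves.

Since a cohort-relative score depends on the cohort, `CooClassifier.fit`
also freezes per-gene reference distributions (empirical quantiles for the
rank method, mean/SD for the z method, and a reference log-geometric-mean
profile for single-sample normalization) so new samples can be scored one
at a time against the training cohort. Classification thresholds default
to the Youden-J optimum on the training labels (a fixed threshold can be
supplied); the exact rank/tie conventions of the original scoring
procedures are not published, so the realization here is documented by its
own definition above and validated on synthetic cohorts with planted
class effects.

Panels are input files (two disjoint oriented gene lists); no published
panel gene list is hard-coded. A plasma-derived panel can be built from a
non-GCB-vs-GCB differential abundance table (significant genes split by
fold-change sign), which fails loudly if either side is empty.

## Survival analysis

All survival machinery is implemented directly and cross-checked against
independent references in the tests (a brute-force partial-likelihood grid
oracle, and lifelines).

**Cox engine.** Newton–Raphson maximization of the partial likelihood with
Breslow tie handling, step-halving to keep the likelihood monotone, and a
|β| cap at 20 with a non-convergence flag for monotone likelihoods
(perfect separation). Constant covariates short-circuit to a flagged
degenerate fit (β = 0, p = 1). The score test at β = 0 is reported as the
"log-rank p" of a univariate gene screen — for a binary covariate without
ties it is exactly the two-group log-rank test, and it is the standard
generalization for continuous covariates. Which test the original
procedure meant by "LogRank p" is unstated; the score test is the choice
here, with the Wald p also reported.

**Gene screen.** Genes enter on the z-scored log₂ normalized scale, so a
screening threshold |β| ≥ c means c log-hazard units per SD of expression.
The expression scale on which a published absolute-β cutoff was evaluated
is generally not reproducible; the threshold is therefore configuration
(default 2.0), and the synthetic-cohort validation passes a threshold
matched to the generator's z-scale (1.0) — see "Synthetic cohorts" below.

**Clustering.** Retained genes are clustered by average-linkage
hierarchical clustering on Euclidean distances between z-scored expression
profiles (genes as objects). Branch extraction uses an adaptive,
dendrogram-only cut in the spirit of dynamic tree cutting: a branch is
split where the joining height exceeds both children's internal heights by
at least a configurable fraction (default 0.15) of the joining height and
both children would hold at least `min_cluster_size` genes (default 3);
identical profiles therefore form a single cluster, and the cut adapts to
the tree instead of a fixed height (a fixed-height cut remains available
by flag). The hybrid variant of dynamic tree cutting, which re-assigns
outlying members using the full distance matrix, is not implemented.

**Signatures.** Each cluster's signature score is the per-sample
arithmetic mean of the members' log₂ normalized expression; orientation
(favorable/unfavorable) follows the mean sign of the members' screened β.
Signatures are tested jointly with the NCCN-IPI (encoded ordinally 0–3) in
a multivariable Cox model. The dichotomizing cutpoint maximizes the
standardized log-rank statistic |U|/√V over midpoints between consecutive
sorted unique scores within the 10th–90th percentile window. No
selection-bias-corrected p-value for the maximally selected statistic is
computed; an optional permutation p (label shuffles) is available instead,
and the reported log-rank p for the high/low split should be read as
optimistic because the cutpoint was selected to maximize separation.
High-risk is above the cutpoint for unfavorable signatures and below it
for favorable ones; regenerating risk groups from a stored signature model
reproduces the stored assignment exactly.

## Synthetic cohorts

The generator emulates the statistical structure of a plasma cfRNA
lymphoma study. Defaults: 22 controls, 41 DLBCL (20 GCB / 21 non-GCB),
14 PMBCL; gene baselines log₂-normal (location 4, scale 1.5); a single
global NB dispersion φ = 0.1; per-sample sequencing depth lognormal with
CV 20% so normalization does real work. Planted structure in the default
design: 100 DLBCL and 150 PMBCL disease genes at |log₂FC| = 2 (balanced up
and down), 64 COO genes at |log₂FC| = 1.5, one 9-gene PFS cluster and one
5-gene OS cluster. Longitudinal designs multiply the lymphoma effect by a
per-timepoint attenuation (responders 1.0 / 0.35 / 0.1 at diagnosis /
interim / final; non-responders ≈ 1).

Prognostic clusters are driven by a shared per-sample latent factor with
loading 1.5 on the log₂ scale, which both correlates the member genes
(needed for cluster recovery) and, summed over members as
`Σ β_sim · z_g + γ · IPI`, sets the exponential event-time hazard;
censoring is uniform over a 1500-day window. Survival is generated from
expression, never from labels, so the discovery pipeline is validated as a
discovery procedure. The per-gene `β_sim` values (0.5 for the PFS cluster,
0.8 for the OS cluster) were calibrated once, analytically and by pilot
simulation, so that the *marginal* per-gene Cox coefficient — which the
screen sees, and which is attenuated relative to `Σ β_sim` by imperfect
gene-gene correlation and by strong-effect rank compression — sits near
2–2.5 per SD at the default cohort size; recovery tests screen at the
matched threshold |β| ≥ 1 on this scale. No published effect-size
distribution exists for these quantities; the magnitudes are properties of
the simulation, not claims about any real cohort.

What the generator does **not** model: read-level artifacts (UMIs,
fragment length, GC bias), batch effects beyond depth, per-gene dispersion
trends, correlated gene networks outside the planted clusters, and
informative censoring. Passing recovery tests therefore demonstrates the
correctness of the algorithms under the stated model, not clinical
performance on real plasma data.

## Numerical choices and problem sizes

Tolerances: IRLS and Cox Newton–Raphson converge at relative step 10⁻⁸
and 10⁻⁹ respectively; dispersion floor 10⁻⁸; Cox |β| cap 20. Ties use
midranks (rank statistics), Breslow (Cox), and the hypergeometric
variance with the `(n−d)/(n−1)` factor (log-rank). BH/Holm adjustments
are exact step-up/step-down with NA p-values excluded from the number of
tests.

Validation problem sizes were chosen to keep the full suite around a
minute: null calibration at 1,500–2,000 genes; Cox recovery at n = 300
over 200 replicates; pipeline recovery on 120-patient cohorts with 400
genes; null pipeline sweeps over 100 replicates of 60-patient, 200–250
gene cohorts; concentration recovery over 100 replicates at depth 10⁶.

## Known limitations

- The NB Wald stage is a stand-in: no dispersion shrinkage across genes,
  no independent filtering, no LFC moderation; its q-values are validated
  for calibration, not for parity with any specific external tool.
- Maxstat p-values are not selection-adjusted (permutation p optional).
- The COO realization fixes rank/tie conventions that published
  procedures leave unspecified; cross-study score values are therefore
  not directly comparable, though orderings are robust.
- Longitudinal analysis reduces to per-timepoint contrasts; no pulse or
  trajectory model is fit.
- Efron tie handling, penalized Cox, time-dependent covariates and
  competing risks are out of scope.
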