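# Methods

This note documents the models and procedures implemented in `glstrat`, the
choices made where the design was genuinely open, and what the synthetic
cohorts do and do not emulate.

## The analysis

The pipeline stratifies an expression cohort by glycolytic activity inferred
from lncRNA co-expression:

1. **Normalization and filtering.** Raw counts are normalized to counts per
   million (CPM). A gene is treated as expressed when its count exceeds 10 in
   strictly more than 90% of samples; the filter is applied identically to
   lncRNAs and to the glycolysis gene set.
2. **Glycolysis score.** Per-sample glycolytic activity is the single-sample
   GSEA (ssGSEA) score of the glycolysis gene set: within each sample,
   features are ranked (average ranks on ties) and the score is the integral
   of the difference between the weighted in-set ECDF (weights
   `rank^tau`) and the unweighted out-of-set ECDF. `tau` defaults to 0.25
   with 0.75 selectable. Because the statistic is rank-based it is invariant
   to any strictly monotone per-sample transform — scoring CPM or log-CPM is
   equivalent. With `normalize=True` (default) scores are divided by their
   range across samples, per score vector; this matches range-normalized
   ssGSEA output and keeps single-set and multi-set calls consistent.
3. **lncRNA selection.** Each expressed lncRNA's log2-CPM is Pearson-correlated
   with the glycolysis score; two-sided p-values use the exact t reference
   with n−2 df and are Benjamini–Hochberg adjusted. lncRNAs with |r| > 0.3
   (strict) and FDR < 0.05 (strict) are glycolysis-associated, carrying the
   sign of r.
4. **Consensus clustering.** Patients are clustered on the z-scored log2-CPM
   of the selected lncRNAs by feature-resampled consensus PAM: 1000
   iterations, each drawing 95% of the lncRNA features, computing a
   sample–sample distance (1 − Pearson correlation of profiles by default;
   Euclidean selectable), and running PAM (BUILD + SWAP, deterministic
   lowest-index tie-breaks). The consensus matrix is the co-assignment
   frequency; final labels cut an average-linkage tree of 1 − consensus.
   The cluster count is guided by the ECDF of consensus values: the area
   under the ECDF per k and the relative delta-area sequence. The suggested
   k is the k just before the first non-appreciable increase
   (delta < 0.1 by default); when no plateau exists — the signature of
   unstructured data, whose consensus area grows indefinitely with k — the
   smallest k is suggested. The full area/delta table is always returned, as
   the choice is advisory.
5. **Canonicalization.** Cluster indices are relabeled by ascending median
   glycolysis score, so cluster 1 is always the lowest-activity group and
   cluster K the highest. All downstream contracts rely on this.
6. **Cluster characterization.** Survival differences use Kaplan–Meier
   curves and the k-group log-rank test (via lifelines); score differences
   use Kruskal–Wallis with a tie-corrected Dunn post hoc (BH-adjusted by
   default); binary mutation enrichment in the high- (or low-) activity
   cluster uses two-sided Fisher's exact tests at p < 0.01; TF activities and
   checkpoint expression are screened by one-way ANOVA with an effect-size
   threshold (Cohen's f > 0.5 by default; eta-squared and max pairwise
   Cohen's d selectable — the appropriate statistic is genuinely ambiguous,
   so all three are implemented and none asserted as canonical).
7. **Differential expression and GSEA.** Two-group DE on CPM is a Welch
   t-test on log2(CPM+1) with a mean-CPM log2 fold change and BH adjustment —
   deliberately light, because DE serves only to rank genes and pre-filter
   classifier candidates. Preranked GSEA uses the classic weighted
   running-sum ES (weight 1 by default), a gene-label permutation null
   (10^4 permutations by default), sign-matched NES, and the sign-stratified
   NES-ratio FDR. ES sign ties (e.g. ±2/7) resolve to the extremum reached
   first in the ranked walk, within a 1e-9 tolerance that absorbs
   floating-point accumulation differences.
8. **TF activity.** Analytic rank-based activity: within-sample ranks map to
   standard-normal quantiles Φ⁻¹(rank/(n+1)); a regulon of m signed targets
   scores Σ mode·q /√m, approximately N(0,1) under exchangeable ranks.
   Implemented one-tailed with mode weights only (no interaction-confidence
   weighting): the analysis uses only directional activity differences.
   Regulons with fewer than 5 present targets are skipped with a warning.
9. **Linkage.** The first-order partial correlation
   r_xy·z = (r_xy − r_xz·r_yz)/√((1−r_xz²)(1−r_yz²)) removes a conditioning
   lncRNA's effect from gene–score correlations; the raw and adjusted
   coefficient distributions over score-associated genes are compared with a
   two-sample Kolmogorov–Smirnov test (asymptotic p — adequate at the
   gene-list sizes involved). The covariate-adjusted association standardizes
   gene, lncRNA, CNV and methylation to unit variance before least squares,
   so the lncRNA coefficient is on a partial-correlation-like scale that an
   |coef| > 0.3 threshold can meaningfully apply to; selection uses
   |coef| > 0.3 and FDR < 1e-6 (both strict).
10. **Genomic classifier.** Candidate genes are those consistently
    up- (FC > 1.5) or down-regulated (FC < 0.7) at FDR < 1e-4 in both the
    3-vs-2 and 2-vs-1 comparisons. Expression is quantile-normalized against
    a pooled reference (mean sorted profile; ties averaged) that the model
    stores, so external samples are projected onto the training reference —
    this is what makes monotone platform distortions harmless. The model is
    a multinomial logistic regression with an L1 penalty, fit by FISTA
    (accelerated proximal gradient, adaptive restart, warm starts) along a
    100-point log-spaced lambda path from lambda_max (the smallest lambda
    zeroing every coefficient) down by 1e-4. Lambda is chosen by minimum
    mean cross-validated multinomial deviance over class-stratified 10-fold
    splits (misclassification selectable). KKT stationarity is checked at
    every path solution. The signature is the set of features with a nonzero
    coefficient in any class at the chosen lambda.

## The synthetic cohort generator

The generator (`glstrat.synthetic`) emulates the statistical shape of a bulk
RNA-Seq tumor cohort with known ground truth; its defaults define the study
conditions used throughout the test suite.

- **Counts** are negative-binomial with shared dispersion 0.3
  (Var = μ + 0.3μ²) over log-normal library sizes centered at 10⁶ reads
  (σ = 0.25 on the natural-log scale), so CPM normalization is non-trivial.
- **Gene baselines** (log2 expected counts at the reference library) are
  drawn once from the universe dimensions, not the cohort seed: independently
  seeded cohorts share gene-level baselines, as real cohorts share a genome.
  Without this, cross-cohort classifier transfer would be impossible by
  construction.
- **Latent activity.** Each sample carries a latent glycolytic activity g,
  Gaussian within cluster (σ = 0.1) around cluster means at −1/0/+1 times
  `cluster_shift` (default 1). Glycolysis-set genes couple to g at 0.6 log2
  units per unit g; a block of 50 "co-regulated" coding genes couples at
  ±1.5 (half up, half down) — the monotone programs the DEG screen and
  classifier learn from.
- **Planted lncRNAs** (20 positive, 20 negative by default) mix g into their
  log2 mean so that the Pearson correlation of observed log2-CPM with g hits
  the target (0.6 by default). The mixing weight is solved per gene with a
  small Monte-Carlo estimate of the attenuation caused by NB count noise and
  the log pseudo-count; the noise component is orthogonalized against g so
  the latent-scale correlation is exact. Half of the non-g variance follows
  a cluster-specific pattern (the quadratic contrast over cluster indices,
  orthogonalized against g): subtype cohorts have expression programs beyond
  the glycolysis axis, and without such a pattern the k-medoids objective is
  nearly flat along the single latent direction. One designated "mediator"
  lncRNA couples strongly (target correlation 0.9, high abundance so it
  always passes the expression filter); conditioning on it visibly shifts
  gene–score correlations toward zero.
- **Survival** is exponential with cluster hazard ratios (1, 1.5, 3) over a
  baseline of 1/1000 events per day; censoring is administrative-uniform
  with the horizon solved numerically to hit the configured censoring
  fraction (0.3).
- **Mutations** are Bernoulli at a 0.15 background rate; one designated
  feature is enriched in the highest-activity cluster at odds ratio 8.
- **Covariates.** Each planted lncRNA gets a CNV row (0.5·latent + noise)
  and a methylation row (negatively coupled, clipped to [0,1]) partially
  confounded with its expression.
- **Gene sets and regulons.** The glycolysis set, size-matched uniform decoy
  sets, disjoint immune marker blocks and a checkpoint list are laid out
  deterministically over disjoint coding blocks; 30 regulons of 10 signed
  targets each, the first 3 planted active (targets shifted by mode × 1.2
  log2 in the top cluster).
- **Compartments.** Paired cytoplasmic/nuclear matrices place 70% of lncRNAs
  nuclear-biased over compartment-neutral coding ballast, for the relative
  concentration index RCI = log2((cyt CPM + 1)/(nuc CPM + 1)) (pseudo-count
  1 CPM keeps it finite).

**What the generator does not emulate:** batch effects, tumor purity,
realistic mutation spectra, gene–gene correlation beyond the planted
programs, probe-level microarray artifacts (platform shift is emulated as a
monotone distortion at test time). Passing tests therefore demonstrate that
the procedures recover the structure they target under a faithful noise
model, not that real cohorts contain such structure.

**Known side effects at desk scale.** With ~180 of 2000 coding genes shifted
in the high-activity cluster, (i) CPM acquires a small composition bias
(~0.1 log2 on neutral genes — a real property of CPM-based analyses, which
is why heavier DE frameworks use compositional normalizations we deliberately
do not reproduce), and (ii) within-sample ranks of neutral genes are slightly
displaced, leaving individual mode-imbalanced inactive regulons with residual
activity differences up to ~0.5 SMD (planted-active TFs sit near 4). Both
shrink with universe size; the tests assert the ensemble behavior.

## Numerical choices

- Ranks use average tie-handling everywhere; ordering ties in ranked walks
  break by feature index, so every statistic is deterministic.
- BH is used wherever "FDR" is required without a named method.
- PAM breaks all ties toward the lowest index; swaps are steepest-descent and
  the within-cluster distance never increases.
- FISTA uses step 1/L with L = σ_max²/(2n) of the intercept-augmented design,
  adaptive restart on objective increase, and stops when the KKT residual
  falls below 1e-8 (KKT is re-verified at every returned solution).
- Degenerate inputs fail loudly: all-zero samples, |r| = 1 conditioning
  variables, collinear covariates (condition number > 1e8), empty groups.

## Problem sizes

Test and acceptance runs use desk-scale problem sizes chosen to keep the full
suite fast while leaving comfortable statistical margins: cohorts of 60–300
samples, a 2000-gene coding universe, 100–200 consensus iterations (the
consensus matrix stabilizes well before the production default of 1000),
2000-cohort calibration ensembles, and 20-seed recovery ensembles. The
pipeline defaults themselves remain at the analysis' standard values
(1000 iterations, 10⁴ GSEA permutations, 100-lambda path).
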