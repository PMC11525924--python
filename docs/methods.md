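# Methods

This note documents the statistical model behind `evmir`, the synthetic
cohorts it is validated on, and the numerical choices made where the design
was genuinely open.

## The analysis pipeline

The package reconstructs a complete miRNA-microarray biomarker workflow for
case/control urine cohorts:

1. **Preprocessing.** Background noise is subtracted from raw fluorescence
   (clamped at zero — negative fluorescence is non-physical), each array is
   scaled so that the median of its *detected, strictly positive* signals
   equals 25 fluorescence units ("global normalization"), and intensities
   are log2-transformed with a floor of 1 so undetected entries map to 0 on
   the log scale. The matrix carries an immutable detection mask and a
   state flag that enforces the order raw → background-subtracted →
   normalized → log2. Including structural zeros in the median would drag
   it to 0 for subjects with low detection counts, which is why the median
   is restricted to detected positives.

2. **Screening.** Each species is tested cancer-vs-noncancer with a
   two-sided Mann–Whitney U test. When both groups have ≤ 8 observations
   and no ties the p-value is exact, computed from the integer rank-sum
   distribution (a dynamic program over subset sums, so it matches
   brute-force enumeration bit-for-bit); otherwise the normal approximation
   with tie and continuity corrections is used. Undetected entries enter
   the test at the floor value, so a prevalence difference between groups
   contributes to significance (a switch can drop them instead). Fold
   change is log2(mean_cancer / mean_noncancer) on the *linear* normalized
   scale — the ratio of fluorescence means, not the difference of log
   means; ranks are identical on either scale so the p-values do not
   depend on this choice. The volcano filter keeps species with
   −log10 p > 3.30 and |log2 FC| > 1.00, both strict inequalities.

3. **The miRNA ensemble.** The classifier is a logistic risk score
   Y = σ(βᵀx + α) over log2 intensities, with β estimated by minimizing

       F(β, α) = Σᵢ (σ(βᵀxᵢ + α) − yᵢ)² + λ‖β‖₁

   with the intercept unpenalized. The least-squares-through-sigmoid form
   is the default objective; a conventional log-loss objective is available
   (`objective="log_loss"`) since "logistic regression" usually implies it
   — both are first-class, and all validation runs on the default.
   Attribute selection runs this fit once per training subset of a
   stratified K-fold cross-validation (20 folds by default, optionally
   repeated), averages β and α across all fits, and keeps species with
   |mean βⱼ| > 0.01. The deployed model uses exactly these thresholded
   averages plus the mean intercept; a post-selection refit is available
   (`refit=True`) but off by default, because the averaged, thresholded
   coefficients *are* the selection result. Folds are stratified by class
   and seeded: 20 folds on 100+100 subjects leaves 5+5 test subjects per
   fold, and unstratified folds could lose a class entirely. Features are
   used on the log2 scale without re-standardization, so a coefficient is
   per unit log2 fluorescence.

4. **Evaluation.** AUROC is the positive-vs-negative pair-counting
   probability with ties at ½ (identical to the normalized U statistic and
   to the trapezoidal ROC area; both identities are asserted in tests).
   ROC curves are TPR vs FPR. Confidence intervals default to DeLong's
   structural-components method, with a seeded stratified bootstrap as an
   alternative; the subject-level decision rule is Y ≥ 0.5 → cancer
   (boundary inclusive). The stage-I hold-out protocol retrains the whole
   selection pipeline on all non-stage-I cancer subjects plus a seeded
   random 75% of noncancer subjects and evaluates only on the held-out
   stage-I cancers and remaining noncancer subjects — on a 100+100 cohort
   with 24 stage-I cancers this gives the 76+75 train / 24+25 test design.
   Whole-cohort scores come in two modes: out-of-fold (each subject scored
   by the fold model that never saw it; the default, honest mode) or
   deployed (averaged model on everyone, the optimistic mode).

5. **Enrichment.** Target genes of a species group are pooled into one
   list and tested pathway-by-pathway with Fisher's exact test on the 2×2
   table over a fixed background gene universe. The one-sided (greater)
   tail is the default — over-representation is the conventional question —
   with a two-sided option. P-values are Benjamini–Hochberg-adjusted across
   the whole database (pathways with zero possible overlap stay in the
   family, keeping m fixed) and flagged at FDR 0.05. Pathways are ranked by
   total overlap across the up / down / non-featured groups.

## The synthetic cohort generator

No subject-level data is distributed with studies of this kind, so the
generator is a first-class module that plants known structure for every
downstream stage:

* **Platform structure.** 2565 probe species; a core of 441 detected in
  every subject; non-core species detected per-subject with Bernoulli
  prevalence πⱼ drawn from a Beta distribution (α = 2) and rescaled so the
  expected detected-species count per subject is 1500. The Beta form is a
  modeling stand-in — real per-sample detection variability has no
  published distributional form — and is exposed as a knob
  (`prevalence_beta_a`), not asserted as faithful.
* **Intensity model.** Per-species baseline μⱼ ~ N(6, 2²) in log2
  fluorescence units (log-normality is the standard microarray
  convention), per-observation noise N(0, 1²) in log2 units, and a planted
  additive group effect δⱼ·1[cancer] with |δⱼ| = 1.5 log2 units for 48 up-
  and 6 down-regulated species. Raw fluorescence is 2^(log2 value) where
  detected and exactly 0 elsewhere.
* **Planted species sit in the core subset by default**
  (`plant_in_core=True`). A biomarker planted in a rarely detected species
  would have its fold change measured mostly against floor values, which
  is not the situation the featured-species analysis represents; the
  switch allows planting anywhere.
* **Stages.** Cancer subjects get stages I–IV by largest-remainder
  apportionment of the stage fractions (default 24% / 24% / 26% / 26%, so
  a 100-cancer cohort has exactly 24 stage-I subjects) followed by a
  seeded shuffle; stages are independent of effect size, because the
  stage-I experiment probes generalization, not a stage-specific biology.
* **Pathway database.** 338 gene sets with log-normal sizes (10–200) over
  an 8430-gene universe; the universe is exactly the union of pathway
  genes (uncovered genes are parked in random pathways), matching how a
  pathway-release background is defined. Each miRNA gets 30 target genes;
  miRNAs designated as signal draw each target from the planted pathways'
  gene union with probability 0.6 (default), giving a controlled
  over-representation.
* **Determinism.** One integer seed governs everything; sub-streams are
  spawned from a single `SeedSequence`, and identical spec + seed gives
  bit-identical cohorts.

What the generator does **not** emulate: probe cross-hybridization, batch
and array-position effects, EV-capture chemistry, correlated miRNA
co-expression, or heavy-tailed noise. Passing tests therefore demonstrate
that the pipeline recovers planted structure under a clean generative
model at realistic scale — not that any particular clinical performance
number would be reproduced on real cohorts.

## Solver

The penalized objective is non-convex (least squares composed with a
sigmoid), so the fitting contract is monotone descent to a stationary
point, not global optimality. The solver is a monotone FISTA: accelerated
proximal gradient with soft-thresholding for the L1 term, backtracking
line search on the smooth part's quadratic upper bound, and a safeguard
that never accepts an objective increase (the momentum sequence may
overshoot; the iterate sequence is non-increasing by construction).
Initialization is β = 0, α = logit(mean y). Convergence is declared when
the relative objective drop stays below `tol` (default 1e-9) for 10
consecutive iterations; exceeding `max_iter` (default 20000) raises a
convergence error carrying the final objective. On small instances
(≤ 2 features, n ≤ 20) the solver's objective is verified against a dense
coarse-to-fine grid search to 1e-6; on the study-scale problem
(2565 features, 200 subjects) one fit takes a few seconds.

Numerical details: the sigmoid is evaluated in a branch-free numerically
stable form; the log-loss objective uses `logaddexp`; an all-identical
score vector yields p = 1 in the rank test rather than a 0/0; fold
assignment is round-robin within each shuffled class so fold sizes differ
by at most one.

## Problem sizes used in validation

The test suite exercises the full study scale where the claim depends on
it — the 2565 × 200 cohort for normalization, screening calibration,
planted-species recovery, the λ = 1 / 20-fold ensemble, and the 76+75 /
24+25 stage-I hold-out. Properties that are scale-free by construction
(λ-path monotonicity, byte-level pipeline reproducibility, recovery
monotonicity in n and effect size) run on reduced cohorts (150–500
species, 30–50 subjects per class, 5–10 folds) as the package's own
choice of economical test design; the assertions do not depend on those
sizes.

## Known limitations

* The exact Mann–Whitney branch is limited to both groups ≤ 8 (beyond
  that the normal approximation is excellent and the exact distribution
  costly); the branch switch is documented rather than configurable.
* The non-convex objective means different column orders can converge to
  coefficients differing at solver tolerance (~1e-4); the selected set is
  stable except for features sitting exactly at the 0.01 threshold.
* DeLong intervals are asymptotic and degenerate to zero width on
  perfectly separated scores; the bootstrap option is preferable near the
  boundary.
* The one-vs-rest multiclass extension is a convenience hook, validated
  only on well-separated synthetic classes.
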