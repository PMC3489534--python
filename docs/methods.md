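# Methods

This note records the statistical model behind each component, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the simulation studies do and do not demonstrate.

## Data model

All computation happens on log-scale (default log2) peptide-by-sample
matrices with missing cells carried as NaN, a sample-to-group (optionally
batch) design, and a many-to-one peptide-to-protein map.  Group levels are
lexically sorted, so the reported two-group difference is always
(first sorted group) − (second); relabelling flips its sign.

## Normalization

**Global centering** subtracts a per-sample location statistic (mean or
median, optionally over a peptide subset such as housekeeping proteins).
Under left-censoring, centering on *all* observed values is subtly biased:
samples with more censored cells have their observed distribution truncated
differently, which leaves a residual per-sample shift that group tests
downstream see as confounding.  The model-based experiment pipeline
therefore centers on peptides in the top abundance quartile, where
censoring is negligible; the "textbook" pipelines used as naive baselines
center on everything, as standard practice does.

**Lowess MA normalization** smooths M = x − r against A = (x + r)/2 between
each sample and a reference (default: the per-peptide median
pseudo-reference, avoiding an arbitrary reference run) and subtracts the
fitted curve.  The smoothing fraction defaults to 0.4, the empirical
standard.  Cells whose reference value is missing are adjusted at their own
abundance as the abscissa.

**Fixed-effects model.**  Per protein,
`y = Prot_i + Pep_ij + Treat_ik [+ Batch_ib] + eps`, sum-to-zero
constraints, independent blocks solved by least squares with
deviation coding.  Per-peptide residual variances use leverage-corrected
degrees of freedom (`df_j = n_j − Σ hat_jj`).  Proteins whose observed
cells miss a group or batch level, or give a rank-deficient design, are
flagged non-estimable and excluded from variance pooling and trend
estimation.

**Eigentrend (SVD) normalization.**  Residual bias of unknown origin is
modelled as a small number of across-sample trends: right singular vectors
of the row-centered complete-row residual matrix.  The number of *bias*
trends is chosen by permutation: entries are permuted independently within
each row (n_perm = 99, alpha = 0.05 by default), singular values are
compared sequentially against their permutation quantiles, and testing
stops at the first non-significant trend.  Every peptide — complete or not
— then has its least-squares projection onto the selected trends (using its
observed cells) subtracted; peptides observed in fewer than k + 2 cells are
left unadjusted and reported.  Because fitted group structure is removed
before the SVD and restored afterwards, group-mean differences are
untouched by construction.  Bias that is *confounded* with the groups is
absorbed by the treatment estimates and cannot be distinguished from
signal; no residual-based method can remove it.

**Residual re-inflation.**  Subtracting an estimated projection consumes k
degrees of freedom per peptide: the residual covariance drops from σ²I to
σ²(I − H), H the hat matrix of the trend basis on the peptide's observed
cells.  Adding isotropic noise scaled by n/(n−k) — the first idea — is not
enough: it restores the *within-group variance* but also inflates the
group-contrast direction that trend removal never touched, leaving
per-peptide tests anti-conservative by a factor ~√(1 + k/n).  The
implementation instead replaces the removed component: it draws fresh
Gaussian noise with covariance σ̂²H (σ̂² = RSS/ν with ν the
leverage-corrected residual df minus k), restoring an isotropic residual
covariance exactly for complete rows.  Measured on null data with injected
bias (1400-protein datasets, ~9 000 peptide tests pooled per seed), pooled
per-peptide p-values pass Kolmogorov–Smirnov uniformity at the 1% level in
19 of 20 seeds with re-inflation and are visibly anti-conservative without
it.

## Missing-data model

The mechanism parameters are global: the MCAR probability π and the
censoring cutoff c.  By default π is estimated as the missing fraction
among top-abundance-quartile peptides (where censoring is negligible) and
c as the median across samples of each sample's minimum observed value.
After per-sample transformations (e.g. centering), a single instrument
threshold sits at a different value in each sample; `cutoff` therefore
accepts a per-sample vector, estimated by each sample's own minimum
observed value.  Ignoring this (one global cutoff on centered data) was
measured to misspecify the likelihood badly enough to inflate Wald
z-scores by ~60%.

**Fitting.**  Complete sub-matrices are solved exactly by iteratively
reweighted least squares (coordinate ascent between weighted means and
per-peptide variances).  With missing cells, L-BFGS-B on
(mean coefficients, log σ_j) with analytic gradients, observed-cell
least-squares initialisation, three jittered restarts, convergence 1e-8 on
the log-likelihood, and log σ bounded in ±7.  The observed information is
assembled analytically (exact Hessian of the censored likelihood), which is
what makes the closed-form information checks hold to 1e-8.

**Identifiability guards.**  A peptide contributes a free offset and a free
variance; with fewer than three observed cells the likelihood is unbounded
along its σ_j (the offset can interpolate), which collapses σ̂_j and wrecks
the information matrix for the whole protein — observed as near-zero-width
intervals with catastrophic coverage.  Such peptides are dropped from the
fit (default `min_obs_per_peptide = 3`); a protein with no observed value
in some group, or none at all, raises a non-identifiability error.

**Information content and filtering.**  The treatment block of the observed
information, after profiling out nuisance parameters via the Schur
complement, is mapped to the pairwise group-difference scale and summarised
as det^(1/d), d = n_groups − 1 (for two groups simply the information of
the difference, n/(2σ²) in the single-peptide complete case).  Forward
greedy selection starts from the most informative single peptide and adds
peptides while the information grows; a protein whose every subset has zero
information is filtered.  Subset evaluations use quick moment fits
(least squares on observed cells) — the paper's "rough estimates without
numerical optimization" device — with the information still evaluated
exactly at those estimates.

**Classification and imputation.**  Each missing cell's posterior
probability of censoring is (1−π)Φ((c−μ̂)/σ̂) / (π + (1−π)Φ((c−μ̂)/σ̂));
ties at the 0.5 threshold are labelled censored (conservative toward the
informative mechanism).  A single imputation draws censored cells from the
normal truncated at c and MCAR cells from the full normal, deterministic
given the seed.  Missing cells of unfitted/filtered proteins are left
missing and reported.  Naive alternatives (`row_mean`, `row_min`,
matrix-wide `min_observed`, `normal_draw`, `group_normal_draw`) are
provided as comparison baselines; the degradation study uses `row_min`
(each peptide's own minimum observed value), the classic censored-value
fill whose within-peptide constants shrink the apparent variance.  The
matrix-wide minimum behaves differently: it is such an extreme outlier
for mid-abundance proteins that it *widens* intervals and pushes coverage
up, not down.

**p-value adjustment.**  Preprocessing can leave mild inflation in test
statistics.  Assuming only the right tail (p > 0.5 by default, ≥ 50
values) is null and modelling inflation as p = U^λ, λ is estimated by
matching the observed tail median of −log p against its model-implied
value; because the tail threshold itself transforms under inflation, the
match is solved self-consistently (1-D root find) rather than taken as a
raw ratio, which would be inconsistent.  All p-values are then mapped
p → p^(1/λ), a rank-preserving transform.  The estimator is deliberately
conservative in information: with only the tail assumed null, λ is
estimated with limited precision for strong inflation (the conditional
tail median saturates), which is the price of not assuming which
discoveries are real.

## Inference

Two routes to protein-level group differences (two-group designs for
interval construction):

* `wald_ml` — ML estimate; SE from the inverse observed information
  **after** rescaling per-peptide variances by n_j/(ν_j − 2)
  (unbiased-precision correction) and a t reference with pooled residual
  df.  The raw inverse-information/normal-quantile interval undercovers
  badly in small samples (measured 87.7% at nominal 95% with 10 samples per
  peptide) because E[1/σ̂²] is biased high at ~9 df; the corrected interval
  measured 94.3%.
* `complete_data_anova` — constrained least squares on observed (or
  imputed) cells; contrast variance as a weighted sum of per-peptide
  variances with a Satterthwaite-pooled t reference.  This is the
  complete-data/complete-case workhorse and the method used for the
  coverage anchor at zero missingness (recorded in experiment reports).

Diagnostics: interval coverage against simulation truth, and the
Kolmogorov–Smirnov uniformity of pooled null p-values with histogram
counts.

## Simulator

`y_ijkm = Prot_i + Pep_ij + Treat_ik + Samp_m + eps` on the log2 scale.
Defaults: protein means N(20, 2²); peptide offsets sd 1 (centered within
protein); 10% of proteins differential with differences N(0, 1); sample
loading shifts sd 0.5; error sd 0.5; 2–12 peptides per protein, uniform.
Missingness: each cell MCAR-deleted with probability π, then cells below
the censor-quantile cutoff of the complete-value distribution deleted as
censored; labels partition the cells (MCAR wins ties).  Presets:
`paper_main` (1400 proteins, 2×10 samples, π = 0.05, censor quantile
0.08/0.95 ≈ 0.084, ≈13% total missing), `coverage_study` (200 proteins,
2×5 samples, sweepable missingness), `null_study` (paper_main with zero
effects).  `inject_bias_trend` adds a rank-1 across-sample drift with
random per-peptide loadings; the preset trend is a sinusoid orthogonalised
against the group indicator, emulating run-order drift that is *not*
confounded with the comparison (confounded drift is unidentifiable, see
above).

What the generator does *not* emulate: peptide-level interference and
shared-peak effects, intensity-dependent (non-additive) bias, correlated
peptide errors within a protein, retention-time structure, or
identification errors.  Passing tests therefore demonstrate calibration
and ordering effects under an additive normal model with a sharp detection
threshold — the regime the methods are designed for — not performance on
arbitrary real data.

## Simulation studies and their scale

* **Coverage** — per missingness level, simulate datasets, apply a strategy
  (naive per-peptide-minimum imputation, complete-case least squares, or
  the censored ML model) and report empirical coverage of nominal 95%
  intervals.  Full scale: 100 simulations × 200 proteins at zero missing
  (the calibration anchor, 20 000 intervals); 60 simulations per level for
  the degradation sweep over censored fractions 0–40% (plus 5% MCAR).
  Under the generator's abundance spread, censoring concentrates on
  low-abundance proteins, so a large share of intervals belong to barely
  touched proteins; the naive pipeline's sharp degradation (to ~82% at 40%
  censoring) comes jointly from biased constant fills and the truncation
  bias of textbook all-value centering.  The censored-ML strategy with
  robust centering does not degrade nearly as fast; at low censoring the
  two are within Monte-Carlo error of each other, so the model's advantage
  is claimed (and tested) at heavy censoring, not everywhere.
* **Ordering** — on `paper_main` data with injected bias: imputing the raw
  biased matrix first (single global cutoff, as a naive pipeline would)
  and normalizing afterwards is compared against normalizing first and
  imputing after.  Both are scored by the correlation of their top
  eigentrend with the group step.  Normalize-then-impute keeps that
  correlation above 0.9; impute-then-normalize is consistently lower,
  because bias and a misplaced cutoff leak into the imputed values where
  later normalization cannot reach them.  With only ~13% missing cells the
  gap is systematic but modest; it grows with the missing fraction.
* **Null p-values** — on `null_study` data with injected bias, per-peptide
  pooled-variance t-tests after each pipeline, assessed by KS uniformity
  (~9 000 peptides per seed).  Raw biased data fail overwhelmingly (the
  loading shifts act as a common group offset); the normalized +
  re-inflated pipeline passes at the 1% level in 19 of 20 seeds.  The rare
  failing seed draws an extreme loading contrast whose interaction with
  censoring leaves a small common offset that no residual-based method can
  see — a real limitation of peptide-level testing on observed cells under
  heavy loading imbalance.

All studies derive every random stream from (seed, level, replicate)
indices via hash-based sub-seeding, so reruns are bit-identical.

## Known limitations

* The censored ML's Wald intervals remain approximate under heavy
  censoring (asymmetric likelihoods); profile-likelihood intervals would
  be better and are not implemented.
* π and c are global (per-sample at most); peptide-specific detection
  efficiency is not modelled.
* The greedy information search evaluates quick fits, not full ML, for
  subset scoring; with strongly non-normal residuals the two can rank
  subsets differently.
* Group-confounded bias is fundamentally unidentifiable from residuals;
  the package removes only bias orthogonal to the design.
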