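# Methods

## The model

`neonorm` implements voxel-wise normative modelling of neonatal diffusion
scalar maps. For each intracerebral voxel $v$ the two tissue metrics —
fractional anisotropy $\mathrm{FA}\in[0,1]$ and mean diffusivity
$\mathrm{MD}$ in μm²/ms — are modelled jointly as a two-output Gaussian
process over the covariates $x=(\text{PMA at scan},\ \text{sex})$, fitted
on the normative (term-born) cohort only:

$$
y_v(x) \sim \mathcal{GP}\!\left(0,\; B \otimes k_{\mathrm{RBF}}(x,x')
\;+\; \mathrm{diag}(\sigma^2_{\mathrm{FA}},\sigma^2_{\mathrm{MD}})\right)
$$

an intrinsic coregionalization (ICM) construction: one shared RBF kernel
$k_{\mathrm{RBF}}(x,x')=\exp(-\lVert x-x'\rVert^2/2\ell^2)$ over
standardized PMA and the 0/1 sex code, coupled across the two outputs by
a 2×2 PSD matrix $B=LL^\top$ parameterized by its Cholesky factor, plus
independent white noise per output. The RBF variance is fixed at 1
because it is not identifiable next to $B$; the per-output signal scales
live entirely in $B$. ICM is the minimal multioutput construction that
lets FA and MD share information through their correlation, which is the
stated motivation for modelling them jointly.

Outputs are standardized per voxel (mean and sample SD, $n-1$
denominator) so the unit-free FA (~0.2) and MD (~1 μm²/ms) can share one
kernel; PMA is standardized by the training mean/SD; sex enters the RBF
unscaled as a 0/1 coordinate. All predictions are de-standardized before
they leave the module.

Hyperparameters $(\ell, L, \sigma^2_{\mathrm{FA}}, \sigma^2_{\mathrm{MD}})$
maximize the exact log marginal likelihood
$-\tfrac12 y^\top K^{-1}y - \tfrac12\log|K| - \tfrac{N}{2}\log 2\pi$
via L-BFGS on log-transformed positive parameters with analytic
gradients, starting from a data-driven split of the unit output variance
(~70% signal / 30% noise) and, by default, 3 restarts with seeded
log-normal jitter; restart seeds derive from (global seed, voxel index)
so results are identical under any processing order. Inference is exact
Cholesky; a 1e-8 diagonal jitter is escalated ×10 up to three times
before a numerical error is raised. Generous box bounds on the log
parameters (e.g. $\log\ell \in [-5, 8]$) only prevent line-search
overflow. L-BFGS stops at a relative objective tolerance of 1e-6 —
hyperparameters only need a few significant digits for stable
predictive moments.

Voxels whose outputs have zero variance across training subjects are
flagged degenerate, excluded from scoring and from every percentage
denominator downstream, and counted per run.

## Deviation scores and atypicality indices

A subject's deviation at a voxel is
$Z = (y_{\text{obs}} - \mu_\ast)/\sigma_\ast$ with $\mu_\ast, \sigma_\ast$
the GP posterior mean and SD at the subject's covariates. The noise
variance is **included** in $\sigma_\ast$ by default: only then is $Z$
standard normal for new normative subjects, so that the extreme rule
$|Z| > 3.1$ (strict inequality throughout) fires at the normal-tail rate
$2(1-\Phi(3.1)) \approx 0.194\%$ in healthy tissue, giving the term
group its small but nonzero extreme-deviation load.

Holdout (preterm) subjects are scored against the model trained on the
full term sample. Term subjects are never scored by a model that saw
them: their Z-scores come from the predictions of the PMA-stratified
5-fold cross-validation (subjects sorted by PMA, ties broken by a seeded
shuffle, dealt round-robin so each fold spans the full PMA range). The
same CV provides the per-voxel mean-absolute-error maps.

Extremes are split by direction and metric (FA+, FA−, MD+, MD−).
Group-level spatial consistency is the voxel-wise percentage of subjects
extreme at a voxel; the consistency threshold (default 4%, strict) marks
voxels where deviations recur across subjects. Per subject, the four
whole-brain atypicality indices are the percentages of valid
intracerebral voxels extreme in each direction; the denominator excludes
degenerate voxels (logged per subject).

## Statistical battery

On the atypicality table joined to the covariates, with Holm (step-down
Bonferroni) correction applied separately within each family:

1. group comparisons per index — Mann–Whitney U (mid-rank ties,
   normal-approximation p with tie and continuity correction, adequate at
   cohort sizes of tens to hundreds) reported with the Vargha–Delaney
   $A = (\#\{x>y\} + \tfrac12\#\{x=y\})/(n_x n_y)$, the
   probability-of-superiority effect size;
2. Spearman correlations of each index with GA at birth, per group
   (t-approximation p; exact permutation enumeration available for
   $n \le 9$);
3. the index × outcome Spearman grid per group (three Bayley-style
   composite scores).

Indices whose outcome correlation survives Holm in the preterm group get
a follow-up multiple regression (outcome ~ index + GA + sex + motion +
IMD): OLS with per-term t tests, adjusted $R^2$, overall F, residual
diagnostics (Shapiro–Wilk, Breusch–Pagan) reported but never gating, a
case-resampling percentile bootstrap 95% CI for the adjusted $R^2$ (1000
replications; singular resamples redrawn and counted, >10% singular
aborts; optional truncation of negative draws at zero, off by default),
an out-of-bag bootstrap prediction adjusted $R^2$ (100 resamples), and an
influential-observation sensitivity rerun: the index is standardized
(sample SD), observations with $|Z| > 3.1$ dropped, and the correlation
recomputed.

Undefined tests (an index constant within a group, which happens on very
small masks) are reported as undefined rows and excluded from the family
size rather than crashing or silently disappearing.

## The synthetic cohort generator

The generator emulates the study design the analysis assumes, directly
in template space (no diffusion simulation, registration or tensor
fitting — out of scope by design):

* **groups** — normative term-born subjects (GA ~ U(37, 42) weeks) and
  atypical preterm subjects (GA ~ U(24, 36.9)), all scanned at PMA
  37–45 weeks with scan-after-birth enforced; defaults 270/82 subjects
  mirror the target study design, and the desk-scale studies in this
  repository use 100/82;
* **fields** — per-voxel FA/MD intercepts (anchored at the reference PMA
  of 40 weeks), PMA slopes (FA rising ~0.010/week, MD falling
  ~0.025 μm²/ms/week) and small sex offsets, generated as Gaussian-kernel
  smoothed random fields (σ = 2 voxels) so neighbouring voxels are
  correlated as in real parameter maps; clip bounds keep the noise-free
  planes inside physical ranges and >3 noise SDs from the FA floor, so
  value clipping is rare and counted;
* **noise** — i.i.d. Gaussian per subject, voxel and metric, SD 0.04
  (FA) and 0.20 μm²/ms (MD), chosen so that a well-specified model's
  cross-validated whole-brain MAE lands at the reported scale of ≈0.031
  (FA) and ≈0.17 μm²/ms (MD) (for Gaussian residuals
  MAE = SD·√(2/π));
* **lesions** — preterm subjects carry 1–4 spherical clusters at random
  in-mask locations (little overlap between subjects; median pairwise
  Jaccard < 0.2), lowering FA and raising MD by ≥5 noise SDs; lesion
  count and size grow with prematurity so lesion load correlates
  negatively with GA;
* **outcomes** — composite scores (mean 100, SD 15). Preterm scores
  decrease linearly with the subject's standardized lesion-volume
  fraction (target correlation 0.55) plus independent noise; term
  outcomes are pure noise. This outcome model is a testing device that
  gives downstream correlation tests a known sign, not a claim about
  real outcome generation.

What the generator deliberately does **not** emulate: spatially
correlated noise, registration error, partial-volume and cortical
variability, heteroscedastic age effects, non-Gaussian residuals, and
any dependence of term outcomes on imaging. Passing tests therefore
demonstrate the pipeline's correctness and calibration under its own
assumptions — not robustness to the artefacts of real neonatal dMRI.

## Numerical and design choices

* Z denominator includes noise variance (see above); a flag exposes the
  noise-free alternative.
* Strict inequalities at |Z| > 3.1 and at the 4% consistency rule; at
  n = 82 the 4% rule and "more than three subjects" agree for counts ≥ 4.
* Sample SD (n−1) for every standardization; sex coded female=0/male=1
  end-to-end; MD generated, stored and reported in μm²/ms.
* "Leave-one-out 5-fold cross-validation" is implemented as plain
  stratified 5-fold (each subject held out exactly once within its
  fold); the two names are contradictory and the stratified-folds
  description is the procedure actually specified.
* Percentile (not BCa) bootstrap for the adjusted-R² CI; the lower bound
  may be negative unless truncation is enabled.
* Holm families are the three blocks listed above, corrected separately;
  family boundaries are a design choice exposed in the report's `family`
  column.
* Model store (`.npz`) keeps per-voxel hyperparameters, standardization
  constants, standardized targets and flags (versioned schema); the
  covariance factorization is rebuilt exactly on load, so a store round
  trip reproduces predictions bit-for-bit.

## Problem sizes used in this repository

The restricted source cohort cannot be redistributed, and a 270-subject
whole-brain study does not fit a desk run, so the repository's own
studies are scaled down and all checks are property-based:

* reference study (calibration, slope recovery, lesion detection):
  100 term subjects, 20³ grid (~3100 mask voxels), 200 null subjects;
* battery study (group effects, correlations, regressions, CV MAE):
  100 term + 82 preterm on a 14³ grid;
* power / family-wise-error meta-repeats: 20 seeded runs each on 10³
  grids with 50+60 (power) and 40+25 (null) subjects, bootstrap
  replications reduced to 100/30 via explicit config;
* determinism demo: 24+10 subjects on an 8³ grid, run twice.

Defaults everywhere remain the analysis values (threshold 3.1,
consistency 4%, 5 folds, 1000/100 bootstrap replications, α = 0.05,
3 optimizer restarts); the big fits in the scripts use 1 restart, which
on these smooth synthetic likelihoods changes fitted hyperparameters
negligibly (the restart test in the suite covers the multi-restart
path).

## Known limitations

* Per-voxel slope recovery is information-limited: at n = 100 and the
  MAE-matched noise levels, even exact-design OLS has a median slope
  error of ~0.6× (FA) / ~1.5× (MD) the slope field's spatial SD, and the
  GP inherits this (slightly worse, from posterior wiggle). The
  acceptance suite keeps the stricter bound as a red marker of this
  limit rather than relaxing it.
* The scoring asymmetry the analysis prescribes — term subjects scored
  by their held-out CV fold's model, preterm subjects by the full-sample
  model — makes the two groups' Z-scores exchangeable only when the
  normative model is well estimated. CV-fold models trained on very
  small cohorts (tens of subjects) systematically underestimate noise a
  little more than the full model, over-dispersing term Z-scores and
  biasing the null group comparison upward for the term group; the
  effect shrinks roughly like 1/n and is negligible at the
  80-subject-and-up normative cohorts used here (and a fortiori at a
  270-subject study), but the family-wise-error simulations deliberately
  avoid the tens-of-subjects regime for this reason.
* Exact GP inference is O(n³) per voxel; cohorts beyond a few hundred
  subjects would need approximate inference, which is out of scope.
* No spatial regularization across voxels (voxels are fitted
  independently, as in the analysis the package implements) and no
  anatomical labelling of deviation clusters.
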