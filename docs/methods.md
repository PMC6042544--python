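# Methods

## Model

`lctmflow` fits latent class trajectory models (LCTMs, also called growth
mixture models) to long-format repeated measures: subject *i* provides
observations *y<sub>ij</sub>* at times *t<sub>ij</sub>* (e.g. BMI at
several adult ages).  Subject *i* belongs to latent class *k* with
probability *π<sub>k</sub>*; conditional on class,

> y<sub>i</sub> | class k ~ N( X<sub>i</sub> β<sub>k</sub>,
> Z<sub>i</sub> B<sub>k</sub> Z<sub>i</sub>ᵀ + σ<sub>k</sub>² I )

where X<sub>i</sub> is a polynomial design in transformed time (default
quadratic), Z<sub>i</sub> its leading columns, B<sub>k</sub> the
random-effects covariance and σ<sub>k</sub>² the residual variance.  Seven
covariance structures form a ladder of assumptions:

| code | description | B<sub>k</sub> | residual |
|---|---|---|---|
| A | homoscedastic fixed effects | 0 | shared σ² |
| B | heteroscedastic fixed effects | 0 | class σ<sub>k</sub>² |
| C | random intercept | shared 1×1 | shared σ² |
| D | random slope | shared 2×2 | shared σ² |
| E | random quadratic, equal | shared 3×3 | shared σ² |
| F | random quadratic, proportional | ω<sub>k</sub>² B | shared σ² |
| G | random quadratic, unrestricted | class B<sub>k</sub> | shared σ² |

Structure F's class scales are identified by pinning the last (smallest-π,
after canonical reordering) class's ω to 1; mixing proportions are the
softmax of K−1 free logits with no membership covariates.  The
free-parameter count entering the BIC penalty is
K(d+1) + (K−1) + cov-parameters + residual-parameters; for quadratic F
this is 5K+5 (10, 15, … 40 for K = 1…7).

Time enters through an affine transform, default *t′ = (t − 45)/10*
(centre mid-adulthood, unit ≈ one decade), purely to condition the
quadratic design; fitted trajectories are reported on the natural age
axis.  Subjects contribute whatever visits they have (unbalanced
likelihood); there is no imputation.

## Estimation

Maximum likelihood by generalised EM:

* **E-step** — posterior class probabilities in log space
  (log-sum-exp; per-class Cholesky factorisations).  Subjects whose
  densities underflow in every class are flagged and given their prior.
* **M-step** — π in closed form; β<sub>k</sub> by posterior-weighted GLS
  under the current covariances; covariance parameters by warm-started
  L-BFGS-B with analytic gradients in a log-Cholesky parameterisation
  (log-scale for σ², ω), capped at 25 inner iterations.  Because the
  warm start is the incumbent and the update is kept only when it
  improves the expected objective, the observed log-likelihood is
  non-decreasing at every iteration — the property the test suite
  asserts on every fit.
* **Multi-start** — start 1 clusters per-subject OLS polynomial
  coefficients with k-means; later starts randomly perturb those labels
  (30% reassignment) under the configured seed.  The best final
  log-likelihood wins.  All randomness flows from one integer seed, so a
  refit is bit-identical.
* **Convergence** — relative log-likelihood change below `tol`
  (default 1e-6) within `max_iter` (default 500).  Failure to converge,
  or a degenerate solution (an effectively empty class, non-finite
  likelihood), is an explicit reported state carried through sweeps —
  never an exception that silently drops the candidate.
* **Numerics** — every marginal covariance receives a ridge jitter
  (default 1e-8) before factorisation; classes below 0.5% receive a
  warning (and below 1% a selection advisory) but are never deleted.
* Subjects sharing a visit-time pattern share V<sub>ik</sub>, so all
  dense factorisations are done once per (pattern, class); this is purely
  a performance device.

Model selection uses BIC = −2ℓ + p ln N with N the number of subjects.

## The eight-step workflow

1. **Scoping** — fit the fixed-effects-only model at a provisional K.
   For each order j ∈ {0,1,2} the residuals are regressed per subject on
   a degree-j polynomial; the across-subject mean square of the top
   coefficient is compared with its pure-noise expectation
   ([(T<sub>j</sub>ᵀT<sub>j</sub>)⁻¹]<sub>jj</sub> × the within-subject
   residual variance, estimated from each subject's highest-degree
   residual mean square, which is free of subject-level polynomial
   effects).  A ratio above 2 (configurable) marks the order present; the
   suggestion is the highest order present in any class.  A class-mean
   residual curve cannot carry this information — it is flat by
   construction once class fixed effects are fitted — which is why the
   rule works at the subject level.  Detection requires the
   random-effect variance to be comparable to the noise variance; weaker
   effects are picked up later by the structure sweep (step 3) rather
   than by scoping.
2. **Class enumeration** — sweep K (default 1–7), lowest BIC among
   converged fits wins; failures are tabulated alongside.
3. **Structure refinement** — sweep A–G at the chosen K, reported in
   ladder order.
4. **Adequacy** — APPA (> 0.70 in every class), OCC (> 5), relative
   entropy E<sub>K</sub> (> 0.5), mismatch.  `select_favoured` returns
   the lowest-BIC candidate passing all thresholds, otherwise the
   lowest-BIC candidate with its violations listed — the trade-off is
   surfaced, not automated away.
5. **Graphics** — plot-ready tables only: class mean curves, 95%
   predictive bands (±1.96 × marginal SD), a seeded spaghetti sample.
6. **Discrimination** — degrees of separation and residual envelopes
   (below).
7. **Characterisation** — concordance of modal classes with an external
   ordinal categorisation (default WHO BMI bands at 18.5/25/30/35) by
   weighted kappa.
8. **Sensitivity** — refits on subjects with ≥ m observations
   (default m ∈ {2, 3}), compared to the main model by aligned-class
   kappa and maximum trajectory deviation.

## Diagnostics: definitions and conventions

* **APPA<sub>k</sub>** — mean of the maximum posterior probability over
  subjects modally assigned to class k (ties to the lower index).  An
  empty class yields a *missing* value, not zero, so collapse is
  distinguishable from poor separation.
* **OCC<sub>k</sub>** = [APPA/(1−APPA)] / [π/(1−π)]; +∞ at APPA = 1.
* **E<sub>K</sub>** = 1 − Σ −p ln p / (N ln K).  Natural logarithms; the
  base cancels in the normalisation.  Undefined at K = 1.
* **Mismatch** δ<sub>k</sub> = π̂<sub>k</sub> − N<sub>k</sub>/N, summing
  to zero exactly.
* **Degrees of separation** — class mean curves μ<sub>k</sub> on a grid
  of T times; pooled covariance V̄ = Σ π<sub>k</sub> V<sub>k</sub>(grid);
  pairwise Mahalanobis d<sub>kl</sub> = √[(μ<sub>k</sub>−μ<sub>l</sub>)ᵀ
  V̄⁻¹ (μ<sub>k</sub>−μ<sub>l</sub>)].  The scalar DoS is the **minimum**
  pairwise distance divided by √T (per-time-point scale), so DoS = 0
  exactly when all curves coincide, doubling the separation doubles DoS,
  and the value is invariant to affine rescaling of the outcome.  The
  full pairwise matrix is exposed so any other summary can be formed;
  min-over-pairs is this package's choice because the criterion guards
  against *any* two classes being indistinguishable.
* **Residual envelopes** — residuals against every candidate class mean,
  weighted by the posterior; per class and time bin the weighted mean and
  local SD give boundaries mean ± SD.  Bins are exact observation times
  when there are ≤ 20 distinct times, else 5-year bins; cells below an
  effective weight of 1.0 are missing.  A class is flagged "parallel"
  when the relative range of its boundary width across bins is
  < 0.5 — homoscedastic residuals in a near-balanced design sit well
  inside this, strong time-heteroscedasticity well outside.
* **Kappa** — Cohen's κ from the K×C count table; disagreement weights
  none, |i−j|/(K−1), or its square.  Because latent labels are
  arbitrary, κ can be maximised exhaustively over row permutations
  (exact for K ≤ 8).  For concordance with ordinal outcome bands the
  package defaults to **quadratic** weights on the canonical
  (descending-π) ordering: on the published 5-ladder worked example this
  convention — and only this one — reproduces the reported κ_ω values
  (0.182 and 0.52) from the printed tables.

## Synthetic data

The simulator draws from exactly the fitted family: class ~
Categorical(π), b<sub>i</sub> ~ N(0, B<sub>k</sub>), Gaussian noise, on a
four-visit adult age grid (18, 35, 50, 62.5 years) with optional time
jitter and independent per-visit dropout (the first visit is always
retained).  What it does *not* emulate about real cohort data: recall or
measurement error in the outcome, informative (missing-not-at-random)
dropout, non-Gaussian within-class variation, and covariate-driven class
membership.  Passing recovery tests therefore demonstrate correctness of
the estimator under the model's own assumptions, not robustness to their
violation.

Shipped scenarios, with magnitudes chosen once as realistic for adult BMI
trajectories:

* `aarp_like_config` — five quadratic BMI-like classes with strongly
  imbalanced proportions (68.1, 25.0, 3.8, 2.7, 0.4%), mean curves
  ranging from stable-normal-weight to rapid-early-obesity; random-effect
  SDs 1.0/0.5/0.25 (intercept/slope/curvature per decade), correlation
  0.3, residual SD 1 kg/m², class scales 0.85–1.2.  These magnitudes make
  a correctly specified fit's classification quality land where large
  adult cohorts report it (class APPA ≈ 0.7–0.9, E<sub>K</sub> ≈ 0.6–0.7):
  neighbouring curves overlap, distant ones do not.  Proportions of the
  two largest classes are only weakly identified here — as in the real
  cohorts this emulates, where they swing by tens of percentage points
  across structures.
* `two_class_config` — two well-separated classes (3 residual SDs apart
  by default) for recovery experiments.
* `three_class_config` — three moderately separated classes (55/33/12%)
  for class-enumeration experiments.

`recovery_experiment` aligns fitted classes to the truth by exhaustive
kappa maximisation over label permutations and reports fixed-effect
bias/RMSE, assignment agreement, and (optionally) how often a BIC sweep
selects the true K.

## Problem sizes used by the test suite

Unit tests run at N = 40–500 subjects; recovery checks use N = 2000 with
one replicate per structure; the class-enumeration consistency experiment
uses 20 replicates of N = 600 with 2 EM starts and a K = 1–5 sweep; the
Monte-Carlo likelihood oracle uses 10⁶ draws on 2-subject instances.
These sizes were chosen to make each property statistically decidable at
the stated tolerances.

## Known limitations

* No standard errors for fitted parameters (the selection framework does
  not use them) and no Bayesian estimation.
* No covariates in the membership or trajectory submodels; stratified
  analyses (e.g. by gender) are the caller's loop.
* EM with multi-start is a local optimiser: the nesting inequality
  ℓ(G) ≥ ℓ(F) ≥ ℓ(E) holds only up to multi-start noise, and sweeps on
  hard data can mark structurally estimable candidates as failed.
* Scoping (step 1) needs subjects with enough visits (order j requires
  n<sub>i</sub> ≥ j+2) and random-effect variances comparable to noise.
* Exhaustive kappa label optimisation is factorial; it is capped at
  K ≤ 8.
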