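# Methods

## Estimands

Let `A` be the randomized arm (1 = digital intervention + enhanced usual
care, 0 = enhanced usual care), `C` baseline covariates, `(M1, M2, M3)` the
mediators at three months and `Y` the binary outcome (PHQ-9 reduced by at
least 50% between baseline and six months; a closed boundary, so a drop of
exactly half counts as improved). M1 and M2 only exist under treatment;
their unexposed level is defined as 0, which makes their counterfactual
distribution under `a = 0` degenerate at 0 rather than undefined. This is
what allows interventional effects to be used for intervention-arm-only
process measures.

For each exposure level, mediator values are *drawn* from estimated
counterfactual distributions rather than set to cross-world individual
values: `G(a)` denotes a draw of the full triple from the joint law at
exposure `a`, and `g_k(a)` an independent draw of mediator `k` from its
marginal law at `a`. With `P[a; spec]` the population mean of the predicted
outcome probability, the six reported quantities are the total effect,
direct effect, one indirect effect per mediator (switching that mediator's
marginal source from 0 to 1 in the fixed order M1, M2, M3), and a
dependence component defined as the joint-minus-marginal remainder
(see README for the formulas). The decomposition telescopes, so additivity
is an algebraic identity, not an approximation.

The sequential switch-on order follows the theorized causal chain —
understanding session content enables completing activities, which raises
behavioural activation. Interventional decompositions are order-dependent;
the order is a configurable argument (`order=`) and is recorded in every
result object.

## Models

All fits use statsmodels on complete cases:

* M1: binomial GLM (logit link) on confounders, intervention arm only.
* M2: multinomial logit (3 levels, reference = none completed) on
  confounders (marginal variant) and additionally on M1 (joint variant),
  intervention arm only.
* M3: linear model on arm + confounders (marginal) and additionally on
  M1 + the two M2 contrasts (joint), both arms.
* Y: binomial GLM (logit link) on arm, M1, M2 (two indicator contrasts
  against level 0), M3, confounders, and interaction terms. The default
  interaction set is all three pairwise mediator–mediator interactions
  plus M3 × medication, with M3 × site added in pooled runs; it is
  config-overridable, and reports echo the set actually used, since the
  exact published model formulas are not reproducible from the main text.

Counterfactual M3 draws add normal noise with the fitted residual SD and
are deliberately **not** truncated to the 0–54 BADS-SF range: truncation
would bias the conditional mean away from the fitted linear model. An
empirical-residual option (`residual_kind="empirical"`) resamples fitted
residuals by inverse CDF instead. The joint mediator law is factorized
M1 → M2 | M1 → M3 | M1, M2; interventional effects only require *a* valid
construction of the joint draw, and this sequential factorization is one.

No random effect is placed in the outcome model for the cluster randomized
site; clustering is honored at the inference stage by the cluster
bootstrap. Binary/multinomial fits are declared failed (and bootstrap
replicates dropped) on non-convergence, an empty mediator category, or
quasi-separation, detected as fitted linear predictors beyond ±30.

Design matrices are assembled from term lists by plain column products
in-package (statsmodels does all fitting). This keeps bootstrap refits at
a few milliseconds and lets counterfactual predictions on ~10^6-row
expanded data split each column into static, exposure and mediator parts
evaluated per draw.

## Monte Carlo estimation

Each record is replicated K times (default K = 1000, matching the analysis
the package reimplements); the empirical covariate rows are the
standardization population and are never resampled. One uniform stream per
expanded row per mediator is mapped through each regime's inverse CDF
(common random numbers), so the seven distinct counterfactual means share
draws, shared terms cancel exactly, and Monte Carlo variance of contrasts
is low. Means within 1e−6 of 0 or 1 trigger a boundary warning, which in
practice flags quasi-degenerate refits on small resamples. A configurable
row budget (default 2×10^7) refuses runaway expansions.

## Inference

Nonparametric bootstrap with B resamples (default 1000) honoring each
site's design: participants are resampled with replacement within arm at
the individually randomized site (arm is used as the stratification
variable, since the trial's actual randomization strata are not published;
this preserves the realized allocation), and whole clusters are resampled
within arm at the cluster randomized site, keeping within-cluster rows
intact. Pooled data resample each site by its own rule and concatenate.

Confounder screening (univariable tests, select at p < 0.10 against any
mediator or the outcome; likelihood-ratio joint test for the 3-level M2;
intervention-arm-only screening for M1/M2 to avoid artefactual association
driven by the structural zeros) is performed once on the original sample
and held fixed across replicates — re-screening per replicate would change
the estimand. Mediator and outcome models are refitted on every replicate;
refits are warm-started from the full-sample estimates. Replicates with
unfittable models are dropped and counted, with a warning above 5%.

Intervals are bias-corrected (BC, not BCa — no acceleration term):
`z0 = Φ⁻¹((#{θ* < θ̂} + ½·#{θ* = θ̂}) / B)` with ties split evenly and the
proportion clamped to (1/2B, 1−1/2B) with a warning if all replicates fall
on one side; bounds are the bootstrap quantiles at `Φ(2·z0 ∓ 1.96)`. With
z0 = 0 this is the plain percentile interval, and a constant estimator
yields the degenerate interval [c, c].

Moderated mediation is tested by a Wald test on the named interaction
column(s) of the fitted outcome model (a joint χ² test when the term
expands over the categorical M2).

## Synthetic generator and oracle

The generator emulates the two-site structure: exact 1:1 individual
randomization at one site; 20 clusters randomized 10:10 at the other, with
cluster random intercepts (SD 0.3 on the log-odds scale) entering the
outcome only. Baseline covariates are truncated normals/Bernoullis whose
truncated means match the pooled trial sample (PHQ-9 15.3 on ≥10, age
56.9, education 8.7, medication 26%, friends 82%, phone-use 4.5,
BADS-SF 23.7). For PHQ-9 and phone use no truncated normal on so short a
range attains the published SD, so those two are mildly underdispersed —
a known, accepted gap between fixture and data. Mediator-model intercepts
were solved numerically (then frozen) so the intervention-arm marginals
match the sample: P(M1 = 1) = 0.775, M2 split (0.122, 0.641, 0.237),
three-month BADS-SF means ≈ 25.4 (control) / 27.7 (intervention), pooled
outcome rate ≈ 0.47. Outcome coefficients were calibrated so the *true*
decomposition shows the published qualitative pattern (small positive
total ≈ +0.03, direct ≈ −0.22, indirect ≈ +0.10 / +0.12 / +0.02, positive
dependence ≈ +0.008 via an M1 → M2 chain and M1 × M3, M1 × M2
outcome interactions).

M2 is generated directly at its 3-level categorization (the 0–27 count
never enters any analysis), and the six-month PHQ-9 is back-filled
consistently with the drawn binary outcome (any integer below half of
baseline when Y = 1) so outcome derivation and the recovery-outcome
(PHQ-9 < 10) sensitivity path are exercisable. Recorded M3 values are
integers clipped to 0–54, exactly as a questionnaire would yield.

What the generator does **not** emulate: missingness mechanisms (records
are complete; the complete-case filter is exercised by injecting
missingness in tests), session-level adherence series, within-site
covariate differences, and real-data model misspecification. Passing
recovery tests therefore demonstrate estimator correctness under a
correctly specified structural model, not robustness to misspecification.

`oracle_true_effects` computes the true estimands by direct large-n
simulation of the structural model under each regime (independent upstream
copies realize true marginal laws), with common random numbers and
batch-based Monte Carlo standard errors (default n = 2×10^6 in 20
batches, giving component MC errors of ~1e−4 — far below estimator
tolerances). A fully discrete configuration (Bernoulli covariates, binary
M3, no cluster effects) is checked against exact enumeration in the tests.

## Problem sizes in the test suite

Simulation-based checks run at sizes chosen to keep the default suite
fast while leaving conclusions statistically meaningful: parameter
recovery uses one n = 5000 trial at K = 500 against the n = 2×10^6 oracle
with B = 60 bootstrap SEs; null-calibration coverage runs 120 simulated
single-site pipelines (n = 300, K = 25, B = 400), judging coverage within
three binomial SEs of 0.95; the moderated-mediation size check uses 500
replicates at n = 2000. The acceptance script runs the full study-scale
pipeline (n = 1045, K = 1000, B = 1000).

## Known limitations

* Estimates are simulation-based; rerunning with another seed moves
  components by O(1/√(nK)) — negligible at K = 1000 but visible at the
  reduced K used inside bootstrap replicates.
* The dependence component conflates mediator covariance and
  interaction-in-effect pathways; it is a remainder, not a named path.
* Small analysis sets with rich interaction models can quasi-separate;
  such fits raise (or are dropped within the bootstrap with a count)
  rather than silently returning degenerate probabilities.
* Natural (pure) direct/indirect effects, path-specific effects and
  machine-learning nuisance estimation are out of scope.
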