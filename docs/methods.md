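# Methods

## Model

The joint latent class mixture model (JLCMM) assumes a finite number G of
latent classes; given class, a subject's longitudinal symptom record and
her event outcome are independent. The per-subject likelihood is

L_i = Σ_g π_g · f_long(y_i | g) · f_surv(T_i, δ_i | g),

with π = softmax(θ), θ_1 = 0.

**Longitudinal component.** The GDS-15 is an integer score on [0, 15] with
a heavy floor; a Gaussian model on the raw score is misspecified. A
monotone transformation H(y; η) = η₀ + Σ_k η_k² I_k(y) built from
quadratic I-splines is estimated jointly with the rest of the model; the
squared coefficients make H nondecreasing by construction, and the
likelihood carries the Jacobian term Σ log H′(y_ij). Knots sit at
empirical score quantiles (default three: minimum, median, maximum, giving
four basis functions). On the transformed scale each class follows a
piecewise-linear mean with a kink at t = 0 (the late-study baseline): an
intercept β0_g and separate slopes before (β1_g) and after (β2_g), plus
class-invariant covariate effects γ and a single Gaussian random intercept
(SD σ_b, shared across classes). Random slopes are deliberately absent,
matching the study design this emulates; this is a known limitation (class
counts can be over-extracted when slope heterogeneity is forced into the
mixture). The within-subject covariance is compound-symmetric, so the
marginal density is evaluated with rank-one determinant/inverse identities
— no quadrature and no per-subject matrix factorisation.

**Identifiability of the link.** H and the trajectory model share a
location and a scale: adding c to η₀ and to every β0_g, or scaling H and
(β, σ_b, σ_e) together, leaves the likelihood unchanged. Exactly one
location and one scale constraint are therefore imposed: η₀ = 0 and
σ_e = 1. Class intercepts stay free and interpretable on the transformed
scale. (An identity-link mode with free σ_e exists for the untransformed
special case; with a linear spline the two parameterisations coincide, a
property the tests exercise against a standard mixed-model fit.)

**Survival component.** Dementia and death without prior dementia are
competing events with cause-specific two-parameter Weibull baselines and
proportional class shifts ζ_gk (reference class zero) plus covariate
effects ω_k. The cause-specific factorisation means the log-likelihood is
[δ = k]·log h_k(T) − Σ_k Λ_k(T) with closed-form cumulative hazards. All
subjects are event-free at t = 0 by design, so no left truncation is
modelled. Cumulative incidence functions integrate h_k·S by composite
Simpson under the substitution u = v³, which removes the singular
derivative of the Weibull hazard at the origin (absolute error below 1e-6
on the default grid).

## Estimation

The observed-data log-likelihood is maximised directly (no EM): every
class-conditional factor is closed form, and the full analytic gradient —
posterior-weighted sums of the component score functions — costs about one
likelihood evaluation. Optimisation uses L-BFGS-B on an unconstrained
parameterisation (log shapes/scales/SDs, squared link coefficients,
reference-constrained logits).

Mixture surfaces are multimodal, so each fit ranks several short runs and
continues the best to convergence:

* a deterministic data-driven start — k-means on per-subject mean
  transformed scores before/after t = 0, each cluster given its own
  piecewise least-squares line and crude event-rate hazard shift;
* `n_starts` (default 30) random starts perturbing the converged one-class
  solution;
* during class enumeration, warm starts that duplicate each class of the
  (G−1)-solution with jittered level and halved prior weight. These make
  the maximized likelihood nondecreasing in G, which the enumeration tests
  assert.

Classes are relabeled deterministically — ascending model-implied score at
t = 0 (back-transformed), ties broken by descending class size — with the
reference constraints restored exactly (the zeta shift is absorbed into
the Weibull scales, leaving every hazard invariant). BIC = −2·loglik +
n_params·log(N) with N the subject count; the parameter count is the
length of the packed vector: (K+1) link coefficients, 3G trajectory, |γ|,
one for σ_b, per cause 2 + (G−1) + |ω|, and G−1 logits. Wald CIs for
hazard ratios use the inverse observed information from a central
finite-difference Hessian at the optimum (step 1e-4·(1+|x|)); a singular
information matrix flags the CIs unavailable rather than failing.

Convergence uses the optimizer's relative-function and projected-gradient
criteria (defaults 1e-10 and 1e-5); the reported diagnostics include the
per-start short-run log-likelihoods so stuck starts are visible.

## Post-classification analyses

Exposures are standardised to per-SD units on complete cases (SD with the
n−1 denominator). The weighted multinomial logistic regression maximises
Σ_i w_i log P(class_i | x_i) by Newton iterations with step halving; each
subject contributes one row weighted by the posterior probability of her
modal class (the alternative — one row per subject × class weighted by the
full posterior — is a deliberate non-default, as the modal-weight reading
matches how such weights are described in practice). Inference is Wald
from the weighted information matrix; coefficients exceeding ±15 on the
standardised scale are flagged as probable separation. Baseline
characteristics are compared across classes by one-way ANOVA (continuous)
and Pearson chi-squared (categorical; Fisher exact for sparse 2×2 tables);
missing categorical values are kept as an explicit level.

## Synthetic cohorts

The generator emulates the structure of a two-study women's cohort with
annual depression assessments (observed study period t = −9..9 years
around the second study's baseline, administrative censoring at t = 13):

* five classes with proportions (36, 25, 5, 9, 25)%;
* piecewise-linear GDS-scale trajectories with t = 0 levels
  (0.50, 2.70, 2.30, 3.24, 0.60) and slopes chosen so the earlier-study
  baseline means match the published per-class values (0.50, 2.69, 4.55,
  0.54, 0.60) and the emerging-mid class crosses the clinical cutoff of 5
  about four years after t = 0; σ_b = 0.8, σ_e = 1.0; scores are rounded
  and clipped to 0..15 — the resulting floor effect is exactly the
  skewness the fitted spline link must absorb, and it is deliberately
  *not* generated from the fitted model's own link family;
* dementia Weibull (shape 2.0, scale 33.61) calibrated so the reference
  class reaches ≈11% cumulative incidence by t = 13 under competing
  mortality, with class hazard ratios (1, 1.82, 2.11, 5.10, 2.78); death
  Weibull (shape 1.5, scale 22.81) calibrated to ≈33% competing mortality,
  equal across classes (per-class mortality differentials are not
  reported, so none are planted);
* an annual visit grid with random start delay (55/20/12/8/5% at 0..4
  years), 87.5% per-visit attendance, 12% loss to follow-up, at least 5
  attended visits, and truncation at dementia/death — reproducing the
  published schedule summary (mean 14.4 assessments, range 5–19; the
  realised SD is ≈2.8 against a published 2.91);
* class-conditional MRI measures for a 569/957 subsample drawn
  independently of class membership: log-normal WM-SVID and logit-normal
  AD-PS, both moment-matched to the published per-class means/SDs;
  history-of-depression prevalence from the published per-class counts;
  per-class age distributions from the published means/SDs.

What the generator does *not* emulate: informative MRI-subsample
selection, visit-timing jitter within a year, item-level GDS structure,
covariate effects on symptoms or hazards (planted at zero by default), and
class-specific random-intercept variance. Passing recovery tests therefore
demonstrate correctness of the estimation machinery under the stated
data-generating process, not robustness to every real-data complication.

## Problem sizes and tolerances

Recovery checks run at n = 2000 subjects (≈29,000 visits), where one
five-class fit takes a few seconds with the analytic gradient; the BIC
enumeration check runs at the emulated study size n = 957, G = 1..6. The
planted-coefficient multinomial checks use the imaging subsample size
n = 569 with 10 replicates. Oracle equivalences (dense multivariate
normal, 10⁶-draw Monte-Carlo integration, adaptive quadrature, Bayes rule)
are asserted at 1e-6..1e-10; stochastic recovery assertions use bounds
derived from realised event counts (3 SE) or fixed bands stated in the
tests. Degenerate inputs are defined errors: constant score distributions
(no knots), zero-derivative link regions (−∞ likelihood, named subject),
nonpositive event times, invalid event codes, empty outcome classes.

## Design notes

* Direct quasi-Newton rather than EM: with closed-form class-conditional
  densities the gradient of the mixture log-likelihood is cheap and exact,
  and L-BFGS converges in far fewer passes than EM on these surfaces.
* Ties between dementia and death dates resolve to dementia (the event of
  interest); assessments exactly at the dementia date are retained (the
  exclusion rule is strictly "after").
* In the age-scale sensitivity analysis only the mixed-model clock changes
  (age − 80); event times stay on the study clock, preserving positive
  survival times.
* The "three-quantile spline" convention is read as three knots with the
  boundary knots counting toward the three; the knot count is
  configurable.
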