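# jlcmm — joint latent class modelling of depressive-symptom trajectories and dementia risk

Older adults differ widely in how depressive symptoms evolve across late
life and in how that course relates to dementia. Modelling the two
separately is biased: symptom assessments stop at dementia onset, and death
competes with dementia. This package implements the joint latent class
mixture model (JLCMM) used to study such data: it simultaneously clusters
long-run trajectories of a bounded symptom score (the 15-item Geriatric
Depression Scale, GDS-15) and class-specific competing risks of dementia
and non-dementia death, then links class membership to structural MRI
measures of cerebrovascular disease (WM-SVID) and Alzheimer-related
neurodegeneration (AD-PS). It is written for biostatisticians and
epidemiologists who want a transparent, fully testable Python
implementation with a calibrated synthetic-cohort generator standing in for
restricted cohort data.

## The model

For subject *i* with latent class *g* ∈ {1..G}:

* **Membership**: P(class = g) = softmax(θ_g), θ_1 = 0.
* **Longitudinal**: a monotone quadratic I-spline link H(·; η) (knots at
  score quantiles, coefficients squared to enforce monotonicity) maps the
  skewed bounded score to a Gaussian scale, where a piecewise-linear mixed
  model holds:

  H(y_ij) = β0_g + β1_g·min(t_ij, 0) + β2_g·max(t_ij, 0) + x_ij′γ + b_i + ε_ij,

  with random intercept b_i ~ N(0, σ_b²), ε_ij ~ N(0, 1) (residual SD and
  the link offset are fixed for identifiability), and t the time in years
  from the late-study baseline (the slope kink).
* **Survival**: cause-specific Weibull proportional hazards for dementia
  (k = 1) and death (k = 2):

  h_k(t | g) = (α_k/σ_k)(t/σ_k)^{α_k−1} exp(ζ_gk + w′ω_k),  ζ_1k = 0,

  so exp(ζ_g1) is the dementia hazard ratio of class g versus the
  reference class.

Longitudinal and survival parts are independent given class. The
observed-data log-likelihood (closed form per class: rank-one Woodbury
identities for the compound-symmetric Gaussian, closed-form Weibull
cumulative hazards, spline Jacobian) is maximised directly by multi-start
L-BFGS with analytic gradients; the number of classes is chosen by BIC;
subjects get Bayes-rule posterior class probabilities. Downstream,
posterior-weighted multinomial logistic regression estimates per-SD odds
ratios of MRI burden on class membership.

## Worked example

```python
import numpy as np
from jlcmm import (default_scenario, generate_cohort, fit_jlcmm, FitConfig,
                   class_hazard_ratios)
from jlcmm.membership import class_prior

scenario = default_scenario()          # calibrated five-class truth, n=957
scenario.n_subjects = 2000
cohort, truth = generate_cohort(scenario, seed=1)

model = fit_jlcmm(cohort, G=5, config=FitConfig(n_starts=10, seed=1))
print(np.round(100 * class_prior(model.params.membership), 1))
print(np.round(np.exp(model.params.survival.zeta[:, 0]), 2))
```

prints

```
[36.5 24.3  4.5 26.6  8.1]
[1.   2.24 1.64 1.57 5.  ]
```

— the estimated class proportions (%) and dementia hazard ratios, with
classes ordered by their model-implied score at t = 0 (ascending): minimal,
emerging-late, remitting/relapsing, mild, emerging-mid. The generator
planted proportions (36, 25, 5, 25, 9)% and hazard ratios (1, 2.78, 2.11,
1.82, 5.10) in that order; a single n = 2000 replicate recovers them to
within sampling noise (the hazard ratio of the small remitting class is the
noisiest, as its confidence interval from `class_hazard_ratios(model)`
shows).

The numbered scripts under `analysis/` run the full pipeline and write
tables and figures to `results/`: `01_simulate_cohort.py` (cohort
generation), `02_fit_jlcmm.py` (BIC enumeration G = 1..6, posteriors,
hazard ratios, trajectory and cumulative-incidence curves),
`03_mri_associations.py` (posterior-weighted multinomial regressions),
`04_sensitivity.py` (age-80 time scale; prior-depression exclusion).

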