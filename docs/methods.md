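# Methods

`umaic` is a simulation laboratory for **unanchored matching-adjusted indirect
comparison (MAIC)** of time-to-event outcomes across two single-arm trials.
This note documents the generative model, the estimators, the numerical
choices, and the limits of what the shipped simulations can show.

## Generative model

Two hypothetical single-arm breast-cancer trials are simulated:

* **Arm A** (n = 1000): the trial whose individual patient data (IPD) the
  analyst holds.
* **Arm B** (n = 800): the comparator, available only as published aggregates
  plus a Kaplan–Meier figure.

Each subject carries three prognostic covariates: age (years), post-menopausal
status (binary), and tumour grade (1/2/3, encoded as grade-2 and grade-3
indicators with grade 1 as reference). Age is drawn from a normal distribution
truncated at arm-specific bounds (A: mean 53, SD 11, range [21, 80]; B: mean
56, SD 12, range [23, 85]), sampled by inverse CDF on the truncated interval
so that one uniform draw maps to one subject — the stream is reproducible
draw-for-draw regardless of bounds. Binary/categorical covariates are drawn
from Bernoulli/categorical distributions (A: 40% postmenopausal, grades
20/65/15%; B: 50%, 10/70/20%). Arm B is deliberately the sicker population.

Recurrence-free survival (RFS, days) follows a Weibull proportional-hazards
model with cumulative hazard

    H(t | x) = lambda * t^gamma * exp(x' beta),
    lambda = 4e-8 per day^gamma,  gamma = 2.2,

so S(t|x) = exp(-H(t|x)) and the latent event time is the inverse-transform

    T = ( -ln U / (lambda * exp(x' beta)) )^(1/gamma),   U ~ Uniform(0, 1].

Under this parameterization the printed lambda and gamma put the bulk of
events inside the 2500-day follow-up window (baseline S(2500) ≈ 0.30 at
x'beta = 0), which is the only reading under which the coefficient scale makes
sense. The log-hazard coefficients are: age 0.02/year, post-menopausal 0.5,
grade 2 0.3, grade 3 0.6. Treatment B carries logHR −0.5 in **scenario 1**; in
**scenario 2** it carries −0.4 plus a B × menopause interaction of −0.2, so
menopausal status is both prognostic and effect-modifying, and with 50%
post-menopausal prevalence in B the population-average treatment effect is the
same −0.5 in both scenarios. That −0.5 is the truth used for bias and
coverage throughout.

**Censoring.** C ~ Uniform(0, 2500 days), independent of covariates and
treatment; the event is observed iff T ≤ C. Because C never exceeds the
2500-day horizon no separate administrative cut is needed. This induces
roughly 38% censoring in arm A and 48% in arm B. A sensitivity parameter
(`ArmSpec.censor_upper`) widens the parent uniform before capping it at the
horizon; as it grows, censoring thins toward the purely administrative ~1–3%
and the per-repetition estimator variance drops from ≈0.004 to ≈0.0025 on the
logHR scale. The default censoring intensity is a genuine modelling choice,
and several downstream magnitudes (Monte-Carlo variance, MSE, absolute
coverage levels) are sensitive to it; see "What the simulations do and do not
show" below.

## The published view of arm B

`publication.publish` produces exactly what a journal article exposes:

* the Kaplan–Meier step-function corners (product-limit estimate via
  lifelines), with times rounded to whole days and survival to 4 decimals —
  a programmatic stand-in for figure digitization;
* a numbers-at-risk table on the grid {0, 500, 1000, 1500, 2000, 2500} days
  (common journal practice over this horizon; configurable);
* baseline aggregates: mean and sample variance (ddof = 1) of age,
  proportions of the binary indicators, total n;
* the total event count (published by default; configurable off).

An optional uniform jitter on both axes emulates pixel-level digitization
error but is **off by default**, because manual-digitization error is
unquantifiable; the default extraction is faithful up to rounding. Corners
that collide on the same day after rounding are merged keeping the lower
survival.

## Pseudo-IPD reconstruction

`reconstruct.reconstruct` inverts the published curve interval by interval in
the manner of the standard curve-inversion algorithm used for digitized KM
figures: within each risk-table interval, the number of censored subjects is
adjusted by a fixed-point iteration until the product-limit curve implied by
the inferred event counts at the published corner times reproduces both the
published survival drops and the next published number at risk. Censoring
times are spread evenly within their interval (deterministic placement —
reconstruction is a pure function of the publication). If the total event
count is published, censoring in the trailing interval is reconciled against
it. Subjects still at risk after every published corner are censored at the
last corner. Event counts are inferred by rounding half-to-even (the
convention of mainstream statistical software).

Two structural guarantees hold: the reconstructed record count equals the
published n at time 0 (censor emissions are capped by the at-risk
bookkeeping), and in the lossless regime — risk table at every event time,
rounding disabled — recovery of event times and event/censor labels is exact
up to within-interval censor placement (exact recovery of everything when
there is no censoring).

**Fidelity validation.** Raw and reconstructed B-arm records are stacked with
a "reconstructed" indicator and fit with a Cox model including the indicator
and its time-varying effect (indicator × analysis time; ln t available as an
option). Faithful reconstruction gives both hazard ratios equal to one.
Because the only covariate is the group label, the Breslow partial likelihood
collapses to per-event-time group counts; `coxtv.py` maximizes that
2-parameter concentrated likelihood directly instead of episode-splitting
~1600 subjects at ~900 event times into a ~10^6-row start–stop frame. The
concentrated fit is cross-checked against lifelines' `CoxTimeVaryingFitter`
on a tie-free fixture in the test-suite.

## Entropy balancing

Weights for the A arm minimize the Kullback–Leibler divergence from uniform
base weights subject to exact moment constraints on the published aggregates:
age on its first **and second** raw moments (second moment reconstructed as
published variance + mean², sample-variance convention taken as-is — the
ddof discrepancy is var/n, far below reporting precision at n = 800), and the
binary indicators on their proportions (their second moments follow their
first). The dual is an unconstrained convex problem over one multiplier per
constraint, solved by damped Newton iteration with step-halving on columns
standardized to zero target and unit scale, falling back to BFGS if the dual
Hessian is ill-conditioned (condition number > 1e12). Convergence requires
every achieved moment within 1e-8 relative of its target; infeasible targets
(outside the open range of the source column) are rejected up front with the
offending moment named. Weights are rescaled to sum to the comparator n, so
the two arms carry equal weighted sample sizes. The effective sample size is
ESS = (Σw)²/Σw² — scale-invariant and at most n.

Weighting strategies: `unweighted`; `all_covariates`; `omit_effect_modifier`
(drops menopause from the constraints); `omit_effect_modifier_and_grades`
(balances age only). Scenario 1 runs the first, second and fourth by default
(the third optionally — it feeds the bias-factor adjustment); scenario 2 runs
all four.

## Treatment-effect estimation

The pooled estimator is a Cox regression of the stacked data (weighted A arm
+ unit-weighted reconstructed B arm) on the B indicator alone, via lifelines
`CoxPHFitter` with the balancing weights as sampling weights and the robust
sandwich variance (`robust=True`); the 95% CI is Wald on the log scale. Ties
(day-rounded reconstructed times) are handled by lifelines' Efron correction;
tie groups are small (mostly 1–2 subjects per day), so the difference from
the Breslow convention is far below Monte-Carlo noise. Estimates are
invariant to rescaling the pooled weight vector by a constant, but *not* to
scaling one arm's weights against the other's — which is why the
sum-to-comparator-n convention is fixed once and applied everywhere.

## Monte Carlo evaluation

`evaluation.run_study` runs seeded repetitions of the full pipeline. For each
strategy it reports, on the logHR scale with truth −0.5:

* bias = mean(estimate − truth);
* MCV = Σ(estimate − mean)²/(N−1), the squared empirical standard error;
* MSE = Σ(estimate − truth)²/N, which satisfies
  MSE = bias² + (N−1)/N · MCV exactly (asserted to machine precision);
* CI coverage: % of Wald CIs containing exp(−0.5);
* mean ESS.

Seeding: one master seed per study; the arm-level generator for repetition
*r* is seeded with `SeedSequence([master_seed, r, arm_code])`, where the
A-arm code is scenario-independent — the same A-arm realization is shared
across scenarios, mirroring a triplet design (one A, one B per scenario).
Failed repetitions (solver or Cox non-convergence, degenerate arms) are
logged and excluded, never imputed; aggregates report the effective N and a
warning fires above 5% exclusions.

**Bias-factor adjustment.** For an omitted binary confounder U, the
VanderWeele bound HR_obs/HR_true ≤ (HR_UD × RR_EU)/(HR_UD + RR_EU − 1) is
used to gauge the strongest plausible effect: the HR estimate and the CI
lower limit of the strategy that omitted U are divided by the bias factor.
With menopausal status as U the defaults derive HR_UD from the generative
coefficient among B-treated subjects (exp(0.5) in scenario 1, exp(0.5 − 0.2)
= exp(0.3) in scenario 2) and RR_EU = 0.50/0.40 = 1.25 from the two
prevalences, giving bias factors ≈1.085 and ≈1.055 (1.05 to two decimals).
Both inputs are explicit parameters — in practice RR_EU comes from external
sources or assumption, and the package deliberately does not hard-code any
other value. The full-precision factor is used for adjustment; rounding is
display-only.

## What the simulations do and do not show

The generator emulates: covariate imbalance between single-arm trials, a
shared Weibull baseline across arms, proportional hazards given covariates,
uniform non-informative censoring, and a faithful (rounding-only)
digitization of the published curve. It does **not** emulate: cure fractions
or non-Weibull shapes, covariate-dependent or informative censoring,
different baseline hazards across trials, or the irregular error of manual
figure digitization. Consequences worth keeping in mind:

* Even the fully-balanced strategy is *not* unbiased for −0.5: the hazard
  ratio is non-collapsible, so the marginal B-vs-A logHR in B's covariate
  population differs from the conditional −0.5 (by roughly +0.04 under the
  default conditions, per the large-sample diagnostics reproduced in the
  acceptance suite). Balancing removes confounding bias, not the
  marginal-vs-conditional gap.
* Because the default extraction is faithful, the reconstruction-indicator
  HR averages ≈1.000; any analysis whose published curves were digitized by
  hand will show an additional, direction-unknown distortion that these
  simulations do not inject (the jitter option exists to explore it).
* Absolute MCV/MSE/coverage levels depend directly on the censoring
  intensity; compare across strategies within a configuration rather than
  across configurations.

## Problem sizes and runtime

The shipped study scale is 200 repetitions per scenario (master seed 1729 in
the acceptance suite), about 1.5 minutes per scenario on one CPU; the
parameter-recovery checks use single simulated samples of 10^5 subjects per
arm without censoring, where a pooled Cox fit recovers every generative
coefficient within ±0.02. All randomness flows from explicit seeds; rerunning
any study with the same seed reproduces every table bit-for-bit.
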