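# umaic — unanchored MAIC for time-to-event outcomes

`umaic` is a simulation laboratory and analysis toolkit for **unanchored
matching-adjusted indirect comparison (MAIC)** of survival outcomes across two
single-arm trials. It is aimed at methodologists and HTA/comparative-
effectiveness analysts who need to know *how well* unanchored MAIC behaves
before trusting it: the package simulates both trials from a known truth,
emulates what one of them looks like once published (a digitized Kaplan–Meier
curve, a numbers-at-risk table, baseline aggregates), reconstructs pseudo
individual patient data (IPD) from that publication, reweights the other
trial's IPD to the published aggregates, estimates the treatment contrast, and
measures bias, efficiency and confidence-interval coverage over seeded Monte
Carlo repetitions.

## The methods at its core

* **Data generation.** Recurrence-free survival follows a Weibull
  proportional-hazards model, S(t|x) = exp(−λ t^γ e^{x'β}) with λ = 4e-8,
  γ = 2.2 and prognostic covariates age, menopausal status and tumour grade;
  latent times are drawn by inverse transform, censoring is U(0, 2500 days).
  The comparator arm B carries treatment logHR −0.5 (scenario 1) or −0.4 plus
  a −0.2 treatment × menopause interaction (scenario 2); both give the same
  population-average effect of −0.5.
* **KM reconstruction.** The published step curve is inverted interval by
  interval against the numbers-at-risk table (and total event count),
  inferring event and censor counts whose product-limit curve reproduces the
  published corners — the standard digitized-KM reconstruction algorithm,
  deterministic given the publication.
* **Entropy balancing.** A-arm weights minimize KL divergence from uniform
  subject to exact moment constraints on B's published aggregates (age mean
  and variance, binary proportions), solved through the convex dual
  (exponential tilting, damped Newton). ESS = (Σw)²/Σw².
* **Estimation.** Weighted Cox regression of the pooled data on the B
  indicator (robust sandwich variance, Wald CI), per weighting strategy:
  unweighted, all covariates, omitting the effect modifier, omitting effect
  modifier and grades.
* **Omitted-confounder bound.** Bias factor
  (HR_UD × RR_EU)/(HR_UD + RR_EU − 1); dividing the estimate and CI lower
  limit by it gauges the strongest plausible true effect when a confounder
  was unavailable for balancing.

See `docs/methods.md` for the full model, numerical choices and limitations,
and `docs/formats.md` for every file schema.

## Worked example

One repetition, from simulation to balanced comparison
(`examples/02_publish_and_reconstruct.py`, `examples/03_entropy_balance.py`):

```text
published: 363 curve corners, risk table [800, 575, 273, 96, 19, 0], 398 events
reconstructed 800 subjects, 410 events (raw arm had 398)
HR(reconstructed indicator) = 1.0011  95% CI [0.735, 1.363]
HR(time-varying effect)     = 0.999998 per day
```

Reconstruction recovered 800 subjects whose hazard is statistically
indistinguishable from the raw arm's (both fidelity HRs ≈ 1); the 12 extra
inferred events are rounding granularity of the published curve.

```text
moment            pre-balance  post-balance       target
age_m1               53.03126      55.86025     55.86025
age_m2             2924.47174    3248.64155   3248.64155
postmenopausal        0.38800       0.49500      0.49500
grade2                0.62900       0.69875      0.69875
grade3                0.14200       0.19250      0.19250

ESS = 790.2 of n = 1000 (weights sum to the comparator n = 800)
balancing age only: ESS = 906.7 (fewer constraints, less weight spread)
```

Entropy balancing moves every A-arm moment exactly onto the published target
at the cost of ~21% effective sample size. `examples/04_monte_carlo_study.py`
then runs a small Monte Carlo study end to end and prints the bias / MCV /
MSE / coverage table per strategy plus the bias-factor adjustment.

The same pipeline is scriptable from the shell:

```sh
umaic run-study --scenario 2 --reps 200 --seed 1729 --out results/sc2
umaic simulate --arm B --seed 3 --out b.csv
umaic publish --ipd b.csv --out pub/
umaic reconstruct --pub pub/ --out recon.csv
```

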