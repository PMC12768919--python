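# Methods note

This note documents the model implemented in `labelsim`: its structure,
the default parameter values and why they were chosen, what the synthetic
population does and does not emulate, and the numerical and design choices
made where the design was genuinely open.

## Model structure

`labelsim` is a dynamic, discrete-time (annual), stochastic, open-cohort
microsimulation. One Monte Carlo *iteration* consists of:

1. **Parameter draw.** Label effects, label coverage, relative risks per
   BMI unit, and mortality-trend slopes are sampled from their declared
   uncertainty distributions (normal on the natural scale for effects and
   coverage, whose printed intervals are symmetric; log-normal for
   relative risks; coverage truncated to [0, 1]). The standard deviation is
   recovered from the 95% CI width as (hi − lo)/(2·1.96).
2. **Population generation.** A fresh synthetic cohort is drawn from an
   iteration-specific seed, so population sampling variability is inside
   the reported uncertainty intervals (a fixed-population mode exists for
   variance decomposition: `RunConfig(resample_population=False)`).
3. **Annual loop, per scenario** (all scenarios traverse identical
   individuals): add the year's 30-year-old entrants → evaluate baseline
   BMI and intake at each individual's fixed quantiles → apply the policy
   energy delta → advance the weight gap → look up the 6-year-lagged BMI
   change and scale cause-specific hazards → simulate deaths from uniforms
   shared across scenarios → censor at age 89.

Scenario contrasts (prevalence change in percentage points at 2043, deaths
prevented or postponed over 2024–2043, per-capita equity ratios) are
computed within iteration and summarised across iterations as medians with
95% uncertainty intervals (empirical 2.5/97.5 percentiles,
linear-interpolation quantile definition).

## Synthetic population

The real analysis this model family is used for rests on survey microdata
(diet and adiposity distributions), official population projections and
historical death registrations, none of which can be shipped. The
generator replaces them with parametric stand-ins that preserve the
*structure* the simulation needs:

* **Exposure distributions.** BMI and daily energy intake are lognormal
  (an LMS/Box-Cox–Cole–Green family is available as a config switch) with
  linear predictors in age (centred at 60), sex, IMD quintile (centred at
  Q3) and calendar year. Scale parameters are modelled on the log scale,
  so they are positive for every covariate combination.
* **Calibration.** Defaults were calibrated once, when the generator was
  designed, so that the 2024 cross-section shows ≈28% adult obesity with
  the observed deprivation gradient (Q1 ≈ 32.5%, Q5 ≈ 23.7% at 200k
  draws) and mean intake ≈ 2180 kcal/day (males ≈ 2360, females ≈ 2000).
  The BMI year-trend is +0.0006/yr on the log scale — a slow continuing
  rise consistent with the near-flat recent adult trend; intake drifts
  −0.001/yr.
* **Rank preservation.** Each individual carries fixed quantiles
  (u_bmi, u_intake) drawn from a Gaussian copula (default ρ = 0.25,
  implying Spearman ≈ 0.24); the same u evaluated against the drifting
  distribution gives a coherent life-course trajectory. Whether the
  original model family preserves ranks or re-samples annually is not
  documented; rank preservation was chosen because it yields
  self-consistent trajectories and makes the cross-sectional distribution
  testable by probability-integral transform.
* **Heights** are fixed over life (normal by sex, 1.618/1.757 m means,
  clipped to 1.30–2.10 m); all BMI change is carried by weight.
* **Mortality rates.** Gompertz-like by cause — at age 60 (female, Q3):
  CHD 9.0·10⁻⁴, stroke 5.0·10⁻⁴, other 5.6·10⁻³ per person-year, with
  age slopes 0.105/0.110/0.092 per year (all-cause roughly doubling every
  8 years), male multipliers 1.6/1.15/1.25, and deprivation gradients of
  −0.16/−0.12/−0.13 per quintile step toward Q5 on the log scale.
  Projection is a log-linear drift per cause (defaults −0.030, −0.025,
  −0.010 per year with ±~0.01-wide CIs), a one-parameter stand-in for a
  full stochastic mortality forecast: it captures forecast uncertainty
  without the historical death series a Lee–Carter-style fit would need.
* **Open cohort.** Entrants are new 30-year-olds at 1.96% of the initial
  stock per year (England's ratio of 30-year-olds to adults 30–89);
  individuals above 89 are censored — removed from denominators and death
  counts — since the model covers ages 30–89 only.

**What passing tests show — and do not.** The generator reproduces the
marginal structure the method consumes (distribution shapes, gradients,
trends, rate tables). It does not emulate survey weighting, household
purchase allocation, regional structure, cohort effects, or covariance
between intake and mortality beyond what BMI mediates. Results on this
population therefore validate the *machinery* (pairing, lags, dynamics,
accounting) and the qualitative policy ordering, not England-specific
point estimates.

## Policy parameters (defaults)

| parameter | value | note |
| --- | --- | --- |
| TLL consumer effect | −6.5% [−11.1; −1.9] | mandatory traffic light vs no label |
| NWL consumer effect | −12.9% [−17.9; −8.0] | nutrient warning vs no label |
| Reformulation (both) | −3.9% [−12.5; +5.0] | CI crosses zero; draws may increase energy |
| TLL coverage | +25% | mandatory adds to the 75% voluntary baseline |
| NWL coverage | 51.0% [49.0; 52.0] | share of packaged products labelled |
| At-home × packaged share | 0.55 × 0.80 | packaged in-store food = 44% of intake |
| Energy balance | k = 24 kcal/day/kg, ρ = 7700 kcal/kg | τ = ρ/k ≈ 0.88 y |
| RR per +1 kg/m² | CHD 1.40^0.2, stroke 1.30^0.2, other 1.10^0.2 | from per-5-unit conventions; log-normal sampling |
| Mortality lag | 6 years | single fixed lag, configurable |
| Iterations | 200 | default Monte Carlo size |

Sensitivity presets: NWL coverage dropping 51%→44% [42; 45] after the
first post-implementation year (the step offset is configurable — sources
differ between one and four years); Chile's octagon effect −8.3%
[−11.6; −5.0]; low TLL reformulation −0.9% (CI endpoints −3.1% and +4.9%
on the reduction scale); a Nutri-Score preset that reuses the TLL effect
structure, since meta-analytic evidence finds no measurable difference on
energy purchased.

## Design choices where the design was open

* **Effect composition.** Consumer and reformulation effects compose
  sequentially and multiplicatively on labelled energy:
  1 − (1−e_c)(1−e_r). Reported component medians are not additive to the
  combined median, which is consistent with nonlinear composition and
  median-of-distribution reporting. Component results come from separate
  scenario evaluations (consumer-only / reformulation-only / both), not
  post-hoc arithmetic.
* **Purchases = intake.** No waste or compensation adjustment; effects
  apply immediately at implementation (2024) and the relative effect stays
  constant thereafter.
* **Effects act on labelled energy only** — coverage × packaged energy —
  for both pathways; for mandatory TLL both effects apply to the
  additional 25% coverage only.
* **Exact exponential weight update.** The gap ODE is integrated in closed
  form per year, so halving the step changes nothing; iterated steps agree
  with ΔW* = ΔE/k to 0.1% after 7τ (property-tested).
* **Obesity is BMI ≥ 30** (inclusive boundary), the WHO convention.
* **Competing risks on the hazard scale.** Sum-hazard conversion
  q = 1 − exp(−Σ h_c) with proportional cause allocation guarantees cause
  probabilities sum to q (exactly conserved in the ledgers), unlike
  per-cause Bernoulli draws.
* **Common random numbers.** Person-year uniforms are keyed by (master
  seed, iteration, year) and indexed by the scenario-independent
  population layout, so pairing survives scenario order and set
  composition; per-scenario parameter draws are keyed by scenario *name*
  (CRC32) for the same reason. All derived seeds stay below 2³¹.
* **Equity metrics.** Per-capita denominators are baseline-scenario
  person-years over the horizon. Iterations with zero Q5 DPPs make the raw
  ratio infinite; the probability-equitable metric is therefore computed
  on the sign of the per-capita difference (ties weighted 0.5), and the
  median ratio over finite iterations with the degenerate count reported.
* **Outperformance** (“policy A beats B in x% of simulations”) uses strict
  exceedance of effect magnitudes; ties are excluded.

## Numerical notes

* Degenerate uncertain quantities (lo = hi) still consume one uniform so
  draw streams stay aligned whether or not a parameter is uncertain.
* Quantile evaluation caches each individual's standard-normal score, so
  the annual loop is pure vectorised arithmetic; a 50,000-person,
  three-scenario iteration takes well under a second.
* Prevalence is measured among individuals alive and aged 30–89 at the
  start of each year, before that year's deaths.
* The empty-denominator case (prevalence over no one) raises rather than
  returning 0.

## Problem sizes

Default desk scale is 50,000 simulated individuals standing for the
~35.8M English adults aged 30–89 (absolute death counts are scaled by that
factor), with 200 Monte Carlo iterations; these sizes were chosen so a
full run completes in minutes on a single core while keeping Monte Carlo
error well below the width of the reported uncertainty intervals. The test
suite uses smaller cohorts for mechanical checks and 50,000 individuals
where a check is about the calibrated population itself.

## Known limitations

* Under-30s are excluded, so total policy benefits are understated.
* Only the BMI pathway to mortality is modelled — no salt/sugar/saturated
  fat CVD pathways, and no disease incidence or morbidity states.
* The synthetic exposure gradients and rate tables are stylised; absolute
  DPP counts should be read as order-of-magnitude, not point forecasts.
  In particular the lognormal BMI density near the obesity threshold
  differs from a survey-fitted distribution, which scales the
  prevalence-change magnitude for the stronger policy.
* The mortality trend is a single log-linear drift per cause; it cannot
  reproduce age-specific forecast divergence.
* No differential policy effects by age, sex or deprivation are modelled;
  equity differences arise only through baseline exposure and mortality
  gradients.
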