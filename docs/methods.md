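# Methods

## The model

`beanphen` predicts early vegetative and reproductive development of common
bean (*Phaseolus vulgaris* L.) genotypes from marker data and daily weather.
Three trait modules share one linear "dynamic QTL-effect" predictor

```
y(t) = μ + Σᵢ b1ᵢ (Eᵢ(t) − Ēᵢ) + Σⱼ b2ⱼ QTLⱼ + Σᵢⱼ b3ᵢⱼ QTLⱼ (Eᵢ(t) − Ēᵢ) [+ E×E]
```

with environmental covariates Eᵢ ∈ {TMEAN (°C), SRAD (MJ m⁻² d⁻¹),
DL (h)}, each centered at a fixed across-site mean Ēᵢ, and marker values
QTLⱼ ∈ {−1, +1} coded Jamapa/Calima (0 for a missing call). The three
instantiations are:

* **RF(t)** — rate of progress from emergence toward first anthesis (d⁻¹),
  evaluated on single-day covariates; it is the only module with an
  environment×environment term (TMEAN×DL). Its reciprocal at the centering
  means is the mean emergence-to-flower duration, 34.5 d with the shipped
  coefficients.
* **NAR(t)** — main-stem node addition rate (nodes d⁻¹) on single-day
  covariates. Its reciprocal is the phyllochron (3.97 d node⁻¹ at the
  means).
* **MSNODmax(t)** — the maximum (final) main-stem node number, evaluated on
  covariates *averaged from planting (day 0) through the current day*, so
  it drifts slowly as the season's running means evolve.

The predictor's residual term is observation noise, not process noise: the
simulator is fully deterministic. Negative predicted rates (reachable at
extreme covariates because the responses are linear) are clamped to zero
with a logged warning; the node ceiling is floored at zero.

## Daily integration

Time is kept in integer days after planting (DAP), planting = day 0, with a
1-day step. From emergence to the end of the experiment:

1. TF(t) = TF(t−1) + RF(t); anthesis is the first day with TF ≥ 1 (no
   sub-day interpolation in reported whole-day output). A fractional
   crossing day, (t−1) + (1 − TF(t−1))/RF(t), is recorded alongside — see
   Calibration.
2. The ceiling MSNODmax(t) is re-evaluated daily on the planting→t running
   means, through the anthesis day inclusive, and frozen thereafter.
3. N(t) = N(t−1) + NAR(t), starting from 0.0 at emergence, provided the
   final node number is not yet set, yesterday's nodes were below
   yesterday's ceiling, and — for determinate genotypes — flowering had not
   occurred before today (so nodes are still added on the anthesis day
   itself). The increment is truncated at today's ceiling.
4. The final node number is set at anthesis (determinate) or when the node
   count reaches the ceiling (either habit); node addition then stops
   permanently. We chose permanent stopping over letting a later rise of
   the running-mean ceiling re-open node addition: the trait is a terminal
   event of apical development, not a reversible constraint.

Determinacy comes from the JC28 marker (+1 determinate, −1 indeterminate);
with a missing call the tied chromosome-1 markers TF2/MSN2/NAR2 (which sit
in the same recombination-suppressed region as *FIN/TFL1Y*) are consulted.

Degenerate inputs: a genotype whose RF never accumulates to 1 by the end of
the experiment is reported with `never_flowered` set rather than raising; a
run that never reaches its ceiling reports the end-of-run node count with
`n_final_censored`. Because nodes cannot be removed, a falling running-mean
ceiling can transiently sit below the already-formed node count; the
guaranteed invariant is nodes ≤ running-max of the ceiling.

A vectorized batch path (`simulate_site_batch`) reproduces the per-genotype
state machine for whole populations at once; the test suite pins the two
paths to each other at 1e-9.

## Day length

When a weather file has no DL column, day length is computed from solar
geometry (Cooper declination, sunrise-hour-angle relation) with a
configurable sun-elevation threshold: −6° (civil twilight, the common
crop-model photoperiod convention) by default, 0° (geometric) available.
TMEAN defaults to (TMAX+TMIN)/2; an explicit TMEAN column wins.

## Calibration

Coefficients are re-estimated by simulate-and-compare nonlinear least
squares: the simulator is run at candidate parameters and residuals are
formed against observations — flowering day (days after emergence) per
genotype×site, node counts per observation date, or final node numbers.
For final nodes the ceiling model is evaluated directly on covariates
averaged from planting to the day the final node number was first observed.

Numerical choices:

* Levenberg–Marquardt on the residual vector, finite-difference Jacobian
  (relative step 1e-6), ftol/xtol/gtol 1e-8, at most 200 iterations; bounds
  (if supplied) switch the solver to trust-region reflective.
* Inside the flowering objective the *fractional* TF=1 crossing is used as
  the simulated flowering day. With whole days the objective is piecewise
  constant in the parameters and gradient-based fitting stalls; the
  fractional crossing is continuous and leaves whole-day output untouched.
* Genotype×site pairs whose simulation never flowers contribute the
  end-of-experiment day as the simulated value (logged), so the objective
  stays informative instead of going flat.
* Standard errors are Gauss–Newton: s²(JᵀJ)⁻¹ at the optimum with
  s² = SSQ/(n−p) (pseudo-inverse if JᵀJ is singular).
* A fit with zero free parameters returns the initial values with the
  objective evaluated (used for objective audits).

## Synthetic data

The generator produces inputs with the structure the model assumes:

* **Weather** — TMEAN = site mean + seasonal sinusoid (one full cycle over
  the season, default amplitude 2 °C) + mean-centered AR(1) noise
  (ρ = 0.6, SD 1.5 °C); TMAX/TMIN symmetric around TMEAN (10 °C diurnal
  range); SRAD positive AR(1) around the site mean (SD = 10 % of mean);
  DL from solar geometry, shifted to match the stated site mean. The five
  default templates carry the latitudes and seasonal mean TMEAN/SRAD/DL of
  the original five field sites (Citra FL 24.61 °C; Palmira 23.94; Isabela
  24.36; Popayan 18.08; Prosper ND 20.39). The AR(1) noise is centered per
  series so generated season means sit exactly on the template.
* **Markers** — i.i.d. ±1 per locus at P(+1) = 0.5 for an RI family
  (default 187 lines), the chromosome-1 region markers tied to JC28, plus
  parental rows Calima (all +1) and Jamapa (all −1). Linkage between other
  loci is not modeled; no module consumes between-marker correlation.
* **Observations** — the simulator is run at a chosen "true" parameter set;
  Gaussian noise is added to the (fractional) flowering day, to weekly node
  counts starting 7 days after emergence (stopping once the trajectory
  reaches its final value, mimicking linear-phase phenotyping), and to the
  final node number. The synthetic final-node phenotype is the module's
  frozen ceiling observed on its freeze day, so calibration's averaging
  window coincides with the simulation's — this is what makes zero-noise
  round-trips exact. Real determinate plants can stop below the ceiling,
  which is one reason field final-node predictions are much harder than
  this round-trip.

What passing these tests shows — and does not: the synthetic world has no
heat stress, no emergence-date variation beyond the per-site constant, no
measurement-plant turnover, linear environmental responses by construction,
and phenotypes generated by the very model being fitted. Recovery results
therefore validate the estimation machinery, not field predictive skill.

## Problem sizes and tunables

Parameter-recovery studies use 40 genotypes × 3 template sites; the noisy
coverage study repeats this for 20 seeded replicates (flowering SD 1.5 d,
node SD 0.5 nodes). These match the study conditions the package is
designed around and run in well under a minute each on one core. The main
user-facing tunables are the sun-elevation threshold for derived day length
(default −6°), `tie_region` (default on), the optimizer settings in
`FitSpec`, and all generator fields of `SyntheticSiteSpec` /
`SyntheticPopulationSpec` / `ObservationNoise`.

## Known limitations

* Linear environmental responses: no cardinal-temperature or nonlinear
  photoperiod functions; extreme covariates are handled only by clamping.
* No emergence-prediction, branching, heat-stress, biomass, or yield
  processes.
* Heterozygous marker codes are not supported (treated as missing).
* The running-mean window for the node ceiling is fixed at planting→t; the
  right window for apical development is an open scientific question.
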