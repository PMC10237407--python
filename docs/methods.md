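# Methods

## Biologically effective dose

For `n` fractions of `d` Gy the biologically effective dose is

```
BED = n · d · (1 + d / (α/β))
```

Multi-phase courses sum phase BEDs; summation across different α/β values
is rejected. Two tissue constants are used throughout: **α/β = 2 Gy** for
late CNS toxicity (the isotoxicity currency of schedule design) and
**α/β = 10 Gy** for tumor effect (the covariate used in outcome models).
The reference course is 35 Gy in 10 once-daily fractions, i.e.
BED = 96.25 Gy at α/β = 2 Gy and 47.25 Gy at α/β = 10 Gy.

The inverse problem — the per-fraction dose that achieves a target BED in
`n` fractions — is the positive root of the quadratic
`n·d²/(α/β) + n·d − BED = 0`:

```
d = (α/β)/2 · (−1 + sqrt(1 + 4·BED / (n·α/β)))
```

This is exact; forward and inverse agree to 1e−9 over the tested domain.

## Schedules and constraints

A schedule is an ordered tuple of phases (fraction count, dose per
fraction, fractions per day, interfraction interval). Expansion places
fractions on consecutive weekdays starting Monday by default, skipping
weekends; the first fraction of each day is at a fixed clock time
(default 09:00) and same-day fractions follow at the interfraction
interval. A day whose last fraction would pass midnight is rejected.

Protocol constraints: at most 2 phases, at most 10 treatment weekdays in
calendar span, at most 3 fractions per day, and multi-fraction days
deliver 1.0 Gy per fraction. Candidate enumeration takes every pair
(`n1` once-daily days, `n2` thrice-daily days) with `n1 ≥ 1`,
`n1 + n2 ≤ 10`, in both phase orders, and solves the QD dose so the course
is exactly isotoxic to the reference; pairs whose TID block already meets
or exceeds the reference BED are dropped. Under the defaults this yields
exactly 100 candidates, verified against an independent closed-form count.
The uniform thrice-daily comparator (30 fractions over 10 weekdays with
the per-fraction dose relaxed to 1.72 Gy for isotoxicity) is provided as a
named schedule rather than an enumeration member, since it violates the
1.0 Gy multi-fraction dose rule.

## Tumor plasticity model

Two compartments: stem-like cells `S` (radioresistant, slowly cycling)
and differentiated cells `D` (radiosensitive, faster cycling). Between
fractions the populations follow the linear system

```
dS/dt = (ρ_S − μ) S
dD/dt = μ S + ρ_D D
```

where `μ` is slow stem-to-differentiated conversion. After each fraction
a compartment is quiescent (its ρ and μ outflow set to zero) for `τ_S`
or `τ_D` hours. The system is integrated in closed form piecewise
between quiescence expiries, including the degenerate branch where the
two exponents coincide; an independent fixed-step midpoint integrator
confirms the solution to 1e−6 relative.

Each fraction of dose `d` kills by the linear-quadratic law,
`SF = exp(−α d − β d²)`, with compartment-specific `α, β`. A fraction
delivered `Δt` hours after the previous one additionally dedifferentiates
a fraction

```
ν(Δt) = ν_max · exp(−(ln(Δt / t_peak))² / (2 · w²))
```

of the surviving differentiated cells into the stem compartment — a
log-normal-shaped window peaking at `t_peak`, zero for the first fraction
and for `Δt ≥ 24 h`. The update is
`S′ = S·SF_S + ν·D·SF_D`, `D′ = (1 − ν)·D·SF_D`; fractions never create
cells.

The simulation clock starts at the first fraction, so the predicted
outcome is exactly invariant to the clock time of day (the model carries
no circadian term). The outcome metric is **time to progression**: the
first post-treatment time at which total volume re-attains its
pre-treatment baseline, located by linear interpolation between samples
and censored at the horizon (2 years by default) if never reached.

## Parameters

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| `rho_D` | ln 2 / 504 ≈ 1.38e−3 | 1/h | differentiated doubling time 21 d, in the range of glioblastoma volume doubling times |
| `rho_S` | `rho_D` / 4 | 1/h | stem-like cells cycle substantially slower |
| `mu` | 1e−5 | 1/h | slow homeostatic differentiation out of the stem pool |
| `alpha_D`, `beta_D` | 0.1, 0.01 | 1/Gy, 1/Gy² | α/β = 10 Gy for tumor tissue |
| `alpha_S`, `beta_S` | 0.025, 0.0025 | 1/Gy, 1/Gy² | 4× radioresistance of the stem-like state at equal α/β |
| `nu_max` | 0.55 | – | peak dedifferentiation fraction (calibration, see below) |
| `t_peak` | 3.25 | h | matches the protocol interfraction interval |
| `log_width` | 0.6 | – | window spans roughly 1.5–7 h at half maximum |
| `tau_S`, `tau_D` | 96, 24 | h | long stem-cell quiescence vs. one-day differentiated arrest |
| initial state | 1e6 cells, 5% stem | – | typical stem-like minority at baseline |

**Calibration.** The radiosensitivity/conversion defaults are not fitted
to data; they are chosen so the model reproduces the qualitative behavior
the mechanism implies, and they ship only because they do: (i) the
two-phase hypofractionated + TID course outperforms the uniform TID
comparator, which outperforms the 10 × 3.5 Gy reference (247 ≥ 190 ≥ 153
days before the final `nu_max` choice; 251.5 / 188.2 / 152.8 days as
shipped); (ii) the benefit peaks at the 3.25 h interval and persists
across its ±1 h tolerance window; (iii) the 7 + 9 course ranks in the top
3 of the exhaustive search within 5% of the best design. `nu_max` was
selected from a coarse scan of {0.50–0.90} as the smallest value
satisfying (iii) while preserving (i) and (ii); the test suite asserts all
three properties, so a recalibration that breaks them fails loudly.
Absolute day counts are model outputs under this calibration, not
clinical predictions.

## Statistics

- **Non-adherence bound**: exact one-sided Clopper–Pearson upper limit,
  the `conf` quantile of Beta(failures + 1, n − failures) (1.0 when all
  fail), cross-checked against direct bisection of the binomial CDF.
  0 failures of 14 gives 19.3% ≤ the 20% feasibility bar.
- **Adherence windows**: a TID fraction is compliant within ±1 h of plan,
  a QD fraction within ±24 h; a missing fraction is non-compliant.
- **Survival**: Kaplan–Meier product-limit estimation via `lifelines`;
  the median is the earliest time with S(t) ≤ 0.5.
- **Arm comparison**: Welch two-sample t-test on per-patient ratios of
  time to progression (current / reference line), raw scale by default
  with a log-scale option.
- **Translation**: closed-form OLS of ln(HR) on the mouse benefit metric;
  prediction intervals use the t distribution with n − 2 degrees of
  freedom and the standard new-observation variance
  `s²·(1 + 1/n + (x − x̄)²/Sxx)`, exponentiated back to the HR scale.
- **Covariates**: tumor BED at α/β = 10 Gy per course; missing Karnofsky
  scores are median-imputed (midpoint convention for even counts).

## Synthetic data

Patient-level trial data and the murine translation dataset are not
public. `gliosched.synth` generates structurally faithful stand-ins:
truncated-normal administration-time jitter around a planned calendar,
exponential survival with a prescribed median and independent exponential
censoring calibrated to a target censoring fraction, benefit/HR pairs on
a known log-linear line, and log-normal parameter perturbations that
respect the model invariants by rejection sampling. Every generator is a
pure function of its arguments and seed. These data support testing and
demonstration only; no clinical conclusion should be drawn from them.

## Numerical choices

- Growth is closed-form (no ODE solver), so accuracy is limited only by
  floating point; trajectories record a pre- and post-kill sample at each
  fraction instant on top of a regular grid (6 h default).
- BED matching in enumeration uses an absolute tolerance of 1e−9 Gy.
- Jitter replicates draw uniform offsets per fraction within the
  tolerance window and enforce strict ordering by forward truncation;
  all Monte Carlo uses `numpy.random.default_rng` with explicit seeds.
- CSV round trips use 17-significant-digit formatting and round-trip
  float parsing so records survive serialization exactly.

## Limitations

- The plasticity model is deliberately minimal: no explicit cell-cycle
  redistribution, reoxygenation, immune interaction, or spatial structure;
  quiescence is all-or-none per compartment.
- The calibration is qualitative (see above); predicted times to
  progression are ordinal comparisons between schedules, not forecasts.
- The translation regression treats interventions as exchangeable and
  linear on the log-HR scale; with few training interventions the
  prediction intervals are wide and anchor-sensitive.
- Isotoxicity is enforced through BED alone; it ignores volume effects,
  cumulative prior dose distributions, and inter-patient variation.
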