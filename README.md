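# gliosched

Design and analysis toolkit for plasticity-informed radiotherapy schedules
in recurrent glioblastoma.

## The problem

Recurrent glioblastoma is routinely re-irradiated with a standard course of
35 Gy in 10 once-daily fractions. Preclinical work suggests that ionizing
radiation itself drives surviving differentiated tumor cells back into a
radioresistant, slowly cycling stem-like state, and that this
dedifferentiation is strongest a few hours after a dose. A schedule that
delivers several small fractions per day at the right interval can
deliberately catch cells in this transient window, while an initial
hypofractionated phase debulks the tumor — all without exceeding the late
CNS toxicity of the standard course.

`gliosched` implements the quantitative machinery around this idea:

- **BED arithmetic** (`gliosched.bed`): biologically effective dose for
  single- and multi-phase courses, and the inverse problem of solving a
  phase dose so a course is isotoxic to a reference (alpha/beta = 2 Gy for
  late CNS effects, 10 Gy for tumor).
- **Schedule calendars** (`gliosched.schedule`): phases, weekday expansion
  with weekend gaps, protocol constraints (≤ 2 phases, ≤ 10 weekdays,
  ≤ 3 fractions/day at 1.0 Gy), and exhaustive enumeration of the
  admissible isotoxic design space (100 candidates).
- **Tumor plasticity model** (`gliosched.plasticity`): a two-compartment
  linear-quadratic model of stem-like and differentiated cells with
  post-irradiation quiescence and an interval-dependent dedifferentiation
  window peaking at 3.25 h, integrated in closed form.
- **Schedule optimization and sensitivity** (`gliosched.optimizer`):
  exhaustive ranking by model-predicted time to progression, plus sweeps
  over the interfraction interval, start weekday, clock time, and random
  administration-time jitter.
- **Mouse-to-human translation** (`gliosched.translation`): regression of
  log hazard ratio on a murine benefit metric with t-based prediction
  intervals.
- **Feasibility-trial statistics** (`gliosched.trial`): exact one-sided
  binomial bounds on the non-adherence rate, per-fraction adherence
  assessment (TID within 1 h, QD within 24 h), Kaplan–Meier estimation,
  Welch tests on per-patient time-to-progression ratios, and covariate
  preparation (tumor BED at alpha/beta = 10 Gy, median imputation).
- **Synthetic data** (`gliosched.synth`): seeded generators for adherence
  logs, right-censored survival cohorts, translation datasets, and
  parameter perturbations — patient-level data are not public, so all
  examples and tests run on these stand-ins.
- **I/O, pipeline and CLI** (`gliosched.io`, `gliosched.cli`): JSON/CSV/
  YAML formats, an end-to-end design pipeline with reproducible reports,
  and a `gliosched` command-line tool.

## Worked example

Solving the isotoxic phase doses and comparing three courses
(`examples/01_isotoxic_doses.py`, `examples/02_simulate_course.py`):

```text
reference BED (alpha/beta = 2 Gy): 96.25 Gy
7 QD fractions + 9 x 1.0 Gy TID (BED 13.5 Gy): QD dose = 3.96 Gy
5 QD fractions + 15 x 1.0 Gy TID (BED 22.5 Gy): QD dose = 4.52 Gy
```

```text
10 x 3.50 Gy (QD)                     BED 96.25 Gy  time to progression 152.8 d  end volume 0.024
30 x 1.72 Gy (TID)                    BED 96.25 Gy  time to progression 188.2 d  end volume 0.146
7 x 3.96 Gy (QD) + 9 x 1.00 Gy (TID)  BED 96.25 Gy  time to progression 251.5 d  end volume 0.028
```

All three courses carry the same late-CNS BED; under the shipped model
calibration the two-phase course delays regrowth the longest. The
exhaustive search (`examples/03_design_search.py`) evaluates all 100
admissible designs; the 7 + 9 course ranks 2nd, within 1% of the best
(6 × 4.20 Gy + 12 × 1.00 Gy, 253.4 d), and the predicted benefit is stable
across the TID-interval tolerance window (±1 h), the start weekday, and
administration-time jitter. Further examples cover feasibility statistics,
mouse-to-human translation, and parameter-perturbation robustness.

The same analyses are available from the shell:

```sh
gliosched bed --n 10 --dose 3.5
gliosched feasibility --failures 0 --n 14
gliosched pipeline --out-dir pipeline_out --seed 0
```

## Reproduction

The headline isotoxic phase doses are reproduced by:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

which writes `{"t1": {"value": 3.96, "n": 7}, "t2": {"value": 4.52, "n": 5}}`
— the once-daily doses for the 7-fraction and 5-fraction hypofractionated
phases of the two course layouts above. The computation is closed-form and
independent of the seed.

See `docs/methods.md` for the model, its assumptions, parameter defaults
and the calibration rationale.
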