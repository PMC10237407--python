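"""File formats, configuration and the end-to-end design pipeline.

Schedules travel as JSON (phase definitions), expanded fractions and
trajectories as CSV, adherence logs and survival cohorts as CSV, and run
configuration as YAML.  :func:`run_design_pipeline` chains the stages of
the schedule-design analysis — reference BED, candidate enumeration,
exhaustive optimization, and the four sensitivity analyses — and writes
CSV/JSON reports plus a human-readable summary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Optional, Union

import pandas as pd
import yaml

from . import __version__, bed as _bed
from .optimizer import (
    DEFAULT_SIM,
    SimSettings,
    adherence_jitter,
    evaluate,
    optimize,
    sweep_interval,
    sweep_start_day,
    sweep_time_of_day,
)
from .plasticity import DEFAULT_PARAMS, PlasticityParams
from .schedule import (
    STANDARD_CONSTRAINTS,
    ConstraintSet,
    Phase,
    Schedule,
    WEEKDAY_NAMES,
    standard_schedule,
)
from .trial import AdherenceRecord, SurvivalRecord

PathLike = Union[str, Path]


class ParseError(ValueError):
    """A file did not match the expected dialect; message carries a locator."""


# ---------------------------------------------------------------------------
# schedules


def schedule_to_dict(schedule: Schedule) -> dict[str, Any]:
    return {
        "start_weekday": schedule.start_weekday,
        "daily_time": schedule.daily_time,
        "phases": [
            {
                "n": p.n_fractions,
                "dose": p.dose_per_fraction,
                "per_day": p.fractions_per_day,
                "interval_h": p.interfraction_interval,
            }
            for p in schedule.phases
        ],
    }


def schedule_from_dict(data: dict[str, Any]) -> Schedule:
    if not isinstance(data, dict) or "phases" not in data:
        raise ParseError("/: expected an object with a 'phases' array")
    phases = []
    for i, ph in enumerate(data["phases"]):
        loc = f"/phases/{i}"
        for key in ("n", "dose", "per_day"):
            if key not in ph:
                raise ParseError(f"{loc}: missing required key '{key}'")
        per_day = ph["per_day"]
        interval = ph.get("interval_h")
        if per_day > 1 and interval is None:
            raise ParseError(f"{loc}/interval_h: required when per_day > 1")
        try:
            phases.append(Phase(ph["n"], ph["dose"], per_day, interval))
        except ValueError as exc:
            raise ParseError(f"{loc}: {exc}") from exc
    try:
        return Schedule(
            phases=tuple(phases),
            start_weekday=data.get("start_weekday", 0),
            daily_time=data.get("daily_time", 9.0),
        )
    except ValueError as exc:
        raise ParseError(f"/: {exc}") from exc


def write_schedule(schedule: Schedule, path: PathLike) -> None:
    Path(path).write_text(json.dumps(schedule_to_dict(schedule), indent=2) + "\n")


def read_schedule(path: PathLike) -> Schedule:
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON ({exc})") from exc
    return schedule_from_dict(data)


def fractions_to_frame(schedule: Schedule) -> pd.DataFrame:
    """Per-fraction CSV dialect: day_index, weekday, clock_time_h, dose_gy."""
    fractions = schedule.expand()
    return pd.DataFrame(
        {
            "day_index": [f.day_index for f in fractions],
            "weekday": [WEEKDAY_NAMES[schedule.weekday_of(f)] for f in fractions],
            "clock_time_h": [f.clock_time for f in fractions],
            "dose_gy": [f.dose for f in fractions],
        }
    )


def write_fractions_csv(schedule: Schedule, path: PathLike) -> None:
    fractions_to_frame(schedule).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# trajectories, adherence logs, cohorts


def trajectory_to_frame(traj) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time_h": traj.times,
            "S": traj.S,
            "D": traj.D,
            "volume": traj.volume,
            "stem_fraction": traj.stem_fraction,
        }
    )


def write_trajectory_csv(traj, path: PathLike) -> None:
    trajectory_to_frame(traj).to_csv(path, index=False)


def write_adherence_csv(log: list[AdherenceRecord], path: PathLike) -> None:
    pd.DataFrame(
        {
            "fraction_index": range(len(log)),
            "phase_kind": [r.phase_kind for r in log],
            "planned_h": [r.planned_h for r in log],
            "actual_h": [r.actual_h for r in log],
        }
    ).to_csv(path, index=False, float_format="%.17g")


def read_adherence_csv(path: PathLike) -> list[AdherenceRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("phase_kind", "planned_h", "actual_h"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column '{col}'")
    return [
        AdherenceRecord(
            planned_h=float(row.planned_h),
            actual_h=None if pd.isna(row.actual_h) else float(row.actual_h),
            phase_kind=str(row.phase_kind),
        )
        for row in df.itertuples()
    ]


def write_survival_csv(records: list[SurvivalRecord], path: PathLike) -> None:
    pd.DataFrame(
        {
            "id": range(len(records)),
            "time_months": [r.time for r in records],
            "event": [int(r.event) for r in records],
        }
    ).to_csv(path, index=False, float_format="%.17g")


def read_survival_csv(path: PathLike) -> list[SurvivalRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("time_months", "event"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column '{col}'")
    return [
        SurvivalRecord(time=float(r.time_months), event=bool(r.event))
        for r in df.itertuples()
    ]


def read_benefit_csv(path: PathLike):
    from .translation import BenefitRecord

    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("intervention_id", "mouse_benefit", "human_hr"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column '{col}'")
    return [
        BenefitRecord(str(r.intervention_id), float(r.mouse_benefit), float(r.human_hr))
        for r in df.itertuples()
    ]


def write_benefit_csv(records, path: PathLike) -> None:
    pd.DataFrame(
        {
            "intervention_id": [r.intervention_id for r in records],
            "mouse_benefit": [r.mouse_benefit for r in records],
            "human_hr": [r.human_hr for r in records],
        }
    ).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# configuration and parameters


def params_from_mapping(data: dict[str, Any]) -> PlasticityParams:
    known = {f.name for f in dataclasses.fields(PlasticityParams)}
    unknown = set(data) - known
    if unknown:
        raise ParseError(f"unknown plasticity parameter(s): {sorted(unknown)}")
    return dataclasses.replace(DEFAULT_PARAMS, **data)


def read_params(path: PathLike) -> PlasticityParams:
    """Read a PlasticityParams override file (YAML or JSON mapping)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ParseError(f"{path}: expected a mapping of parameter names to values")
    return params_from_mapping(data)


@dataclass
class RunConfig:
    """Configuration of the end-to-end design pipeline."""

    out_dir: Path
    seed: int = 0
    tid_interval: float = 3.25
    interval_grid: tuple[float, ...] = (2.25, 2.75, 3.25, 3.75, 4.25)
    time_of_day_grid: tuple[float, ...] = (8.0, 9.0, 10.0, 11.0)
    jitter_reps: int = 50
    constraints: ConstraintSet = STANDARD_CONSTRAINTS
    params: PlasticityParams = DEFAULT_PARAMS
    sim: SimSettings = DEFAULT_SIM

    @classmethod
    def from_yaml(cls, path: PathLike, out_dir: Optional[PathLike] = None) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ParseError(f"{path}: expected a mapping")
        kwargs: dict[str, Any] = {}
        if out_dir is not None:
            kwargs["out_dir"] = Path(out_dir)
        elif "out_dir" in data:
            kwargs["out_dir"] = Path(data["out_dir"])
        else:
            raise ParseError(f"{path}: 'out_dir' is required")
        for key in ("seed", "tid_interval", "jitter_reps"):
            if key in data:
                kwargs[key] = data[key]
        for key in ("interval_grid", "time_of_day_grid"):
            if key in data:
                kwargs[key] = tuple(data[key])
        if "constraints" in data:
            kwargs["constraints"] = ConstraintSet(**data["constraints"])
        if "params" in data:
            kwargs["params"] = params_from_mapping(data["params"])
        if "sim" in data:
            kwargs["sim"] = SimSettings(**data["sim"])
        return cls(**kwargs)


def _provenance(config: RunConfig) -> dict[str, Any]:
    blob = json.dumps(
        {
            "seed": config.seed,
            "tid_interval": config.tid_interval,
            "constraints": dataclasses.asdict(config.constraints),
            "params": dataclasses.asdict(config.params),
            "sim": dataclasses.asdict(config.sim),
        },
        sort_keys=True,
    )
    return {
        "package_version": __version__,
        "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:16],
        "seed": config.seed,
    }


def run_design_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run the full schedule-design analysis and write its reports.

    Stages: reference BED -> candidate enumeration -> exhaustive
    optimization -> interval / start-day / time-of-day / jitter sensitivity
    analyses.  Returns the report bundle (also written to ``out_dir`` as
    JSON/CSV plus a plain-text summary).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    provenance = _provenance(config)

    stage = "reference_bed"
    try:
        ref = _bed.reference_bed("standard_reirradiation", config.sim.alpha_beta)

        stage = "optimization"
        ranking = optimize(
            constraints=config.constraints,
            params=config.params,
            tid_interval=config.tid_interval,
            reference_bed=ref,
            sim=config.sim,
        )
        ranking_df = pd.DataFrame(
            {
                "rank": range(1, len(ranking) + 1),
                "design": [r.schedule.label() for r in ranking],
                "metric_h": [r.metric for r in ranking],
                "censored": [r.censored for r in ranking],
                "end_volume": [r.end_volume for r in ranking],
                "end_stem_fraction": [r.end_stem_fraction for r in ranking],
                "total_bed_gy": [r.total_bed for r in ranking],
            }
        )
        top = ranking[0]
        best_schedule = top.schedule

        stage = "baseline_evaluation"
        std_metric = evaluate(
            standard_schedule(start_weekday=config.constraints.start_weekday),
            config.params,
            config.sim,
        ).metric

        stage = "sweep_interval"
        interval = sweep_interval(best_schedule, config.params, config.interval_grid, config.sim)

        stage = "sweep_start_day"
        start_day = sweep_start_day(best_schedule, config.params, config.sim)

        stage = "sweep_time_of_day"
        time_of_day = sweep_time_of_day(
            best_schedule, config.params, config.time_of_day_grid, config.sim
        )

        stage = "adherence_jitter"
        jitter = adherence_jitter(
            best_schedule,
            config.params,
            tid_window=1.0,
            qd_window=24.0,
            n_rep=config.jitter_reps,
            seed=config.seed,
            sim=config.sim,
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    report = {
        "provenance": provenance,
        "reference_bed_gy": ref,
        "standard_schedule_metric_h": std_metric,
        "top_design": {
            "label": best_schedule.label(),
            "schedule": schedule_to_dict(best_schedule),
            "metric_h": top.metric,
            "end_volume": top.end_volume,
            "end_stem_fraction": top.end_stem_fraction,
            "total_bed_gy": top.total_bed,
        },
        "n_candidates": len(ranking),
        "sweeps": {
            "interval": [{"delta_t_h": d, "metric_h": m} for d, m in interval],
            "start_day": [
                {"weekday": WEEKDAY_NAMES[w], "metric_h": m} for w, m in start_day
            ],
            "time_of_day": [{"daily_time_h": t, "metric_h": m} for t, m in time_of_day],
            "jitter": dataclasses.asdict(jitter),
        },
    }

    ranking_df.to_csv(out_dir / "ranking.csv", index=False)
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    summary = [
        f"# gliosched design pipeline (version {provenance['package_version']}, "
        f"config {provenance['config_hash']}, seed {provenance['seed']})",
        f"Reference BED (alpha/beta = {config.sim.alpha_beta} Gy): {ref:.2f} Gy",
        f"Candidates evaluated: {len(ranking)}",
        f"Top schedule: {best_schedule.label()}",
        f"  predicted time to progression: {top.metric / 24.0:.1f} days "
        f"(standard schedule: {std_metric / 24.0:.1f} days)",
    ]
    (out_dir / "summary.txt").write_text("\n".join(summary) + "\n")
    return report
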