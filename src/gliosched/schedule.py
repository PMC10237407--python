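"""Fractionation-schedule data model, calendar expansion and enumeration.

A :class:`Schedule` is an ordered list of up to two :class:`Phase` objects
(e.g. a once-daily hypofractionated phase followed by a three-times-daily
phase), a start weekday and a daily start time.  Expansion turns phases into
concrete :class:`Fraction` objects with calendar-day indices and clock
times, skipping weekends.  :func:`enumerate_candidates` builds the full
discrete space of isotoxic two-phase designs: the multi-fraction (TID) dose
is pinned at 1.0 Gy and the once-daily dose is solved so that the total BED
at alpha/beta = 2 Gy equals a reference regimen's BED.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator, Optional, Sequence

from . import bed as _bed

WEEKDAY_NAMES = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")

#: Tolerance on BED matching for enumerated candidates.
BED_MATCH_TOL = 1e-9


class InvalidScheduleError(ValueError):
    """A schedule that cannot be expanded to a legal calendar."""


class ConstraintError(ValueError):
    """A structural violation of the active constraint set."""


@dataclass(frozen=True)
class Fraction:
    """One radiation administration.

    ``day_index`` counts calendar days since the course start (day 0 is the
    start day, weekends included in the count even though no fraction lands
    on them); ``clock_time`` is in decimal hours, ``dose`` in Gy.
    """

    day_index: int
    clock_time: float
    dose: float

    def __post_init__(self) -> None:
        if self.day_index < 0:
            raise InvalidScheduleError(f"negative day index {self.day_index}")
        if not 0.0 <= self.clock_time < 24.0:
            raise InvalidScheduleError(f"clock time {self.clock_time} outside [0, 24)")
        if self.dose < 0:
            raise InvalidScheduleError(f"negative dose {self.dose}")

    @property
    def abs_time_h(self) -> float:
        """Absolute time in hours since midnight of day 0."""
        return self.day_index * 24.0 + self.clock_time


@dataclass(frozen=True)
class Phase:
    """A uniform block of fractions: count, dose, fractions/day, interval."""

    n_fractions: int
    dose_per_fraction: float
    fractions_per_day: int = 1
    interfraction_interval: Optional[float] = None  # hours, multi-fraction days

    def __post_init__(self) -> None:
        if self.n_fractions < 1:
            raise InvalidScheduleError("phase must contain at least one fraction")
        if self.dose_per_fraction <= 0:
            raise InvalidScheduleError("dose per fraction must be positive")
        if self.fractions_per_day not in (1, 2, 3):
            raise InvalidScheduleError(
                f"fractions per day must be 1, 2 or 3, got {self.fractions_per_day}"
            )
        if self.fractions_per_day > 1:
            if self.interfraction_interval is None or self.interfraction_interval <= 0:
                raise InvalidScheduleError(
                    "multi-fraction phases require a positive interfraction interval"
                )


@dataclass(frozen=True)
class ConstraintSet:
    """The admissibility rules a schedule must satisfy."""

    max_fractions_per_day: int = 3
    max_weekdays: int = 10
    max_phases: int = 2
    multi_fraction_dose: Optional[float] = 1.0  # Gy; None disables the rule
    allow_weekends: bool = False
    start_weekday: int = 0  # 0 = Monday

    def __post_init__(self) -> None:
        if self.max_fractions_per_day < 1 or self.max_weekdays < 1 or self.max_phases < 1:
            raise ConstraintError("constraint counts must be >= 1")
        if self.multi_fraction_dose is not None and self.multi_fraction_dose <= 0:
            raise ConstraintError("multi-fraction dose must be positive")
        if not 0 <= self.start_weekday <= 6:
            raise ConstraintError("start weekday must be in 0..6")


#: The standard constraint set: <=3 fractions/day, 10 weekdays, <=2 phases,
#: 1.0 Gy on multi-fraction days, weekdays only, Monday start.
STANDARD_CONSTRAINTS = ConstraintSet()


@dataclass(frozen=True)
class Violation:
    """One failed constraint; violations are data, not exceptions."""

    constraint: str
    detail: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.constraint}: {self.detail}"


@dataclass(frozen=True)
class Schedule:
    """An ordered list of phases plus calendar placement."""

    phases: tuple[Phase, ...]
    start_weekday: int = 0
    daily_time: float = 9.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "phases", tuple(self.phases))
        if not self.phases:
            raise InvalidScheduleError("schedule must contain at least one phase")
        if not 0 <= self.start_weekday <= 6:
            raise InvalidScheduleError("start weekday must be in 0..6")
        if not 0.0 <= self.daily_time < 24.0:
            raise InvalidScheduleError("daily time must be in [0, 24)")

    def expand(self, skip_weekends: bool = True) -> list[Fraction]:
        return expand_schedule(self.phases, self.start_weekday, self.daily_time, skip_weekends)

    def weekday_of(self, fraction: Fraction) -> int:
        return (self.start_weekday + fraction.day_index) % 7

    def bed_specs(self, alpha_beta: float = _bed.ALPHA_BETA_CNS) -> list[_bed.BEDSpec]:
        return [
            _bed.BEDSpec(p.n_fractions, p.dose_per_fraction, alpha_beta) for p in self.phases
        ]

    def total_bed(self, alpha_beta: float = _bed.ALPHA_BETA_CNS) -> float:
        return _bed.bed_total(self.bed_specs(alpha_beta))

    def total_dose(self) -> float:
        return sum(p.n_fractions * p.dose_per_fraction for p in self.phases)

    def n_fractions(self) -> int:
        return sum(p.n_fractions for p in self.phases)

    def label(self) -> str:
        """Human-readable 'n x d Gy' description, e.g. '7 x 3.96 Gy (QD) + 9 x 1.00 Gy (TID)'."""
        kind = {1: "QD", 2: "BID", 3: "TID"}
        parts = [
            f"{p.n_fractions} x {p.dose_per_fraction:.2f} Gy ({kind[p.fractions_per_day]})"
            for p in self.phases
        ]
        return " + ".join(parts)

    def with_tid_interval(self, interval_h: float) -> "Schedule":
        """Copy of this schedule with every multi-fraction phase re-timed."""
        new_phases = tuple(
            replace(p, interfraction_interval=interval_h) if p.fractions_per_day > 1 else p
            for p in self.phases
        )
        return replace(self, phases=new_phases)


def expand_schedule(
    phases: Sequence[Phase],
    start_weekday: int = 0,
    daily_time: float = 9.0,
    skip_weekends: bool = True,
) -> list[Fraction]:
    """Expand phases into chronologically ordered fractions.

    Phases occupy consecutive delivery days; weekend calendar days are
    skipped when ``skip_weekends`` is set.  On a multi-fraction day the
    fractions sit at ``daily_time + k * interval`` for k = 0, 1, ...; a day
    whose last fraction would spill past midnight raises
    :class:`InvalidScheduleError`.
    """
    if not phases:
        raise InvalidScheduleError("empty phase list")
    fractions: list[Fraction] = []
    day = 0
    for phase in phases:
        remaining = phase.n_fractions
        interval = phase.interfraction_interval or 0.0
        while remaining > 0:
            if skip_weekends:
                while (start_weekday + day) % 7 >= 5:
                    day += 1
            k_today = min(phase.fractions_per_day, remaining)
            last_time = daily_time + (k_today - 1) * interval
            if last_time >= 24.0:
                raise InvalidScheduleError(
                    f"day {day}: fraction at {last_time:.2f} h spills past midnight"
                )
            for k in range(k_today):
                fractions.append(
                    Fraction(day, daily_time + k * interval, phase.dose_per_fraction)
                )
            remaining -= k_today
            day += 1
    return fractions


def _weekday_span(fractions: Sequence[Fraction], start_weekday: int) -> int:
    """Number of weekdays from the first to the last fraction day, inclusive."""
    first = min(f.day_index for f in fractions)
    last = max(f.day_index for f in fractions)
    return sum(1 for d in range(first, last + 1) if (start_weekday + d) % 7 < 5)


def validate_schedule(
    schedule: Schedule, constraints: ConstraintSet = STANDARD_CONSTRAINTS
) -> list[Violation]:
    """Check a schedule against a constraint set; empty list iff admissible."""
    violations: list[Violation] = []
    if len(schedule.phases) > constraints.max_phases:
        violations.append(
            Violation("max_phases", f"{len(schedule.phases)} phases > {constraints.max_phases}")
        )
    try:
        fractions = schedule.expand(skip_weekends=not constraints.allow_weekends)
    except InvalidScheduleError as exc:
        violations.append(Violation("expansion", str(exc)))
        return violations

    # unique, strictly increasing absolute times
    times = [f.abs_time_h for f in fractions]
    for a, b in zip(times, times[1:]):
        if b <= a:
            violations.append(
                Violation("ordering", f"fraction times not strictly increasing at {b} h")
            )
            break

    per_day: dict[int, list[Fraction]] = {}
    for f in fractions:
        per_day.setdefault(f.day_index, []).append(f)
    for day, fx in sorted(per_day.items()):
        if len(fx) > constraints.max_fractions_per_day:
            violations.append(
                Violation(
                    "max_fractions_per_day",
                    f"day {day} has {len(fx)} fractions > {constraints.max_fractions_per_day}",
                )
            )
        if len(fx) > 1 and constraints.multi_fraction_dose is not None:
            for f in fx:
                if abs(f.dose - constraints.multi_fraction_dose) > 1e-12:
                    violations.append(
                        Violation(
                            "multi_fraction_dose",
                            f"day {day} delivers {f.dose} Gy on a multi-fraction day "
                            f"(must be {constraints.multi_fraction_dose} Gy)",
                        )
                    )
                    break
        if not constraints.allow_weekends and (schedule.start_weekday + day) % 7 >= 5:
            violations.append(
                Violation("weekend", f"day {day} falls on a weekend")
            )

    span = _weekday_span(fractions, schedule.start_weekday)
    if span > constraints.max_weekdays:
        violations.append(
            Violation("span", f"schedule spans {span} weekdays > {constraints.max_weekdays}")
        )
    return violations


def trial_schedule(tid_interval: float = 3.25, start_weekday: int = 0, daily_time: float = 9.0) -> Schedule:
    """The clinically evaluated course: 7 x 3.96 Gy (QD) then 9 x 1.0 Gy (TID).

    The QD dose is re-solved at full precision so the total BED at
    alpha/beta = 2 Gy matches the 35 Gy / 10 fx reference exactly (the
    printed 3.96 is that solution rounded to 2 decimals).
    """
    ref = _bed.reference_bed("standard_reirradiation", _bed.ALPHA_BETA_CNS)
    residual = ref - _bed.bed_single(9, 1.0, _bed.ALPHA_BETA_CNS)
    d_qd = _bed.solve_dose_per_fraction(7, residual, _bed.ALPHA_BETA_CNS)
    return Schedule(
        phases=(
            Phase(7, d_qd, 1),
            Phase(9, 1.0, 3, tid_interval),
        ),
        start_weekday=start_weekday,
        daily_time=daily_time,
    )


def standard_schedule(start_weekday: int = 0, daily_time: float = 9.0) -> Schedule:
    """The reference re-irradiation course: 35 Gy in 10 daily fractions."""
    return Schedule(phases=(Phase(10, 3.5, 1),), start_weekday=start_weekday, daily_time=daily_time)


def tid_uniform_schedule(
    n_days: int = 10,
    tid_interval: float = 3.25,
    reference: float | None = None,
    alpha_beta: float = _bed.ALPHA_BETA_CNS,
    start_weekday: int = 0,
    daily_time: float = 9.0,
) -> Schedule:
    """A uniform three-times-daily course with the dose relaxed to match BED.

    With 10 weekdays this reproduces the ~51.6 Gy / 30 fx comparator: the
    1.0 Gy multi-fraction-day rule is relaxed and the common dose per
    fraction is solved so the course is isotoxic with the reference.
    """
    if reference is None:
        reference = _bed.reference_bed("standard_reirradiation", alpha_beta)
    n = 3 * n_days
    d = _bed.solve_dose_per_fraction(n, reference, alpha_beta)
    return Schedule(
        phases=(Phase(n, d, 3, tid_interval),),
        start_weekday=start_weekday,
        daily_time=daily_time,
    )


def enumerate_candidates(
    constraints: ConstraintSet = STANDARD_CONSTRAINTS,
    tid_interval: float = 3.25,
    reference_bed: float | None = None,
    alpha_beta: float = _bed.ALPHA_BETA_CNS,
    daily_time: float = 9.0,
) -> list[Schedule]:
    """All isotoxic one- and two-phase designs on the discrete weekday grid.

    The space is {QD days n1 in 0..W} x {TID days n2 in 0..W-n1} x
    {QD-first, TID-first}, with W = ``constraints.max_weekdays``.  TID days
    carry exactly ``constraints.max_fractions_per_day`` fractions of the
    fixed multi-fraction dose; the QD dose is solved so the total BED equals
    ``reference_bed``.  Designs with a non-positive residual BED (including
    every pure-TID design here, whose fixed-dose BED cannot reach the
    reference) or a non-positive solved dose are omitted.
    """
    if alpha_beta <= 0:
        raise _bed.BEDError("alpha/beta must be positive")
    if reference_bed is None:
        reference_bed = _bed.reference_bed("standard_reirradiation", alpha_beta)
    if reference_bed <= 0:
        raise _bed.BEDError("reference BED must be positive")
    tid_dose = constraints.multi_fraction_dose
    if tid_dose is None:
        raise ConstraintError("enumeration requires a fixed multi-fraction dose")
    per_day = constraints.max_fractions_per_day
    W = constraints.max_weekdays

    candidates: list[Schedule] = []
    for n1 in range(0, W + 1):
        for n2 in range(0, W - n1 + 1):
            if n1 == 0 and n2 == 0:
                continue
            if n1 > 0 and n2 > 0 and constraints.max_phases < 2:
                continue
            n_tid = per_day * n2
            tid_bed = _bed.bed_single(n_tid, tid_dose, alpha_beta) if n_tid else 0.0
            residual = reference_bed - tid_bed
            if n1 == 0:
                # no QD dose to solve: admissible only if already isotoxic
                if abs(residual) > BED_MATCH_TOL:
                    continue
                phases_list = [(Phase(n_tid, tid_dose, per_day, tid_interval),)]
            else:
                if residual <= 0:
                    continue
                d_qd = _bed.solve_dose_per_fraction(n1, residual, alpha_beta)
                if d_qd <= 0:
                    continue
                qd = Phase(n1, d_qd, 1)
                if n2 == 0:
                    phases_list = [(qd,)]
                else:
                    tid = Phase(n_tid, tid_dose, per_day, tid_interval)
                    phases_list = [(qd, tid), (tid, qd)]
            for phases in phases_list:
                candidates.append(
                    Schedule(
                        phases=phases,
                        start_weekday=constraints.start_weekday,
                        daily_time=daily_time,
                    )
                )
    return candidates


def per_day_counts(fractions: Sequence[Fraction]) -> dict[int, int]:
    """Number of fractions delivered on each calendar day."""
    counts: dict[int, int] = {}
    for f in fractions:
        counts[f.day_index] = counts.get(f.day_index, 0) + 1
    return counts


def iter_phase_days(schedule: Schedule, skip_weekends: bool = True) -> Iterator[tuple[int, int]]:
    """Yield (phase_index, day_index) pairs in delivery order."""
    day_phase: list[tuple[int, int]] = []
    day = 0
    for pi, phase in enumerate(schedule.phases):
        remaining = phase.n_fractions
        while remaining > 0:
            if skip_weekends:
                while (schedule.start_weekday + day) % 7 >= 5:
                    day += 1
            day_phase.append((pi, day))
            remaining -= min(phase.fractions_per_day, remaining)
            day += 1
    yield from day_phase
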