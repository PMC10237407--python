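"""Exhaustive search over all admissible isotoxic schedules.

Constraints: at most 2 phases, 10 weekdays, 3 fractions/day (1.0 Gy when
multiple per day), all courses matched to the reference BED of 96.25 Gy at
alpha/beta = 2 Gy.  The sensitivity sweeps probe the TID interfraction
interval and the start weekday of the top design.
"""

from gliosched.optimizer import optimize, sweep_interval, sweep_start_day
from gliosched.schedule import WEEKDAY_NAMES

ranking = optimize()
print(f"{len(ranking)} candidates evaluated; top 5:")
for rank, res in enumerate(ranking[:5], start=1):
    print(f"  {rank}. {res.schedule.label():45s} {res.metric_days():6.1f} d")

best = ranking[0].schedule
print("\nTID interval sweep of the top design:")
for dt, m in sweep_interval(best, grid=[1.0, 2.25, 3.25, 4.25, 6.0]):
    print(f"  {dt:5.2f} h  {'invalid' if m is None else f'{m / 24.0:6.1f} d'}")

print("\nstart-day sweep of the top design:")
for wd, m in sweep_start_day(best):
    print(f"  {WEEKDAY_NAMES[wd]}  {m / 24.0:6.1f} d")
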