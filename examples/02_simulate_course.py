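"""Simulate tumor response to three isotoxic courses.

The two-compartment plasticity model (radioresistant stem-like cells,
radiosensitive differentiated cells, interval-dependent dedifferentiation)
predicts the time until the tumor regrows to its pre-treatment volume.
"""

from gliosched import standard_schedule, tid_uniform_schedule, trial_schedule
from gliosched.optimizer import evaluate

for schedule in (standard_schedule(), tid_uniform_schedule(), trial_schedule()):
    res = evaluate(schedule)
    print(
        f"{schedule.label():45s} BED {res.total_bed:6.2f} Gy  "
        f"time to progression {res.metric_days():6.1f} d  "
        f"end volume {res.end_volume:.3f}  "
        f"end stem fraction {res.end_stem_fraction:.3f}"
    )
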