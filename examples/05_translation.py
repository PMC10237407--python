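"""Mouse-to-human benefit translation.

Interventions with a known survival benefit in a murine glioma model and a
known patient hazard ratio define a regression of log hazard ratio on the
mouse benefit metric; a new intervention's mouse benefit then yields a
predicted patient hazard ratio with a prediction interval.
"""

from gliosched.synth import gen_translation_records
from gliosched.translation import fit_translation, predict_hr

records = gen_translation_records(12, intercept=0.2, slope=-0.5, noise_sd=0.05, seed=0)
fit = fit_translation(records)
print(
    f"fit on {fit.n_obs} interventions: ln(HR) = {fit.intercept:.3f} "
    f"{fit.slope:+.3f} x benefit (residual sd {fit.residual_sd:.3f})"
)

for benefit in (1.0, 1.5, 2.0):
    pred = predict_hr(fit, benefit)
    print(
        f"mouse benefit {benefit:.1f}: predicted HR {pred.hr:.2f} "
        f"({pred.level:.0%} PI {pred.lower:.2f}-{pred.upper:.2f})"
    )
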