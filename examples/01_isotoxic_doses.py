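"""Isotoxic dose arithmetic for two-phase re-irradiation courses.

The reference course is 35 Gy in 10 once-daily fractions.  At the CNS
late-toxicity alpha/beta of 2 Gy its biologically effective dose (BED) is
96.25 Gy.  For a two-phase course that ends with a block of 1.0 Gy
thrice-daily (TID) fractions, the once-daily (QD) phase dose is solved so
the summed BED matches the reference exactly.
"""

from gliosched.bed import bed_single, reference_bed, solve_dose_per_fraction

ref = reference_bed("standard_reirradiation", 2.0)
print(f"reference BED (alpha/beta = 2 Gy): {ref:.2f} Gy")

for n_qd, n_tid in [(7, 9), (5, 15)]:
    tid_bed = bed_single(n_tid, 1.0, 2.0)
    dose = solve_dose_per_fraction(n_qd, ref - tid_bed, 2.0)
    print(
        f"{n_qd} QD fractions + {n_tid} x 1.0 Gy TID "
        f"(BED {tid_bed:.1f} Gy): QD dose = {dose:.2f} Gy"
    )
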