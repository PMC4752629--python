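"""Classify nodules and run the volumetric care pathway on serial scans.

Three archetypal subjects: a large baseline nodule (immediate MDT
referral), an intermediate nodule growing with VDT < 400 days (growth
referral at the 3-month scan), and a stable small nodule (12-month repeat
then discharge).
"""

from lungscreen.pathway import (
    NoduleMeasurement,
    compute_vdt,
    run_pathway,
)

subjects = {
    "large_baseline": [
        NoduleMeasurement("large_baseline", "n0", 0.0, volume=650.0),
    ],
    "growing_cat3": [
        NoduleMeasurement("growing_cat3", "n0", 0.0, volume=120.0),
        NoduleMeasurement("growing_cat3", "n0", 91.0, volume=120.0 * 2 ** (91 / 250)),
        NoduleMeasurement("growing_cat3", "n0", 365.0, volume=120.0 * 2 ** (365 / 250)),
    ],
    "stable_cat2": [
        NoduleMeasurement("stable_cat2", "n0", 0.0, volume=40.0),
        NoduleMeasurement("stable_cat2", "n0", 365.0, volume=41.0),
    ],
}

for name, measurements in subjects.items():
    print(f"--- {name}")
    for d in run_pathway(measurements):
        print(f"  day {d.timepoint:>5.0f}  {d.action:<20s} ({d.reason}) {d.note}")

v1, v2 = 120.0, 120.0 * 2 ** (91 / 250)
print()
print(f"VDT of the growing nodule over 91 days: {compute_vdt(v1, v2, 91.0):.0f} days")
print("(< 400 days, hence the multidisciplinary-team referral at month 3)")
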