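"""Recompute the pilot trial's outcome rates from the bundled reference tables.

Expands the packaged per-category counts and the 42 cancer case records
into 1994 per-subject records, then recomputes every published rate
(detection, false-positive, interval-imaging, stage and resection
fractions) from those records rather than from the pre-aggregated numbers.
"""

from lungscreen.fixtures import evaluate_fixtures

df = evaluate_fixtures()
print(df.to_string(index=False))
print()
print(
    "Each row is a screening outcome rate in percent: 'computed' is derived\n"
    "from per-subject records, 'expected' is the published figure; an exact\n"
    "match means the statistics layer reproduces the trial's arithmetic."
)
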