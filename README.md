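# lungscreen

A Python library for simulating and evaluating a **risk-stratified,
single-screen low-dose CT (LDCT) lung-cancer screening trial**: who is
invited, how screen-detected pulmonary nodules are managed by volumetry,
what the trial-level outcome statistics are, and whether the screen is
cost-effective.

It is aimed at screening methodologists and health economists who want a
transparent, fully seeded re-implementation of the computational machinery
behind a UK single-screen LDCT pilot (1994 subjects screened, 42 cancers
detected), exercised both on bundled transcriptions of the trial's summary
tables and on a calibrated synthetic cohort generator.

## What it implements

**Eligibility** — a Liverpool-Lung-Project-style risk model: a logistic
linear predictor over smoking duration, respiratory disease history,
asbestos exposure, prior malignancy and family history gives a relative
risk `RR = exp(lp − intercept)`, converted to 5-year absolute risk with
age/sex incidence `h(a, s)` treated as a hazard,

```
risk_5yr = 1 − exp( − Σ_{t=0..4} h(age+t, sex) · RR / mean_RR )
```

with screening eligibility at `risk_5yr ≥ 5%`. (The published model's
coefficients are not reproduced; an illustrative default configuration with
the same structure is shipped.)

**Nodule management** — the four-category volumetric protocol. With volume
primary and maximum diameter the fallback: category 1 ≤ 15 mm³ (≤ 3 mm),
category 2 ≤ 50 mm³ (≤ 5 mm, 12-month repeat CT), category 3 ≤ 500 mm³
(≤ 10 mm, 3- and 12-month repeat CT), category 4 above that (immediate
multidisciplinary-team referral). Growth between scans is assessed by
volume doubling time,

```
VDT = Δt · ln 2 / ln(V₂/V₁),
```

with referral when `VDT < 400` days.

**Outcome statistics** — the trial's bespoke definitions: detection rate,
false-positive rate `(MDT referrals − cancers)/screened`, interval-imaging
rate `(category-3 subjects − their cancers)/screened`, stage I / I–II
fractions, surgical and benign resection rates.

**Cost-effectiveness** — a stage-shift life-table model: screening moves
the stage distribution at diagnosis; stage-specific 5-year survival,
background life-table mortality, utility weights and 3.5%/year discounting
convert the shift into QALYs per person screened, scaled so the implied
5-year cancer-mortality reduction matches a 20% anchor from randomised CT
screening. The ICER is incremental cost over incremental QALYs with a
seeded percentile-bootstrap CI.

**Synthetic cohorts** — a seeded generator whose risk-factor marginals,
largest-nodule log-normal volume distribution, malignancy-vs-volume
logistic and VDT distributions are calibrated so a simulated screen
reproduces the pilot's category mix (~49/24/24/3%) and ~2.1% detection.

## Worked example

```
$ python examples/05_cost_effectiveness.py
anchor weight (fraction of full stage-shift benefit): 0.563
QALYs gained per person screened: 0.0340
incremental cost per person:      GBP 272
ICER: GBP 7,995 per QALY  (bootstrap 95% CI 7,365 to 12,104)
in USD at 1.544: 12,344 per QALY
```

Reading: a single screen costs £272 per person (£212 screening and workup
plus £60 net treatment). Detecting 2.1% of subjects at mostly stage I
instead of late stage yields 0.034 discounted QALYs per person screened
once the stage-shift benefit is anchored to a 20% mortality reduction, so
screening buys a QALY for roughly £8,000 — comfortably below usual UK
willingness-to-pay thresholds. The other examples cover the fixture-based
outcome rates (`01`), the care pathway on serial scans (`02`), risk scoring
and the 5% gate (`03`) and a full synthetic screening round (`04`).

A thin CLI mirrors the library: `lungscreen evaluate-fixtures`,
`lungscreen simulate --config cfg.yaml`, `lungscreen pathway`,
`lungscreen risk`, `lungscreen econ`.

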