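# Methods

This note documents the models behind `lungscreen`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## The system being modelled

A single-screen LDCT lung-cancer screening trial in a high-risk UK
population: postal questionnaires identify candidates, a risk model gates
eligibility at a 5-year absolute risk of ≥ 5%, consenting subjects are
randomised 1:1 to a screening or control arm, the screened arm receives a
baseline volumetric CT, and detected nodules are managed by a pre-specified
category protocol with 3- and 12-month follow-up scans, volume-doubling-time
(VDT) growth assessment and multidisciplinary-team (MDT) referral.
The reference dataset bundled as package fixtures summarises such a pilot:
1994 subjects screened, nodule categories 979/479/472/64, 114 MDT
referrals, 42 cancers (34 within the baseline round, 8 at 12 months),
35 cancer resections and 4 benign resections.

## Risk model

Structure: logistic linear predictor over categorical risk factors
(smoking-duration band 0 / 1–20 / 21–40 / 41+ years, respiratory disease
history, asbestos exposure, prior malignancy, family history none / early
(< 60 y) / late). Relative risk `RR = exp(lp − intercept)` scales age/sex
annual incidence (as a hazard), normalised by a population-mean relative
risk `mean_RR`, accumulated over five years and complemented:
`risk = 1 − exp(−Σ h·RR/mean_RR)`. This is the conventional construction
for converting a case–control logistic model into absolute risk.

Decisions:

* **Coefficients are config inputs.** The published model's values are
  not public in the source material; the shipped defaults are labelled
  illustrative and chosen only to be epidemiologically plausible (log odds
  ratios 0.35–2.3, strongest for long smoking duration).
* **Incidence and life tables are synthetic defaults** (5-year bands
  rising from 60 to 650 per 100 000 for men, 0.75× for women; Gompertz
  mortality doubling every 8 years anchored at q₆₇ = 0.015 for men).
  Both are ordinary CSV inputs and can be replaced by registry tables.
* **Competing mortality is ignored** in the 5-year risk (the gate operates
  at ages 50–75 over a short horizon where the distortion is modest).
* The eligibility gate is **inclusive** at the threshold (≥ 5%).

## Nodule pathway

Category from volume when volumetry is possible, else diameter, with all
lower bounds exclusive ("greater than"): 15/50/500 mm³, 3/5/10 mm. The
sphere-equivalent diameter `d = (6V/π)^(1/3)` maps the volume cuts to
≈ 3.06/4.57/9.85 mm, so the paired diameter cuts nearly agree; volume
always wins when both are present. Subject-level category is the maximum
over the subject's nodules (the reference tables are per subject); no
recorded nodules means category 1.

Follow-up: category 2 → 12 months; category 3 → 3 and 12 months
(91/365 days by a declared months-to-days convention); category 4 →
immediate MDT referral; category 1 → discharge. At each scheduled scan
every nodule is compared with its most recent prior measurement:
`VDT = Δt·ln2/ln(V₂/V₁)`, with stable or shrinking nodules (V₂ ≤ V₁)
assigned +∞ — they can never trigger a growth referral. Any nodule with
VDT < 400 days refers the subject (at most one referral per subject; the
pathway stops there). A nodule first seen at follow-up is categorised as
at baseline; only a new category-4 nodule triggers referral. A subject
whose category increases at follow-up without VDT < 400 is not referred —
the protocol's growth rule is the only escalation path — but the decision
trace flags the case. Growth assessment requires volumetry at both scans;
diameter-only measurements continue the schedule. A baseline-recorded
nodule missing from a scheduled follow-up scan is treated as a data error,
not as resolution.

## Synthetic cohort generator

The generator defines the study conditions for all stochastic tests.

* **Risk-factor marginals** are the screened arm's: 75.4% male, age
  ~N(67.1, 4.1²) clipped to [50, 75], smoking status 0.1/38.3/61.6%
  never/current/ex, duration bands 0.7/5.8/93.5% (1–9/10–19/20+ years),
  asbestos 37.6%, respiratory disease 52.1%, prior malignancy 19.9%,
  family history early/late 10.6/14.0%. Factors are drawn independently;
  real risk factors correlate (see limitations).
* **Largest-nodule volume**: 30% of subjects have no nodule and 19.1% only
  a sub-threshold (≤ 15 mm³) nodule, so 50.9% carry a recordable nodule —
  the fixture's category-2–4 share. Conditional on exceeding 15 mm³ the
  volume is log-normal with (μ, σ) = (2.805, 1.852) in ln-mm³, solved by
  quantile-matching the category proportions 479/472/64 of 1994
  (`lungscreen.calibrate.calibrate_volume_lognormal`). Nodules per subject
  beyond the largest are a free parameter (default 0 extra); the reference
  tables are per subject, so the per-nodule multiplicity is unidentified.
* **Malignancy**: `P(malignant | V) = expit(−16.716 + 2.435 ln V)`, solved
  exactly so the expected cancer yields of categories 3 and 4 match 9/472
  and 32/64. The implied category-2 yield (~0.02%) is the model's
  prediction, the same order as the printed 1/479; the implied overall
  malignancy prevalence among screened subjects is ≈ 2.1%.
* **Growth**: exponential in volume with constant VDT — the only growth
  law under which VDT is well defined. Malignant VDT is log-normal,
  median 180 days, σ = 0.7 (field-typical: most screen-detected cancers
  double in 50–400 days, a tail is slower and escapes a 12-month window).
  Benign nodules are static (VDT = +∞) except a 12% slow-growing tail,
  log-normal median 550 days, σ = 0.5, which generates growth-rule false
  positives. Stage at diagnosis is drawn from the 42-case frequencies
  (IA…IV = 26/2/7/1/3/0/3 over 42).
* **Measurement noise**: multiplicative log-normal, mean-preserving, with
  coefficient of variation 0.05 — the order of repeat-volumetry
  repeatability for solid nodules under fixed software. Noise-free
  observation at t = 0 returns the baseline volume exactly.
* **Randomness**: one `numpy.random.SeedSequence` child stream per stage
  (profiles, nodules, observation, funnel, randomisation, bootstrap), all
  derived from one master seed, so each stage is independently
  reproducible and byte-identical under a fixed seed.

What passing the stochastic tests shows: the category mix and detection
rate of a simulated round land near the reference values because the
generator was calibrated to the same tables — it is a consistency check on
the whole pipeline (generation → observation → pathway → statistics), not
external validation. The generator does not emulate reader disagreement,
non-solid/part-solid morphology, nodule resolution, inter-scan attendance
loss, or correlation between risk factors and nodule prevalence.

## Trial pipeline

The recruitment funnel applies independent Bernoulli stages (positive
response 30.7%, negative 9.2%; second questionnaire 68.4%; consent 68.1%)
to the mailed population, with the risk gate in between and a recruitment
cap; only marginal rates are reported in the source, so stage independence
is an assumption. Randomisation is a seeded permutation, screen arm
receiving the extra subject on odd counts. Screen-arm attendance is one
compliance probability (default 0.983).

Outcome definitions follow the trial's printed arithmetic:

* false-positive rate = (MDT referrals − cancers) / screened;
* interval-imaging rate = (category-3 subjects − category-3 cancers) /
  screened — category-2 subjects are excluded, matching the printed
  formula rather than the looser verbal definition;
* baseline prevalence counts cancers detected at the baseline scan *or*
  the 3-month scan (the reference counts 34 baseline cancers = 32
  category-4 + 2 category-3 at month three);
* benign resection rate = benign surgeries / all resections (4/39);
* "further CT" = any scan after baseline, i.e. category-2 and -3 subjects.

Rates are raw fractions internally, percentages to one decimal place for
reporting; zero denominators yield NaN (an undefined-marker), never an
exception. The design precision check is the normal-approximation CI
half-width `z·sqrt(p(1−p)/n)`.

The fixture expansion assigns the four benign resections to category-4
false positives; the source does not state their categories, and no
computed statistic depends on that placement (the benign-resection
denominator is category-free).

## Cost-effectiveness model

The published evaluation's internals are not printed in the source
material, so the module implements a transparent stage-shift life-table
model and ships a calibration configuration:

* Per-cancer QALYs under a stage distribution d:
  `Σ_s d_s [ S5_s·Q_cured + (1−S5_s)·Q_term ]`, where `S5_s` is stage-
  specific 5-year survival, `Q_cured` is discounted quality-adjusted
  survival under background life-table mortality from the mean diagnosis
  age (67, 75% male) over a 25-year horizon with utility 0.78, and
  `Q_term` is a 1.5-year terminal phase at utility 0.60. Survival is
  measured from a common age origin, so lead time without stage shift
  contributes nothing.
* Stage distributions: screen arm = the 42 detected cancers' frequencies;
  symptomatic presentation = a UK-audit-like mix (I 13%, II 9%, IIIA 12%,
  IIIB 14%, IV 52%). Survivals 0.55/0.45/0.35/0.25/0.15/0.07/0.02 for
  IA…IV are field-typical round values.
* **Anchoring**: the full stage shift would imply a ~35% reduction in
  5-year cancer mortality — more than a single screen plausibly delivers.
  The benefit is therefore multiplied by
  `w = anchor · M_sympt / (M_sympt − M_screen)` (≈ 0.56 with the 20%
  randomised-trial anchor), which makes the model's implied mortality
  reduction equal the anchor. This is the calibration mechanism: no
  survival or utility input was hand-adjusted. With the default
  configuration the gain is ≈ 0.034 QALYs per person screened at a 2.1%
  detection rate (the acceptance script computes the exact value).
* Discounting at 3.5%/year (UK health-technology-assessment reference
  case), NHS perspective (no patient time/travel costs); costs within the
  first year are not discounted.
* Costs default to the aggregate published per-person figures
  (£212 screening + workup, £60 net treatment); an itemised mode weights
  unit costs by utilisation counts from a simulated run.
* **Uncertainty**: seeded percentile bootstrap over per-person (cost,
  QALY) samples, evaluating `mean(cost)/mean(QALY)` per resample.
  Resamples with non-positive mean QALY gain are excluded and counted,
  with a warning above 1%. The percentile interval for a ratio of means
  is slightly asymmetric at small cancer counts; the coverage simulation
  in the acceptance suite checks it stays near nominal under a benign
  sampling model.

## Numerical conventions and degenerate inputs

* Category intervals are open below, closed above; boundary values (15,
  50, 500 mm³; 3, 5, 10 mm) stay in the lower category.
* VDT of a non-growing nodule is +∞, compared with any finite threshold.
* An empty population yields an empty, schema-valid run report.
* ICER with zero QALY difference is NaN; dominance (sign disagreement) is
  left to the caller to interpret with the inputs at hand.
* All CSV output carries a `# master_seed=… / # config_sha256=…` comment
  block; floats are written with round-trip precision.

## Known limitations

* Coefficients, incidence and life tables are illustrative defaults, so
  absolute risk values and gate pass rates are not externally meaningful;
  only the model structure and its monotonicities are.
* MDT workup is modelled as perfectly discriminating (referred subjects'
  cancer status equals ground truth); real workup has its own error rates.
* The funnel's independent-thinning assumption cannot reproduce joint
  response/risk correlations, only the marginal counts.
* The cost-effectiveness result is a calibrated reconstruction, not a
  re-derivation of the published model; its CI reflects sampling of
  detected cancers only, not parameter uncertainty (no probabilistic
  sensitivity analysis over survivals, utilities or costs).
* One screening round only: no incidence screens, no overdiagnosis
  modelling beyond the mortality anchor, no smoking-cessation effects.
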