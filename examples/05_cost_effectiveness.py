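"""Stage-shift cost-effectiveness of a single LDCT screen.

Computes the discounted QALY gain per person screened from the calibrated
stage-shift life-table model, forms the ICER from the published per-person
cost components, and attaches a percentile-bootstrap confidence interval
over per-person samples.
"""

import numpy as np

from lungscreen import econ

life = econ.make_synthetic_lifetable()
effect = econ.EffectConfig()
detection_rate = 42 / 1994

cost_pp = 212.0 + 60.0  # screening+workup and net treatment, per person
gain_pp = econ.qaly_gain_pp(effect, life, detection_rate=detection_rate)
point = econ.icer(cost_pp, gain_pp)

# per-person samples: screening cost for everyone, treatment cost and QALY
# gain attached to detected cancers
rng = np.random.Generator(np.random.PCG64(1))
n = 2000
cancer = rng.random(n) < detection_rate
costs = np.full(n, 212.0)
costs[cancer] += 60.0 * n / cancer.sum()
qalys = np.zeros(n)
qalys[cancer] = gain_pp / detection_rate
lo, hi, _ = econ.bootstrap_ci(costs, qalys, n_bootstrap=2000, seed=2)

print(f"anchor weight (fraction of full stage-shift benefit): "
      f"{econ.anchor_weight(effect):.3f}")
print(f"QALYs gained per person screened: {gain_pp:.4f}")
print(f"incremental cost per person:      GBP {cost_pp:.0f}")
print(f"ICER: GBP {point:,.0f} per QALY  (bootstrap 95% CI {lo:,.0f} to {hi:,.0f})")
print(f"in USD at 1.544: {econ.currency_compare(point, 1.544):,.0f} per QALY")
print()
print(
    "The gain is driven by diagnosing cancers at earlier stages; the anchor\n"
    "scales the stage-shift benefit so the implied 5-year cancer-mortality\n"
    "reduction matches the 20% observed in randomised CT screening."
)
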