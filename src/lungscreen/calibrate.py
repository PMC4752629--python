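"""Calibration solvers for the synthetic-cohort generator.

The generator's nodule-size distribution and malignancy-vs-volume model are
not observed directly; what the pilot trial reports are per-subject nodule
category counts (979/479/472/64 over 1994 screened) and per-category cancer
yields (1/479, 9/472, 32/64).  These solvers invert those summaries:

* :func:`calibrate_volume_lognormal` finds the log-normal parameters of the
  largest-recordable-nodule volume such that, conditional on exceeding the
  15 mm^3 recording threshold, the category-2/3/4 proportions match the
  targets (quantile matching).
* :func:`calibrate_malignancy` finds the logistic model
  P(malignant | V) = expit(a + b ln V) whose expected per-category cancer
  yields best match the printed yields, weighted by category size.

The frozen defaults in :mod:`lungscreen.cohort` were produced by these
functions; a unit test checks they still agree.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import optimize, stats
from scipy.special import expit

__all__ = ["calibrate_volume_lognormal", "calibrate_malignancy"]


def calibrate_volume_lognormal(
    category_fractions: dict[int, float],
    cuts: tuple[float, float, float] = (15.0, 50.0, 500.0),
) -> tuple[float, float]:
    """Solve (mu, sigma) of ln-volume so category proportions match targets.

    ``category_fractions`` maps category -> per-subject fraction (must cover
    2, 3 and 4; category 1 is the remainder).  The distribution describes
    the largest nodule of subjects with a recordable (> ``cuts[0]`` mm^3)
    nodule, so the matching is conditional on V > cuts[0]:

        P(V <= 50 | V > 15)  = f2 / (f2+f3+f4)
        P(V <= 500 | V > 15) = (f2+f3) / (f2+f3+f4)
    """
    f2, f3, f4 = (category_fractions[k] for k in (2, 3, 4))
    rec = f2 + f3 + f4
    if not 0 < rec <= 1:
        raise ValueError("category fractions 2..4 must sum into (0, 1]")
    p2 = f2 / rec
    p23 = (f2 + f3) / rec
    c1, c2, c3 = (math.log(c) for c in cuts)

    def residuals(params):
        mu, log_sigma = params
        sigma = math.exp(log_sigma)
        z = stats.norm.cdf
        tail = 1.0 - z((c1 - mu) / sigma)
        if tail <= 0:
            return [1.0, 1.0]
        q2 = (z((c2 - mu) / sigma) - z((c1 - mu) / sigma)) / tail
        q23 = (z((c3 - mu) / sigma) - z((c1 - mu) / sigma)) / tail
        return [q2 - p2, q23 - p23]

    sol = optimize.root(residuals, x0=[math.log(60.0), math.log(1.5)], method="hybr")
    if not sol.success:
        raise RuntimeError(f"volume calibration failed: {sol.message}")
    mu, log_sigma = sol.x
    return float(mu), float(math.exp(log_sigma))


def calibrate_malignancy(
    volume_mu: float,
    volume_sigma: float,
    yields: dict[int, float],
    cuts: tuple[float, float, float] = (15.0, 50.0, 500.0),
    n_grid: int = 4000,
) -> tuple[float, float]:
    """Solve (a, b) of P(malignant | V) = expit(a + b ln V).

    Matches the expected malignancy yield within a nodule category,
    E[p(V) | V in category], to the printed cancer yields of the two
    highest categories in ``yields`` — two equations for the two logistic
    parameters, solved exactly.  The yield of any lower category is then
    implied by the model; with the default calibration it comes out of the
    same order as the printed category-2 yield (a few per mille).
    """
    lo, hi = math.log(cuts[0]), volume_mu + 6 * volume_sigma
    x = np.linspace(lo, hi, n_grid)  # ln V grid over the recordable range
    dens = stats.norm.pdf(x, loc=volume_mu, scale=volume_sigma)
    edges = [math.log(cuts[1]), math.log(cuts[2])]
    cat_of_x = np.digitize(x, edges) + 2  # 2, 3, 4

    k_hi = sorted(yields)[-2:]
    if len(k_hi) < 2:
        raise ValueError("need yields for at least two categories")
    sels = [cat_of_x == k for k in k_hi]
    targets = [yields[k] for k in k_hi]

    def residuals(params):
        a, b = params
        p = expit(a + b * x)
        return [
            float((p[s] * dens[s]).sum() / dens[s].sum()) - t
            for s, t in zip(sels, targets)
        ]

    sol = optimize.root(residuals, x0=[-14.0, 2.0], method="hybr")
    if not sol.success:
        raise RuntimeError(f"malignancy calibration failed: {sol.message}")
    a, b = sol.x
    return float(a), float(b)
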