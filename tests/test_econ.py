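"""Cost-effectiveness model: costs, QALY gain, ICER and bootstrap CI."""

import math

import numpy as np
import pandas as pd
import pytest

from lungscreen.econ import (
    CostConfig,
    EffectConfig,
    LifeTable,
    anchor_weight,
    bootstrap_ci,
    ce_analysis,
    currency_compare,
    icer,
    make_synthetic_lifetable,
    per_person_incremental_cost,
    qaly_gain_pp,
)

LIFE = make_synthetic_lifetable()


def immortal_lifetable(max_age=110):
    rows = [
        {"age": a, "sex": s, "qx": 0.0}
        for a in range(50, max_age)
        for s in ("male", "female")
    ]
    return LifeTable(pd.DataFrame(rows))


class TestCosts:
    def test_aggregate_sum(self):
        cfg = CostConfig(screening_workup_cost_pp=212.0, net_treatment_cost_pp=60.0)
        assert per_person_incremental_cost(cfg) == 272.0

    def test_zero_costs(self):
        cfg = CostConfig(screening_workup_cost_pp=0.0, net_treatment_cost_pp=0.0)
        assert per_person_incremental_cost(cfg) == 0.0

    def test_itemised_equals_manual_weighted_sum(self):
        items = {"invitation": 2.0, "ct_scan": 80.0, "repeat_ct": 70.0, "mdt": 400.0}
        counts = {"invitation": 2000, "ct_scan": 2000, "repeat_ct": 951, "mdt": 114}
        cfg = CostConfig(item_costs=items)
        got = per_person_incremental_cost(
            cfg, {"persons_screened": 2000, "utilisation": counts}
        )
        manual = sum(items[k] * counts[k] for k in items) / 2000
        assert got == pytest.approx(manual)

    def test_mixed_mode_rejected(self):
        with pytest.raises(ValueError, match="mutually exclusive"):
            CostConfig(screening_workup_cost_pp=1.0, item_costs={"a": 1.0})


class TestQalyGain:
    def test_identical_distributions_give_zero(self):
        eff = EffectConfig()
        same = EffectConfig(
            stage_distribution_screen=eff.stage_distribution_symptomatic,
            mortality_reduction_anchor=None,
        )
        assert qaly_gain_pp(same, LIFE) == pytest.approx(0.0)

    def test_two_stage_toy_matches_hand_computation(self):
        """No discounting, utility 1, no background mortality: the gain is
        (S5_screen - S5_sympt) * (horizon - terminal_years) per cancer."""
        eff = EffectConfig(
            stage_distribution_screen={"IA": 1.0, "IV": 0.0},
            stage_distribution_symptomatic={"IA": 0.0, "IV": 1.0},
            stage_survival={"IA": 0.8, "IV": 0.2},
            utility_cured=1.0,
            utility_terminal=1.0,
            terminal_years=1.5,
            discount_rate=0.0,
            horizon=20,
            mortality_reduction_anchor=None,
        )
        gain = qaly_gain_pp(eff, immortal_lifetable(), detection_rate=1.0)
        assert gain == pytest.approx((0.8 - 0.2) * (20 - 1.5))

    def test_monotone_nonincreasing_in_discount_rate(self):
        gains = [
            qaly_gain_pp(EffectConfig(discount_rate=r), LIFE)
            for r in (0.0, 0.015, 0.035, 0.06, 0.10)
        ]
        assert all(a >= b for a, b in zip(gains, gains[1:]))

    def test_anchor_scales_benefit_to_target_mortality_reduction(self):
        eff = EffectConfig()
        w = anchor_weight(eff)
        assert 0.0 < w < 1.0
        full = qaly_gain_pp(
            EffectConfig(mortality_reduction_anchor=None), LIFE
        )
        assert qaly_gain_pp(eff, LIFE) == pytest.approx(w * full)

    def test_calibrated_default_near_reference_gain(self):
        gain = qaly_gain_pp(EffectConfig(), LIFE, detection_rate=42 / 1994)
        assert gain == pytest.approx(0.03, abs=0.005)

    def test_horizon_beyond_life_table_rejected(self):
        with pytest.raises(ValueError, match="life table"):
            qaly_gain_pp(EffectConfig(horizon=60), LIFE)


class TestIcer:
    def test_reference_arithmetic(self):
        # the published per-person figures: (212+60)/0.03, "order of 9000"
        assert icer(272.0, 0.03) == pytest.approx(9066.7, abs=0.1)
        assert round(icer(272.0, 0.03), -3) == 9000

    def test_zero_cost(self):
        assert icer(0.0, 0.03) == 0.0

    def test_undefined_marker_on_zero_qaly(self):
        assert math.isnan(icer(100.0, 0.0))

    def test_scale_invariance(self):
        assert icer(2 * 272.0, 2 * 0.03) == pytest.approx(icer(272.0, 0.03))
        assert icer(2 * 272.0, 0.03) == pytest.approx(2 * icer(272.0, 0.03))


class TestBootstrap:
    def test_degenerate_samples_collapse_to_point(self):
        costs = np.full(50, 272.0)
        qalys = np.full(50, 0.03)
        lo, hi, excl = bootstrap_ci(costs, qalys, 200, seed=1)
        assert lo == hi == pytest.approx(icer(272.0, 0.03))
        assert excl == 0

    def test_same_seed_identical_different_seed_overlapping(self):
        rng = np.random.Generator(np.random.PCG64(7))
        costs = rng.normal(272, 40, 300)
        qalys = rng.normal(0.03, 0.004, 300)
        a = bootstrap_ci(costs, qalys, 500, seed=11)
        b = bootstrap_ci(costs, qalys, 500, seed=11)
        c = bootstrap_ci(costs, qalys, 500, seed=12)
        assert a == b
        assert a != c
        assert max(a[0], c[0]) < min(a[1], c[1])  # overlapping intervals

    def test_ci_contains_point_icer_across_seeds(self):
        rng = np.random.Generator(np.random.PCG64(3))
        costs = rng.normal(272, 40, 400)
        qalys = rng.normal(0.03, 0.004, 400)
        point = icer(costs.mean(), qalys.mean())
        for seed in range(5):
            lo, hi, _ = bootstrap_ci(costs, qalys, 400, seed=seed)
            assert lo <= point <= hi

    def test_nonpositive_resamples_warn_when_frequent(self):
        rng = np.random.Generator(np.random.PCG64(5))
        costs = rng.normal(272, 10, 40)
        qalys = rng.normal(0.0005, 0.01, 40)  # mean QALY barely positive
        with pytest.warns(UserWarning, match="excluded"):
            bootstrap_ci(costs, qalys, 500, seed=2)

    def test_ce_analysis_wraps_point_and_interval(self):
        rng = np.random.Generator(np.random.PCG64(9))
        costs = rng.normal(272, 30, 200)
        qalys = rng.normal(0.03, 0.003, 200)
        res = ce_analysis(costs, qalys, n_bootstrap=300, seed=4)
        assert res.ci_low <= res.icer <= res.ci_high
        assert res.icer == pytest.approx(costs.mean() / qalys.mean())


class TestCurrency:
    def test_published_pair_round_trip(self):
        # rate implied by the printed GBP/USD pair: 13071/8466
        rate = 13071 / 8466
        assert currency_compare(8466, rate) == pytest.approx(13071)
        assert rate == pytest.approx(1.544, abs=0.001)

    def test_identity_and_inverse(self):
        assert currency_compare(100.0, 1.0) == 100.0
        assert currency_compare(currency_compare(123.4, 1.7), 1 / 1.7) == pytest.approx(123.4)


class TestLifeTable:
    def test_survival_curve_monotone_and_bounded(self):
        s = LIFE.survival_curve(67, "male", 25)
        assert s[0] == 1.0
        assert ((s[1:] - s[:-1]) <= 0).all()
        assert (s >= 0).all()

    def test_female_mortality_lower(self):
        sm = LIFE.survival_curve(67, "male", 25)
        sf = LIFE.survival_curve(67, "female", 25)
        assert (sf >= sm).all() and sf[-1] > sm[-1]
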