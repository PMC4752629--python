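"""Synthetic cohort generator: determinism, marginals, growth observation."""

import math

import numpy as np
import pytest

from lungscreen.calibrate import calibrate_malignancy, calibrate_volume_lognormal
from lungscreen.cohort import (
    STATIC,
    NoduleTruth,
    RiskFactorProfile,
    SynthConfig,
    generate_population,
    observe,
    sow_nodules,
)


class TestProfiles:
    def test_age_bounds_enforced(self):
        with pytest.raises(ValueError, match="age"):
            RiskFactorProfile(49, "male", "never", 0, False, False, False, "none")

    def test_duration_zero_iff_never(self):
        with pytest.raises(ValueError, match="smoking_duration"):
            RiskFactorProfile(60, "male", "never", 10, False, False, False, "none")
        with pytest.raises(ValueError, match="smoking_duration"):
            RiskFactorProfile(60, "male", "current", 0, False, False, False, "none")


class TestGeneratePopulation:
    def test_empty(self):
        assert generate_population(SynthConfig(n_individuals=0, seed=1)) == []

    def test_deterministic_given_seed(self):
        cfg = SynthConfig(n_individuals=200, seed=42)
        a = generate_population(cfg)
        b = generate_population(cfg)
        assert [(p.id, p.profile) for p in a] == [(p.id, p.profile) for p in b]
        c = generate_population(SynthConfig(n_individuals=200, seed=43))
        assert [p.profile for p in a] != [p.profile for p in c]

    def test_marginals_within_three_se(self):
        n = 10000
        cfg = SynthConfig(n_individuals=n, seed=5)
        pop = generate_population(cfg)

        def se(p):
            return math.sqrt(p * (1 - p) / n)

        checks = {
            "current smokers": (
                np.mean([p.profile.smoking_status == "current" for p in pop]), 0.383),
            "male": (np.mean([p.profile.sex == "male" for p in pop]), 0.754),
            "asbestos": (np.mean([p.profile.asbestos_exposure for p in pop]), 0.376),
            "respiratory": (np.mean([p.profile.respiratory_disease for p in pop]), 0.521),
            "fh early": (np.mean([p.profile.family_history == "early" for p in pop]), 0.106),
        }
        for name, (obs, target) in checks.items():
            assert abs(obs - target) < 3 * se(target), name

    def test_invalid_config_names_parameter(self):
        with pytest.raises(ValueError, match="volume_sigma"):
            SynthConfig(volume_sigma=-1.0)
        with pytest.raises(ValueError, match="smoking_status_probs"):
            SynthConfig(smoking_status_probs=(0.5, 0.5, 0.5))


class TestSowNodules:
    def test_degenerate_all_nodule_free(self):
        cfg = SynthConfig(n_individuals=50, seed=1, p_no_nodule=1.0, p_subthreshold=0.0)
        pop = sow_nodules(generate_population(cfg), cfg)
        assert all(not p.nodules for p in pop)

    def test_malignant_nodules_are_larger_on_average(self):
        cfg = SynthConfig(n_individuals=20000, seed=3)
        pop = sow_nodules(generate_population(cfg), cfg)
        vols = {True: [], False: []}
        for p in pop:
            for nod in p.nodules:
                vols[nod.malignant].append(nod.baseline_volume)
        assert len(vols[True]) > 100
        assert np.mean(vols[True]) > np.mean(vols[False])

    def test_malignant_have_stage_and_finite_vdt(self):
        cfg = SynthConfig(n_individuals=5000, seed=9)
        pop = sow_nodules(generate_population(cfg), cfg)
        for p in pop:
            for nod in p.nodules:
                if nod.malignant:
                    assert nod.stage_if_cancer is not None
                    assert math.isfinite(nod.true_vdt)
                else:
                    assert nod.stage_if_cancer is None

    def test_deterministic(self):
        cfg = SynthConfig(n_individuals=300, seed=11)
        a = sow_nodules(generate_population(cfg), cfg)
        b = sow_nodules(generate_population(cfg), cfg)
        assert [p.nodules for p in a] == [p.nodules for p in b]


class TestObserve:
    def test_exact_doubling_noise_free(self, rng):
        nod = NoduleTruth(100.0, False, 365.0)
        m = observe(nod, 365.0, 0.0, rng)
        assert m.volume == pytest.approx(200.0)

    def test_static_nodule_unchanged(self, rng):
        nod = NoduleTruth(100.0, False, STATIC)
        assert observe(nod, 365.0, 0.0, rng).volume == pytest.approx(100.0)

    def test_t0_noise_free_returns_baseline_exactly(self, rng):
        nod = NoduleTruth(123.4, False, 200.0)
        assert observe(nod, 0.0, 0.0, rng).volume == 123.4

    def test_noise_cv_recovered_by_monte_carlo(self, rng):
        nod = NoduleTruth(100.0, False, STATIC)
        vols = np.array([observe(nod, 0.0, 0.1, rng).volume for _ in range(10000)])
        cv = vols.std() / vols.mean()
        assert abs(cv - 0.1) < 0.01  # within 10% of the target CV
        assert vols.mean() == pytest.approx(100.0, rel=0.01)  # mean-preserving

    def test_negative_timepoint_rejected(self, rng):
        with pytest.raises(ValueError):
            observe(NoduleTruth(100.0, False, STATIC), -1.0, 0.0, rng)

    def test_diameter_is_sphere_equivalent(self, rng):
        m = observe(NoduleTruth(500.0, False, STATIC), 0.0, 0.0, rng)
        assert m.max_diameter == pytest.approx((6 * 500 / math.pi) ** (1 / 3))


class TestCalibration:
    def test_frozen_defaults_match_solver(self):
        """The shipped volume/malignancy parameters are the solver's output."""
        cfg = SynthConfig()
        mu, sigma = calibrate_volume_lognormal(
            {2: 479 / 1994, 3: 472 / 1994, 4: 64 / 1994}
        )
        assert mu == pytest.approx(cfg.volume_mu, rel=1e-6)
        assert sigma == pytest.approx(cfg.volume_sigma, rel=1e-6)
        a, b = calibrate_malignancy(mu, sigma, {2: 1 / 479, 3: 9 / 472, 4: 32 / 64})
        assert a == pytest.approx(cfg.malignancy_intercept, rel=1e-6)
        assert b == pytest.approx(cfg.malignancy_slope, rel=1e-6)

    def test_category_proportions_close_to_targets(self, small_cohort):
        from lungscreen.pipeline import simulate_screen_round

        cohort, cfg = small_cohort
        res = simulate_screen_round(cohort, cfg)
        targets = {1: 0.491, 2: 0.240, 3: 0.237, 4: 0.032}
        for cat, target in targets.items():
            assert res.category_proportions[cat] == pytest.approx(target, abs=0.03)
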