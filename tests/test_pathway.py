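"""Nodule categorisation, VDT and care-pathway decision logic."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lungscreen.pathway import (
    NO_GROWTH,
    CareDecision,
    NoduleMeasurement,
    PathwayThresholds,
    categorize_nodule,
    compute_vdt,
    run_pathway,
    schedule,
    sphere_diameter,
    subject_category,
)

TH = PathwayThresholds()


def vol(v, t=0.0, sid="s1", nid="n1"):
    return NoduleMeasurement(sid, nid, t, volume=v)


def dia(d, t=0.0, sid="s1", nid="n1"):
    return NoduleMeasurement(sid, nid, t, max_diameter=d, volumetry_possible=False)


class TestCategorize:
    @pytest.mark.parametrize(
        "volume, expected",
        [(10, 1), (15, 1), (15.1, 2), (50, 2), (50.1, 3), (500, 3), (500.1, 4), (600, 4)],
    )
    def test_volume_boundaries_exclusive_below(self, volume, expected):
        assert categorize_nodule(vol(volume), TH) == expected

    @pytest.mark.parametrize(
        "diameter, expected",
        [(2.9, 1), (3, 1), (3.1, 2), (5, 2), (7, 3), (10, 3), (10.1, 4)],
    )
    def test_diameter_fallback(self, diameter, expected):
        assert categorize_nodule(dia(diameter), TH) == expected

    def test_volume_primary_when_volumetry_possible(self):
        # a 600 mm^3 nodule is category 4 regardless of any recorded diameter
        m = NoduleMeasurement("s1", "n1", 0.0, volume=600.0, max_diameter=4.0)
        assert categorize_nodule(m, TH) == 4

    def test_benign_features_override(self):
        m = NoduleMeasurement("s1", "n1", 0.0, volume=600.0, benign_features=True)
        assert categorize_nodule(m, TH) == 1

    @given(st.floats(min_value=0.1, max_value=5000), st.floats(min_value=0.0, max_value=1000))
    @settings(derandomize=True, max_examples=200)
    def test_monotone_in_volume(self, v, dv):
        assert categorize_nodule(vol(v + dv), TH) >= categorize_nodule(vol(v), TH)

    def test_sphere_diameter_matches_category_cuts_approximately(self):
        # d = (6V/pi)^(1/3) maps 15/50/500 mm^3 to ~3.06/4.57/9.85 mm: the
        # paired diameter cuts 3/5/10 nearly agree, volume stays primary
        for v, d_expect in [(15, 3.06), (50, 4.57), (500, 9.85)]:
            assert sphere_diameter(v) == pytest.approx(d_expect, abs=0.01)

    @given(st.floats(min_value=0.1, max_value=1e4), st.floats(min_value=0.1, max_value=1e4))
    @settings(derandomize=True, max_examples=100)
    def test_sphere_diameter_strictly_increasing(self, v1, v2):
        if v1 < v2:
            assert sphere_diameter(v1) < sphere_diameter(v2)


class TestSubjectCategory:
    def test_max_rule(self):
        ms = [vol(40, nid="a"), vol(200, nid="b")]
        assert subject_category(ms, TH) == 3

    def test_no_nodules_is_category_1(self):
        assert subject_category([], TH) == 1

    def test_max_rule_with_cat4(self):
        ms = [vol(10, nid="a"), vol(12, nid="b"), vol(700, nid="c")]
        assert subject_category(ms, TH) == 4

    def test_mixed_subjects_rejected(self):
        with pytest.raises(ValueError, match="mix subjects"):
            subject_category([vol(40, sid="s1"), vol(40, sid="s2")], TH)


class TestVDT:
    def test_exact_doubling(self):
        assert compute_vdt(100, 200, 365) == pytest.approx(365)

    def test_no_growth_sentinel(self):
        assert compute_vdt(100, 100, 365) == NO_GROWTH
        assert compute_vdt(100, 80, 365) == NO_GROWTH

    def test_partial_growth_closed_form(self):
        # 90 * ln 2 / ln 1.5, evaluated independently
        expected = 90 * math.log(2) / math.log(1.5)
        assert compute_vdt(100, 150, 90) == pytest.approx(expected)
        assert compute_vdt(100, 150, 90) == pytest.approx(153.9, abs=0.05)

    @given(
        st.floats(min_value=1e-3, max_value=1e6),
        st.floats(min_value=1e-3, max_value=1e5),
    )
    @settings(derandomize=True, max_examples=200)
    def test_doubling_identity(self, v, t):
        assert compute_vdt(v, 2 * v, t) == pytest.approx(t, rel=1e-9)

    @pytest.mark.parametrize("v1, v2, dt", [(0, 1, 1), (1, 0, 1), (1, 2, 0), (1, 2, -5)])
    def test_invalid_inputs(self, v1, v2, dt):
        with pytest.raises(ValueError):
            compute_vdt(v1, v2, dt)


class TestSchedule:
    @pytest.mark.parametrize("cat, expected", [(1, []), (2, [365.0]), (3, [91.0, 365.0]), (4, [])])
    def test_followup_times(self, cat, expected):
        assert schedule(cat, TH) == expected


class TestRunPathway:
    def test_category2_stable_discharged_at_12m(self):
        ms = [vol(40, 0), vol(40, 365)]
        d = run_pathway(ms, TH)
        assert [(x.action, x.timepoint) for x in d] == [
            ("repeat_12m", 0.0), ("discharge", 365.0)
        ]

    def test_category3_growth_referred_at_3m(self):
        # VDT 300 days over 91 days: ratio = 2**(91/300)
        v2 = 100 * 2 ** (91 / 300)
        ms = [vol(100, 0), vol(v2, 91), vol(v2, 365)]
        d = run_pathway(ms, TH)
        assert d[-1].action == "refer_MDT"
        assert d[-1].reason == "growth_vdt"
        assert d[-1].timepoint == 91.0

    def test_category2_growth_referred_at_12m(self):
        v2 = 40 * 2 ** (365 / 350)  # VDT 350 < 400
        d = run_pathway([vol(40, 0), vol(v2, 365)], TH)
        assert d[-1].action == "refer_MDT" and d[-1].timepoint == 365.0

    def test_category4_immediate_referral_no_followup(self):
        d = run_pathway([vol(700, 0)], TH)
        assert d == [CareDecision("s1", 0.0, "refer_MDT", "baseline_category")]

    def test_category3_stable_repeat_then_discharge(self):
        ms = [vol(100, 0), vol(100, 91), vol(100, 365)]
        actions = [x.action for x in run_pathway(ms, TH)]
        assert actions == ["repeat_3m_then_12m", "repeat_12m", "discharge"]

    def test_new_cat4_nodule_at_followup_referred(self):
        ms = [vol(40, 0, nid="a"), vol(40, 365, nid="a"), vol(700, 365, nid="b")]
        d = run_pathway(ms, TH)
        assert d[-1].action == "refer_MDT" and d[-1].reason == "new_nodule"

    def test_at_most_one_referral(self, small_cohort):
        from lungscreen.pipeline import simulate_screen_round

        cohort, cfg = small_cohort
        res = simulate_screen_round(cohort, cfg)
        per_subject = {}
        for d in res.decisions:
            if d.action == "refer_MDT":
                per_subject[d.subject_id] = per_subject.get(d.subject_id, 0) + 1
        assert all(v == 1 for v in per_subject.values())

    def test_missing_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            run_pathway([vol(40, 91)], TH)

    def test_disappeared_nodule_rejected(self):
        ms = [vol(40, 0, nid="a"), vol(40, 0, nid="b"), vol(40, 365, nid="a")]
        with pytest.raises(ValueError, match="unmatched"):
            run_pathway(ms, TH)

    def test_shrinking_nodule_never_referred(self):
        ms = [vol(400, 0), vol(200, 91), vol(100, 365)]
        assert all(x.action != "refer_MDT" for x in run_pathway(ms, TH))
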