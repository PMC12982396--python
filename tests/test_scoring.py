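"""Corrected-activity arithmetic, exclusions, and classification rules."""

import dataclasses
import math

import numpy as np
import pytest

from batkit.gating import PopulationCounts
from batkit.scoring import (
    ConditionSummary, ResponseProfile, ScoringError, activity_results,
    apply_exclusions, classify_margin, classify_rank_split,
    condition_summaries, corrected_activity, missing_basophils,
    response_profile, tukey_fences, tukey_hinges,
)
from batkit.synthetic import Condition, expected_response


def summary(cond, b, c):
    return ConditionSummary(Condition(cond), b=b, c=c)


def four_summaries(ctrl, oma, alg, alg_oma):
    return {
        Condition.CTRL: summary("CTRL", *ctrl),
        Condition.OMA: summary("OMA", *oma),
        Condition.ALG: summary("ALG", *alg),
        Condition.ALG_OMA: summary("ALG_OMA", *alg_oma),
    }


class TestConditionSummaries:
    def test_hand_arithmetic(self):
        pc = PopulationCounts(n_total=20000, n_singlets=15000, n_cd45=10000,
                              n_basophil_intact=100, n_cd63pos=30)
        counts = {c: pc for c in Condition}
        s = condition_summaries(counts)[Condition.CTRL]
        assert s.b == pytest.approx(0.01)
        assert s.c == pytest.approx(0.003)
        assert s.p63 == pytest.approx(0.30)

    def test_no_cd63_events(self):
        s = summary("CTRL", 0.01, 0.0)
        assert s.c == 0.0 and s.p63 == 0.0

    def test_degenerate_no_basophils_flagged(self):
        s = summary("CTRL", 0.0, 0.0)
        assert math.isnan(s.p63)

    def test_no_cd45_events_flagged_invalid(self):
        empty = PopulationCounts()
        counts = {c: empty for c in Condition}
        s = condition_summaries(counts)
        assert not s[Condition.CTRL].valid


class TestMissingBasophils:
    def test_hand_arithmetic(self):
        m = missing_basophils(summary("CTRL", 0.010, 0.001),
                              summary("ALG", 0.006, 0.003))
        assert m == pytest.approx(0.004)

    def test_clamped_at_zero_when_basophils_increase(self):
        assert missing_basophils(summary("OMA", 0.006, 0.001),
                                 summary("ALG_OMA", 0.009, 0.001)) == 0.0

    def test_equal_totals_give_zero(self):
        assert missing_basophils(summary("CTRL", 0.01, 0.001),
                                 summary("ALG", 0.01, 0.002)) == 0.0

    def test_arm_mismatch_rejected(self):
        with pytest.raises(ScoringError, match="arm"):
            missing_basophils(summary("CTRL", 0.01, 0.001),
                              summary("ALG_OMA", 0.006, 0.001))


class TestCorrectedActivity:
    def test_hand_arithmetic(self):
        a = corrected_activity(summary("ALG", 0.006, 0.003), 0.004)
        assert a == pytest.approx(0.7)

    def test_zero_loss_reduces_to_uncorrected_ratio(self):
        s = summary("ALG", 0.0062, 0.0017)
        assert corrected_activity(s, 0.0) == pytest.approx(s.c / s.b)

    def test_saturation_when_all_basophils_activated(self):
        for m in (0.0, 0.001, 0.05):
            assert corrected_activity(summary("ALG", 0.004, 0.004), m) \
                == pytest.approx(1.0)

    def test_zero_denominator_flagged(self):
        assert math.isnan(corrected_activity(summary("ALG", 0.0, 0.0), 0.0))

    def test_monotone_in_missing_fraction(self):
        # A increases with m whenever c < b
        s = summary("ALG", 0.008, 0.002)
        grid = [corrected_activity(s, m) for m in np.linspace(0, 0.05, 200)]
        assert all(b >= a for a, b in zip(grid, grid[1:]))
        assert all(0.0 <= a <= 1.0 for a in grid)


class TestResponseProfile:
    def test_hand_worked_fold_changes(self):
        s = four_summaries(ctrl=(0.010, 0.001), alg=(0.006, 0.003),
                           oma=(0.010, 0.001), alg_oma=(0.009, 0.0015))
        prof = response_profile("PT01", s)
        assert prof.fc_allergen == pytest.approx(7.0, rel=1e-12)
        assert prof.bat_fc == pytest.approx(0.25 / 0.7, rel=1e-12)
        assert prof.positive_bat  # p63(ALG) = 0.5 > 5%

    def test_each_arm_uses_its_own_reference(self):
        s = four_summaries(ctrl=(0.010, 0.001), alg=(0.006, 0.003),
                           oma=(0.008, 0.001), alg_oma=(0.0075, 0.0015))
        arms = activity_results(s)
        assert arms["untreated"].m == pytest.approx(0.004)
        assert arms["omalizumab"].m == pytest.approx(0.0005)

    def test_full_blockade_limit(self, small_cohort):
        cfg, donors = small_cohort
        d = dataclasses.replace(donors[0], rho=1.0)
        assert expected_response(d, cfg).bat_fc < 0.5

    def test_no_blockade_limit(self, small_cohort):
        cfg, donors = small_cohort
        d = dataclasses.replace(donors[0], rho=0.0)
        assert expected_response(d, cfg).bat_fc == pytest.approx(1.0, abs=1e-9)


class TestExclusions:
    def make_profiles(self, bat_fcs, positives=None):
        positives = positives or [True] * len(bat_fcs)
        return [
            ResponseProfile(donor_id=f"P{i:02d}", fc_allergen=5.0, bat_fc=fc,
                            positive_bat=pos)
            for i, (fc, pos) in enumerate(zip(bat_fcs, positives))
        ]

    def test_tukey_hinges_hand_worked(self):
        assert tukey_hinges([1, 2, 3, 4, 100]) == (2.0, 4.0)
        assert tukey_fences([1, 2, 3, 4, 100]) == (-1.0, 7.0)

    def test_outlier_excluded_by_hinge_fences(self):
        profiles, audit = apply_exclusions(
            self.make_profiles([1, 2, 3, 4, 100]))
        assert [p.excluded for p in profiles] == \
            ["none", "none", "none", "none", "outlier"]
        rules = {a["donor_id"]: a["rule"] for a in audit
                 if a["decision"] == "excluded"}
        assert rules == {"P04": "tukey_iqr"}

    def test_equal_values_have_no_outliers(self):
        profiles, _ = apply_exclusions(self.make_profiles([0.7] * 6))
        assert all(p.excluded == "none" for p in profiles)

    def test_nonreactive_excluded_regardless_of_bat_fc(self):
        profiles, _ = apply_exclusions(
            self.make_profiles([0.5, 0.6, 0.7, 0.8],
                               positives=[True, False, True, True]))
        assert profiles[1].excluded == "nonreactive"
        assert profiles[1].responder_class == "unassigned"

    def test_nonreactive_values_never_enter_iqr(self):
        # the nonreactive donor's extreme BAT Fc must not widen the fences:
        # with it removed, 100 is an outlier of {1,2,3,4}
        profiles, _ = apply_exclusions(
            self.make_profiles([1, 2, 3, 4, 100, 1000],
                               positives=[True] * 5 + [False]))
        assert profiles[4].excluded == "outlier"
        assert profiles[5].excluded == "nonreactive"

    def test_too_few_for_outlier_rule(self):
        profiles, _ = apply_exclusions(self.make_profiles([1, 2, 100]))
        assert all(p.excluded == "none" for p in profiles)

    def test_audit_covers_every_donor_once(self):
        profiles, audit = apply_exclusions(
            self.make_profiles([1, 2, 3, 4, 100],
                               positives=[True, True, False, True, True]))
        ids = [a["donor_id"] for a in audit]
        assert sorted(ids) == sorted(p.donor_id for p in profiles)


class TestClassification:
    def make(self, bat_fcs):
        return [ResponseProfile(donor_id=f"P{i:02d}", fc_allergen=5.0,
                                bat_fc=fc, positive_bat=True)
                for i, fc in enumerate(bat_fcs)]

    def test_rank_split_even(self):
        labeled = classify_rank_split(self.make([0.3, 0.5, 0.7, 0.9]))
        assert [p.responder_class for p in labeled] == \
            ["better", "better", "poor_non", "poor_non"]

    def test_rank_split_odd_median_goes_to_poor(self):
        labeled = classify_rank_split(self.make([0.1, 0.2, 0.3, 0.4, 0.5]))
        assert sum(p.responder_class == "better" for p in labeled) == 2
        assert sum(p.responder_class == "poor_non" for p in labeled) == 3

    def test_rank_split_ties_break_by_donor_id(self):
        labeled = classify_rank_split(self.make([0.5, 0.5, 0.5, 0.5]))
        better = {p.donor_id for p in labeled if p.responder_class == "better"}
        assert better == {"P00", "P01"}

    def test_margin_boundary_goes_to_poor(self):
        labeled = classify_margin(self.make([0.59, 0.60]), margin=0.6)
        assert [p.responder_class for p in labeled] == ["better", "poor_non"]

    def test_margin_all_above_yields_no_better(self):
        labeled = classify_margin(self.make([0.7, 0.9, 1.2]), margin=0.6)
        assert all(p.responder_class == "poor_non" for p in labeled)

    def test_excluded_stay_unassigned(self):
        profiles = self.make([0.3, 0.9])
        profiles.append(ResponseProfile(donor_id="P99", bat_fc=0.2,
                                        positive_bat=False,
                                        excluded="nonreactive"))
        for labeled in (classify_rank_split(profiles),
                        classify_margin(profiles)):
            assert labeled[-1].responder_class == "unassigned"
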