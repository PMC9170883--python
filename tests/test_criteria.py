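"""Classification engines: target selection, change summaries, categories,
composite logic, boundary behavior, and the responder-set algebra."""

import itertools
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alpharecist.cohort import (
    AFPPair,
    Cohort,
    LesionMeasurement,
    NontargetStatus,
    Timepoint,
)
from alpharecist.criteria import (
    CRITERIA,
    ChangeSummary,
    NoTargetLesionError,
    ResponseCategory,
    afp_delta,
    classify_composite,
    classify_mrecist,
    classify_recist11,
    evaluate_cohort,
    resolve_criterion,
    select_target_lesions,
    summarize_changes,
)

from conftest import make_patient


def _bl(lid, organ, d):
    return LesionMeasurement(lid, organ, Timepoint.BASELINE, d, d * 0.5, True)


def summary(sld_bl, sld_fu, viable_bl=None, viable_fu=None, afp=None):
    viable_bl = sld_bl * 0.8 if viable_bl is None else viable_bl
    viable_fu = min(sld_fu * 0.8, sld_fu) if viable_fu is None else viable_fu
    return ChangeSummary(
        sld_bl=sld_bl,
        sld_fu=sld_fu,
        sld_change=(sld_fu - sld_bl) / sld_bl,
        viable_sld_bl=viable_bl,
        viable_sld_fu=viable_fu,
        viable_change=(viable_fu - viable_bl) / viable_bl if viable_bl > 0 else None,
        afp_delta=afp,
    )


class TestTargetSelection:
    def test_single_large_lesion_selected(self):
        assert select_target_lesions([_bl("L1", "liver", 70.0)]) == ["L1"]

    def test_two_per_organ_rule_keeps_largest_two(self):
        lesions = [_bl("a", "liver", 40.0), _bl("b", "liver", 30.0),
                   _bl("c", "liver", 20.0)]
        assert set(select_target_lesions(lesions)) == {"a", "b"}

    def test_sub_centimetre_lesions_are_ineligible(self):
        with pytest.raises(NoTargetLesionError):
            select_target_lesions([_bl("a", "liver", 9.9)])

    def test_seven_lesions_four_organs_respects_both_limits(self):
        # brute-force check: selection satisfies the constraints and matches
        # the greedy optimum (largest diameters first) over all valid subsets
        rng = np.random.default_rng(42)
        organs = ["liver", "lung", "liver", "node", "lung", "adrenal", "liver"]
        lesions = [_bl(f"L{i}", org, float(d)) for i, (org, d) in
                   enumerate(zip(organs, rng.uniform(10, 80, 7)))]
        chosen = select_target_lesions(lesions)
        assert len(chosen) == 5
        by_id = {l.lesion_id: l for l in lesions}
        per_organ = {}
        for lid in chosen:
            per_organ[by_id[lid].organ] = per_organ.get(by_id[lid].organ, 0) + 1
        assert max(per_organ.values()) <= 2

        best_sum = 0.0
        for subset in itertools.combinations(lesions, 5):
            cnt = {}
            for l in subset:
                cnt[l.organ] = cnt.get(l.organ, 0) + 1
            if max(cnt.values()) <= 2:
                best_sum = max(best_sum, sum(l.longest_diameter for l in subset))
        assert sum(by_id[lid].longest_diameter for lid in chosen) == pytest.approx(best_sum)


class TestChangeSummary:
    def test_single_lesion_42_percent_decrease(self):
        s = summarize_changes(make_patient("p", 100.0, 58.0))
        assert s.sld_change == pytest.approx(-0.42)

    def test_identical_measurements_give_zero_change(self):
        s = summarize_changes(make_patient("p", 50.0, 50.0))
        assert s.sld_change == 0.0 and s.viable_change == 0.0

    def test_two_lesion_sum(self):
        lesions = (
            _bl("a", "liver", 50.0), _bl("b", "lung", 50.0),
            LesionMeasurement("a", "liver", Timepoint.FOLLOWUP, 40.0, 20.0, True),
            LesionMeasurement("b", "lung", Timepoint.FOLLOWUP, 20.0, 10.0, True),
        )
        rec = replace(make_patient("p", 50.0, 40.0), lesions=lesions)
        s = summarize_changes(rec)
        assert s.sld_bl == 100.0 and s.sld_fu == 60.0
        assert s.sld_change == pytest.approx(-0.40)


class TestAFPDelta:
    @pytest.mark.parametrize(
        "bl,fu,expected", [(200.0, 48.0, -0.76), (100.0, 100.0, 0.0), (50.0, 100.0, 1.0)]
    )
    def test_values(self, bl, fu, expected):
        assert afp_delta(AFPPair(bl, fu)) == pytest.approx(expected)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            afp_delta(AFPPair(0.0, 5.0))


class TestRecist11:
    def test_forty_two_percent_decrease_is_pr(self):
        assert classify_recist11(summary(100, 58), False) is ResponseCategory.PR

    def test_growth_below_5mm_absolute_is_sd(self):
        # +24% but only +2.4 mm: the absolute rule blocks PD
        assert classify_recist11(summary(10, 12.4), False) is ResponseCategory.SD

    def test_growth_meeting_both_pd_conditions(self):
        assert classify_recist11(summary(50, 61), False) is ResponseCategory.PD

    def test_disappearance_is_cr(self):
        assert classify_recist11(summary(100, 0), False) is ResponseCategory.CR

    def test_new_lesions_force_pd(self):
        assert classify_recist11(summary(100, 58), True) is ResponseCategory.PD

    def test_nontarget_pd_forces_pd(self):
        assert (
            classify_recist11(summary(100, 58), False, NontargetStatus.PD)
            is ResponseCategory.PD
        )

    def test_boundary_30_percent_is_pr(self):
        assert classify_recist11(summary(100, 70), False) is ResponseCategory.PR

    def test_boundary_20_percent_and_5mm_is_pd(self):
        # 25 -> 30 mm: exactly +20% and exactly +5 mm
        assert classify_recist11(summary(25, 30), False) is ResponseCategory.PD


class TestMrecist:
    def test_enhancement_disappearance_is_cr_while_recist_sd(self):
        s = summary(80, 60, viable_bl=64.0, viable_fu=0.0)
        assert classify_mrecist(s, False) is ResponseCategory.CR
        assert classify_recist11(s, False) is ResponseCategory.SD

    def test_viable_decrease_35_percent_is_pr(self):
        s = summary(100, 90, viable_bl=80.0, viable_fu=52.0)
        assert classify_mrecist(s, False) is ResponseCategory.PR

    def test_viable_increase_with_new_lesion_is_pd(self):
        s = summary(100, 110, viable_bl=80.0, viable_fu=100.0)
        assert classify_mrecist(s, True) is ResponseCategory.PD

    def test_no_absolute_mm_rule_for_viable_pd(self):
        s = summary(10, 10, viable_bl=8.0, viable_fu=10.0)  # +25%, +2 mm
        assert classify_mrecist(s, False) is ResponseCategory.PD


class TestComposite:
    alpha = CRITERIA["αΔ-RECIST"]

    @pytest.mark.parametrize(
        "sld_fu,afp_fu",
        [(58.0, 42.0), (66.0, 850.0), (83.0, 26.0)],
        ids=["both-thresholds", "size-only", "afp-only"],
    )
    def test_three_pr_patterns(self, sld_fu, afp_fu):
        rec = make_patient("p", 100.0, sld_fu, afp_bl=1000.0, afp_fu=afp_fu)
        assert classify_composite(rec, self.alpha) is ResponseCategory.PR

    def test_neither_threshold_met_is_sd(self):
        rec = make_patient("p", 100.0, 83.0, afp_bl=100.0, afp_fu=50.0)
        assert classify_composite(rec, self.alpha) is ResponseCategory.SD

    def test_and_variant_requires_both(self):
        rec = make_patient("p", 100.0, 58.0, afp_bl=100.0, afp_fu=85.0)
        assert (
            classify_composite(rec, CRITERIA["α&Δ-RECIST"]) is ResponseCategory.SD
        )
        assert classify_composite(rec, self.alpha) is ResponseCategory.PR

    def test_afp_boundary_76_percent_qualifies(self):
        rec = make_patient("p", 100.0, 95.0, afp_bl=200.0, afp_fu=48.0)
        assert classify_composite(rec, self.alpha) is ResponseCategory.PR

    def test_new_lesions_veto_afp_response(self):
        rec = make_patient("p", 100.0, 95.0, afp_bl=1000.0, afp_fu=10.0,
                           new_lesions=True)
        assert classify_composite(rec, self.alpha) is ResponseCategory.PD

    def test_missing_afp_is_non_evaluable(self):
        rec = make_patient("p", 100.0, 58.0)
        assert classify_composite(rec, self.alpha) is None

    def test_baseline_component_counts_high_afp_toward_response(self):
        # implemented exactly as stated: AFP_BL >= 54.4 ng/ml qualifies
        rec = make_patient("p", 100.0, 95.0, afp_bl=60.0, afp_fu=60.0)
        assert classify_composite(rec, CRITERIA["αBL-RECIST"]) is ResponseCategory.PR
        rec2 = make_patient("p", 100.0, 95.0, afp_bl=50.0, afp_fu=50.0)
        assert classify_composite(rec2, CRITERIA["αBL-RECIST"]) is ResponseCategory.SD


class TestMonotonicity:
    @given(
        sld_fu=st.floats(0.0, 200.0),
        delta=st.floats(0.1, 50.0),
    )
    @settings(max_examples=50)
    def test_larger_followup_sld_never_improves_category(self, sld_fu, delta):
        a = classify_recist11(summary(100.0, sld_fu), False)
        b = classify_recist11(summary(100.0, sld_fu + delta), False)
        assert b >= a  # IntEnum order CR < PR < SD < PD

    @given(afp_fu=st.floats(0.0, 500.0), drop=st.floats(0.1, 100.0))
    @settings(max_examples=50)
    def test_lower_followup_afp_never_worsens_composite(self, afp_fu, drop):
        spec = CRITERIA["αΔ-RECIST"]
        high = make_patient("p", 100.0, 90.0, afp_bl=500.0, afp_fu=afp_fu)
        low = make_patient("p", 100.0, 90.0, afp_bl=500.0,
                           afp_fu=max(afp_fu - drop, 0.0))
        assert classify_composite(low, spec) <= classify_composite(high, spec)


class TestResponderAlgebra:
    def _pd_free_cohort(self, seed, n=120):
        from alpharecist.simulate import GeneratorParams, generate_cohort

        cohort = generate_cohort(GeneratorParams(n=n, seed=seed)).cohort
        base = CRITERIA["RECIST11"]
        keep = [r for r in cohort
                if classify_composite(r, base) is not ResponseCategory.PD
                and classify_composite(r, CRITERIA["mRECIST"]) is not ResponseCategory.PD]
        return Cohort(records=keep)

    @pytest.mark.parametrize("seed", [11, 23, 57])
    @pytest.mark.parametrize("base,orv,andv", [
        ("RECIST11", "αΔ-RECIST", "α&Δ-RECIST"),
        ("RECIST11", "αBL-RECIST", "α&BL-RECIST"),
        ("mRECIST", "αΔ-mRECIST", "α&Δ-mRECIST"),
    ])
    def test_subset_laws_and_count_identity(self, seed, base, orv, andv):
        cohort = self._pd_free_cohort(seed)
        table = evaluate_cohort(
            cohort, [CRITERIA[base], CRITERIA[orv], CRITERIA[andv]])
        r_base = set(table.index[table[f"responder_{base}"].fillna(False)])
        r_or = set(table.index[table[f"responder_{orv}"].fillna(False)])
        r_and = set(table.index[table[f"responder_{andv}"].fillna(False)])
        assert r_and <= r_base <= r_or

        spec = CRITERIA[orv]
        afp_ok = set()
        for rec in cohort:
            if rec.afp is None:
                continue
            if spec.afp_component == "delta":
                ok = afp_delta(rec.afp) <= spec.afp_delta_cutoff
            else:
                ok = rec.afp.afp_bl >= spec.afp_bl_cutoff
            if ok:
                afp_ok.add(rec.patient_id)
        assert len(r_or) + len(r_and) == len(r_base) + len(afp_ok)

    def test_reclassification_of_base_sd_afp_satisfiers(self):
        # base-PR patients plus 8 base-SD patients who satisfy the AFP rule:
        # the OR composite's responder count is base-PR + 8
        records = [make_patient(f"pr{i}", 100.0, 60.0, 100.0, 90.0) for i in range(4)]
        records += [make_patient(f"sd{i}", 100.0, 90.0, 1000.0, 10.0) for i in range(8)]
        records += [make_patient(f"nn{i}", 100.0, 90.0, 100.0, 90.0) for i in range(5)]
        table = evaluate_cohort(Cohort(records=records),
                                [CRITERIA["RECIST11"], CRITERIA["αΔ-RECIST"]])
        assert int(table["responder_RECIST11"].sum()) == 4
        assert int(table["responder_αΔ-RECIST"].sum()) == 12


def test_evaluate_cohort_marks_missing_afp_as_ne(example_cases_cohort):
    rec = replace(example_cases_cohort.records[0], patient_id="noafp", afp=None)
    cohort = Cohort(records=example_cases_cohort.records + [rec])
    table = evaluate_cohort(cohort, [CRITERIA["αΔ-RECIST"]])
    assert table.loc["noafp", "αΔ-RECIST"] == "NE"
    assert table.loc["case1", "αΔ-RECIST"] == "PR"


def test_alias_resolution():
    assert resolve_criterion("alpha-recist").name == "αΔ-RECIST"
    assert resolve_criterion("RECIST11").name == "RECIST11"
    with pytest.raises(KeyError):
        resolve_criterion("easl")
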