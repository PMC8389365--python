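"""Rule-engine tests: one minimal fixture per reason code, dispositions,
INR resolution policies, corrections, determinism and code ordering."""

from dataclasses import replace
from datetime import date, datetime, timedelta

import pytest

from meldqa import (
    AnalytePanel,
    Anticoagulation,
    ClottingResult,
    ClottingStatus,
    DialysisMode,
    DialysisStatus,
    Disposition,
    MeldResult,
    PatientHistory,
    ReasonCode,
    Specimen,
    TubeType,
    ValidationVerdict,
    apply_correction,
    check_anticoagulation,
    check_dialysis,
    check_order_integrity,
    check_preanalytics,
    compute_meld,
    delta_check,
    resolve_inr,
    validate,
)

from conftest import T0, make_clean_request, make_history

RC = ReasonCode


def _shift_specimens(request, *, draw=timedelta(), arrival=timedelta(), only=None):
    specimens = tuple(
        replace(s, draw_time=s.draw_time + draw, lab_arrival_time=s.lab_arrival_time + draw + arrival)
        if only is None or s.tube_type == only
        else s
        for s in request.specimens
    )
    return replace(request, specimens=specimens)


def _no_clot(request):
    panel = replace(request.panel, inr=None)
    clotting = ClottingResult(status=ClottingStatus.NO_CLOT_WITHIN_TIMEOUT)
    return replace(request, panel=panel, clotting=clotting)


# Each fixture builder returns (request, history) tripping exactly one rule.
ISOLATION_FIXTURES = {
    RC.MATERIAL_ERROR: lambda: (
        replace(make_clean_request(), specimens=make_clean_request().specimens[:1]),
        None,
    ),
    RC.UNDERFILLED_CITRATE: lambda: (
        replace(
            make_clean_request(),
            specimens=(
                make_clean_request().specimens[0],
                replace(make_clean_request().specimens[1], fill_ratio=0.60),
            ),
        ),
        None,
    ),
    RC.PATIENT_MISIDENTIFICATION: lambda: (
        replace(
            make_clean_request(),
            specimens=(
                replace(make_clean_request().specimens[0], labeled_patient_id="P99999"),
                make_clean_request().specimens[1],
            ),
        ),
        None,
    ),
    RC.PROLONGED_PREANALYTIC: lambda: (
        _shift_specimens(make_clean_request(), arrival=timedelta(hours=4.0)),
        None,
    ),
    RC.PELD_REQUIRED: lambda: (
        make_clean_request(birth_date=date(2009, 1, 10)),  # age 6 at T0
        None,
    ),
    RC.CITRATE_CLOTTED: lambda: (
        replace(
            make_clean_request(),
            specimens=(
                make_clean_request().specimens[0],
                replace(make_clean_request().specimens[1], clotted=True),
            ),
        ),
        None,
    ),
    RC.LATE_LAB_ENTRANCE: lambda: (
        _shift_specimens(make_clean_request(), draw=timedelta(hours=30)),
        None,
    ),
    RC.SPLIT_ORDER: lambda: (
        _shift_specimens(make_clean_request(), draw=timedelta(hours=2), only=TubeType.CITRATE),
        None,
    ),
    RC.MISSING_DIALYSIS_STATUS: lambda: (
        replace(make_clean_request(), stated_dialysis=None),
        None,
    ),
    RC.DIALYSIS_CRITERIA_NOT_MET: lambda: (
        make_clean_request(
            creatinine=320.0,
            dialysis=DialysisStatus(DialysisMode.INTERMITTENT, sessions_prior_week=1),
        ),
        None,
    ),
    RC.DIALYSIS_IMPLAUSIBLE: lambda: (
        make_clean_request(
            creatinine=60.0,
            dialysis=DialysisStatus(DialysisMode.INTERMITTENT, sessions_prior_week=2),
        ),
        None,
    ),
    RC.ALBUMIN_DIALYSIS_NOT_RRT: lambda: (
        make_clean_request(
            creatinine=320.0, dialysis=DialysisStatus(DialysisMode.ALBUMIN_DIALYSIS)
        ),
        None,
    ),
    RC.ANTICOAGULATION_INR_IMPACT: lambda: (
        make_clean_request(inr=2.65, anticoagulation=Anticoagulation.VKA),
        None,
    ),
    RC.INR_UNDETERMINABLE: lambda: (
        _no_clot(make_clean_request()),
        make_history(inr=3.3),
    ),
    RC.DELTA_CHECK_FAIL: lambda: (
        make_clean_request(creatinine=400.0),
        make_history(creatinine=80.0),
    ),
}

EXPECTED_DISPOSITION = {
    RC.MATERIAL_ERROR: Disposition.INVALID,
    RC.UNDERFILLED_CITRATE: Disposition.INVALID,
    RC.PATIENT_MISIDENTIFICATION: Disposition.INVALID,
    RC.PROLONGED_PREANALYTIC: Disposition.INVALID,
    RC.PELD_REQUIRED: Disposition.INVALID,
    RC.CITRATE_CLOTTED: Disposition.INVALID,
    RC.LATE_LAB_ENTRANCE: Disposition.INVALID,
    RC.SPLIT_ORDER: Disposition.INVALID,
    RC.ANTICOAGULATION_INR_IMPACT: Disposition.INVALID,
    RC.MISSING_DIALYSIS_STATUS: Disposition.NEEDS_CONSULTATION,
    RC.DIALYSIS_CRITERIA_NOT_MET: Disposition.NEEDS_CONSULTATION,
    RC.DIALYSIS_IMPLAUSIBLE: Disposition.NEEDS_CONSULTATION,
    RC.ALBUMIN_DIALYSIS_NOT_RRT: Disposition.NEEDS_CONSULTATION,
    RC.INR_UNDETERMINABLE: Disposition.NEEDS_CONSULTATION,
    RC.DELTA_CHECK_FAIL: Disposition.NEEDS_CONSULTATION,
}


class TestRuleIndependence:
    @pytest.mark.parametrize("code", sorted(ISOLATION_FIXTURES, key=lambda c: c.value))
    def test_each_code_fires_in_isolation(self, code):
        request, history = ISOLATION_FIXTURES[code]()
        verdict = validate(request, history)
        assert verdict.reasons == (code,)
        assert verdict.disposition == EXPECTED_DISPOSITION[code]
        if verdict.disposition == Disposition.INVALID:
            assert verdict.result is None

    def test_clean_request_passes_everything(self, clean_request, history):
        verdict = validate(clean_request, history)
        assert verdict.disposition == Disposition.VALID
        assert verdict.reasons == ()
        assert verdict.result is not None
        assert 6 <= verdict.result.score <= 40


class TestOrderIntegrity:
    def test_clean_codraw_passes(self, clean_request):
        assert check_order_integrity(clean_request) == []

    def test_missing_citrate_is_material_error(self, clean_request):
        request = replace(clean_request, specimens=clean_request.specimens[:1])
        assert check_order_integrity(request) == [RC.MATERIAL_ERROR]

    def test_foreign_order_id_splits(self, clean_request):
        specimens = (
            clean_request.specimens[0],
            replace(clean_request.specimens[1], order_id="O_OTHER"),
        )
        request = replace(clean_request, specimens=specimens)
        assert RC.SPLIT_ORDER in check_order_integrity(request)

    def test_lithium_heparin_is_material_error(self, clean_request):
        specimens = (
            replace(clean_request.specimens[0], tube_type=TubeType.LITHIUM_HEPARIN),
            clean_request.specimens[1],
        )
        request = replace(clean_request, specimens=specimens)
        assert RC.MATERIAL_ERROR in check_order_integrity(request)

    def test_missing_dialysis_status_flagged(self, clean_request):
        request = replace(clean_request, stated_dialysis=None)
        assert check_order_integrity(request) == [RC.MISSING_DIALYSIS_STATUS]


class TestPreanalytics:
    def test_four_and_a_half_hour_transport_flagged(self, clean_request):
        # draw 10:00, arrival 14:30
        specimens = tuple(
            replace(
                s,
                draw_time=datetime(2015, 6, 1, 10, 0),
                lab_arrival_time=datetime(2015, 6, 1, 14, 30),
            )
            for s in clean_request.specimens
        )
        request = replace(clean_request, specimens=specimens)
        assert RC.PROLONGED_PREANALYTIC in check_preanalytics(request)

    def test_exactly_four_hours_passes(self, clean_request):
        specimens = tuple(
            replace(s, lab_arrival_time=s.draw_time + timedelta(hours=4))
            for s in clean_request.specimens
        )
        request = replace(clean_request, specimens=specimens)
        assert check_preanalytics(request) == []

    def test_underfilled_citrate(self, clean_request):
        specimens = (
            clean_request.specimens[0],
            replace(clean_request.specimens[1], fill_ratio=0.70),
        )
        request = replace(clean_request, specimens=specimens)
        assert check_preanalytics(request) == [RC.UNDERFILLED_CITRATE]

    def test_child_routes_to_peld(self):
        request = make_clean_request(birth_date=date(2009, 1, 10))
        assert check_preanalytics(request) == [RC.PELD_REQUIRED]

    def test_twelfth_birthday_is_adult_pathway(self):
        request = make_clean_request(birth_date=date(2003, 6, 1))
        assert check_preanalytics(request) == []


class TestDialysisPlausibility:
    def test_one_session_fails_criteria(self):
        request = make_clean_request(
            creatinine=320.0,
            dialysis=DialysisStatus(DialysisMode.INTERMITTENT, sessions_prior_week=1),
        )
        assert check_dialysis(request) == [RC.DIALYSIS_CRITERIA_NOT_MET]

    def test_twenty_hours_cvvhd_fails_criteria(self):
        request = make_clean_request(
            creatinine=320.0,
            dialysis=DialysisStatus(DialysisMode.CVVHD, cvvhd_hours_prior_week=20),
        )
        assert check_dialysis(request) == [RC.DIALYSIS_CRITERIA_NOT_MET]

    def test_albumin_dialysis_is_not_rrt(self):
        request = make_clean_request(
            creatinine=320.0, dialysis=DialysisStatus(DialysisMode.ALBUMIN_DIALYSIS)
        )
        assert check_dialysis(request) == [RC.ALBUMIN_DIALYSIS_NOT_RRT]

    def test_qualifying_dialysis_with_high_creatinine_passes(self):
        request = make_clean_request(
            creatinine=320.0,
            dialysis=DialysisStatus(DialysisMode.INTERMITTENT, sessions_prior_week=2),
        )
        assert check_dialysis(request) == []

    def test_low_creatinine_under_stated_rrt_implausible(self):
        request = make_clean_request(
            creatinine=60.0,
            dialysis=DialysisStatus(DialysisMode.INTERMITTENT, sessions_prior_week=2),
        )
        assert check_dialysis(request) == [RC.DIALYSIS_IMPLAUSIBLE]


class TestAnticoagulation:
    def test_vka_with_elevated_inr_blocks(self):
        request = make_clean_request(inr=2.65, anticoagulation=Anticoagulation.VKA)
        assert check_anticoagulation(request) == [RC.ANTICOAGULATION_INR_IMPACT]

    def test_heparin_with_unchanged_inr_passes(self):
        request = make_clean_request(inr=1.3, anticoagulation=Anticoagulation.HEPARIN)
        history = make_history(inr=1.3, anticoagulation=Anticoagulation.HEPARIN)
        assert check_anticoagulation(request, history) == []

    def test_unraveling_inr_jump_with_stable_synthesis_markers(self):
        # INR 1.1 -> 2.8 while albumin/fibrinogen/cholinesterase unchanged:
        # oracle is direct threshold arithmetic (2.8 > 1.2 * 1.1)
        request = make_clean_request(inr=2.8, anticoagulation=Anticoagulation.NONE)
        history = make_history(inr=1.1)
        assert check_anticoagulation(request, history) == [RC.ANTICOAGULATION_INR_IMPACT]

    def test_inr_jump_with_collapsing_synthesis_markers_is_disease(self):
        # the same INR excursion with deteriorating markers reads as liver
        # failure, not hidden anticoagulation
        request = make_clean_request(
            inr=2.8, albumin=20.0, fibrinogen=0.9, cholinesterase=1.2
        )
        history = make_history(inr=1.1)
        assert check_anticoagulation(request, history) == []

    def test_vka_with_inr_in_range_passes(self):
        request = make_clean_request(inr=1.3, anticoagulation=Anticoagulation.VKA)
        assert check_anticoagulation(request) == []


class TestDeltaCheck:
    def test_empty_history_never_fires(self, clean_request):
        assert delta_check(clean_request.panel, None) == []
        assert delta_check(clean_request.panel, PatientHistory("P00001")) == []

    def test_fivefold_creatinine_jump_fires(self):
        history = make_history(creatinine=80.0)
        panel = AnalytePanel(bilirubin=50.0, creatinine=400.0, inr=1.3)
        assert delta_check(panel, history, when=T0) == [RC.DELTA_CHECK_FAIL]

    def test_ten_percent_change_passes(self):
        history = make_history(creatinine=80.0)
        panel = AnalytePanel(bilirubin=50.0, creatinine=88.0, inr=1.3)
        assert delta_check(panel, history, when=T0) == []

    def test_prior_outside_lookback_ignored(self):
        history = make_history(creatinine=80.0, when=T0 - timedelta(days=30))
        panel = AnalytePanel(bilirubin=50.0, creatinine=400.0, inr=1.3)
        assert delta_check(panel, history, when=T0) == []


class TestResolveInr:
    def test_detected_clot_passes_through(self):
        clotting = ClottingResult(ClottingStatus.CLOT_DETECTED, pt_seconds=15.4, inr=1.4)
        assert resolve_inr(clotting) == (1.4, [])

    def test_timeout_last_determinable_uses_prior(self):
        clotting = ClottingResult(ClottingStatus.NO_CLOT_WITHIN_TIMEOUT)
        history = make_history(inr=3.3)
        inr, codes = resolve_inr(clotting, history, "last_determinable")
        assert inr == 3.3
        assert codes == [RC.INR_UNDETERMINABLE]

    def test_timeout_table_max_uses_configured_maximum(self):
        clotting = ClottingResult(ClottingStatus.NO_CLOT_WITHIN_TIMEOUT)
        inr, codes = resolve_inr(clotting, None, "table_max")
        assert inr == 9.0
        assert codes == [RC.INR_UNDETERMINABLE]

    def test_timeout_block_policy_blocks(self):
        clotting = ClottingResult(ClottingStatus.NO_CLOT_WITHIN_TIMEOUT)
        inr, codes = resolve_inr(clotting, make_history(inr=3.3), "block")
        assert inr is None
        assert codes == [RC.INR_UNDETERMINABLE]

    def test_last_determinable_without_history_blocks(self):
        clotting = ClottingResult(ClottingStatus.NO_CLOT_WITHIN_TIMEOUT)
        inr, codes = resolve_inr(clotting, None, "last_determinable")
        assert inr is None
        assert codes == [RC.INR_UNDETERMINABLE]

    def test_manual_curve_read_is_flagged_but_usable(self):
        clotting = ClottingResult(
            ClottingStatus.MANUAL_CURVE_READ, pt_seconds=120.0, inr=5.0
        )
        inr, codes = resolve_inr(clotting)
        assert inr == 5.0
        assert codes == [RC.INR_UNDETERMINABLE]

    def test_unknown_policy_rejected(self):
        clotting = ClottingResult(ClottingStatus.CLOT_DETECTED, inr=1.2)
        with pytest.raises(ValueError):
            resolve_inr(clotting, None, "guess")

    def test_blocked_inr_invalidates_request(self):
        request = make_clean_request(clotting_status=ClottingStatus.NO_CLOT_WITHIN_TIMEOUT)
        verdict = validate(request, None)  # no prior INR on file
        assert verdict.disposition == Disposition.INVALID
        assert RC.INR_UNDETERMINABLE in verdict.reasons

    def test_resolved_timeout_scores_with_substituted_inr(self):
        request = make_clean_request(clotting_status=ClottingStatus.NO_CLOT_WITHIN_TIMEOUT)
        history = make_history(inr=3.3)
        verdict = validate(request, history)
        assert verdict.disposition == Disposition.NEEDS_CONSULTATION
        assert verdict.result is None  # consultation first, no release yet


class TestApplyCorrection:
    def _consult_on_stated_dialysis(self):
        request = make_clean_request(
            creatinine=90.0,
            dialysis=DialysisStatus(DialysisMode.INTERMITTENT, sessions_prior_week=2),
        )
        verdict = validate(request)
        assert verdict.disposition == Disposition.NEEDS_CONSULTATION
        return request, verdict

    def test_confirmed_no_dialysis_lowers_score(self):
        request, verdict = self._consult_on_stated_dialysis()
        corrected = apply_correction(request, verdict, DialysisStatus())
        assert corrected.disposition == Disposition.CORRECTED_VALID
        assert ReasonCode.DIALYSIS_STATUS_CORRECTED in corrected.reasons
        with_override = compute_meld(
            request.panel, DialysisStatus(DialysisMode.INTERMITTENT, sessions_prior_week=2)
        )
        assert corrected.result.score < with_override.score
        assert corrected.corrections["dialysis_status"][1]["mode"] == "none"

    def test_confirmed_dialysis_raises_score_from_missing_status(self):
        request = replace(make_clean_request(creatinine=90.0), stated_dialysis=None)
        verdict = validate(request)
        assert verdict.reasons == (RC.MISSING_DIALYSIS_STATUS,)
        without = compute_meld(request.panel, DialysisStatus())
        corrected = apply_correction(
            request,
            verdict,
            DialysisStatus(DialysisMode.INTERMITTENT, sessions_prior_week=2),
        )
        assert corrected.disposition == Disposition.CORRECTED_VALID
        assert corrected.result.score >= without.score

    def test_identical_confirmation_changes_nothing(self):
        request, verdict = self._consult_on_stated_dialysis()
        same = apply_correction(
            request,
            verdict,
            DialysisStatus(DialysisMode.INTERMITTENT, sessions_prior_week=2),
        )
        assert same is verdict
        assert same.corrections == {}

    def test_confirmed_status_failing_criteria_stays_in_consultation(self):
        request, verdict = self._consult_on_stated_dialysis()
        still = apply_correction(
            request,
            verdict,
            DialysisStatus(DialysisMode.INTERMITTENT, sessions_prior_week=1),
        )
        assert still.disposition == Disposition.NEEDS_CONSULTATION

    def test_requires_dialysis_reason(self, clean_request, history):
        verdict = validate(clean_request, history)
        with pytest.raises(ValueError):
            apply_correction(clean_request, verdict, DialysisStatus())

    def test_correction_monotonicity(self):
        # qualifying -> none never raises the score; none -> qualifying never
        # lowers it while measured creatinine is below the cap
        for creat in (60.0, 90.0, 250.0, 340.0):
            request = make_clean_request(
                creatinine=creat,
                dialysis=DialysisStatus(DialysisMode.INTERMITTENT, sessions_prior_week=2),
            )
            with_override = compute_meld(request.panel, request.stated_dialysis).score
            without = compute_meld(request.panel, DialysisStatus()).score
            assert without <= with_override


class TestVerdictInvariants:
    def test_invalid_carries_no_result(self):
        result = compute_meld(AnalytePanel(bilirubin=50.0, creatinine=90.0, inr=1.3))
        with pytest.raises(ValueError):
            ValidationVerdict(Disposition.INVALID, (RC.MATERIAL_ERROR,), result=result)

    def test_corrected_requires_corrections(self):
        with pytest.raises(ValueError):
            ValidationVerdict(Disposition.CORRECTED_VALID, (RC.DIALYSIS_STATUS_CORRECTED,))

    def test_valid_requires_empty_reasons(self):
        with pytest.raises(ValueError):
            ValidationVerdict(Disposition.VALID, (RC.DELTA_CHECK_FAIL,))

    def test_duplicate_reasons_rejected(self):
        with pytest.raises(ValueError):
            ValidationVerdict(
                Disposition.INVALID, (RC.MATERIAL_ERROR, RC.MATERIAL_ERROR)
            )


class TestDeterminismAndOrder:
    def test_identical_inputs_identical_verdicts(self, history):
        request = make_clean_request(inr=2.65, anticoagulation=Anticoagulation.VKA)
        v1 = validate(request, history)
        v2 = validate(request, history)
        assert v1 == v2

    def test_codes_follow_stage_order_regardless_of_specimen_order(self):
        base = make_clean_request(
            creatinine=60.0,
            inr=2.65,
            anticoagulation=Anticoagulation.VKA,
            dialysis=DialysisStatus(DialysisMode.INTERMITTENT, sessions_prior_week=2),
        )
        underfilled = (
            base.specimens[0],
            replace(base.specimens[1], fill_ratio=0.5),
        )
        forward = replace(base, specimens=underfilled)
        backward = replace(base, specimens=tuple(reversed(underfilled)))
        expected = (
            RC.UNDERFILLED_CITRATE,       # preanalytics stage
            RC.DIALYSIS_IMPLAUSIBLE,      # dialysis stage
            RC.ANTICOAGULATION_INR_IMPACT,  # anticoagulation stage
        )
        assert validate(forward).reasons == expected
        assert validate(backward).reasons == expected


class TestStructuralInvariants:
    def test_specimen_arrival_before_draw_rejected(self):
        with pytest.raises(ValueError):
            Specimen(
                "S1", TubeType.SERUM, "P1",
                draw_time=T0, lab_arrival_time=T0 - timedelta(hours=1),
            )

    def test_clotting_timeout_with_inr_rejected(self):
        with pytest.raises(ValueError):
            ClottingResult(ClottingStatus.NO_CLOT_WITHIN_TIMEOUT, inr=2.0)

    def test_history_requires_increasing_timestamps(self):
        entry = make_history().prior[0]
        with pytest.raises(ValueError):
            PatientHistory("P1", [entry, entry])

    def test_dialysis_none_with_sessions_rejected(self):
        with pytest.raises(ValueError):
            DialysisStatus(DialysisMode.NONE, sessions_prior_week=2)
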