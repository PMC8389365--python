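"""Laboratory verification of MELD requests.

Implements the request screen a transplant laboratory runs before a lab-MELD
score is released: order integrity (one order, one co-draw, the right
tubes), preanalytical quality (transport time, citrate fill and clotting,
patient identity, pediatric routing), plausibility of the stated dialysis
status, anticoagulation influence on the INR, coagulation measurability
(clotting-timeout handling), and delta checks against the patient's prior
results.  Each rule emits machine-readable :class:`ReasonCode`\\ s; the
aggregate verdict either releases a validated score, releases a corrected
score after consultation, escalates to consultation, or blocks reporting.

Rules are evaluated in a fixed sequence (order integrity -> preanalytics ->
INR resolution -> dialysis -> anticoagulation -> delta check) and the codes
on a verdict keep that order, so the first code identifies the earliest
failing stage.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from datetime import date, datetime, timedelta
from typing import Optional, Sequence

from .config import VerificationConfig
from .scoring import (
    AnalytePanel,
    DialysisMode,
    DialysisStatus,
    MeldResult,
    compute_meld,
    compute_meld_na,
)

__all__ = [
    "TubeType",
    "Specimen",
    "ClottingStatus",
    "ClottingResult",
    "Anticoagulation",
    "MeldRequest",
    "ReasonCode",
    "Disposition",
    "ValidationVerdict",
    "HistoryEntry",
    "PatientHistory",
    "check_order_integrity",
    "check_preanalytics",
    "check_dialysis",
    "check_anticoagulation",
    "delta_check",
    "resolve_inr",
    "validate",
    "apply_correction",
    "age_years_at",
]


class TubeType(str, enum.Enum):
    SERUM = "serum"
    CITRATE = "citrate"
    LITHIUM_HEPARIN = "lithium_heparin"
    ASCITES = "ascites"
    OTHER = "other"


@dataclass(frozen=True)
class Specimen:
    """One collected tube of a MELD order."""

    specimen_id: str
    tube_type: TubeType
    labeled_patient_id: str
    draw_time: datetime
    lab_arrival_time: datetime
    order_id: Optional[str] = None      # None: same order as the request
    fill_ratio: Optional[float] = None  # citrate only, fraction of nominal volume
    clotted: bool = False               # citrate only

    def __post_init__(self) -> None:
        if self.lab_arrival_time < self.draw_time:
            raise ValueError(
                f"specimen {self.specimen_id}: lab arrival precedes draw time"
            )
        if self.fill_ratio is not None and not (0.0 <= self.fill_ratio <= 1.2):
            raise ValueError(
                f"specimen {self.specimen_id}: fill_ratio {self.fill_ratio!r} outside [0, 1.2]"
            )


class ClottingStatus(str, enum.Enum):
    CLOT_DETECTED = "clot_detected"
    NO_CLOT_WITHIN_TIMEOUT = "no_clot_within_timeout"
    MANUAL_CURVE_READ = "manual_curve_read"


@dataclass(frozen=True)
class ClottingResult:
    """Outcome of the prothrombin-time measurement.

    In advanced liver failure the clotting reaction may never occur within
    the instrument timeout (315 s by default); the INR is then undeterminable
    and must be resolved by policy.  A manual read of the clotting curve by
    the laboratory physician yields an INR but is flagged for review.
    """

    status: ClottingStatus
    pt_seconds: Optional[float] = None
    inr: Optional[float] = None
    timeout_seconds: float = 315.0

    def __post_init__(self) -> None:
        if self.status == ClottingStatus.NO_CLOT_WITHIN_TIMEOUT and self.inr is not None:
            raise ValueError("no clot within timeout implies no INR")
        if self.status in (ClottingStatus.CLOT_DETECTED, ClottingStatus.MANUAL_CURVE_READ):
            if self.inr is None:
                raise ValueError(f"clotting status {self.status.value} requires an INR")


class Anticoagulation(str, enum.Enum):
    NONE = "none"
    HEPARIN = "heparin"
    VKA = "vka"
    DOAC = "doac"
    FONDAPARINUX = "fondaparinux"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class MeldRequest:
    """One electronically ordered MELD diagnostic."""

    order_id: str
    patient_id: str
    birth_date: date
    sex: str
    request_time: datetime
    specimens: tuple[Specimen, ...]
    panel: AnalytePanel
    clotting: ClottingResult
    stated_dialysis: Optional[DialysisStatus] = None
    stated_anticoagulation: Anticoagulation = Anticoagulation.NONE
    anticoagulant_name: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "specimens", tuple(self.specimens))

    def specimens_of_type(self, tube: TubeType) -> tuple[Specimen, ...]:
        return tuple(s for s in self.specimens if s.tube_type == tube)


class ReasonCode(str, enum.Enum):
    MATERIAL_ERROR = "MATERIAL_ERROR"
    UNDERFILLED_CITRATE = "UNDERFILLED_CITRATE"
    PATIENT_MISIDENTIFICATION = "PATIENT_MISIDENTIFICATION"
    PROLONGED_PREANALYTIC = "PROLONGED_PREANALYTIC"
    PELD_REQUIRED = "PELD_REQUIRED"
    CITRATE_CLOTTED = "CITRATE_CLOTTED"
    LATE_LAB_ENTRANCE = "LATE_LAB_ENTRANCE"
    SPLIT_ORDER = "SPLIT_ORDER"
    MISSING_DIALYSIS_STATUS = "MISSING_DIALYSIS_STATUS"
    DIALYSIS_CRITERIA_NOT_MET = "DIALYSIS_CRITERIA_NOT_MET"
    DIALYSIS_IMPLAUSIBLE = "DIALYSIS_IMPLAUSIBLE"
    ALBUMIN_DIALYSIS_NOT_RRT = "ALBUMIN_DIALYSIS_NOT_RRT"
    DIALYSIS_STATUS_CORRECTED = "DIALYSIS_STATUS_CORRECTED"
    ANTICOAGULATION_INR_IMPACT = "ANTICOAGULATION_INR_IMPACT"
    INR_UNDETERMINABLE = "INR_UNDETERMINABLE"
    DELTA_CHECK_FAIL = "DELTA_CHECK_FAIL"


#: Codes that block reporting outright: a fresh specimen (or a resolved
#: anticoagulation status) is needed; no score may be released.
BLOCKING_CODES = frozenset(
    {
        ReasonCode.MATERIAL_ERROR,
        ReasonCode.UNDERFILLED_CITRATE,
        ReasonCode.PATIENT_MISIDENTIFICATION,
        ReasonCode.PROLONGED_PREANALYTIC,
        ReasonCode.PELD_REQUIRED,
        ReasonCode.CITRATE_CLOTTED,
        ReasonCode.LATE_LAB_ENTRANCE,
        ReasonCode.SPLIT_ORDER,
        ReasonCode.ANTICOAGULATION_INR_IMPACT,
    }
)

#: Codes that escalate to the laboratory physician / sender consultation.
CONSULTATION_CODES = frozenset(
    {
        ReasonCode.MISSING_DIALYSIS_STATUS,
        ReasonCode.DIALYSIS_CRITERIA_NOT_MET,
        ReasonCode.DIALYSIS_IMPLAUSIBLE,
        ReasonCode.ALBUMIN_DIALYSIS_NOT_RRT,
        ReasonCode.DELTA_CHECK_FAIL,
        ReasonCode.INR_UNDETERMINABLE,
    }
)


class Disposition(str, enum.Enum):
    VALID = "VALID"
    CORRECTED_VALID = "CORRECTED_VALID"
    INVALID = "INVALID"
    NEEDS_CONSULTATION = "NEEDS_CONSULTATION"


@dataclass(frozen=True)
class ValidationVerdict:
    """Outcome of validating one MELD request.

    ``reasons`` preserve rule-evaluation order; ``corrections`` maps a field
    name to its (stated, confirmed) pair after consultation.  A
    :class:`MeldResult` is attached only when a score may be released.
    """

    disposition: Disposition
    reasons: tuple[ReasonCode, ...] = ()
    corrections: dict = field(default_factory=dict)
    result: Optional[MeldResult] = None
    narrative: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "reasons", tuple(self.reasons))
        if self.disposition == Disposition.INVALID and self.result is not None:
            raise ValueError("INVALID verdicts carry no MeldResult")
        if self.disposition == Disposition.CORRECTED_VALID and not self.corrections:
            raise ValueError("CORRECTED_VALID requires a non-empty corrections map")
        if self.disposition == Disposition.VALID and self.reasons:
            raise ValueError("VALID verdicts carry no reason codes")
        if len(set(self.reasons)) != len(self.reasons):
            raise ValueError("reason codes must be unique")


@dataclass(frozen=True)
class HistoryEntry:
    timestamp: datetime
    panel: AnalytePanel
    dialysis: DialysisStatus = DialysisStatus()
    anticoagulation: Anticoagulation = Anticoagulation.NONE
    result: Optional[MeldResult] = None


@dataclass
class PatientHistory:
    """Chronological record of a patient's prior validated MELD diagnostics."""

    patient_id: str
    prior: list[HistoryEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        times = [e.timestamp for e in self.prior]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("history timestamps must be strictly increasing")

    def append(self, entry: HistoryEntry) -> None:
        if self.prior and entry.timestamp <= self.prior[-1].timestamp:
            raise ValueError("history timestamps must be strictly increasing")
        self.prior.append(entry)

    def latest_before(self, when: datetime) -> Optional[HistoryEntry]:
        for entry in reversed(self.prior):
            if entry.timestamp < when:
                return entry
        return None

    def latest_inr_before(self, when: datetime) -> Optional[float]:
        for entry in reversed(self.prior):
            if entry.timestamp < when and entry.panel.inr is not None:
                return entry.panel.inr
        return None

    def baseline_without_anticoagulation(self, when: datetime) -> Optional[HistoryEntry]:
        """Most recent prior entry with no anticoagulation and a measured INR."""
        for entry in reversed(self.prior):
            if (
                entry.timestamp < when
                and entry.anticoagulation == Anticoagulation.NONE
                and entry.panel.inr is not None
            ):
                return entry
        return None


def age_years_at(birth_date: date, when: datetime) -> int:
    """Completed calendar years of age at a point in time."""
    d = when.date() if isinstance(when, datetime) else when
    years = d.year - birth_date.year
    if (d.month, d.day) < (birth_date.month, birth_date.day):
        years -= 1
    return years


# ---------------------------------------------------------------------------
# individual rule stages
# ---------------------------------------------------------------------------

def check_order_integrity(
    request: MeldRequest, config: VerificationConfig = VerificationConfig()
) -> list[ReasonCode]:
    """Order-level screen: one order, one co-draw, the right tube set.

    The MELD analytes must be ordered within the same laboratory order and
    drawn together; a serum and a citrate tube are both required, and
    lithium-heparin or ascites material is not acceptable.
    """
    codes: list[ReasonCode] = []
    serum = request.specimens_of_type(TubeType.SERUM)
    citrate = request.specimens_of_type(TubeType.CITRATE)

    split = False
    order_ids = {s.order_id for s in request.specimens if s.order_id is not None}
    if len(order_ids | ({request.order_id} if order_ids else set())) > 1:
        split = True
    if serum and citrate:
        tolerance = timedelta(hours=config.co_draw_tolerance_hours)
        gap = max(
            abs(a.draw_time - b.draw_time) for a in serum for b in citrate
        )
        if gap > tolerance:
            split = True
    if split:
        codes.append(ReasonCode.SPLIT_ORDER)

    bad_material = any(
        s.tube_type in (TubeType.LITHIUM_HEPARIN, TubeType.ASCITES)
        for s in request.specimens
    )
    if not serum or not citrate or bad_material:
        codes.append(ReasonCode.MATERIAL_ERROR)

    if request.stated_dialysis is None:
        codes.append(ReasonCode.MISSING_DIALYSIS_STATUS)
    return codes


def check_preanalytics(
    request: MeldRequest, config: VerificationConfig = VerificationConfig()
) -> list[ReasonCode]:
    """Specimen-level screen for preanalytical errors.

    Flags transport beyond the stability window, late laboratory entrance
    relative to the order, underfilled or clotted citrate tubes (both
    falsify the INR), patient misidentification on the tube label, and
    pediatric requests that belong to the PELD pathway.
    """
    codes: list[ReasonCode] = []
    required = [
        s
        for s in request.specimens
        if s.tube_type in (TubeType.SERUM, TubeType.CITRATE)
    ] or list(request.specimens)

    if any(
        (s.lab_arrival_time - s.draw_time)
        > timedelta(hours=config.preanalytic_max_hours)
        for s in required
    ):
        codes.append(ReasonCode.PROLONGED_PREANALYTIC)

    if any(
        (s.lab_arrival_time - request.request_time)
        > timedelta(hours=config.late_entrance_hours)
        for s in required
    ):
        codes.append(ReasonCode.LATE_LAB_ENTRANCE)

    citrate = request.specimens_of_type(TubeType.CITRATE)
    if any(
        s.fill_ratio is not None and s.fill_ratio < config.citrate_underfill_ratio
        for s in citrate
    ):
        codes.append(ReasonCode.UNDERFILLED_CITRATE)
    if any(s.clotted for s in citrate):
        codes.append(ReasonCode.CITRATE_CLOTTED)

    if any(s.labeled_patient_id != request.patient_id for s in request.specimens):
        codes.append(ReasonCode.PATIENT_MISIDENTIFICATION)

    if request.specimens:
        draw = min(s.draw_time for s in request.specimens)
        if age_years_at(request.birth_date, draw) < config.peld_age_years:
            codes.append(ReasonCode.PELD_REQUIRED)
    return codes


def check_dialysis(
    request: MeldRequest,
    history: Optional[PatientHistory] = None,
    config: VerificationConfig = VerificationConfig(),
) -> list[ReasonCode]:
    """Plausibility of the stated dialysis status.

    A stated status below the official criteria (fewer than two sessions, or
    under 24 h of CVVHD, in the prior week) and albumin dialysis — which is
    not a kidney replacement method — both need consultation.  A stated
    renal replacement that is incompatible with the creatinine picture
    (normal creatinine with no recent dialysis on record) is flagged as
    implausible, typically an order-creation mistake.
    """
    stated = request.stated_dialysis
    if stated is None:
        return []
    codes: list[ReasonCode] = []
    if stated.mode == DialysisMode.INTERMITTENT and stated.sessions_prior_week < 2:
        codes.append(ReasonCode.DIALYSIS_CRITERIA_NOT_MET)
    elif stated.mode == DialysisMode.CVVHD and stated.cvvhd_hours_prior_week < 24.0:
        codes.append(ReasonCode.DIALYSIS_CRITERIA_NOT_MET)
    if stated.mode == DialysisMode.ALBUMIN_DIALYSIS:
        codes.append(ReasonCode.ALBUMIN_DIALYSIS_NOT_RRT)
    if (
        stated.mode in (DialysisMode.INTERMITTENT, DialysisMode.CVVHD)
        and request.panel.creatinine < config.implausible_creatinine_max_umol
    ):
        # patients under renal replacement carry elevated creatinine; an
        # unremarkable value alongside a stated RRT points to an
        # order-creation mistake regardless of what the history shows
        codes.append(ReasonCode.DIALYSIS_IMPLAUSIBLE)
    return codes


def check_anticoagulation(
    request: MeldRequest,
    history: Optional[PatientHistory] = None,
    config: VerificationConfig = VerificationConfig(),
) -> list[ReasonCode]:
    """Anticoagulation influence on the INR.

    Vitamin-K antagonists and direct oral anticoagulants inflate the INR;
    with such a drug stated and the INR above the impact threshold the score
    would misrepresent liver function and must not be reported.  When no
    INR-active drug is stated, an INR elevated against the patient's latest
    non-anticoagulated baseline *while the liver synthesis markers (albumin,
    fibrinogen, cholinesterase) are unchanged* suggests undeclared
    anticoagulation rather than deterioration and is flagged likewise.
    Heparin with an unchanged INR passes.
    """
    inr = request.panel.inr
    if inr is None:
        return []
    if request.stated_anticoagulation in (Anticoagulation.VKA, Anticoagulation.DOAC):
        if inr > config.inr_absolute_impact:
            return [ReasonCode.ANTICOAGULATION_INR_IMPACT]
        return []
    if history is None:
        return []
    baseline = history.baseline_without_anticoagulation(request.request_time)
    if baseline is None:
        return []
    if inr <= config.inr_baseline_ratio * baseline.panel.inr:
        return []
    # INR elevated: corroborate with at least one stable synthesis marker
    tol = config.synthesis_marker_tolerance
    compared = 0
    stable = 0
    for marker in ("albumin", "fibrinogen", "cholinesterase"):
        cur = getattr(request.panel, marker)
        base = getattr(baseline.panel, marker)
        if cur is not None and base is not None:
            compared += 1
            if abs(cur / base - 1.0) <= tol:
                stable += 1
    if compared and stable == compared:
        return [ReasonCode.ANTICOAGULATION_INR_IMPACT]
    return []


def delta_check(
    current: AnalytePanel,
    history: Optional[PatientHistory] = None,
    config: VerificationConfig = VerificationConfig(),
    *,
    when: Optional[datetime] = None,
) -> list[ReasonCode]:
    """Flag improbable analyte changes against the most recent prior result.

    Relative-change thresholds per analyte (creatinine, bilirubin, INR)
    within a lookback window; an empty history yields no flag.
    """
    if history is None or not history.prior:
        return []
    when = when or history.prior[-1].timestamp + timedelta(seconds=1)
    prior = history.latest_before(when)
    if prior is None:
        return []
    if when - prior.timestamp > timedelta(days=config.delta_lookback_days):
        return []
    thresholds = {
        "creatinine": config.delta_creatinine,
        "bilirubin": config.delta_bilirubin,
        "inr": config.delta_inr,
    }
    for name, threshold in thresholds.items():
        cur = getattr(current, name)
        base = getattr(prior.panel, name)
        if cur is None or base is None:
            continue
        if abs(cur - base) / base > threshold:
            return [ReasonCode.DELTA_CHECK_FAIL]
    return []


def resolve_inr(
    clotting: ClottingResult,
    history: Optional[PatientHistory] = None,
    policy: str = "last_determinable",
    config: VerificationConfig = VerificationConfig(),
    *,
    when: Optional[datetime] = None,
) -> tuple[Optional[float], list[ReasonCode]]:
    """Resolve the INR to use for scoring from the clotting measurement.

    Returns ``(inr, codes)``; ``inr`` is None when reporting is blocked.
    A detected clot passes its INR through unflagged.  A manual curve read
    yields a usable INR but is flagged for physician review.  When no clot
    formed within the instrument timeout the INR is undeterminable and the
    policy decides: ``last_determinable`` substitutes the patient's most
    recent measured INR (the allocation auditors' accepted practice),
    ``table_max`` substitutes the INR at the maximum of the laboratory's
    conversion table, and ``block`` refuses to report.
    """
    if policy not in ("last_determinable", "table_max", "block"):
        raise ValueError(f"unknown INR policy {policy!r}")
    if clotting.status == ClottingStatus.CLOT_DETECTED:
        return clotting.inr, []
    if clotting.status == ClottingStatus.MANUAL_CURVE_READ:
        return clotting.inr, [ReasonCode.INR_UNDETERMINABLE]
    # no clot within timeout
    if policy == "last_determinable":
        prior = None
        if history is not None:
            prior = history.latest_inr_before(when or datetime.max)
        return prior, [ReasonCode.INR_UNDETERMINABLE]
    if policy == "table_max":
        return config.conversion_table_max_inr, [ReasonCode.INR_UNDETERMINABLE]
    return None, [ReasonCode.INR_UNDETERMINABLE]


# ---------------------------------------------------------------------------
# aggregate validation
# ---------------------------------------------------------------------------

def _score_request(
    panel: AnalytePanel,
    dialysis: Optional[DialysisStatus],
    config: VerificationConfig,
) -> MeldResult:
    result = compute_meld(panel, dialysis or DialysisStatus(), config.coefficients)
    return compute_meld_na(result, panel.sodium, config.coefficients)


def _narrative(disposition: Disposition, reasons: Sequence[ReasonCode]) -> str:
    if not reasons:
        return "All verification rules passed; score released."
    listed = ", ".join(c.value for c in reasons)
    if disposition == Disposition.INVALID:
        return f"Reporting blocked ({listed}); a new specimen or resolution is required."
    if disposition == Disposition.NEEDS_CONSULTATION:
        return f"Escalated to laboratory-physician consultation ({listed})."
    return f"Score released after correction ({listed})."


def validate(
    request: MeldRequest,
    history: Optional[PatientHistory] = None,
    config: VerificationConfig = VerificationConfig(),
) -> ValidationVerdict:
    """Run the full verification sequence on one MELD request.

    Stages run in fixed order: order integrity, preanalytics, INR
    resolution, dialysis plausibility, anticoagulation, delta check.  Any
    blocking code (or an unresolvable INR) yields INVALID with no score;
    consultation codes yield NEEDS_CONSULTATION; a clean pass yields VALID
    with the computed :class:`~meldqa.scoring.MeldResult` (MELD-Na attached
    when sodium was measured).
    """
    codes: list[ReasonCode] = []
    codes += check_order_integrity(request, config)
    codes += check_preanalytics(request, config)

    inr, inr_codes = resolve_inr(
        request.clotting,
        history,
        config.inr_policy,
        config,
        when=request.request_time,
    )
    codes += inr_codes
    blocked_inr = inr is None

    panel = request.panel
    if not blocked_inr and panel.inr != inr:
        panel = replace(panel, inr=inr)
    effective = replace(request, panel=panel) if panel is not request.panel else request

    codes += check_dialysis(effective, history, config)
    if not blocked_inr:
        codes += check_anticoagulation(effective, history, config)
        codes += delta_check(panel, history, config, when=request.request_time)

    # preserve first occurrence order
    seen: set[ReasonCode] = set()
    ordered = [c for c in codes if not (c in seen or seen.add(c))]

    if blocked_inr or any(c in BLOCKING_CODES for c in ordered):
        disposition = Disposition.INVALID
        result = None
    elif ordered:
        disposition = Disposition.NEEDS_CONSULTATION
        result = None
    else:
        disposition = Disposition.VALID
        result = _score_request(panel, request.stated_dialysis, config)

    return ValidationVerdict(
        disposition=disposition,
        reasons=tuple(ordered),
        result=result,
        narrative=_narrative(disposition, ordered),
    )


_DIALYSIS_REASONS = frozenset(
    {
        ReasonCode.MISSING_DIALYSIS_STATUS,
        ReasonCode.DIALYSIS_CRITERIA_NOT_MET,
        ReasonCode.DIALYSIS_IMPLAUSIBLE,
        ReasonCode.ALBUMIN_DIALYSIS_NOT_RRT,
    }
)


def _dialysis_repr(status: Optional[DialysisStatus]) -> dict:
    if status is None:
        return {"mode": None}
    return {
        "mode": status.mode.value,
        "sessions_prior_week": status.sessions_prior_week,
        "cvvhd_hours_prior_week": status.cvvhd_hours_prior_week,
    }


def apply_correction(
    request: MeldRequest,
    verdict: ValidationVerdict,
    confirmed_dialysis: DialysisStatus,
    history: Optional[PatientHistory] = None,
    config: VerificationConfig = VerificationConfig(),
) -> ValidationVerdict:
    """Re-score a consultation case with the sender-confirmed dialysis status.

    Applicable to NEEDS_CONSULTATION verdicts carrying a dialysis reason.
    The confirmed status replaces the stated one; the plausibility heuristic
    is not re-applied (the consultation is its resolution), but a confirmed
    status that itself fails the official criteria keeps the verdict in
    consultation.  A confirmed status identical to the stated one changes
    nothing.
    """
    if verdict.disposition != Disposition.NEEDS_CONSULTATION:
        raise ValueError("corrections apply only to NEEDS_CONSULTATION verdicts")
    if not any(c in _DIALYSIS_REASONS for c in verdict.reasons):
        raise ValueError("verdict carries no dialysis reason to correct")
    if confirmed_dialysis == request.stated_dialysis:
        return verdict

    if confirmed_dialysis.mode == DialysisMode.ALBUMIN_DIALYSIS:
        return verdict
    if (
        confirmed_dialysis.mode
        in (DialysisMode.INTERMITTENT, DialysisMode.CVVHD)
        and not confirmed_dialysis.qualifies_for_override()
    ):
        return verdict

    inr, _ = resolve_inr(
        request.clotting, history, config.inr_policy, config, when=request.request_time
    )
    if inr is None:
        return verdict
    panel = request.panel if request.panel.inr == inr else replace(request.panel, inr=inr)
    result = _score_request(panel, confirmed_dialysis, config)
    reasons = tuple(verdict.reasons) + (ReasonCode.DIALYSIS_STATUS_CORRECTED,)
    corrections = dict(verdict.corrections)
    corrections["dialysis_status"] = (
        _dialysis_repr(request.stated_dialysis),
        _dialysis_repr(confirmed_dialysis),
    )
    return ValidationVerdict(
        disposition=Disposition.CORRECTED_VALID,
        reasons=reasons,
        corrections=corrections,
        result=result,
        narrative=_narrative(Disposition.CORRECTED_VALID, reasons),
    )
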