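"""Synthetic MELD-request cohorts with calibrated error injection.

Generates laboratory MELD requests whose marginal analyte distributions,
dialysis prevalence and anticoagulation mix resemble a tertiary-care liver
transplant evaluation cohort, and injects each of the verification error
categories at configurable per-request probabilities.  A clean request is
constructed to pass every verification rule; an injected request is a clean
request minimally mutated so that the targeted rule — and, as the first
firing rule, only it — trips.  Together with per-request truth labels this
makes the whole verification pipeline testable end-to-end without any
patient data.

Analyte marginals are log-normal, loosely calibrated so that medians sit near
bilirubin 32 umol/L, creatinine 86 umol/L and INR 1.3 with ranges spanning
roughly two orders of magnitude at cohort sizes of a few thousand — the
shape of a real MELD workload — and are documented as a calibration, not an
estimate.  Patients recur with geometrically distributed request counts
(about five requests per patient), which builds the histories the delta and
anticoagulation baselines need.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, datetime, timedelta
from typing import Optional

import numpy as np

from .config import VerificationConfig
from .scoring import (
    AnalytePanel,
    DialysisMode,
    DialysisStatus,
    compute_meld,
    compute_meld_na,
)
from .verification import (
    Anticoagulation,
    ClottingResult,
    ClottingStatus,
    Disposition,
    HistoryEntry,
    MeldRequest,
    PatientHistory,
    ReasonCode,
    Specimen,
    TubeType,
    ValidationVerdict,
    validate,
)

__all__ = [
    "SimulationConfig",
    "CohortBundle",
    "simulate_cohort",
    "inject_error",
    "run_pipeline",
    "DEFAULT_ERROR_RATES",
]

#: Default per-request injection probabilities: observed category counts in a
#: six-year workload of 7,270 requests, divided by 7,270.  They sum to
#: 193/7270 (the overall flagged fraction, 2.7%).
DEFAULT_ERROR_RATES: dict[ReasonCode, float] = {
    ReasonCode.MATERIAL_ERROR: 56 / 7270,
    ReasonCode.UNDERFILLED_CITRATE: 7 / 7270,
    ReasonCode.PATIENT_MISIDENTIFICATION: 7 / 7270,
    ReasonCode.PROLONGED_PREANALYTIC: 5 / 7270,
    ReasonCode.PELD_REQUIRED: 5 / 7270,
    ReasonCode.CITRATE_CLOTTED: 3 / 7270,
    ReasonCode.LATE_LAB_ENTRANCE: 2 / 7270,
    ReasonCode.MISSING_DIALYSIS_STATUS: 4 / 7270,
    ReasonCode.ANTICOAGULATION_INR_IMPACT: 24 / 7270,
    ReasonCode.DIALYSIS_CRITERIA_NOT_MET: 8 / 7270,
    ReasonCode.DIALYSIS_IMPLAUSIBLE: 26 / 7270,
    ReasonCode.ALBUMIN_DIALYSIS_NOT_RRT: 1 / 7270,
    ReasonCode.INR_UNDETERMINABLE: 42 / 7270,
    ReasonCode.DELTA_CHECK_FAIL: 3 / 7270,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort generator settings.

    ``error_rates`` are per-request injection probabilities by category; at
    most one category is injected per request and the probabilities must sum
    to at most 1.  ``repeat_mean_requests`` sets the geometric mean number
    of requests per patient (about 7,270/1,494 ~ 4.9 in a six-year
    workload).
    """

    n_requests: int = 1000
    seed: int = 0
    # log-normal parameters on the umol/L scale
    bilirubin_mu: float = np.log(32.0)
    bilirubin_sigma: float = 1.1
    creatinine_mu: float = np.log(86.0)
    creatinine_sigma: float = 0.45
    # INR = 0.8 + lognormal shift
    inr_shift: float = 0.8
    inr_mu: float = np.log(0.5)
    inr_sigma: float = 0.6
    dialysis_prevalence: float = 0.077
    anticoagulation_mix: dict = field(
        default_factory=lambda: {
            Anticoagulation.NONE: 1.0 - 524 / 7270,
            Anticoagulation.HEPARIN: 488 / 7270,
            Anticoagulation.VKA: 33 / 7270,
            Anticoagulation.DOAC: 1 / 7270,
            Anticoagulation.FONDAPARINUX: 2 / 7270,
        }
    )
    error_rates: dict = field(default_factory=lambda: dict(DEFAULT_ERROR_RATES))
    repeat_mean_requests: float = 7270 / 1494
    start: datetime = datetime(2012, 11, 1, 8, 0)
    multi_error: bool = False  # allow >1 injected category per request

    def __post_init__(self) -> None:
        total = sum(self.error_rates.values())
        if any(not (0.0 <= p <= 1.0) for p in self.error_rates.values()):
            raise ValueError("error rates must lie in [0, 1]")
        if total > 1.0 + 1e-12:
            raise ValueError(f"error rates sum to {total:.3f} > 1")
        if not (0.0 <= self.dialysis_prevalence <= 1.0):
            raise ValueError("dialysis prevalence must lie in [0, 1]")
        if self.n_requests < 0:
            raise ValueError("n_requests must be >= 0")

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        """Build a config from a parsed YAML/JSON mapping.

        String keys in ``error_rates`` and ``anticoagulation_mix`` are
        coerced to their enums; ``start`` accepts an ISO 8601 string.
        """
        data = dict(data)
        if "error_rates" in data:
            data["error_rates"] = {
                ReasonCode(k) if not isinstance(k, ReasonCode) else k: float(v)
                for k, v in data["error_rates"].items()
            }
        if "anticoagulation_mix" in data:
            data["anticoagulation_mix"] = {
                Anticoagulation(k) if not isinstance(k, Anticoagulation) else k: float(v)
                for k, v in data["anticoagulation_mix"].items()
            }
        if isinstance(data.get("start"), str):
            data["start"] = datetime.fromisoformat(data["start"])
        return cls(**data)


@dataclass
class CohortBundle:
    """A simulated cohort: requests, per-patient histories, truth labels.

    ``truth`` maps order id to the injected category name ("clean" when
    nothing was injected).  ``histories`` hold each patient's prior
    validated results consistent with the request timeline; entries are
    appended as the pipeline releases results.
    """

    requests: list[MeldRequest]
    histories: dict[str, PatientHistory]
    truth: dict[str, str]


# ---------------------------------------------------------------------------
# clean-request generation
# ---------------------------------------------------------------------------

@dataclass
class _PatientProfile:
    patient_id: str
    birth_date: date
    sex: str
    bilirubin: float
    creatinine: float
    inr: float
    sodium: float
    albumin: float
    fibrinogen: float
    cholinesterase: float
    dialysis: DialysisStatus
    anticoagulation: Anticoagulation


def _draw_profile(rng: np.random.Generator, cfg: SimulationConfig, idx: int) -> _PatientProfile:
    sex = "F" if rng.random() < 2633 / 7270 else "M"
    age = int(rng.integers(18, 80))
    birth = cfg.start - timedelta(days=int(age * 365.25) + int(rng.integers(0, 365)))
    on_dialysis = rng.random() < cfg.dialysis_prevalence
    if on_dialysis:
        if rng.random() < 0.7:
            dialysis = DialysisStatus(DialysisMode.INTERMITTENT, sessions_prior_week=int(rng.integers(2, 5)))
        else:
            dialysis = DialysisStatus(DialysisMode.CVVHD, cvvhd_hours_prior_week=float(rng.integers(24, 169)))
        # renal-replacement patients carry an elevated creatinine so the
        # stated status is congruous with the laboratory picture
        creatinine = float(np.exp(rng.normal(np.log(300.0), 0.3)))
        creatinine = max(creatinine, 150.0)
    else:
        dialysis = DialysisStatus()
        creatinine = float(np.exp(rng.normal(cfg.creatinine_mu, cfg.creatinine_sigma)))
    modes = list(cfg.anticoagulation_mix)
    probs = np.array([cfg.anticoagulation_mix[m] for m in modes], dtype=float)
    anticoag = modes[int(rng.choice(len(modes), p=probs / probs.sum()))]
    # clean requests under VKA/DOAC keep the INR below the impact threshold
    inr = cfg.inr_shift + float(np.exp(rng.normal(cfg.inr_mu, cfg.inr_sigma)))
    if anticoag in (Anticoagulation.VKA, Anticoagulation.DOAC):
        inr = min(inr, 1.35)
    return _PatientProfile(
        patient_id=f"P{idx:05d}",
        birth_date=birth.date(),
        sex=sex,
        bilirubin=float(np.exp(rng.normal(cfg.bilirubin_mu, cfg.bilirubin_sigma))),
        creatinine=creatinine,
        inr=inr,
        sodium=float(rng.normal(135.0, 4.0)),
        albumin=float(rng.normal(32.0, 4.0)),
        fibrinogen=float(max(rng.normal(2.5, 0.6), 0.4)),
        cholinesterase=float(max(rng.normal(3.5, 1.0), 0.5)),
        dialysis=dialysis,
        anticoagulation=anticoag,
    )


def _jitter(rng: np.random.Generator, value: float, rel: float, low: float = 1e-6) -> float:
    return max(value * float(rng.uniform(1.0 - rel, 1.0 + rel)), low)


def _clean_request(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    profile: _PatientProfile,
    order_idx: int,
    when: datetime,
) -> MeldRequest:
    """One request that passes every verification rule by construction.

    Analytes jitter multiplicatively around the patient's profile values, so
    consecutive results stay well inside the delta-check and
    anticoagulation-baseline bands.
    """
    panel = AnalytePanel(
        bilirubin=_jitter(rng, profile.bilirubin, 0.15),
        creatinine=_jitter(rng, profile.creatinine, 0.15),
        inr=round(_jitter(rng, profile.inr, 0.08), 2),
        sodium=round(_jitter(rng, profile.sodium, 0.02), 1),
        albumin=round(_jitter(rng, profile.albumin, 0.08), 1),
        fibrinogen=round(_jitter(rng, profile.fibrinogen, 0.08), 2),
        cholinesterase=round(_jitter(rng, profile.cholinesterase, 0.08), 2),
    )
    order_id = f"O{order_idx:06d}"
    draw = when + timedelta(minutes=int(rng.integers(5, 30)))
    arrival = draw + timedelta(minutes=int(rng.integers(20, 120)))
    specimens = (
        Specimen(
            specimen_id=f"{order_id}-S",
            tube_type=TubeType.SERUM,
            labeled_patient_id=profile.patient_id,
            draw_time=draw,
            lab_arrival_time=arrival,
        ),
        Specimen(
            specimen_id=f"{order_id}-C",
            tube_type=TubeType.CITRATE,
            labeled_patient_id=profile.patient_id,
            draw_time=draw,
            lab_arrival_time=arrival,
            fill_ratio=round(float(rng.uniform(0.92, 1.05)), 2),
        ),
    )
    pt = 11.0 * panel.inr  # nominal prothrombin time for a normal ~11 s
    clotting = ClottingResult(
        status=ClottingStatus.CLOT_DETECTED, pt_seconds=round(pt, 1), inr=panel.inr
    )
    return MeldRequest(
        order_id=order_id,
        patient_id=profile.patient_id,
        birth_date=profile.birth_date,
        sex=profile.sex,
        request_time=when,
        specimens=specimens,
        panel=panel,
        clotting=clotting,
        stated_dialysis=profile.dialysis,
        stated_anticoagulation=profile.anticoagulation,
    )


# ---------------------------------------------------------------------------
# error injection
# ---------------------------------------------------------------------------

def inject_error(
    request: MeldRequest,
    category: ReasonCode,
    rng: np.random.Generator,
    config: VerificationConfig = VerificationConfig(),
) -> MeldRequest:
    """Minimally mutate a clean request so the targeted rule fires.

    The targeted rule is guaranteed to be the *first* rule that fires under
    the given thresholds, so the verdict's first reason code equals the
    injected category; a large injected excursion may additionally trip a
    downstream check (e.g. the delta check) as a secondary code.
    """
    if category == ReasonCode.MATERIAL_ERROR:
        # drop the citrate tube or substitute unacceptable material
        if rng.random() < 0.5:
            specimens = request.specimens_of_type(TubeType.SERUM)
        else:
            specimens = tuple(
                replace(s, tube_type=TubeType.LITHIUM_HEPARIN)
                if s.tube_type == TubeType.SERUM
                else s
                for s in request.specimens
            )
        return replace(request, specimens=specimens)

    if category == ReasonCode.UNDERFILLED_CITRATE:
        ratio = round(float(rng.uniform(0.4, config.citrate_underfill_ratio - 0.05)), 2)
        specimens = tuple(
            replace(s, fill_ratio=ratio) if s.tube_type == TubeType.CITRATE else s
            for s in request.specimens
        )
        return replace(request, specimens=specimens)

    if category == ReasonCode.PATIENT_MISIDENTIFICATION:
        wrong = request.patient_id + "X"
        specimens = (
            replace(request.specimens[0], labeled_patient_id=wrong),
        ) + request.specimens[1:]
        return replace(request, specimens=specimens)

    if category == ReasonCode.PROLONGED_PREANALYTIC:
        extra = timedelta(hours=float(rng.uniform(config.preanalytic_max_hours + 0.5, 12.0)))
        specimens = tuple(
            replace(s, lab_arrival_time=s.draw_time + extra) for s in request.specimens
        )
        return replace(request, specimens=specimens)

    if category == ReasonCode.PELD_REQUIRED:
        age = int(rng.integers(1, 7))
        birth = (request.request_time - timedelta(days=age * 366)).date()
        return replace(request, birth_date=birth)

    if category == ReasonCode.CITRATE_CLOTTED:
        specimens = tuple(
            replace(s, clotted=True) if s.tube_type == TubeType.CITRATE else s
            for s in request.specimens
        )
        return replace(request, specimens=specimens)

    if category == ReasonCode.LATE_LAB_ENTRANCE:
        # drawn and sent in long after the order was created; transport
        # itself stays inside the stability window
        shift = timedelta(hours=float(rng.uniform(config.late_entrance_hours + 2.0, 72.0)))
        specimens = tuple(
            replace(s, draw_time=s.draw_time + shift, lab_arrival_time=s.lab_arrival_time + shift)
            for s in request.specimens
        )
        return replace(request, specimens=specimens)

    if category == ReasonCode.SPLIT_ORDER:
        gap = timedelta(hours=float(rng.uniform(config.co_draw_tolerance_hours + 0.5, 3.0)))
        specimens = tuple(
            replace(s, draw_time=s.draw_time + gap, lab_arrival_time=s.lab_arrival_time + gap)
            if s.tube_type == TubeType.CITRATE
            else s
            for s in request.specimens
        )
        return replace(request, specimens=specimens)

    if category == ReasonCode.MISSING_DIALYSIS_STATUS:
        return replace(request, stated_dialysis=None)

    if category == ReasonCode.DIALYSIS_CRITERIA_NOT_MET:
        if rng.random() < 0.5:
            stated = DialysisStatus(DialysisMode.INTERMITTENT, sessions_prior_week=1)
        else:
            stated = DialysisStatus(
                DialysisMode.CVVHD, cvvhd_hours_prior_week=float(rng.integers(4, 24))
            )
        # keep creatinine clearly elevated so only the interval criterion fails
        panel = replace(
            request.panel,
            creatinine=max(request.panel.creatinine, config.implausible_creatinine_max_umol * 2.5),
        )
        return replace(request, stated_dialysis=stated, panel=panel)

    if category == ReasonCode.DIALYSIS_IMPLAUSIBLE:
        # order-creation mistake: renal replacement stated for a patient with
        # unremarkable creatinine and no dialysis on record
        stated = DialysisStatus(DialysisMode.INTERMITTENT, sessions_prior_week=2)
        panel = replace(
            request.panel,
            creatinine=float(rng.uniform(45.0, config.implausible_creatinine_max_umol * 0.9)),
        )
        return replace(request, stated_dialysis=stated, panel=panel)

    if category == ReasonCode.ALBUMIN_DIALYSIS_NOT_RRT:
        return replace(
            request, stated_dialysis=DialysisStatus(DialysisMode.ALBUMIN_DIALYSIS)
        )

    if category == ReasonCode.ANTICOAGULATION_INR_IMPACT:
        inr = round(float(rng.uniform(max(config.inr_absolute_impact + 0.3, 1.8), 3.5)), 2)
        panel = replace(request.panel, inr=inr)
        clotting = ClottingResult(
            status=ClottingStatus.CLOT_DETECTED, pt_seconds=round(11.0 * inr, 1), inr=inr
        )
        return replace(
            request,
            panel=panel,
            clotting=clotting,
            stated_anticoagulation=Anticoagulation.VKA,
            anticoagulant_name="phenprocoumon",
        )

    if category == ReasonCode.INR_UNDETERMINABLE:
        panel = replace(request.panel, inr=None)
        clotting = ClottingResult(
            status=ClottingStatus.NO_CLOT_WITHIN_TIMEOUT, timeout_seconds=315.0
        )
        return replace(request, panel=panel, clotting=clotting)

    if category == ReasonCode.DELTA_CHECK_FAIL:
        # implausible creatinine excursion vs the prior result without any
        # dialysis that could explain it
        factor = 1.0 + config.delta_creatinine + float(rng.uniform(1.0, 3.0))
        panel = replace(request.panel, creatinine=request.panel.creatinine * factor)
        return replace(request, panel=panel)

    raise KeyError(f"unknown injection category {category!r}")


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def _baseline_entry(
    profile: _PatientProfile, first_request: datetime, coeffs
) -> HistoryEntry:
    """A pre-cohort validated diagnostic seeding the patient's history.

    Transplant-evaluation patients have prior laboratory results on file;
    this gives the delta check and the anticoagulation baseline something to
    compare against from the first in-cohort request.
    """
    panel = AnalytePanel(
        bilirubin=round(profile.bilirubin, 1),
        creatinine=round(profile.creatinine, 1),
        inr=round(profile.inr, 2),
        sodium=round(profile.sodium, 1),
        albumin=round(profile.albumin, 1),
        fibrinogen=round(profile.fibrinogen, 2),
        cholinesterase=round(profile.cholinesterase, 2),
    )
    result = compute_meld_na(
        compute_meld(panel, profile.dialysis, coeffs), panel.sodium, coeffs
    )
    return HistoryEntry(
        timestamp=first_request - timedelta(days=2),
        panel=panel,
        dialysis=profile.dialysis,
        anticoagulation=profile.anticoagulation,
        result=result,
    )


def simulate_cohort(config: SimulationConfig) -> CohortBundle:
    """Generate a reproducible cohort of MELD requests with truth labels.

    Requests are laid out chronologically (a few per day); each patient
    recurs a geometric number of times, repeat requests at least a day
    apart, and starts with one pre-cohort validated result in their history.
    At most one error category is injected per request unless
    ``multi_error`` is set.
    """
    rng = np.random.default_rng(config.seed)
    requests: list[MeldRequest] = []
    truth: dict[str, str] = {}
    profiles: dict[str, _PatientProfile] = {}
    first_time: dict[str, datetime] = {}

    categories = list(config.error_rates)
    probs = np.array([config.error_rates[c] for c in categories], dtype=float)
    p_clean = max(1.0 - probs.sum(), 0.0)

    profile: Optional[_PatientProfile] = None
    remaining = 0
    patient_idx = 0
    next_time: dict[str, datetime] = {}
    when = config.start

    for i in range(config.n_requests):
        if remaining <= 0:
            profile = _draw_profile(rng, config, patient_idx)
            profiles[profile.patient_id] = profile
            patient_idx += 1
            # geometric(p) on {1, 2, ...} with mean repeat_mean_requests
            remaining = int(rng.geometric(1.0 / config.repeat_mean_requests))
        remaining -= 1

        when = when + timedelta(minutes=int(rng.integers(60, 600)))
        start = max(when, next_time.get(profile.patient_id, when))
        request = _clean_request(rng, config, profile, i, start)
        next_time[profile.patient_id] = start + timedelta(days=1)
        first_time.setdefault(profile.patient_id, start)

        u = rng.random()
        label = "clean"
        if u >= p_clean:
            acc = p_clean
            chosen = None
            for cat, p in zip(categories, probs):
                acc += p
                if u < acc:
                    chosen = cat
                    break
            if chosen is not None:
                request = inject_error(request, chosen, rng)
                label = chosen.value
                if config.multi_error and rng.random() < 0.05:
                    other = categories[int(rng.integers(0, len(categories)))]
                    if other != chosen:
                        request = inject_error(request, other, rng)
                        label = f"{label}+{other.value}"
        requests.append(request)
        truth[request.order_id] = label

    coeffs = VerificationConfig().coefficients
    histories = {
        pid: PatientHistory(
            pid, [_baseline_entry(profiles[pid], first_time[pid], coeffs)]
        )
        for pid in profiles
        if pid in first_time
    }
    return CohortBundle(requests=requests, histories=histories, truth=truth)


def run_pipeline(
    bundle: CohortBundle,
    config: VerificationConfig = VerificationConfig(),
) -> list[ValidationVerdict]:
    """Validate every request in order, growing histories as results release.

    Requests are processed chronologically; released results (VALID) are
    appended to the patient's history so later requests see realistic
    baselines, mirroring routine operation.  The bundle's histories are not
    modified: the pipeline works on copies, so repeated runs are identical.
    """
    working = {
        pid: PatientHistory(pid, list(h.prior)) for pid, h in bundle.histories.items()
    }
    verdicts: dict[str, ValidationVerdict] = {}
    for request in sorted(bundle.requests, key=lambda r: (r.request_time, r.order_id)):
        history = working.setdefault(
            request.patient_id, PatientHistory(request.patient_id)
        )
        verdict = validate(request, history, config)
        verdicts[request.order_id] = verdict
        if verdict.disposition == Disposition.VALID:
            history.append(
                HistoryEntry(
                    timestamp=request.request_time,
                    panel=request.panel,
                    dialysis=request.stated_dialysis or DialysisStatus(),
                    anticoagulation=request.stated_anticoagulation,
                    result=verdict.result,
                )
            )
    return [verdicts[r.order_id] for r in bundle.requests]
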