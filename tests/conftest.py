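"""Shared fixtures: a clean request that passes every rule, plus history."""

from datetime import date, datetime, timedelta

import pytest

from meldqa import (
    AnalytePanel,
    Anticoagulation,
    ClottingResult,
    ClottingStatus,
    DialysisStatus,
    HistoryEntry,
    MeldRequest,
    PatientHistory,
    Specimen,
    TubeType,
    VerificationConfig,
    compute_meld,
)

T0 = datetime(2015, 6, 1, 8, 0)


def make_clean_request(
    *,
    order_id: str = "O000001",
    patient_id: str = "P00001",
    birth_date: date = date(1970, 3, 15),
    bilirubin: float = 50.0,
    creatinine: float = 90.0,
    inr: float = 1.3,
    sodium: float = 136.0,
    albumin: float = 32.0,
    fibrinogen: float = 2.4,
    cholinesterase: float = 3.1,
    dialysis: DialysisStatus = DialysisStatus(),
    anticoagulation: Anticoagulation = Anticoagulation.NONE,
    request_time: datetime = T0,
    clotting_status: ClottingStatus = ClottingStatus.CLOT_DETECTED,
) -> MeldRequest:
    """A request constructed to pass every verification rule."""
    panel = AnalytePanel(
        bilirubin=bilirubin,
        creatinine=creatinine,
        inr=inr if clotting_status != ClottingStatus.NO_CLOT_WITHIN_TIMEOUT else None,
        sodium=sodium,
        albumin=albumin,
        fibrinogen=fibrinogen,
        cholinesterase=cholinesterase,
    )
    draw = request_time + timedelta(minutes=15)
    arrival = draw + timedelta(hours=1)
    specimens = (
        Specimen(
            specimen_id=f"{order_id}-S",
            tube_type=TubeType.SERUM,
            labeled_patient_id=patient_id,
            draw_time=draw,
            lab_arrival_time=arrival,
        ),
        Specimen(
            specimen_id=f"{order_id}-C",
            tube_type=TubeType.CITRATE,
            labeled_patient_id=patient_id,
            draw_time=draw,
            lab_arrival_time=arrival,
            fill_ratio=0.98,
        ),
    )
    clotting = ClottingResult(
        status=clotting_status,
        pt_seconds=None if panel.inr is None else 11.0 * panel.inr,
        inr=panel.inr,
    )
    return MeldRequest(
        order_id=order_id,
        patient_id=patient_id,
        birth_date=birth_date,
        sex="M",
        request_time=request_time,
        specimens=specimens,
        panel=panel,
        clotting=clotting,
        stated_dialysis=dialysis,
        stated_anticoagulation=anticoagulation,
    )


def make_history(
    patient_id: str = "P00001",
    *,
    when: datetime = T0 - timedelta(days=2),
    bilirubin: float = 50.0,
    creatinine: float = 90.0,
    inr: float = 1.3,
    albumin: float = 32.0,
    fibrinogen: float = 2.4,
    cholinesterase: float = 3.1,
    dialysis: DialysisStatus = DialysisStatus(),
    anticoagulation: Anticoagulation = Anticoagulation.NONE,
) -> PatientHistory:
    panel = AnalytePanel(
        bilirubin=bilirubin,
        creatinine=creatinine,
        inr=inr,
        albumin=albumin,
        fibrinogen=fibrinogen,
        cholinesterase=cholinesterase,
    )
    entry = HistoryEntry(
        timestamp=when,
        panel=panel,
        dialysis=dialysis,
        anticoagulation=anticoagulation,
        result=compute_meld(panel, dialysis),
    )
    return PatientHistory(patient_id, [entry])


@pytest.fixture
def clean_request() -> MeldRequest:
    return make_clean_request()


@pytest.fixture
def history() -> PatientHistory:
    return make_history()


@pytest.fixture
def config() -> VerificationConfig:
    return VerificationConfig()
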