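"""Reading and writing the request, verdict and truth-label dialects.

Two request encodings are supported with identical information content:

* **CSV** — one row per request; specimen columns are prefixed ``serum_`` /
  ``citrate_`` (the two required tubes of a MELD order); analyte columns
  carry their units in the header (``bilirubin_umol_l`` ...).
* **JSON** — a list of request objects with a nested ``specimens`` array.

Verdicts serialise to a JSON report per request containing the reporting
document fields (patient and order identifiers, analytes in both unit
systems, score, dialysis status) plus disposition, reasons and corrections.
Truth labels from the simulator travel in a sidecar JSON mapping order id to
category.
"""

from __future__ import annotations

import csv
import json
from datetime import date, datetime
from pathlib import Path
from typing import Optional, Sequence, Union

from .scoring import AnalytePanel, DialysisMode, DialysisStatus
from .verification import (
    Anticoagulation,
    ClottingResult,
    ClottingStatus,
    MeldRequest,
    Specimen,
    TubeType,
    ValidationVerdict,
)

__all__ = [
    "request_to_dict",
    "request_from_dict",
    "write_requests_json",
    "read_requests_json",
    "write_requests_csv",
    "read_requests_csv",
    "write_truth_json",
    "read_truth_json",
    "write_verdicts_json",
]

PathLike = Union[str, Path]

_CSV_COLUMNS = [
    "order_id",
    "patient_id",
    "birth_date",
    "sex",
    "request_time",
    "bilirubin_umol_l",
    "creatinine_umol_l",
    "inr",
    "sodium_mmol_l",
    "albumin_g_l",
    "fibrinogen_g_l",
    "cholinesterase_ku_l",
    "clotting_status",
    "pt_seconds",
    "clotting_timeout_s",
    "dialysis_mode",
    "dialysis_sessions_prior_week",
    "cvvhd_hours_prior_week",
    "anticoagulation",
    "anticoagulant_name",
    "serum_specimen_id",
    "serum_tube_type",
    "serum_labeled_patient_id",
    "serum_draw_time",
    "serum_arrival_time",
    "serum_order_id",
    "citrate_specimen_id",
    "citrate_tube_type",
    "citrate_labeled_patient_id",
    "citrate_draw_time",
    "citrate_arrival_time",
    "citrate_order_id",
    "citrate_fill_ratio",
    "citrate_clotted",
]


# ---------------------------------------------------------------------------
# JSON request dialect
# ---------------------------------------------------------------------------

def _specimen_to_dict(s: Specimen) -> dict:
    return {
        "specimen_id": s.specimen_id,
        "tube_type": s.tube_type.value,
        "labeled_patient_id": s.labeled_patient_id,
        "draw_time": s.draw_time.isoformat(),
        "lab_arrival_time": s.lab_arrival_time.isoformat(),
        "order_id": s.order_id,
        "fill_ratio": s.fill_ratio,
        "clotted": s.clotted,
    }


def _specimen_from_dict(d: dict) -> Specimen:
    return Specimen(
        specimen_id=d["specimen_id"],
        tube_type=TubeType(d["tube_type"]),
        labeled_patient_id=d["labeled_patient_id"],
        draw_time=datetime.fromisoformat(d["draw_time"]),
        lab_arrival_time=datetime.fromisoformat(d["lab_arrival_time"]),
        order_id=d.get("order_id"),
        fill_ratio=d.get("fill_ratio"),
        clotted=bool(d.get("clotted", False)),
    )


def request_to_dict(request: MeldRequest) -> dict:
    """Serialise one request to the nested JSON object dialect."""
    panel = request.panel
    dialysis = request.stated_dialysis
    return {
        "order_id": request.order_id,
        "patient_id": request.patient_id,
        "birth_date": request.birth_date.isoformat(),
        "sex": request.sex,
        "request_time": request.request_time.isoformat(),
        "specimens": [_specimen_to_dict(s) for s in request.specimens],
        "panel": {
            "bilirubin_umol_l": panel.bilirubin,
            "creatinine_umol_l": panel.creatinine,
            "inr": panel.inr,
            "sodium_mmol_l": panel.sodium,
            "albumin_g_l": panel.albumin,
            "fibrinogen_g_l": panel.fibrinogen,
            "cholinesterase_ku_l": panel.cholinesterase,
        },
        "clotting": {
            "status": request.clotting.status.value,
            "pt_seconds": request.clotting.pt_seconds,
            "inr": request.clotting.inr,
            "timeout_seconds": request.clotting.timeout_seconds,
        },
        "stated_dialysis": None
        if dialysis is None
        else {
            "mode": dialysis.mode.value,
            "sessions_prior_week": dialysis.sessions_prior_week,
            "cvvhd_hours_prior_week": dialysis.cvvhd_hours_prior_week,
        },
        "stated_anticoagulation": request.stated_anticoagulation.value,
        "anticoagulant_name": request.anticoagulant_name,
    }


def request_from_dict(d: dict) -> MeldRequest:
    """Parse one request from the nested JSON object dialect."""
    p = d["panel"]
    panel = AnalytePanel(
        bilirubin=p["bilirubin_umol_l"],
        creatinine=p["creatinine_umol_l"],
        inr=p.get("inr"),
        sodium=p.get("sodium_mmol_l"),
        albumin=p.get("albumin_g_l"),
        fibrinogen=p.get("fibrinogen_g_l"),
        cholinesterase=p.get("cholinesterase_ku_l"),
    )
    c = d["clotting"]
    clotting = ClottingResult(
        status=ClottingStatus(c["status"]),
        pt_seconds=c.get("pt_seconds"),
        inr=c.get("inr"),
        timeout_seconds=c.get("timeout_seconds", 315.0),
    )
    sd = d.get("stated_dialysis")
    dialysis = (
        None
        if sd is None
        else DialysisStatus(
            mode=DialysisMode(sd["mode"]),
            sessions_prior_week=int(sd.get("sessions_prior_week", 0)),
            cvvhd_hours_prior_week=float(sd.get("cvvhd_hours_prior_week", 0.0)),
        )
    )
    return MeldRequest(
        order_id=d["order_id"],
        patient_id=d["patient_id"],
        birth_date=date.fromisoformat(d["birth_date"]),
        sex=d["sex"],
        request_time=datetime.fromisoformat(d["request_time"]),
        specimens=tuple(_specimen_from_dict(s) for s in d["specimens"]),
        panel=panel,
        clotting=clotting,
        stated_dialysis=dialysis,
        stated_anticoagulation=Anticoagulation(d.get("stated_anticoagulation", "none")),
        anticoagulant_name=d.get("anticoagulant_name"),
    )


def write_requests_json(requests: Sequence[MeldRequest], path: PathLike) -> None:
    Path(path).write_text(
        json.dumps([request_to_dict(r) for r in requests], indent=1)
    )


def read_requests_json(path: PathLike) -> list[MeldRequest]:
    data = json.loads(Path(path).read_text())
    return [request_from_dict(d) for d in data]


# ---------------------------------------------------------------------------
# CSV request dialect
# ---------------------------------------------------------------------------

def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (datetime, date)):
        return value.isoformat()
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _request_to_row(request: MeldRequest) -> dict:
    row = {col: "" for col in _CSV_COLUMNS}
    d = request_to_dict(request)
    row.update(
        {
            "order_id": d["order_id"],
            "patient_id": d["patient_id"],
            "birth_date": d["birth_date"],
            "sex": d["sex"],
            "request_time": d["request_time"],
            "bilirubin_umol_l": _fmt(request.panel.bilirubin),
            "creatinine_umol_l": _fmt(request.panel.creatinine),
            "inr": _fmt(request.panel.inr),
            "sodium_mmol_l": _fmt(request.panel.sodium),
            "albumin_g_l": _fmt(request.panel.albumin),
            "fibrinogen_g_l": _fmt(request.panel.fibrinogen),
            "cholinesterase_ku_l": _fmt(request.panel.cholinesterase),
            "clotting_status": request.clotting.status.value,
            "pt_seconds": _fmt(request.clotting.pt_seconds),
            "clotting_timeout_s": _fmt(request.clotting.timeout_seconds),
            "anticoagulation": request.stated_anticoagulation.value,
            "anticoagulant_name": _fmt(request.anticoagulant_name),
        }
    )
    if request.stated_dialysis is not None:
        row["dialysis_mode"] = request.stated_dialysis.mode.value
        row["dialysis_sessions_prior_week"] = _fmt(
            request.stated_dialysis.sessions_prior_week
        )
        row["cvvhd_hours_prior_week"] = _fmt(
            request.stated_dialysis.cvvhd_hours_prior_week
        )
    # the serum_/citrate_ slots hold the first specimen of each required
    # kind; a substituted tube (e.g. lithium heparin instead of serum) stays
    # in its slot with its actual tube_type
    slots: dict[str, Optional[Specimen]] = {"serum": None, "citrate": None}
    leftovers = []
    for s in request.specimens:
        if s.tube_type == TubeType.SERUM and slots["serum"] is None:
            slots["serum"] = s
        elif s.tube_type == TubeType.CITRATE and slots["citrate"] is None:
            slots["citrate"] = s
        else:
            leftovers.append(s)
    for s in leftovers:
        if slots["serum"] is None:
            slots["serum"] = s
        elif slots["citrate"] is None:
            slots["citrate"] = s
    for prefix, s in slots.items():
        if s is None:
            continue
        row[f"{prefix}_specimen_id"] = s.specimen_id
        row[f"{prefix}_tube_type"] = s.tube_type.value
        row[f"{prefix}_labeled_patient_id"] = s.labeled_patient_id
        row[f"{prefix}_draw_time"] = s.draw_time.isoformat()
        row[f"{prefix}_arrival_time"] = s.lab_arrival_time.isoformat()
        row[f"{prefix}_order_id"] = _fmt(s.order_id)
        if prefix == "citrate":
            row["citrate_fill_ratio"] = _fmt(s.fill_ratio)
            row["citrate_clotted"] = _fmt(s.clotted)
    return row


def _opt_float(cell: str) -> Optional[float]:
    return float(cell) if cell not in ("", None) else None


def _row_to_request(row: dict) -> MeldRequest:
    specimens = []
    for prefix in ("serum", "citrate"):
        if not row.get(f"{prefix}_specimen_id"):
            continue
        specimens.append(
            Specimen(
                specimen_id=row[f"{prefix}_specimen_id"],
                tube_type=TubeType(row.get(f"{prefix}_tube_type") or prefix),
                labeled_patient_id=row[f"{prefix}_labeled_patient_id"],
                draw_time=datetime.fromisoformat(row[f"{prefix}_draw_time"]),
                lab_arrival_time=datetime.fromisoformat(row[f"{prefix}_arrival_time"]),
                order_id=row.get(f"{prefix}_order_id") or None,
                fill_ratio=_opt_float(row.get("citrate_fill_ratio", ""))
                if prefix == "citrate"
                else None,
                clotted=(row.get("citrate_clotted", "") == "true")
                if prefix == "citrate"
                else False,
            )
        )
    panel = AnalytePanel(
        bilirubin=float(row["bilirubin_umol_l"]),
        creatinine=float(row["creatinine_umol_l"]),
        inr=_opt_float(row.get("inr", "")),
        sodium=_opt_float(row.get("sodium_mmol_l", "")),
        albumin=_opt_float(row.get("albumin_g_l", "")),
        fibrinogen=_opt_float(row.get("fibrinogen_g_l", "")),
        cholinesterase=_opt_float(row.get("cholinesterase_ku_l", "")),
    )
    clotting = ClottingResult(
        status=ClottingStatus(row["clotting_status"]),
        pt_seconds=_opt_float(row.get("pt_seconds", "")),
        inr=_opt_float(row.get("inr", "")),
        timeout_seconds=_opt_float(row.get("clotting_timeout_s", "")) or 315.0,
    )
    dialysis = None
    if row.get("dialysis_mode"):
        dialysis = DialysisStatus(
            mode=DialysisMode(row["dialysis_mode"]),
            sessions_prior_week=int(float(row.get("dialysis_sessions_prior_week") or 0)),
            cvvhd_hours_prior_week=float(row.get("cvvhd_hours_prior_week") or 0.0),
        )
    return MeldRequest(
        order_id=row["order_id"],
        patient_id=row["patient_id"],
        birth_date=date.fromisoformat(row["birth_date"]),
        sex=row["sex"],
        request_time=datetime.fromisoformat(row["request_time"]),
        specimens=tuple(specimens),
        panel=panel,
        clotting=clotting,
        stated_dialysis=dialysis,
        stated_anticoagulation=Anticoagulation(row.get("anticoagulation") or "none"),
        anticoagulant_name=row.get("anticoagulant_name") or None,
    )


def write_requests_csv(requests: Sequence[MeldRequest], path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_CSV_COLUMNS)
        writer.writeheader()
        for request in requests:
            writer.writerow(_request_to_row(request))


def read_requests_csv(path: PathLike) -> list[MeldRequest]:
    with open(path, newline="") as fh:
        return [_row_to_request(row) for row in csv.DictReader(fh)]


# ---------------------------------------------------------------------------
# truth labels and verdict reports
# ---------------------------------------------------------------------------

def write_truth_json(truth: dict, path: PathLike) -> None:
    Path(path).write_text(json.dumps(truth, indent=1, sort_keys=True))


def read_truth_json(path: PathLike) -> dict:
    return json.loads(Path(path).read_text())


def write_verdicts_json(
    verdicts: Sequence[ValidationVerdict],
    requests: Sequence[MeldRequest],
    path: PathLike,
) -> None:
    """Write one report document per request (see reporting.render_report)."""
    from .reporting import render_report

    if len(verdicts) != len(requests):
        raise ValueError("one verdict per request required")
    docs = [render_report(v, r) for v, r in zip(verdicts, requests)]
    Path(path).write_text(json.dumps(docs, indent=1))
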