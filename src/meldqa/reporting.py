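"""Cohort summaries, the 2x2 association helper, and report rendering.

``summarize`` condenses a validated cohort into the counts and rates a
laboratory would publish: how many scores passed verification outright, how
many were released after correction, how many could not be reported, and the
per-reason breakdown.  Percentages are reported to one decimal with half-up
rounding.  ``chi_square_2x2`` wraps the Pearson chi-squared test for 2x2
tables (e.g. dialysis by sex).  ``render_report`` produces the per-request
reporting document handed on to the allocation organization.
"""

from __future__ import annotations

import statistics
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .config import VerificationConfig
from .scoring import (
    DialysisStatus,
    compute_meld,
    compute_meld_na,
    round_half_up,
    to_mg_dl,
)
from .verification import (
    Disposition,
    MeldRequest,
    ValidationVerdict,
)

__all__ = [
    "CohortSummary",
    "summarize",
    "chi_square_2x2",
    "render_report",
    "render_report_text",
    "percent",
]


def percent(count: float, total: float, decimals: int = 1) -> float:
    """Percentage with half-up rounding to the given number of decimals."""
    if total == 0:
        raise ZeroDivisionError("percentage of an empty denominator")
    scale = 10 ** decimals
    return round_half_up(100.0 * count / total * scale) / scale


@dataclass
class CohortSummary:
    """Validation outcome counts and rates for one cohort.

    ``n_invalid`` counts requests that could not be reported, including
    consultation cases that were never resolved.  Rates are percentages of
    ``n_requests`` rounded half-up to one decimal: ``valid_pct`` covers
    scores that passed verification outright, ``flagged_pct`` everything
    that did not, and ``unreported_pct`` the finally invalid remainder.
    """

    n_requests: int
    n_valid: int
    n_corrected: int
    n_invalid: int
    n_unresolved_consultation: int
    reason_counts: dict = field(default_factory=dict)
    valid_pct: float = 0.0
    flagged_pct: float = 0.0
    unreported_pct: float = 0.0
    median_score_valid: Optional[float] = None
    median_score_before_correction: Optional[float] = None
    median_score_after_correction: Optional[float] = None
    dialysis_prevalence_pct: Optional[float] = None
    dialysis_prevalence_by_sex: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_requests": self.n_requests,
            "n_valid": self.n_valid,
            "n_corrected": self.n_corrected,
            "n_invalid": self.n_invalid,
            "n_unresolved_consultation": self.n_unresolved_consultation,
            "reason_counts": dict(self.reason_counts),
            "valid_pct": self.valid_pct,
            "flagged_pct": self.flagged_pct,
            "unreported_pct": self.unreported_pct,
            "median_score_valid": self.median_score_valid,
            "median_score_before_correction": self.median_score_before_correction,
            "median_score_after_correction": self.median_score_after_correction,
            "dialysis_prevalence_pct": self.dialysis_prevalence_pct,
            "dialysis_prevalence_by_sex": dict(self.dialysis_prevalence_by_sex),
        }


def summarize(
    verdicts: Sequence[ValidationVerdict],
    requests: Sequence[MeldRequest],
    config: VerificationConfig = VerificationConfig(),
) -> CohortSummary:
    """Condense final verdicts into a :class:`CohortSummary`.

    One verdict per request, in the same order.  NEEDS_CONSULTATION verdicts
    still unresolved at summary time count as unreported: no score may leave
    the laboratory without a resolution.
    """
    if len(verdicts) != len(requests):
        raise ValueError(
            f"got {len(verdicts)} verdicts for {len(requests)} requests"
        )
    n = len(requests)
    if n == 0:
        raise ValueError("cannot summarize an empty cohort")

    n_valid = sum(v.disposition == Disposition.VALID for v in verdicts)
    n_corrected = sum(v.disposition == Disposition.CORRECTED_VALID for v in verdicts)
    n_unresolved = sum(
        v.disposition == Disposition.NEEDS_CONSULTATION for v in verdicts
    )
    n_invalid = n - n_valid - n_corrected

    reason_counts = Counter(c.value for v in verdicts for c in v.reasons)

    valid_scores = [
        v.result.score for v in verdicts if v.disposition == Disposition.VALID
    ]
    before: list[int] = []
    after: list[int] = []
    for v, r in zip(verdicts, requests):
        if v.disposition != Disposition.CORRECTED_VALID:
            continue
        after.append(v.result.score)
        # score as it would have been released with the stated status
        if r.panel.inr is not None:
            stated = compute_meld_na(
                compute_meld(
                    r.panel, r.stated_dialysis or DialysisStatus(), config.coefficients
                ),
                r.panel.sodium,
                config.coefficients,
            )
            before.append(stated.score)

    released = [
        (v, r)
        for v, r in zip(verdicts, requests)
        if v.disposition in (Disposition.VALID, Disposition.CORRECTED_VALID)
    ]
    dialysis_pct: Optional[float] = None
    by_sex: dict[str, float] = {}
    if released:
        on_dialysis = [v.result.dialysis_override_applied for v, _ in released]
        dialysis_pct = percent(sum(on_dialysis), len(released))
        for sex in sorted({r.sex for _, r in released}):
            sub = [
                v.result.dialysis_override_applied
                for v, r in released
                if r.sex == sex
            ]
            by_sex[sex] = percent(sum(sub), len(sub))

    return CohortSummary(
        n_requests=n,
        n_valid=n_valid,
        n_corrected=n_corrected,
        n_invalid=n_invalid,
        n_unresolved_consultation=n_unresolved,
        reason_counts=dict(reason_counts),
        valid_pct=percent(n_valid, n),
        flagged_pct=percent(n - n_valid, n),
        unreported_pct=percent(n_invalid, n),
        median_score_valid=statistics.median(valid_scores) if valid_scores else None,
        median_score_before_correction=statistics.median(before) if before else None,
        median_score_after_correction=statistics.median(after) if after else None,
        dialysis_prevalence_pct=dialysis_pct,
        dialysis_prevalence_by_sex=by_sex,
    )


def chi_square_2x2(
    table: Sequence[Sequence[float]], correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-squared test of independence on a 2x2 count table.

    Continuity correction is off by default; p-values come from the
    chi-squared distribution with one degree of freedom.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero row or column margin")
    res = sps.chi2_contingency(arr, correction=correction)
    return float(res.statistic), float(res.pvalue)


def render_report(verdict: ValidationVerdict, request: MeldRequest) -> dict:
    """The per-request reporting document as a JSON-ready mapping.

    Contains patient and order identifiers, the analytes in both unit
    systems, the stated (and corrected, if any) dialysis status, the
    disposition with its reason codes, and — only when a score was released
    — the score block with its clamped components.
    """
    panel = request.panel
    doc: dict = {
        "document": "MELD_REPORT",
        "patient_id": request.patient_id,
        "order_id": request.order_id,
        "birth_date": request.birth_date.isoformat(),
        "sex": request.sex,
        "request_time": request.request_time.isoformat(),
        "analytes": {
            "bilirubin_umol_l": panel.bilirubin,
            "bilirubin_mg_dl": round(to_mg_dl("bilirubin", panel.bilirubin), 2),
            "creatinine_umol_l": panel.creatinine,
            "creatinine_mg_dl": round(to_mg_dl("creatinine", panel.creatinine), 2),
            "inr": panel.inr,
            "sodium_mmol_l": panel.sodium,
        },
        "dialysis_status": None
        if request.stated_dialysis is None
        else request.stated_dialysis.mode.value,
        "anticoagulation": request.stated_anticoagulation.value,
        "disposition": verdict.disposition.value,
        "reasons": [c.value for c in verdict.reasons],
        "corrections": {
            k: {"stated": old, "confirmed": new}
            for k, (old, new) in verdict.corrections.items()
        },
        "narrative": verdict.narrative,
    }
    if verdict.result is not None:
        res = verdict.result
        doc["score"] = res.score
        doc["meld_na"] = res.meld_na
        doc["score_components"] = {
            "bilirubin_mg_dl": round(res.bilirubin_mgdl, 2),
            "creatinine_mg_dl": round(res.creatinine_mgdl, 2),
            "inr": round(res.inr_used, 2),
            "dialysis_override_applied": res.dialysis_override_applied,
            "clamps_applied": list(res.clamps_applied),
        }
    return doc


def render_report_text(verdict: ValidationVerdict, request: MeldRequest) -> str:
    """Plain-text rendering of the reporting document."""
    doc = render_report(verdict, request)
    lines = [
        "MELD laboratory report",
        f"  patient {doc['patient_id']}  order {doc['order_id']}",
        f"  requested {doc['request_time']}",
        "  analytes: "
        f"bilirubin {doc['analytes']['bilirubin_umol_l']:.1f} umol/L, "
        f"creatinine {doc['analytes']['creatinine_umol_l']:.1f} umol/L, "
        f"INR {doc['analytes']['inr'] if doc['analytes']['inr'] is not None else 'undeterminable'}",
        f"  dialysis status: {doc['dialysis_status'] or 'not stated'}",
        f"  disposition: {doc['disposition']}",
    ]
    if doc["reasons"]:
        lines.append(f"  reasons: {', '.join(doc['reasons'])}")
    for fieldname, pair in doc["corrections"].items():
        lines.append(
            f"  corrected {fieldname}: {pair['stated']} -> {pair['confirmed']}"
        )
    if "score" in doc:
        score_line = f"  MELD score: {doc['score']}"
        if doc["meld_na"] is not None:
            score_line += f"  (MELD-Na {doc['meld_na']})"
        lines.append(score_line)
    lines.append(f"  {doc['narrative']}")
    return "\n".join(lines)
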