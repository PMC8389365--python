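"""Lab-MELD and MELD-Na score computation.

The Model for End-stage Liver Disease (MELD) score predicts three-month
mortality in end-stage liver disease and drives liver-graft allocation.  It is
computed from three laboratory analytes — serum bilirubin, serum creatinine
and the INR — on the mg/dL scale:

    MELD = round(10 * (0.957 ln Cr + 0.378 ln Bili + 1.12 ln INR + 0.643))

with every component floored at 1.0, creatinine capped at 4.0 mg/dL, and the
final score clamped to [6, 40].  Patients on renal replacement therapy (at
least two dialysis sessions, or >= 24 h of continuous veno-venous
hemodialysis, within the prior week) have their creatinine overridden to
4.0 mg/dL (353.6 umol/L) regardless of the measured value.

MELD-Na adds a serum-sodium adjustment for patients whose initial MELD score
is at least 11, with sodium clamped to [125, 137] mmol/L:

    MELD-Na = round(MELD + 1.32 * (137 - Na) - 0.033 * MELD * (137 - Na))

All public entry points take analyte concentrations in the laboratory's SI
units (bilirubin and creatinine in umol/L, sodium in mmol/L) and convert
internally.  Rounding is half-up to the nearest integer throughout.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "AnalytePanel",
    "DialysisMode",
    "DialysisStatus",
    "ScoreCoefficients",
    "MeldResult",
    "MeasurabilityError",
    "to_mg_dl",
    "compute_meld",
    "compute_meld_na",
    "round_half_up",
]

# umol/L -> mg/dL divisors; creatinine pinned by the 353.6 umol/L == 4.0 mg/dL
# equivalence used by the dialysis override, bilirubin by molar mass.
CREATININE_UMOL_PER_MGDL = 88.4
BILIRUBIN_UMOL_PER_MGDL = 17.1

_CONVERSION_FACTORS = {
    "creatinine": CREATININE_UMOL_PER_MGDL,
    "bilirubin": BILIRUBIN_UMOL_PER_MGDL,
}


class MeasurabilityError(ValueError):
    """Raised when a score is requested for an undeterminable analyte.

    The typical case is a clotting test that timed out without clot
    detection, leaving no INR.  The verification layer resolves such
    requests through its INR policy before scoring.
    """


def round_half_up(x: float) -> int:
    """Round to the nearest integer, ties away from zero (half-up)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def to_mg_dl(analyte_name: str, value: float, *, factor: Optional[float] = None) -> float:
    """Convert a bilirubin or creatinine concentration from umol/L to mg/dL.

    Parameters
    ----------
    analyte_name : {"bilirubin", "creatinine"}
    value : float
        Concentration in umol/L; must be positive.
    factor : float, optional
        Override the default divisor (88.4 for creatinine, 17.1 for
        bilirubin).
    """
    if analyte_name not in _CONVERSION_FACTORS:
        raise KeyError(f"unknown analyte {analyte_name!r}; expected 'bilirubin' or 'creatinine'")
    if not value > 0:
        raise ValueError(f"{analyte_name} concentration must be > 0 umol/L, got {value!r}")
    divisor = _CONVERSION_FACTORS[analyte_name] if factor is None else factor
    return value / divisor


class DialysisMode(str, enum.Enum):
    NONE = "none"
    INTERMITTENT = "intermittent"
    CVVHD = "cvvhd"
    ALBUMIN_DIALYSIS = "albumin_dialysis"


@dataclass(frozen=True)
class DialysisStatus:
    """Stated renal-replacement status for the week before the blood draw.

    Albumin dialysis (e.g. MARS) is not a kidney replacement method and never
    triggers the creatinine override.
    """

    mode: DialysisMode = DialysisMode.NONE
    sessions_prior_week: int = 0
    cvvhd_hours_prior_week: float = 0.0

    def __post_init__(self) -> None:
        if self.sessions_prior_week < 0 or self.cvvhd_hours_prior_week < 0:
            raise ValueError("dialysis session counts and CVVHD hours must be >= 0")
        if self.mode == DialysisMode.NONE and (
            self.sessions_prior_week or self.cvvhd_hours_prior_week
        ):
            raise ValueError("mode 'none' is incompatible with nonzero sessions/hours")

    def qualifies_for_override(self) -> bool:
        """Whether the stated status meets the official creatinine-override criteria."""
        if self.mode == DialysisMode.INTERMITTENT:
            return self.sessions_prior_week >= 2
        if self.mode == DialysisMode.CVVHD:
            return self.cvvhd_hours_prior_week >= 24.0
        return False


@dataclass(frozen=True)
class AnalytePanel:
    """Measured analytes for one MELD request, in laboratory SI units.

    bilirubin, creatinine in umol/L; sodium in mmol/L; INR dimensionless and
    absent (None) when clotting was undeterminable.  Albumin (g/L),
    fibrinogen (g/L) and cholinesterase (kU/L) are context-only synthesis
    markers used by the verification heuristics, never by the score.
    """

    bilirubin: float
    creatinine: float
    inr: Optional[float] = None
    sodium: Optional[float] = None
    albumin: Optional[float] = None
    fibrinogen: Optional[float] = None
    cholinesterase: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("bilirubin", "creatinine", "inr", "sodium", "albumin",
                     "fibrinogen", "cholinesterase"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be > 0 when present, got {v!r}")


@dataclass(frozen=True)
class ScoreCoefficients:
    """Weights, clamps and thresholds of the MELD / MELD-Na formulae.

    Defaults are the published UNOS/Eurotransplant values; regulatory
    variants are a configuration change, not a code change.
    """

    w_creatinine: float = 0.957
    w_bilirubin: float = 0.378
    w_inr: float = 1.12
    intercept: float = 0.643
    input_floor_mgdl: float = 1.0
    creatinine_cap_mgdl: float = 4.0
    score_min: int = 6
    score_max: int = 40
    meldna_threshold: int = 11
    na_clamp_low: float = 125.0
    na_clamp_high: float = 137.0
    creatinine_umol_per_mgdl: float = CREATININE_UMOL_PER_MGDL
    bilirubin_umol_per_mgdl: float = BILIRUBIN_UMOL_PER_MGDL

    def __post_init__(self) -> None:
        if not (self.creatinine_cap_mgdl > self.input_floor_mgdl > 0):
            raise ValueError("require creatinine cap > input floor > 0")
        if not self.score_max > self.score_min:
            raise ValueError("require score_max > score_min")


@dataclass(frozen=True)
class MeldResult:
    """A computed lab-MELD score with its clamped components.

    Component concentrations are on the mg/dL scale actually entered into the
    formula (after flooring, capping and any dialysis override);
    ``clamps_applied`` lists which adjustments fired.
    """

    score: int
    bilirubin_mgdl: float
    creatinine_mgdl: float
    inr_used: float
    dialysis_override_applied: bool = False
    meld_na: Optional[int] = None
    clamps_applied: tuple[str, ...] = field(default_factory=tuple)

    @property
    def reported_score(self) -> int:
        """MELD-Na when computed, otherwise the lab-MELD score."""
        return self.meld_na if self.meld_na is not None else self.score


def compute_meld(
    panel: AnalytePanel,
    dialysis: DialysisStatus = DialysisStatus(),
    coeffs: ScoreCoefficients = ScoreCoefficients(),
) -> MeldResult:
    """Compute the lab-MELD score from a measured analyte panel.

    Raises
    ------
    MeasurabilityError
        If the panel carries no INR (undeterminable clotting); callers should
        resolve the INR through the verification module first.
    """
    if panel.inr is None:
        raise MeasurabilityError(
            "INR is undeterminable; resolve the clotting result before scoring"
        )

    clamps: list[str] = []
    bili = to_mg_dl("bilirubin", panel.bilirubin, factor=coeffs.bilirubin_umol_per_mgdl)
    cr = to_mg_dl("creatinine", panel.creatinine, factor=coeffs.creatinine_umol_per_mgdl)
    inr = panel.inr

    if bili < coeffs.input_floor_mgdl:
        bili = coeffs.input_floor_mgdl
        clamps.append("bilirubin_floor")
    if cr < coeffs.input_floor_mgdl:
        cr = coeffs.input_floor_mgdl
        clamps.append("creatinine_floor")
    if inr < 1.0:
        inr = 1.0
        clamps.append("inr_floor")

    override = dialysis.qualifies_for_override()
    if override:
        cr = coeffs.creatinine_cap_mgdl
        clamps.append("dialysis_override")
    elif cr > coeffs.creatinine_cap_mgdl:
        cr = coeffs.creatinine_cap_mgdl
        clamps.append("creatinine_cap")

    raw = 10.0 * (
        coeffs.w_creatinine * math.log(cr)
        + coeffs.w_bilirubin * math.log(bili)
        + coeffs.w_inr * math.log(inr)
        + coeffs.intercept
    )
    score = round_half_up(raw)
    if score < coeffs.score_min:
        score = coeffs.score_min
        clamps.append("score_min")
    elif score > coeffs.score_max:
        score = coeffs.score_max
        clamps.append("score_max")

    return MeldResult(
        score=score,
        bilirubin_mgdl=bili,
        creatinine_mgdl=cr,
        inr_used=inr,
        dialysis_override_applied=override,
        clamps_applied=tuple(clamps),
    )


def compute_meld_na(
    meld: MeldResult,
    sodium: Optional[float],
    coeffs: ScoreCoefficients = ScoreCoefficients(),
) -> MeldResult:
    """Attach the MELD-Na score to a computed MELD result.

    Sodium is clamped to [na_clamp_low, na_clamp_high] mmol/L.  The sodium
    adjustment applies only when the initial MELD score is at least the
    MELD-Na threshold (11); below it, MELD-Na equals the lab-MELD score.
    Missing sodium leaves ``meld_na`` unset — the lab-MELD score stands.
    """
    if sodium is None:
        return meld
    if not sodium > 0:
        raise ValueError(f"sodium must be > 0 mmol/L, got {sodium!r}")

    na = min(max(sodium, coeffs.na_clamp_low), coeffs.na_clamp_high)
    if meld.score >= coeffs.meldna_threshold:
        deficit = coeffs.na_clamp_high - na
        value = meld.score + 1.32 * deficit - 0.033 * meld.score * deficit
        meld_na = min(round_half_up(value), coeffs.score_max)
    else:
        meld_na = meld.score
    return replace(meld, meld_na=meld_na)
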