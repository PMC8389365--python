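"""Tunable thresholds of the verification rules, loadable from YAML/JSON.

Every numeric decision point in the rule engine lives here so that a site can
adapt the screen to local practice without touching code.  Defaults follow
common clinical-laboratory convention where the source workflow names a check
but not a bound.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any, Union

import yaml

from .scoring import ScoreCoefficients

__all__ = ["VerificationConfig", "load_config", "dump_config"]


@dataclass(frozen=True)
class VerificationConfig:
    """Thresholds for the MELD request verification rules.

    Time quantities are hours, ages years, concentrations umol/L; ratios are
    dimensionless fractions.
    """

    # order integrity
    co_draw_tolerance_hours: float = 0.5     # serum/citrate draws of one order
    # preanalytics
    preanalytic_max_hours: float = 4.0       # draw -> lab arrival
    late_entrance_hours: float = 24.0        # request -> lab arrival
    citrate_underfill_ratio: float = 0.90    # minimum citrate fill fraction
    peld_age_years: float = 12.0             # under this age PELD applies
    # dialysis plausibility
    implausible_creatinine_max_umol: float = 100.0  # stated RRT but creatinine below this
    # anticoagulation / INR
    inr_absolute_impact: float = 1.5         # VKA/DOAC stated and INR above this
    inr_baseline_ratio: float = 1.2          # elevated vs non-anticoagulated baseline
    synthesis_marker_tolerance: float = 0.20  # "unchanged" band for albumin etc.
    inr_timeout_seconds: float = 315.0       # instrument clot-detection timeout
    inr_policy: str = "last_determinable"    # last_determinable | table_max | block
    conversion_table_max_inr: float = 9.0    # table maximum used by policy table_max
    # delta checks (relative change vs most recent prior within lookback)
    delta_lookback_days: float = 7.0
    delta_creatinine: float = 1.00
    delta_bilirubin: float = 1.50
    delta_inr: float = 0.75
    # scoring
    coefficients: ScoreCoefficients = field(default_factory=ScoreCoefficients)
    report_meld_na: bool = False             # lab-MELD is the default reported score

    def __post_init__(self) -> None:
        if self.inr_policy not in ("last_determinable", "table_max", "block"):
            raise ValueError(f"unknown INR policy {self.inr_policy!r}")
        for name in ("co_draw_tolerance_hours", "preanalytic_max_hours",
                     "late_entrance_hours", "delta_lookback_days"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "VerificationConfig":
        data = dict(data)
        coeffs = data.pop("coefficients", None)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise KeyError(f"unknown configuration keys: {sorted(unknown)}")
        if coeffs is not None:
            data["coefficients"] = (
                coeffs if isinstance(coeffs, ScoreCoefficients) else ScoreCoefficients(**coeffs)
            )
        return cls(**data)


def load_config(path: Union[str, Path]) -> VerificationConfig:
    """Read a VerificationConfig from a YAML (or JSON) file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        return VerificationConfig()
    return VerificationConfig.from_dict(data)


def dump_config(config: VerificationConfig, path: Union[str, Path]) -> None:
    """Write a VerificationConfig to YAML (or JSON if the suffix is .json)."""
    p = Path(path)
    if p.suffix == ".json":
        p.write_text(json.dumps(config.to_dict(), indent=2))
    else:
        p.write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
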