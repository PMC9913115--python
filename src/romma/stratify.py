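"""Risk categories and the RoMMa triage decision.

Two parallel three-level risk scales are used:

* aMMs: very low if aMMs <= 12, low if 12 < aMMs <= 18, high if aMMs > 18.
* Oncotype DX, TAILORx-informed: very low if ODX < 11; low if 11 <= ODX < 16,
  or 16 <= ODX <= 25 in patients *over* 50 years of age; high if ODX > 25, or
  16 <= ODX <= 25 in patients 50 or younger (age exactly 50 takes the
  younger branch).

The triage decision (should tissue be sent for Oncotype DX testing?) depends
only on the aMMs category: very low - testing not indicated; low - testing
conditional on clinical/pathologic context; high - testing indicated.  The
ODX category, when an ODX score exists, is carried alongside for concordance
analysis but never feeds back into the triage decision.

All cutoffs live in :class:`StratificationConfig` and compare against the
unrounded aMMs; rounding is a display concern.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from enum import Enum, IntEnum
from pathlib import Path

from .cohort import PatientRecord
from .errors import ValidationError
from .magee import CoefficientSet, MageeResult, compute_amms

__all__ = [
    "RiskCategory",
    "TriageDecision",
    "StratificationConfig",
    "DEFAULT_CONFIG",
    "categorize_amms",
    "categorize_odx",
    "romma_triage",
    "RiskAssignment",
]


class RiskCategory(IntEnum):
    """Ordered risk levels; comparisons follow VERY_LOW < LOW < HIGH."""

    VERY_LOW = 0
    LOW = 1
    HIGH = 2

    def __str__(self) -> str:  # stable lower-snake labels for files/reports
        return self.name.lower()


class TriageDecision(str, Enum):
    ODX_NOT_INDICATED = "odx_not_indicated"
    ODX_CONDITIONAL = "odx_conditional"
    ODX_INDICATED = "odx_indicated"


_TRIAGE_BY_CATEGORY = {
    RiskCategory.VERY_LOW: TriageDecision.ODX_NOT_INDICATED,
    RiskCategory.LOW: TriageDecision.ODX_CONDITIONAL,
    RiskCategory.HIGH: TriageDecision.ODX_INDICATED,
}


@dataclass(frozen=True)
class StratificationConfig:
    """Cutoffs for both risk scales (defaults as studied).

    ``odx_low_max_exclusive``/``odx_mid_max`` delimit the age-dependent
    16-25 band from the TAILORx trial; ``age_threshold_years`` is the age at
    or below which that band counts as high risk.
    """

    amms_very_low_max: float = 12.0
    amms_low_max: float = 18.0
    odx_very_low_max_exclusive: float = 11.0
    odx_low_max_exclusive: float = 16.0
    odx_mid_max: float = 25.0
    age_threshold_years: float = 50.0

    def __post_init__(self) -> None:
        if not self.amms_very_low_max < self.amms_low_max:
            raise ValidationError("aMMs cutoffs must be strictly increasing")
        if not (
            self.odx_very_low_max_exclusive
            < self.odx_low_max_exclusive
            <= self.odx_mid_max
        ):
            raise ValidationError("ODX cutoffs must be strictly increasing")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "StratificationConfig":
        return cls(**json.loads(Path(path).read_text()))


DEFAULT_CONFIG = StratificationConfig()


def categorize_amms(
    amms: float, config: StratificationConfig = DEFAULT_CONFIG
) -> RiskCategory:
    """aMMs band: <= very-low cutoff, (very-low, low], or above. Boundaries inclusive."""
    if not math.isfinite(amms):
        raise ValidationError(f"aMMs must be finite, got {amms}")
    if amms <= config.amms_very_low_max:
        return RiskCategory.VERY_LOW
    if amms <= config.amms_low_max:
        return RiskCategory.LOW
    return RiskCategory.HIGH


def categorize_odx(
    odx: float, age_years: float, config: StratificationConfig = DEFAULT_CONFIG
) -> RiskCategory:
    """TAILORx-informed ODX band; the 16-25 window is high risk at age <= 50."""
    if not math.isfinite(odx) or not 0 <= odx <= 100:
        raise ValidationError(f"ODX score {odx} outside [0, 100]")
    if age_years <= 0:
        raise ValidationError(f"age_years {age_years} must be > 0")
    if odx < config.odx_very_low_max_exclusive:
        return RiskCategory.VERY_LOW
    if odx < config.odx_low_max_exclusive:
        return RiskCategory.LOW
    if odx <= config.odx_mid_max:
        if age_years <= config.age_threshold_years:
            return RiskCategory.HIGH
        return RiskCategory.LOW
    return RiskCategory.HIGH


@dataclass(frozen=True)
class RiskAssignment:
    """Paired risk categories plus the triage decision, with the aMMs audit trail."""

    amms: float
    amms_category: RiskCategory
    triage: TriageDecision
    magee: MageeResult
    odx_category: RiskCategory | None = None
    note: str = ""


def romma_triage(
    record: PatientRecord,
    coeffs: CoefficientSet | None = None,
    config: StratificationConfig = DEFAULT_CONFIG,
    note: str = "",
) -> RiskAssignment:
    """Score a patient and decide whether Oncotype DX testing is indicated.

    The decision is a function of the aMMs category alone; discordant
    clinical or pathologic features that might override it are narrative and
    can be carried in ``note``.
    """
    result = compute_amms(record.profile, coeffs)
    amms_cat = categorize_amms(result.amms, config)
    odx_cat = (
        categorize_odx(record.odx_score, record.age_years, config)
        if record.odx_score is not None
        else None
    )
    return RiskAssignment(
        amms=result.amms,
        amms_category=amms_cat,
        triage=_TRIAGE_BY_CATEGORY[amms_cat],
        magee=result,
        odx_category=odx_cat,
        note=note,
    )
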