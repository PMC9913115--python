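"""Modified H-scores, modified Magee equation scores, and their average (aMMs).

The Magee equations are published multivariable linear models that estimate
the Oncotype DX recurrence score from routine histopathology (Nottingham
score, tumor size, semi-quantitative ER/PR immunohistochemistry, HER2
status, Ki-67).  This package evaluates them with the *modified* H-score —
overall dominant stain intensity (0-3) times percent positive cells, range
0-300 — a simplification of the classical three-term H-score.

The average Modified Magee score (aMMs) is the arithmetic mean of every
equation whose required inputs are present for the patient; which equations
contributed is always recorded so a score computed from a reduced set (for
example when Ki-67 was never stained) is auditable.

Coefficients are configuration, not code: they ship as a versioned JSON
file with provenance strings and can be replaced by the caller.  No
refitting happens here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

from .cohort import Her2Status, TumorProfile
from .errors import MissingInputError, ValidationError

__all__ = [
    "modified_hscore",
    "classical_hscore",
    "EquationSpec",
    "CoefficientSet",
    "MageeResult",
    "equation_score",
    "compute_amms",
    "VARIABLES",
]

#: Profile variables a coefficient set may weight.
VARIABLES = (
    "nottingham_score",
    "er_hscore",
    "pr_hscore",
    "ki67_percent",
    "tumor_size_cm",
    "mitotic_count",
)


def modified_hscore(intensity: int, percent_positive: float) -> float:
    """Modified (single-term) H-score: dominant intensity grade x percent positive.

    Range 0-300.  This is the form the Rochester modification of the Magee
    equations uses for ER and PR.
    """
    if intensity not in (0, 1, 2, 3):
        raise ValidationError(f"intensity {intensity} not in {{0,1,2,3}}")
    if not 0 <= percent_positive <= 100:
        raise ValidationError(f"percent_positive {percent_positive} outside [0, 100]")
    return float(intensity) * float(percent_positive)


def classical_hscore(
    percent_weak: float, percent_moderate: float, percent_strong: float
) -> float:
    """Classical three-term H-score: 1xp1 + 2xp2 + 3xp3, range 0-300.

    Provided for comparison with the modified form; the Magee scoring in
    this package uses :func:`modified_hscore`.
    """
    for name, p in (
        ("percent_weak", percent_weak),
        ("percent_moderate", percent_moderate),
        ("percent_strong", percent_strong),
    ):
        if not 0 <= p <= 100:
            raise ValidationError(f"{name} {p} outside [0, 100]")
    if percent_weak + percent_moderate + percent_strong > 100 + 1e-9:
        raise ValidationError("intensity-fraction percentages sum over 100")
    return percent_weak + 2.0 * percent_moderate + 3.0 * percent_strong


@dataclass(frozen=True)
class EquationSpec:
    """One linear equation: score = intercept + sum(weight_v * v) + her2_offset."""

    intercept: float
    weights: Mapping[str, float]
    her2_offsets: Mapping[str, float]
    required_variables: frozenset[str]
    source: str = ""

    def __post_init__(self) -> None:
        unknown = set(self.weights) - set(VARIABLES)
        if unknown:
            raise ValidationError(f"unknown equation variables: {sorted(unknown)}")
        not_required = set(self.weights) - set(self.required_variables)
        if not_required:
            raise ValidationError(
                f"weighted variables missing from required_variables: {sorted(not_required)}"
            )


@dataclass(frozen=True)
class CoefficientSet:
    """A named family of Magee equations loaded from JSON configuration."""

    equations: Mapping[str, EquationSpec]

    @classmethod
    def from_dict(cls, raw: Mapping[str, Mapping]) -> "CoefficientSet":
        eqs = {}
        for eq_id, spec in raw.items():
            offsets = dict(spec.get("her2_offsets", {}))
            offsets.setdefault("negative", 0.0)
            for status in Her2Status:
                offsets.setdefault(status.value, 0.0)
            eqs[eq_id] = EquationSpec(
                intercept=float(spec["intercept"]),
                weights={k: float(v) for k, v in spec.get("weights", {}).items()},
                her2_offsets=offsets,
                required_variables=frozenset(spec.get("required_variables", spec.get("weights", {}))),
                source=spec.get("source", ""),
            )
        if not eqs:
            raise ValidationError("coefficient set defines no equations")
        return cls(eqs)

    @classmethod
    def from_json(cls, path: str | Path) -> "CoefficientSet":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def default(cls) -> "CoefficientSet":
        """The shipped new-Magee coefficient set (modified H-score inputs)."""
        raw = json.loads(
            resources.files("romma.data").joinpath("magee_coefficients.json").read_text()
        )
        return cls.from_dict(raw)


_DEFAULT: CoefficientSet | None = None


def default_coefficients() -> CoefficientSet:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = CoefficientSet.default()
    return _DEFAULT


@dataclass(frozen=True)
class MageeResult:
    """Per-equation scores and their average, with the contributing equations."""

    per_equation_scores: Mapping[str, float]
    amms: float
    equations_used: tuple[str, ...]


def _profile_value(profile: TumorProfile, variable: str):
    value = getattr(profile, variable)
    return value


def equation_score(
    profile: TumorProfile, coeffs: CoefficientSet, equation_id: str
) -> float:
    """Evaluate one Magee equation on a profile; no clamping is applied."""
    try:
        eq = coeffs.equations[equation_id]
    except KeyError:
        raise MissingInputError(f"unknown equation id {equation_id!r}") from None
    for var in sorted(eq.required_variables):
        if _profile_value(profile, var) is None:
            raise MissingInputError(
                f"equation {equation_id!r} requires {var!r}, absent from profile"
            )
    score = eq.intercept + eq.her2_offsets[profile.her2.value]
    for var, weight in eq.weights.items():
        score += weight * float(_profile_value(profile, var))
    return score


def computable_equations(profile: TumorProfile, coeffs: CoefficientSet) -> list[str]:
    """Equation ids whose required variables are all present on the profile."""
    out = []
    for eq_id, eq in coeffs.equations.items():
        if all(_profile_value(profile, v) is not None for v in eq.required_variables):
            out.append(eq_id)
    return out


def compute_amms(
    profile: TumorProfile, coeffs: CoefficientSet | None = None
) -> MageeResult:
    """Average Modified Magee score: mean over every computable equation.

    Raises :class:`MissingInputError` if no equation can be evaluated.
    Scores are kept at full floating precision; round only for display.
    """
    coeffs = coeffs or default_coefficients()
    usable = computable_equations(profile, coeffs)
    if not usable:
        raise MissingInputError("no Magee equation computable: required inputs absent")
    scores = {eq_id: equation_score(profile, coeffs, eq_id) for eq_id in usable}
    amms = sum(scores.values()) / len(scores)
    return MageeResult(
        per_equation_scores=scores, amms=amms, equations_used=tuple(usable)
    )
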