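"""Patient-level data model, cohort file I/O and study-eligibility filtering.

A cohort is a flat table of ER-positive / HER2-negative breast-cancer
patients with the routine histopathology needed by the modified Magee
equations (Nottingham score, tumor size, modified ER/PR H-scores, Ki-67,
mitotic count), the Oncotype DX recurrence score when the patient was
tested, and recurrence follow-up.

Files are plain delimited text (comma by default, tab accepted), UTF-8,
with a header row of canonical lower-snake column names (see ``COLUMNS``).
An empty field means *not recorded*; the string ``"0"`` is always a
measured zero — the distinction matters because a missing Ki-67 changes
which Magee equations can be evaluated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator

import pandas as pd

from .errors import CohortFormatError, ValidationError

__all__ = [
    "Her2Status",
    "IHCMarker",
    "IHCMeasurement",
    "TumorProfile",
    "PatientRecord",
    "Cohort",
    "read_cohort",
    "write_cohort",
    "apply_eligibility",
    "eligibility_failures",
    "COLUMNS",
]


class Her2Status(str, Enum):
    NEGATIVE = "negative"
    EQUIVOCAL = "equivocal"
    POSITIVE = "positive"


class IHCMarker(str, Enum):
    ER = "ER"
    PR = "PR"
    KI67 = "KI67"


#: Canonical header, in file order.
COLUMNS = [
    "patient_id",
    "age_years",
    "tumor_size_cm",
    "nottingham_score",
    "mitotic_count",
    "er_intensity",
    "er_percent",
    "pr_intensity",
    "pr_percent",
    "er_hscore",
    "pr_hscore",
    "ki67_percent",
    "her2_status",
    "odx_score",
    "followup_months",
    "recurred",
    "recurrence_month",
    "endocrine_therapy",
    "chemotherapy",
]

_MANDATORY = [
    "patient_id",
    "age_years",
    "tumor_size_cm",
    "nottingham_score",
    "her2_status",
    "followup_months",
    "recurred",
    "endocrine_therapy",
    "chemotherapy",
]


@dataclass(frozen=True)
class IHCMeasurement:
    """One immunostain read-out: dominant intensity grade and percent positivity.

    ``intensity`` applies to ER/PR only (0-3 scale); Ki-67 is reported as a
    percent alone.  Intensity 0 forces percent 0 (nothing stains).
    """

    marker: IHCMarker
    percent_positive: float
    intensity: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.percent_positive <= 100:
            raise ValidationError(
                f"{self.marker.value} percent_positive {self.percent_positive} outside [0, 100]"
            )
        if self.intensity is not None:
            if self.intensity not in (0, 1, 2, 3):
                raise ValidationError(
                    f"{self.marker.value} intensity {self.intensity} not in {{0,1,2,3}}"
                )
            if self.intensity == 0 and self.percent_positive != 0:
                raise ValidationError(
                    f"{self.marker.value} intensity 0 with nonzero percent_positive"
                )


@dataclass(frozen=True)
class TumorProfile:
    """Histopathologic inputs to the modified Magee equations.

    ``ki67_percent`` absent (``None``) is distinct from a measured 0: the
    Ki-67-bearing equations are skipped, not evaluated at zero.
    ``mitotic_count`` (per 10 HPF) is carried for completeness; under the
    shipped coefficient set it enters only through the Nottingham score.
    """

    nottingham_score: int
    tumor_size_cm: float
    er_hscore: float
    pr_hscore: float
    her2: Her2Status = Her2Status.NEGATIVE
    ki67_percent: float | None = None
    mitotic_count: int | None = None

    def __post_init__(self) -> None:
        if not 3 <= self.nottingham_score <= 9:
            raise ValidationError(
                f"nottingham_score {self.nottingham_score} outside [3, 9]"
            )
        if not self.tumor_size_cm > 0:
            raise ValidationError(f"tumor_size_cm {self.tumor_size_cm} must be > 0")
        for name, value in (("er_hscore", self.er_hscore), ("pr_hscore", self.pr_hscore)):
            if not 0 <= value <= 300:
                raise ValidationError(f"{name} {value} outside [0, 300]")
        if self.ki67_percent is not None and not 0 <= self.ki67_percent <= 100:
            raise ValidationError(f"ki67_percent {self.ki67_percent} outside [0, 100]")
        if self.mitotic_count is not None and self.mitotic_count < 0:
            raise ValidationError(f"mitotic_count {self.mitotic_count} must be >= 0")


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    age_years: float
    profile: TumorProfile
    followup_months: float
    recurred: bool
    odx_score: float | None = None
    recurrence_month: float | None = None
    endocrine_therapy: bool = True
    chemotherapy: bool = False

    def __post_init__(self) -> None:
        if not self.age_years > 0:
            raise ValidationError(f"age_years {self.age_years} must be > 0")
        if self.followup_months < 0:
            raise ValidationError(f"followup_months {self.followup_months} must be >= 0")
        if self.odx_score is not None and not 0 <= self.odx_score <= 100:
            raise ValidationError(f"odx_score {self.odx_score} outside [0, 100]")
        if self.recurred:
            if self.recurrence_month is None:
                raise ValidationError(
                    f"patient {self.patient_id}: recurred without recurrence_month"
                )
            if self.recurrence_month > self.followup_months + 1e-9:
                raise ValidationError(
                    f"patient {self.patient_id}: recurrence_month after followup_months"
                )
        if self.recurrence_month is not None and self.recurrence_month < 0:
            raise ValidationError("recurrence_month must be >= 0")

    @property
    def event_time_months(self) -> float:
        """Disease-free-survival time: recurrence month if recurred, else censoring time."""
        return self.recurrence_month if self.recurred else self.followup_months


@dataclass
class Cohort:
    """Ordered collection of patient records with unique ids."""

    records: list[PatientRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate patient ids: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> PatientRecord:
        return self.records[i]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self:
            p = r.profile
            rows.append(
                {
                    "patient_id": r.patient_id,
                    "age_years": r.age_years,
                    "tumor_size_cm": p.tumor_size_cm,
                    "nottingham_score": p.nottingham_score,
                    "mitotic_count": p.mitotic_count,
                    "er_intensity": None,
                    "er_percent": None,
                    "pr_intensity": None,
                    "pr_percent": None,
                    "er_hscore": p.er_hscore,
                    "pr_hscore": p.pr_hscore,
                    "ki67_percent": p.ki67_percent,
                    "her2_status": p.her2.value,
                    "odx_score": r.odx_score,
                    "followup_months": r.followup_months,
                    "recurred": r.recurred,
                    "recurrence_month": r.recurrence_month,
                    "endocrine_therapy": r.endocrine_therapy,
                    "chemotherapy": r.chemotherapy,
                }
            )
        return pd.DataFrame(rows, columns=COLUMNS)


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    if isinstance(value, str) and value.strip() == "":
        return True
    return False


_TRUE = {"true", "t", "1", "yes", "y"}
_FALSE = {"false", "f", "0", "no", "n", ""}


def _parse_bool(value, column: str, row: int) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, float)) and not _is_missing(value):
        return bool(int(value))
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE and s != "":
        return False
    raise ValidationError(f"column {column}: cannot interpret {value!r} as boolean", row=row)


def _parse_float(value, column: str, row: int) -> float | None:
    if _is_missing(value):
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"column {column}: {value!r} is not numeric", row=row) from None


def read_cohort(path: str | Path, delimiter: str | None = None) -> Cohort:
    """Read a cohort from delimited text.

    Accepts either precomputed modified H-scores (``er_hscore``/``pr_hscore``)
    or (intensity, percent) pairs — or both, in which case they must agree.
    Empty fields are *absent*, never zero.

    Raises
    ------
    CohortFormatError
        If the file lacks a mandatory column.
    ValidationError
        If a value is out of range; the message carries the 0-based row index.
    """
    path = Path(path)
    if delimiter is None:
        with open(path, "r", encoding="utf-8") as fh:
            header = fh.readline()
        delimiter = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    df.columns = [c.strip() for c in df.columns]

    for col in _MANDATORY:
        if col not in df.columns:
            raise CohortFormatError(f"mandatory column {col!r} missing from {path}")
    for marker in ("er", "pr"):
        if f"{marker}_hscore" not in df.columns and not (
            f"{marker}_intensity" in df.columns and f"{marker}_percent" in df.columns
        ):
            raise CohortFormatError(
                f"need column {marker}_hscore or the pair {marker}_intensity/{marker}_percent"
            )

    from .magee import modified_hscore  # local import to avoid a cycle

    records: list[PatientRecord] = []
    for i, row in enumerate(df.to_dict("records")):
        def fget(col):
            return row.get(col) if col in df.columns else None

        hscores = {}
        for marker in ("er", "pr"):
            hs = _parse_float(fget(f"{marker}_hscore"), f"{marker}_hscore", i)
            inten = _parse_float(fget(f"{marker}_intensity"), f"{marker}_intensity", i)
            pct = _parse_float(fget(f"{marker}_percent"), f"{marker}_percent", i)
            if inten is not None and pct is not None:
                try:
                    derived = modified_hscore(int(inten), pct)
                except ValidationError as exc:
                    raise ValidationError(str(exc), row=i) from None
                if hs is not None and abs(hs - derived) > 1e-6:
                    raise ValidationError(
                        f"{marker}_hscore {hs} disagrees with intensity x percent = {derived}",
                        row=i,
                    )
                hs = derived
            if hs is None:
                raise ValidationError(f"no {marker} H-score or intensity/percent pair", row=i)
            hscores[marker] = hs

        her2_raw = str(fget("her2_status")).strip().lower()
        try:
            her2 = Her2Status(her2_raw)
        except ValueError:
            raise ValidationError(f"her2_status {her2_raw!r} not one of negative/equivocal/positive", row=i) from None

        mc = _parse_float(fget("mitotic_count"), "mitotic_count", i)
        ns = _parse_float(fget("nottingham_score"), "nottingham_score", i)
        try:
            profile = TumorProfile(
                nottingham_score=int(ns),
                tumor_size_cm=_parse_float(fget("tumor_size_cm"), "tumor_size_cm", i),
                er_hscore=hscores["er"],
                pr_hscore=hscores["pr"],
                her2=her2,
                ki67_percent=_parse_float(fget("ki67_percent"), "ki67_percent", i),
                mitotic_count=int(mc) if mc is not None else None,
            )
            record = PatientRecord(
                patient_id=str(fget("patient_id")).strip(),
                age_years=_parse_float(fget("age_years"), "age_years", i),
                profile=profile,
                odx_score=_parse_float(fget("odx_score"), "odx_score", i),
                followup_months=_parse_float(fget("followup_months"), "followup_months", i),
                recurred=_parse_bool(fget("recurred"), "recurred", i),
                recurrence_month=_parse_float(fget("recurrence_month"), "recurrence_month", i),
                endocrine_therapy=_parse_bool(fget("endocrine_therapy"), "endocrine_therapy", i),
                chemotherapy=_parse_bool(fget("chemotherapy"), "chemotherapy", i),
            )
        except ValidationError as exc:
            if exc.row is None:
                raise ValidationError(str(exc), row=i) from None
            raise
        records.append(record)
    return Cohort(records)


def write_cohort(cohort: Cohort, path: str | Path, delimiter: str = ",") -> None:
    """Write a cohort as delimited text; absent optional values become empty fields."""
    df = cohort.to_dataframe()
    df["recurred"] = df["recurred"].map({True: "true", False: "false"})
    df["endocrine_therapy"] = df["endocrine_therapy"].map({True: "true", False: "false"})
    df["chemotherapy"] = df["chemotherapy"].map({True: "true", False: "false"})
    df.to_csv(path, sep=delimiter, index=False, na_rep="")


def eligibility_failures(
    record: PatientRecord,
    min_followup_months: float = 60.0,
    require_er_positive: bool = False,
) -> list[str]:
    """Return the list of study-eligibility criteria the record fails (empty = eligible).

    Criteria: endocrine therapy received; no systemic chemotherapy; HER2
    negative; and at least ``min_followup_months`` of recurrence-free
    follow-up *or* a breast-cancer recurrence at any time.
    ER positivity is usually asserted upstream of this package; when
    ``require_er_positive`` it is checked as er_hscore > 0 (no published
    H-score threshold is imposed).
    """
    reasons = []
    if not record.endocrine_therapy:
        reasons.append("no endocrine therapy")
    if record.chemotherapy:
        reasons.append("received chemotherapy")
    if record.profile.her2 != Her2Status.NEGATIVE:
        reasons.append(f"HER2 {record.profile.her2.value}")
    if not (record.recurred or record.followup_months >= min_followup_months):
        reasons.append(f"follow-up {record.followup_months} < {min_followup_months} without recurrence")
    if require_er_positive and record.profile.er_hscore <= 0:
        reasons.append("ER H-score 0 (not ER-positive)")
    return reasons


def apply_eligibility(
    cohort: Cohort,
    min_followup_months: float = 60.0,
    require_er_positive: bool = False,
) -> Cohort:
    """Filter a cohort to study-eligible records; never mutates field values."""
    kept = [
        r
        for r in cohort
        if not eligibility_failures(r, min_followup_months, require_er_positive)
    ]
    return Cohort(kept)
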