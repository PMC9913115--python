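"""Synthetic cohorts with the statistical structure of the study population.

Two generators are provided:

* :func:`generate_exact_fixture` — a deterministic 355-patient cohort whose
  cross-classified (aMMs category x ODX category) cell counts and per-cell
  recurrence counts equal the study's published 3x3 tables, including the
  age footnotes (the 32 patients aged <= 50 with an ODX of 16-25, two of
  whom recurred).  Tumor profiles are constructed by inverting the loaded
  Magee coefficient set, so running the full scoring pipeline on the
  fixture reproduces every count.

* :func:`generate_cohort` — a seeded stochastic generator for property
  tests, in two modes: ``category_level`` samples the 3x3 cell multinomially
  and places scores uniformly within category bands; ``feature_level``
  samples correlated tumor profiles within the observed pathology ranges,
  computes the aMMs honestly, and samples ODX conditionally on the aMMs
  category to target the cell probabilities.

All synthetic values (survival times in particular) are just that —
synthetic; they carry the category-level structure of the study, not the
patient-level reality behind it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import count as _count
from typing import Sequence

import numpy as np

from .cohort import Cohort, Her2Status, PatientRecord, TumorProfile
from .errors import ValidationError
from .magee import CoefficientSet, compute_amms, default_coefficients
from .stratify import (
    DEFAULT_CONFIG,
    RiskCategory,
    StratificationConfig,
    categorize_amms,
)

__all__ = [
    "STUDY_CELL_COUNTS",
    "STUDY_RECURRENCE_COUNTS",
    "GeneratorParams",
    "profile_for_amms",
    "generate_exact_fixture",
    "generate_cohort",
    "synthetic_event_times",
]

#: Study 3x3 cell counts, rows = aMMs category, columns = ODX category.
STUDY_CELL_COUNTS = np.array([[26, 30, 6], [53, 101, 19], [15, 77, 28]], dtype=int)
#: Recurrences per cell of the same cross-classification.
STUDY_RECURRENCE_COUNTS = np.array([[0, 2, 0], [5, 7, 2], [2, 9, 4]], dtype=int)

# Anchor profiles spanning the pathology ranges: a maximally favourable
# tumor (strong ER/PR, no proliferation, small) and a maximally adverse one.
# aMMs is linear along the segment between them at fixed Nottingham score,
# which makes exact inversion a one-dimensional solve.
_ANCHOR_LOW = {"er_hscore": 300.0, "pr_hscore": 300.0, "ki67_percent": 0.0, "tumor_size_cm": 0.5}
_ANCHOR_HIGH = {"er_hscore": 40.0, "pr_hscore": 0.0, "ki67_percent": 70.0, "tumor_size_cm": 10.0}


def _mitotic_for_ns(ns: int) -> int:
    # plausible mitoses/10 HPF for the grade; not used by the shipped equations
    return {3: 1, 4: 2, 5: 3, 6: 6, 7: 9, 8: 14, 9: 20}[ns]


def _profile_at(t: float, ns: int) -> TumorProfile:
    f = {
        k: _ANCHOR_LOW[k] + t * (_ANCHOR_HIGH[k] - _ANCHOR_LOW[k]) for k in _ANCHOR_LOW
    }
    return TumorProfile(
        nottingham_score=ns,
        tumor_size_cm=f["tumor_size_cm"],
        er_hscore=f["er_hscore"],
        pr_hscore=f["pr_hscore"],
        her2=Her2Status.NEGATIVE,
        ki67_percent=f["ki67_percent"],
        mitotic_count=_mitotic_for_ns(ns),
    )


def profile_for_amms(
    target_amms: float, coeffs: CoefficientSet | None = None
) -> TumorProfile:
    """Construct a HER2-negative tumor profile whose aMMs equals ``target_amms``.

    Solves along the favourable-to-adverse anchor segment at the Nottingham
    score that leaves the interpolation parameter closest to mid-range (so
    the resulting pathology is as ordinary as possible for that score).
    Raises :class:`ValidationError` if the target is outside the range the
    coefficient set can produce.
    """
    coeffs = coeffs or default_coefficients()
    best = None
    for ns in range(3, 10):
        a0 = compute_amms(_profile_at(0.0, ns), coeffs).amms
        a1 = compute_amms(_profile_at(1.0, ns), coeffs).amms
        if a1 == a0:
            continue
        t = (target_amms - a0) / (a1 - a0)
        if 0.0 <= t <= 1.0 and (best is None or abs(t - 0.5) < abs(best[0] - 0.5)):
            best = (t, ns)
    if best is None:
        raise ValidationError(
            f"target aMMs {target_amms} unattainable with the loaded coefficient set"
        )
    return _profile_at(*best)


def attainable_amms_range(coeffs: CoefficientSet | None = None) -> tuple[float, float]:
    """(min, max) aMMs producible by :func:`profile_for_amms`."""
    coeffs = coeffs or default_coefficients()
    vals = [
        compute_amms(_profile_at(t, ns), coeffs).amms
        for ns in (3, 9)
        for t in (0.0, 1.0)
    ]
    return min(vals), max(vals)


def _amms_band_targets(
    config: StratificationConfig, coeffs: CoefficientSet, margin: float = 0.3
) -> dict[RiskCategory, tuple[float, float]]:
    """Target intervals strictly inside each aMMs category band, clipped to
    what the coefficient set can attain and to the observed score span."""
    amin, amax = attainable_amms_range(coeffs)
    v, l = config.amms_very_low_max, config.amms_low_max
    bands = {
        RiskCategory.VERY_LOW: (max(amin + 0.05, 6.5), v - margin),
        RiskCategory.LOW: (v + margin, l - margin),
        RiskCategory.HIGH: (l + margin, min(amax - 0.05, 30.0)),
    }
    for cat, (lo, hi) in bands.items():
        if not lo < hi:
            raise ValidationError(f"empty attainable band for {cat}")
    return bands


def generate_exact_fixture(
    coeffs: CoefficientSet | None = None,
    config: StratificationConfig = DEFAULT_CONFIG,
) -> Cohort:
    """Deterministic 355-patient cohort reproducing the study's 3x3 tables.

    Guarantees, for the loaded coefficient set and default cutoffs:

    * cell counts equal ``STUDY_CELL_COUNTS`` and per-cell recurrences equal
      ``STUDY_RECURRENCE_COUNTS`` when the cohort is re-scored through the
      full pipeline;
    * the high-ODX column decomposes into 32 patients aged <= 50 with ODX
      16-25 (all 19 in the low-aMMs row, 13 non-recurrent in the high row;
      the 2 recurrent low-row patients are among them) and 21 with ODX > 25;
    * every patient passes the eligibility filter (endocrine therapy, no
      chemotherapy, HER2-negative, >= 60 months follow-up or a recurrence);
    * recurrence months lie in (3, 144), other follow-up in (60, 160).

    Re-running always yields an identical cohort.
    """
    coeffs = coeffs or default_coefficients()
    C, R = STUDY_CELL_COUNTS, STUDY_RECURRENCE_COUNTS
    bands = _amms_band_targets(config, coeffs)
    records: list[PatientRecord] = []
    serial = _count()

    for i, row_cat in enumerate(RiskCategory):
        lo, hi = bands[row_cat]
        n_row = int(C[i].sum())
        targets = iter(np.linspace(lo, hi, n_row))
        for j in range(3):
            m = int(C[i, j])
            n_rec = int(R[i, j])
            for k in range(m):
                idx = next(serial)
                recurred = k < n_rec
                # ODX value + age, honouring the table footnotes
                if j == 0:
                    odx = 1 + (idx % 10)  # < 11
                    young = False
                elif j == 1:
                    odx = 11 + (idx % 15)  # 11..25; low band requires age > 50 when >= 16
                    young = False
                else:
                    if i == 1:  # all 19 low-row/high-ODX patients: <= 50y, ODX 16-25
                        odx = 16 + (idx % 10)
                        young = True
                    elif i == 2 and not recurred and k - n_rec < 13:
                        odx = 16 + (idx % 10)  # the other 13 young patients
                        young = True
                    else:
                        odx = 26 + (idx % 19)  # > 25
                        young = False
                age = 38 + (idx % 13) if young else 52 + (idx % 33)
                if recurred:
                    month = float(6 + (idx * 9) % 136)  # within (3, 144)
                    followup = month
                else:
                    month = None
                    followup = float(63 + (idx % 88))  # within (60, 160)
                records.append(
                    PatientRecord(
                        patient_id=f"SYN{idx:04d}",
                        age_years=float(age),
                        profile=profile_for_amms(next(targets), coeffs),
                        odx_score=float(odx),
                        followup_months=followup,
                        recurred=recurred,
                        recurrence_month=month,
                        endocrine_therapy=True,
                        chemotherapy=False,
                    )
                )
    return Cohort(records)


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the stochastic cohort generator; defaults are the study conditions.

    ``cell_probabilities`` defaults to the study's 3x3 counts divided by 355
    and ``recurrence_probability_per_cell`` to the elementwise ratio of
    recurrences to counts.  ``young_fraction_high_odx`` is the fraction of
    high-ODX-category patients who are there through the age-dependent
    16-25 window (32/53 in the study).
    """

    n_patients: int = 355
    seed: int = 0
    mode: str = "category_level"  # category_level | feature_level | exact_table
    cell_probabilities: np.ndarray | None = None
    recurrence_probability_per_cell: np.ndarray | None = None
    young_fraction_high_odx: float = 32.0 / 53.0
    followup_range_months: tuple[float, float] = (60.0, 160.0)
    recurrence_window_months: tuple[float, float] = (3.0, 144.0)
    age_mean: float = 59.0
    age_sd: float = 10.0
    age_bounds: tuple[float, float] = (33.0, 84.0)

    def resolved_cells(self) -> np.ndarray:
        p = (
            STUDY_CELL_COUNTS / STUDY_CELL_COUNTS.sum()
            if self.cell_probabilities is None
            else np.asarray(self.cell_probabilities, dtype=float)
        )
        if p.shape != (3, 3) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValidationError("cell_probabilities must be a 3x3 simplex")
        return p

    def resolved_recurrence(self) -> np.ndarray:
        if self.recurrence_probability_per_cell is None:
            with np.errstate(invalid="ignore"):
                q = STUDY_RECURRENCE_COUNTS / STUDY_CELL_COUNTS
            return np.nan_to_num(q)
        q = np.asarray(self.recurrence_probability_per_cell, dtype=float)
        if q.shape != (3, 3) or (q < 0).any() or (q > 1).any():
            raise ValidationError("recurrence probabilities must be 3x3 in [0, 1]")
        return q

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValidationError("n_patients must be positive")
        if self.mode not in ("category_level", "feature_level", "exact_table"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        self.resolved_cells()
        self.resolved_recurrence()
        if not 0 <= self.young_fraction_high_odx <= 1:
            raise ValidationError("young_fraction_high_odx must be in [0, 1]")


def _sample_age(rng: np.random.Generator, params: GeneratorParams) -> float:
    lo, hi = params.age_bounds
    return float(np.clip(rng.normal(params.age_mean, params.age_sd), lo, hi))


def _sample_odx_age(
    rng: np.random.Generator, j: int, params: GeneratorParams
) -> tuple[float, float]:
    """ODX score and a compatible age for target ODX category ``j``."""
    age = _sample_age(rng, params)
    if j == 0:
        odx = float(rng.integers(0, 11))
    elif j == 1:
        odx = float(rng.integers(11, 26))
        if odx >= 16:
            age = max(age, 51.0)
    else:
        if rng.random() < params.young_fraction_high_odx:
            odx = float(rng.integers(16, 26))
            age = min(max(age, params.age_bounds[0]), 50.0)
        else:
            odx = float(rng.integers(26, 45))
            age = max(age, 51.0)
    return odx, age


def _sample_followup(
    rng: np.random.Generator, recurred: bool, params: GeneratorParams
) -> tuple[float, float | None]:
    if recurred:
        month = float(rng.uniform(*params.recurrence_window_months))
        return month, month
    return float(rng.uniform(*params.followup_range_months)), None


def generate_cohort(
    params: GeneratorParams, coeffs: CoefficientSet | None = None
) -> Cohort:
    """Seeded stochastic cohort; identical parameters give identical cohorts."""
    coeffs = coeffs or default_coefficients()
    if params.mode == "exact_table":
        return generate_exact_fixture(coeffs)
    rng = np.random.default_rng(params.seed)
    if params.mode == "category_level":
        return _generate_category_level(params, coeffs, rng)
    return _generate_feature_level(params, coeffs, rng)


def _generate_category_level(
    params: GeneratorParams, coeffs: CoefficientSet, rng: np.random.Generator
) -> Cohort:
    p = params.resolved_cells()
    q = params.resolved_recurrence()
    bands = _amms_band_targets(DEFAULT_CONFIG, coeffs)
    cells = rng.multinomial(params.n_patients, p.ravel()).reshape(3, 3)
    records = []
    idx = 0
    for i, cat in enumerate(RiskCategory):
        lo, hi = bands[cat]
        for j in range(3):
            for _ in range(int(cells[i, j])):
                target = float(rng.uniform(lo, hi))
                odx, age = _sample_odx_age(rng, j, params)
                recurred = bool(rng.random() < q[i, j])
                followup, month = _sample_followup(rng, recurred, params)
                records.append(
                    PatientRecord(
                        patient_id=f"SIM{idx:06d}",
                        age_years=age,
                        profile=profile_for_amms(target, coeffs),
                        odx_score=odx,
                        followup_months=followup,
                        recurred=recurred,
                        recurrence_month=month,
                    )
                )
                idx += 1
    return Cohort(records)


def _generate_feature_level(
    params: GeneratorParams, coeffs: CoefficientSet, rng: np.random.Generator
) -> Cohort:
    """Correlated pathology sampling along a latent aggressiveness axis.

    A single latent u in (0, 1) drives grade up, ER/PR H-scores down and
    Ki-67 up simultaneously (real pathology features co-vary; independent
    sampling would produce profile combinations never seen in practice).
    Tumor size is drawn log-normally, nearly independent of u.  ODX is then
    sampled conditionally on the *computed* aMMs category using the
    row-conditional cell probabilities.
    """
    p = params.resolved_cells()
    q = params.resolved_recurrence()
    row_cond = p / p.sum(axis=1, keepdims=True)
    n = params.n_patients
    # left-skewed latent: cohorts of this kind are dominated by lower-risk
    # tumors (mean aMMs well below the band midpoint)
    u = 0.02 + 0.88 * rng.beta(1.6, 2.8, n)
    ns = np.clip(np.rint(3 + 6 * u + rng.normal(0, 0.5, n)), 3, 9).astype(int)
    er = np.clip(300 + u * (40 - 300) + rng.normal(0, 20, n), 40, 300)
    pr = np.clip(300 * (1 - u) + rng.normal(0, 40, n), 0, 300)
    ki67 = np.clip(70 * u + rng.normal(0, 5, n), 0, 70)
    size = np.clip(rng.lognormal(np.log(1.9), 0.45, n), 0.4, 14.0)
    records = []
    for k in range(n):
        profile = TumorProfile(
            nottingham_score=int(ns[k]),
            tumor_size_cm=float(size[k]),
            er_hscore=float(er[k]),
            pr_hscore=float(pr[k]),
            her2=Her2Status.NEGATIVE,
            ki67_percent=float(ki67[k]),
            mitotic_count=_mitotic_for_ns(int(ns[k])),
        )
        i = int(categorize_amms(compute_amms(profile, coeffs).amms))
        j = int(rng.choice(3, p=row_cond[i]))
        odx, age = _sample_odx_age(rng, j, params)
        recurred = bool(rng.random() < q[i, j])
        followup, month = _sample_followup(rng, recurred, params)
        records.append(
            PatientRecord(
                patient_id=f"SIM{k:06d}",
                age_years=age,
                profile=profile,
                odx_score=odx,
                followup_months=followup,
                recurred=recurred,
                recurrence_month=month,
            )
        )
    return Cohort(records)


#: Monthly recurrence hazards by risk category for synthetic survival data
#: (ordered very low < low < high; scaled so event fractions over a typical
#: 60-160 month follow-up echo the per-category recurrence rates).
SYNTHETIC_HAZARDS = {
    RiskCategory.VERY_LOW: 0.0003,
    RiskCategory.LOW: 0.00075,
    RiskCategory.HIGH: 0.0012,
}


def synthetic_event_times(
    categories: Sequence[RiskCategory],
    rng: np.random.Generator,
    hazards: dict[RiskCategory, float] | None = None,
    censor_range_months: tuple[float, float] = (60.0, 160.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Purely synthetic DFS data: exponential event times with category-ordered
    hazards, administratively censored.  For survival-machinery property
    tests only; carries no patient-level information from any real cohort.
    """
    hazards = hazards or SYNTHETIC_HAZARDS
    cats = list(categories)
    event_t = np.array([rng.exponential(1.0 / hazards[c]) for c in cats])
    censor_t = rng.uniform(*censor_range_months, size=len(cats))
    events = event_t <= censor_t
    times = np.where(events, event_t, censor_t)
    return times, events
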