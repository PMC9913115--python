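"""Concordance tables, recurrence rates, association tests, survival, and
forego-testing strategy metrics.

The central object is a 3x3 contingency table of patients cross-classified
by aMMs risk category (rows) and Oncotype DX risk category (columns), with
an optional parallel table of recurrence counts per cell.  Everything the
evaluation reports — per-category recurrence rates, discordance rates,
chi-square comparisons of recurrence between matched categories, and the
performance of "forego ODX testing below an aMMs cutoff" strategies — is a
function of those counts.

Strategy metrics follow an assume-correct-above-cutoff rule: patients in
the forego rows are predicted non-high without testing; everyone else is
tested and therefore receives their actual ODX label.  False positives are
impossible under this rule (tested patients are always "correct"), so
specificity and PPV are identically 1; the informative quantities are
sensitivity (what fraction of truly high-ODX patients would still be
caught), NPV, the two-point AUC (sensitivity + specificity)/2, and the
fraction of the cohort spared testing.

Survival is disease-free survival: the event is breast-cancer recurrence,
and anything else (including death without recurrence) censors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as _stats

from .cohort import Cohort
from .errors import EvaluationError, ValidationError
from .magee import CoefficientSet, compute_amms
from .stratify import (
    DEFAULT_CONFIG,
    RiskCategory,
    StratificationConfig,
    categorize_amms,
    categorize_odx,
)

__all__ = [
    "ContingencyTable",
    "build_contingency",
    "StrategyMetrics",
    "strategy_metrics",
    "Rate",
    "RecurrenceRates",
    "recurrence_rates",
    "discordance_summary",
    "TestResult",
    "chi_square_2x2",
    "category_chi_square",
    "SurvivalCurve",
    "km_estimate",
    "log_rank",
    "dfs_times",
    "matched_category_logrank",
]

_CATEGORIES = (RiskCategory.VERY_LOW, RiskCategory.LOW, RiskCategory.HIGH)


@dataclass(frozen=True)
class ContingencyTable:
    """3x3 patient counts indexed (aMMs category, ODX category), with
    optional per-cell recurrence counts."""

    counts: np.ndarray
    recurrence_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (3, 3) or (counts < 0).any():
            raise ValidationError("counts must be a 3x3 array of non-negative integers")
        object.__setattr__(self, "counts", counts)
        if self.recurrence_counts is not None:
            rec = np.asarray(self.recurrence_counts, dtype=int)
            if rec.shape != (3, 3) or (rec < 0).any():
                raise ValidationError("recurrence_counts must be 3x3 non-negative")
            if (rec > counts).any():
                raise ValidationError("recurrence_counts exceed cell counts")
            object.__setattr__(self, "recurrence_counts", rec)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def amms_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def odx_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def build_contingency(
    cohort: Cohort,
    coeffs: CoefficientSet | None = None,
    config: StratificationConfig = DEFAULT_CONFIG,
) -> ContingencyTable:
    """Cross-classify every patient by computed aMMs category and ODX category.

    Raises :class:`EvaluationError` naming the offending patients if any
    record lacks an ODX score (an aMMs that cannot be computed raises the
    underlying :class:`~romma.errors.MissingInputError`).
    """
    missing = [r.patient_id for r in cohort if r.odx_score is None]
    if missing:
        raise EvaluationError(
            f"{len(missing)} record(s) without odx_score: {missing[:10]}"
        )
    counts = np.zeros((3, 3), dtype=int)
    rec = np.zeros((3, 3), dtype=int)
    for r in cohort:
        i = categorize_amms(compute_amms(r.profile, coeffs).amms, config)
        j = categorize_odx(r.odx_score, r.age_years, config)
        counts[i, j] += 1
        if r.recurred:
            rec[i, j] += 1
    return ContingencyTable(counts=counts, recurrence_counts=rec)


@dataclass(frozen=True)
class StrategyMetrics:
    """Performance of a forego-testing strategy for predicting high-ODX status.

    Metrics are proportions in [0, 1]; any member of ``undefined`` had a
    zero denominator and holds ``nan``.
    """

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    auc: float
    proportion_avoided: float
    counts: Mapping[str, int]
    undefined: frozenset[str] = frozenset()


def strategy_metrics(
    table: ContingencyTable, forego_categories: Iterable[RiskCategory]
) -> StrategyMetrics:
    """Evaluate "forego ODX testing in the given aMMs categories" on a table.

    The forego set must be downward-closed in risk (empty, {very low}, or
    {very low, low}): the strategy is an aMMs *cutoff*.  Patients in forego
    rows are predicted non-high; tested patients get their actual label, so
    FP = 0 by construction.
    """
    forego = frozenset(forego_categories)
    allowed = [
        frozenset(),
        frozenset({RiskCategory.VERY_LOW}),
        frozenset({RiskCategory.VERY_LOW, RiskCategory.LOW}),
    ]
    if forego not in allowed:
        raise ValidationError(
            "forego_categories must be downward-closed: {}, {very_low} or {very_low, low}"
        )
    counts = table.counts
    total = int(counts.sum())
    high_col = counts[:, RiskCategory.HIGH]
    fn = int(sum(high_col[c] for c in forego))
    tp = int(high_col.sum() - fn)
    fp = 0
    tn = int(counts[:, : RiskCategory.HIGH].sum())
    predicted_negative = total - tp
    avoided = int(sum(counts[c, :].sum() for c in forego))

    undefined = set()

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.add(name)
            return float("nan")
        return num / den

    sensitivity = ratio(tp, tp + fn, "sensitivity")
    specificity = ratio(tn, tn + fp, "specificity")
    ppv = 1.0 if tp + fp > 0 else ratio(tp, 0, "ppv")
    npv = ratio(tn, predicted_negative, "npv")
    auc = (sensitivity + specificity) / 2.0
    if "sensitivity" in undefined or "specificity" in undefined:
        undefined.add("auc")
    return StrategyMetrics(
        sensitivity=sensitivity,
        specificity=specificity,
        ppv=ppv,
        npv=npv,
        auc=auc,
        proportion_avoided=ratio(avoided, total, "proportion_avoided"),
        counts={
            "tp": tp,
            "fp": fp,
            "fn": fn,
            "tn": tn,
            "predicted_negative": predicted_negative,
            "total": total,
        },
        undefined=frozenset(undefined),
    )


@dataclass(frozen=True)
class Rate:
    """events / total, with ``proportion`` nan (and flagged) when total is 0."""

    events: int
    total: int

    @property
    def proportion(self) -> float:
        return self.events / self.total if self.total else float("nan")

    @property
    def defined(self) -> bool:
        return self.total > 0


@dataclass(frozen=True)
class RecurrenceRates:
    """Per-category and pooled lower-risk recurrence proportions, both axes."""

    amms: Mapping[RiskCategory, Rate]
    odx: Mapping[RiskCategory, Rate]
    pooled_lower_amms: Rate
    pooled_lower_odx: Rate
    overall: Rate


def recurrence_rates(table: ContingencyTable) -> RecurrenceRates:
    if table.recurrence_counts is None:
        raise EvaluationError("table has no recurrence counts")
    c, r = table.counts, table.recurrence_counts
    amms = {
        cat: Rate(int(r[cat, :].sum()), int(c[cat, :].sum())) for cat in _CATEGORIES
    }
    odx = {
        cat: Rate(int(r[:, cat].sum()), int(c[:, cat].sum())) for cat in _CATEGORIES
    }
    lo = slice(0, 2)  # very low + low
    return RecurrenceRates(
        amms=amms,
        odx=odx,
        pooled_lower_amms=Rate(int(r[lo, :].sum()), int(c[lo, :].sum())),
        pooled_lower_odx=Rate(int(r[:, lo].sum()), int(c[:, lo].sum())),
        overall=Rate(int(r.sum()), int(c.sum())),
    )


def discordance_summary(table: ContingencyTable) -> dict[str, Rate]:
    """Cross-scale discordance rates, and recurrence within the discordant sets.

    Keys: ``very_low_amms_high_odx`` (high-ODX fraction of the very-low-aMMs
    row), ``lower_amms_high_odx`` (pooled rows), the ODX-axis mirrors, and
    ``recurrence_in_*`` rates among those discordant patients (requires
    recurrence counts).
    """
    c = table.counts
    r = table.recurrence_counts
    lo, hi = slice(0, 2), RiskCategory.HIGH
    out = {
        "very_low_amms_high_odx": Rate(int(c[0, hi]), int(c[0, :].sum())),
        "lower_amms_high_odx": Rate(int(c[lo, hi].sum()), int(c[lo, :].sum())),
        "very_low_odx_high_amms": Rate(int(c[hi, 0]), int(c[:, 0].sum())),
        "lower_odx_high_amms": Rate(int(c[hi, lo].sum()), int(c[:, lo].sum())),
    }
    if r is not None:
        out["recurrence_in_very_low_amms_high_odx"] = Rate(int(r[0, hi]), int(c[0, hi]))
        out["recurrence_in_lower_amms_high_odx"] = Rate(
            int(r[lo, hi].sum()), int(c[lo, hi].sum())
        )
        out["recurrence_in_very_low_odx_high_amms"] = Rate(int(r[hi, 0]), int(c[hi, 0]))
        out["recurrence_in_lower_odx_high_amms"] = Rate(
            int(r[hi, lo].sum()), int(c[hi, lo].sum())
        )
    return out


@dataclass(frozen=True)
class TestResult:
    """A test statistic with its p-value; ``undefined`` marks degenerate data."""

    statistic: float
    p_value: float
    degrees_of_freedom: int
    undefined: bool = False
    note: str = ""


def chi_square_2x2(
    a: int, b: int, c: int, d: int, correction: bool = False
) -> TestResult:
    """Pearson chi-square test of independence on the 2x2 table [[a, b], [c, d]].

    Uncorrected by default (``correction=True`` applies Yates continuity);
    df = 1, p from the upper tail of chi-square(1).
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise ValidationError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise EvaluationError("degenerate margin: a row or column sums to zero")
    res = _stats.chi2_contingency(table, correction=correction)
    return TestResult(
        statistic=float(res.statistic), p_value=float(res.pvalue), degrees_of_freedom=1
    )


def category_chi_square(table: ContingencyTable) -> dict[RiskCategory, TestResult]:
    """Compare recurrence between matched aMMs and ODX categories.

    For each risk level, tests recurred/not-recurred (rows) against
    scale (aMMs margin vs ODX margin) in a 2x2 table.  Note the two margins
    overlap in patients; this mirrors the marginal comparison as reported.
    """
    rates = recurrence_rates(table)
    out = {}
    for cat in _CATEGORIES:
        ra, ro = rates.amms[cat], rates.odx[cat]
        out[cat] = chi_square_2x2(
            ra.events, ra.total - ra.events, ro.events, ro.total - ro.events
        )
    return out


@dataclass(frozen=True)
class SurvivalCurve:
    """Kaplan-Meier product-limit estimate at each distinct event time."""

    event_times: np.ndarray
    survival_probabilities: np.ndarray
    at_risk: np.ndarray

    def probability_at(self, t: float) -> float:
        """S(t): survival just after time t (right-continuous step function)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival_probabilities[idx])


def km_estimate(
    times: Sequence[float], events: Sequence[bool]
) -> SurvivalCurve:
    """Kaplan-Meier estimator; censored subjects leave the risk set at their time."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise EvaluationError("km_estimate requires at least one subject")
    if times.shape != events.shape:
        raise ValidationError("times and events must have equal length")
    if (times < 0).any():
        raise ValidationError("times must be non-negative")
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    # keep only the distinct event times (where the curve can step)
    event_times = np.unique(times[events])
    if event_times.size == 0:
        return SurvivalCurve(
            event_times=np.array([]),
            survival_probabilities=np.array([]),
            at_risk=np.array([], dtype=int),
        )
    surv = np.array(
        [float(kmf.survival_function_at_times(t).iloc[0]) for t in event_times]
    )
    at_risk = np.array([(times >= t).sum() for t in event_times], dtype=int)
    return SurvivalCurve(
        event_times=event_times, survival_probabilities=surv, at_risk=at_risk
    )


def log_rank(
    times_a: Sequence[float],
    events_a: Sequence[bool],
    times_b: Sequence[float],
    events_b: Sequence[bool],
) -> TestResult:
    """Two-group log-rank test (df = 1); ties use the hypergeometric variance.

    With no events in either group the statistic carries no information and
    the result is flagged ``undefined`` rather than raised.
    """
    ta, tb = np.asarray(times_a, float), np.asarray(times_b, float)
    ea, eb = np.asarray(events_a, bool), np.asarray(events_b, bool)
    if ta.size == 0 or tb.size == 0:
        raise EvaluationError("both groups must be non-empty")
    if not ea.any() and not eb.any():
        return TestResult(
            statistic=float("nan"),
            p_value=float("nan"),
            degrees_of_freedom=1,
            undefined=True,
            note="no events in either group",
        )
    from lifelines.statistics import logrank_test

    res = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return TestResult(
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        degrees_of_freedom=1,
    )


def dfs_times(cohort: Cohort) -> tuple[np.ndarray, np.ndarray]:
    """Disease-free-survival (time, event) arrays for a cohort."""
    t = np.array([r.event_time_months for r in cohort], dtype=float)
    e = np.array([r.recurred for r in cohort], dtype=bool)
    return t, e


def matched_category_logrank(
    cohort: Cohort,
    coeffs: CoefficientSet | None = None,
    config: StratificationConfig = DEFAULT_CONFIG,
) -> dict[RiskCategory, TestResult]:
    """Log-rank comparison of DFS between matched aMMs and ODX categories.

    For each risk level the aMMs-classified group is compared against the
    ODX-classified group (groups overlap in concordant patients, as in the
    marginal comparison)."""
    groups_a: dict[RiskCategory, list] = {c: [] for c in _CATEGORIES}
    groups_o: dict[RiskCategory, list] = {c: [] for c in _CATEGORIES}
    for r in cohort:
        amms_cat = categorize_amms(compute_amms(r.profile, coeffs).amms, config)
        groups_a[amms_cat].append(r)
        if r.odx_score is not None:
            groups_o[categorize_odx(r.odx_score, r.age_years, config)].append(r)
    out = {}
    for cat in _CATEGORIES:
        ga, go = Cohort(groups_a[cat]), Cohort(groups_o[cat])
        if len(ga) == 0 or len(go) == 0:
            out[cat] = TestResult(
                float("nan"), float("nan"), 1, undefined=True, note="empty group"
            )
            continue
        ta, ea = dfs_times(ga)
        to, eo = dfs_times(go)
        out[cat] = log_rank(ta, ea, to, eo)
    return out
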