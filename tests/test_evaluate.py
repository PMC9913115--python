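"""Evaluation calculus: tables, strategy metrics, chi-square, KM, log-rank.

Independent oracles used here:

* strategy metrics — per-patient brute-force enumeration of the
  assume-correct-above-cutoff prediction rule;
* chi-square — Monte-Carlo permutation p-value with fixed margins;
* Kaplan-Meier — hand product-limit calculations;
* log-rank — observed-minus-expected hand tally over event times.
"""

import numpy as np
import pytest
from scipy import stats as sps

from romma import (
    Cohort,
    ContingencyTable,
    EvaluationError,
    RiskCategory,
    ValidationError,
    chi_square_2x2,
    km_estimate,
    log_rank,
    recurrence_rates,
    strategy_metrics,
)
from romma.evaluate import build_contingency, discordance_summary

VL, LO, HI = RiskCategory.VERY_LOW, RiskCategory.LOW, RiskCategory.HIGH


# ---------------------------------------------------------------- contingency
def test_contingency_from_exact_fixture_rows(exact_table):
    assert exact_table.counts[VL].tolist() == [26, 30, 6]
    assert exact_table.recurrence_counts[HI].tolist() == [2, 9, 4]
    assert exact_table.total == 355


def test_contingency_empty_cohort_is_all_zero(coeffs):
    table = build_contingency(Cohort([]), coeffs)
    assert table.counts.sum() == 0 and table.recurrence_counts.sum() == 0


def test_contingency_missing_odx_lists_ids(coeffs, exact_fixture):
    import dataclasses

    bad = dataclasses.replace(exact_fixture[0], odx_score=None)
    with pytest.raises(EvaluationError, match=bad.patient_id):
        build_contingency(Cohort([bad, exact_fixture[1]]), coeffs)


def test_recurrences_cannot_exceed_counts():
    with pytest.raises(ValidationError):
        ContingencyTable(
            counts=np.ones((3, 3), dtype=int),
            recurrence_counts=np.full((3, 3), 2),
        )


# ------------------------------------------------------------ strategy metrics
def brute_force_strategy(counts, forego):
    """Enumerate every patient's predicted and actual high-ODX label."""
    tp = fp = fn = tn = avoided = 0
    for i in range(3):
        for j in range(3):
            for _ in range(int(counts[i, j])):
                actual_high = j == int(HI)
                predicted_high = (i not in forego) and actual_high
                if i in forego:
                    avoided += 1
                if predicted_high and actual_high:
                    tp += 1
                elif predicted_high:
                    fp += 1
                elif actual_high:
                    fn += 1
                else:
                    tn += 1
    total = counts.sum()
    return dict(tp=tp, fp=fp, fn=fn, tn=tn, avoided=avoided, total=int(total))


@pytest.mark.parametrize("forego", [set(), {VL}, {VL, LO}])
def test_strategy_metrics_match_brute_force_on_random_tables(rng, forego):
    for _ in range(50):
        counts = rng.integers(0, 40, size=(3, 3))
        if counts[:, int(HI)].sum() == 0 or counts.sum() == 0:
            continue
        table = ContingencyTable(counts=counts)
        m = strategy_metrics(table, forego)
        o = brute_force_strategy(counts, {int(c) for c in forego})
        assert m.counts["tp"] == o["tp"] and m.counts["fn"] == o["fn"]
        assert m.sensitivity == pytest.approx(o["tp"] / (o["tp"] + o["fn"]))
        assert m.specificity == 1.0  # FP impossible by rule
        if o["tp"] > 0:
            assert m.ppv == 1.0
        else:  # no predicted positives at all: PPV flagged, not fabricated
            assert "ppv" in m.undefined and np.isnan(m.ppv)
        assert m.npv == pytest.approx(o["tn"] / (o["total"] - o["tp"]))
        assert m.auc == pytest.approx((m.sensitivity + 1.0) / 2)
        assert m.proportion_avoided == pytest.approx(o["avoided"] / o["total"])


def test_strategy_sensitivity_decreases_avoidance_increases(rng):
    for _ in range(25):
        counts = rng.integers(1, 60, size=(3, 3))
        table = ContingencyTable(counts=counts)
        m1 = strategy_metrics(table, {VL})
        m2 = strategy_metrics(table, {VL, LO})
        assert m2.sensitivity <= m1.sensitivity + 1e-12
        assert m2.proportion_avoided >= m1.proportion_avoided - 1e-12


def test_strategy_empty_forego_is_perfect():
    table = ContingencyTable(counts=np.full((3, 3), 5))
    m = strategy_metrics(table, set())
    assert m.sensitivity == 1.0 and m.specificity == 1.0
    assert m.proportion_avoided == 0.0


def test_strategy_rejects_non_downward_closed_forego():
    table = ContingencyTable(counts=np.full((3, 3), 5))
    with pytest.raises(ValidationError):
        strategy_metrics(table, {LO})


def test_strategy_zero_high_column_flags_sensitivity():
    counts = np.array([[5, 5, 0], [5, 5, 0], [5, 5, 0]])
    m = strategy_metrics(ContingencyTable(counts=counts), {VL})
    assert "sensitivity" in m.undefined and np.isnan(m.sensitivity)


# ------------------------------------------------------------ recurrence rates
def test_recurrence_rates_on_exact_fixture(exact_table):
    rates = recurrence_rates(exact_table)
    assert (rates.amms[VL].events, rates.amms[VL].total) == (2, 62)
    assert (rates.amms[LO].events, rates.amms[LO].total) == (14, 173)
    assert (rates.amms[HI].events, rates.amms[HI].total) == (15, 120)
    assert (rates.pooled_lower_amms.events, rates.pooled_lower_amms.total) == (16, 235)
    assert (rates.pooled_lower_odx.events, rates.pooled_lower_odx.total) == (25, 302)
    assert rates.overall.proportion == pytest.approx(31 / 355)


def test_recurrence_rates_all_zero_and_undefined_cells():
    counts = np.array([[0, 1, 1], [1, 1, 1], [1, 1, 1]])
    table = ContingencyTable(counts=counts, recurrence_counts=np.zeros((3, 3), int))
    rates = recurrence_rates(table)
    assert all(r.proportion == 0.0 for r in rates.amms.values())
    empty = ContingencyTable(
        counts=np.zeros((3, 3), int), recurrence_counts=np.zeros((3, 3), int)
    )
    assert not recurrence_rates(empty).amms[VL].defined


def test_discordance_summary_on_exact_fixture(exact_table):
    d = discordance_summary(exact_table)
    assert (d["very_low_amms_high_odx"].events, d["very_low_amms_high_odx"].total) == (6, 62)
    assert (d["lower_amms_high_odx"].events, d["lower_amms_high_odx"].total) == (25, 235)
    assert (d["very_low_odx_high_amms"].events, d["very_low_odx_high_amms"].total) == (15, 94)
    assert (d["lower_odx_high_amms"].events, d["lower_odx_high_amms"].total) == (92, 302)
    assert (
        d["recurrence_in_lower_odx_high_amms"].events,
        d["recurrence_in_lower_odx_high_amms"].total,
    ) == (11, 92)
    assert d["recurrence_in_very_low_amms_high_odx"].events == 0


# ------------------------------------------------------------------ chi-square
@pytest.mark.parametrize(
    "cells,p_2dp",
    [
        ((2, 60, 7, 87), 0.27),
        ((14, 159, 18, 190), 0.84),
        ((15, 105, 6, 47), 0.83),
    ],
)
def test_chi_square_uncorrected_reproduces_two_decimal_p(cells, p_2dp):
    result = chi_square_2x2(*cells)
    assert result.degrees_of_freedom == 1
    assert round(result.p_value, 2) == p_2dp


def test_chi_square_identical_rows_gives_zero_statistic():
    result = chi_square_2x2(5, 5, 5, 5)
    assert result.statistic == pytest.approx(0.0)
    assert result.p_value == pytest.approx(1.0)


def test_chi_square_degenerate_margin_errors():
    with pytest.raises(EvaluationError):
        chi_square_2x2(0, 0, 5, 5)


def test_yates_correction_available_and_smaller_statistic():
    plain = chi_square_2x2(2, 60, 7, 87)
    corrected = chi_square_2x2(2, 60, 7, 87, correction=True)
    assert corrected.statistic < plain.statistic


def permutation_p_bracket(a, b, c, d, n_draws, rng):
    """Fixed-margin Monte-Carlo null of the Pearson statistic.

    Returns (P[S > obs], P[S >= obs]): the exact conditional null is
    discrete, so a continuous approximation can only be expected to land
    inside this bracket, not on either endpoint."""
    row1, col1, n = a + b, a + c, a + b + c + d

    def stat(a_):
        table = np.array([[a_, row1 - a_], [col1 - a_, n - row1 - col1 + a_]], float)
        exp = np.outer(table.sum(1), table.sum(0)) / n
        return ((table - exp) ** 2 / exp).sum()

    observed = stat(a)
    draws = rng.hypergeometric(col1, n - col1, row1, size=n_draws)
    sims = np.array([stat(x) for x in draws])
    return (sims > observed + 1e-9).mean(), (sims >= observed - 1e-9).mean()


@pytest.mark.parametrize("cells", [(2, 60, 7, 87), (14, 159, 18, 190), (15, 105, 6, 47)])
def test_chi_square_agrees_with_permutation_oracle(rng, cells):
    """The asymptotic p lies inside the discrete permutation bracket.

    Monte-Carlo slack fixed a priori at 3 x SE (~0.01 at 20k draws)."""
    p_strict, p_full = permutation_p_bracket(*cells, n_draws=20_000, rng=rng)
    p_asym = chi_square_2x2(*cells).p_value
    assert p_strict - 0.01 <= p_asym <= p_full + 0.01


# -------------------------------------------------------------- Kaplan-Meier
def test_km_hand_product_limit():
    # events at 10 and 30, censoring at 20:
    # S(10) = (1 - 1/3) = 2/3; at 30 the risk set is 1, so S(30) = 2/3 x 0 = 0
    curve = km_estimate([10, 20, 30], [True, False, True])
    assert curve.probability_at(10) == pytest.approx(2 / 3)
    assert curve.probability_at(30) == pytest.approx(0.0)
    assert curve.at_risk.tolist() == [3, 1]


def test_km_all_censored_is_flat_one():
    curve = km_estimate([12, 50, 70], [False, False, False])
    assert curve.event_times.size == 0
    assert curve.probability_at(100) == 1.0


def test_km_single_event_drops_to_zero():
    curve = km_estimate([42.0], [True])
    assert curve.probability_at(42.0) == 0.0
    assert curve.probability_at(41.9) == 1.0


def test_km_no_censoring_equals_empirical_survival(rng):
    times = rng.uniform(1, 100, 40)
    curve = km_estimate(times, np.ones(40, bool))
    for t in (10, 35, 70, 99):
        assert curve.probability_at(t) == pytest.approx((times > t).mean())


def test_km_empty_input_errors():
    with pytest.raises(EvaluationError):
        km_estimate([], [])


def test_km_curve_is_nonincreasing_product_limit(rng):
    times = rng.uniform(1, 120, 60)
    events = rng.random(60) < 0.5
    curve = km_estimate(times, events)
    s = curve.survival_probabilities
    assert (np.diff(s) <= 1e-12).all()
    # product-limit consistency: each step multiplies by (1 - d/n)
    expected = 1.0
    for t, n_risk, s_t in zip(curve.event_times, curve.at_risk, s):
        d = ((times == t) & events).sum()
        expected *= 1 - d / n_risk
        assert s_t == pytest.approx(expected)


# ------------------------------------------------------------------- log-rank
def test_log_rank_identical_groups_statistic_zero():
    t = [10, 20, 30, 40.0]
    e = [True, False, True, False]
    result = log_rank(t, e, t, e)
    assert result.statistic == pytest.approx(0.0, abs=1e-9)
    assert result.p_value == pytest.approx(1.0)


def test_log_rank_no_events_flagged_undefined():
    result = log_rank([10, 20], [False, False], [15, 25], [False, False])
    assert result.undefined


def test_log_rank_empty_group_errors():
    with pytest.raises(EvaluationError):
        log_rank([], [], [10], [True])


def test_log_rank_matches_hand_tally_small_example():
    """Observed-minus-expected tally over the pooled event times.

    Group A: events at 1, 2; B: event at 3, censored at 4.
    t=1: risk A2 B2, d=1, E_A = 2/4; V = (2*2*1*3)/(16*3) = 1/4
    t=2: risk A1 B2, d=1, E_A = 1/3; V = (1*2*1*2)/(9*2)  = 2/9
    t=3: risk A0 B2, d=1, E_A = 0;   V = 0
    O-E = 2 - 5/6 = 7/6; Var = 1/4 + 2/9 = 17/36; X2 = (7/6)^2/(17/36) = 49/17
    """
    result = log_rank([1.0, 2.0], [True, True], [3.0, 4.0], [True, False])
    assert result.statistic == pytest.approx(49 / 17, rel=1e-6)
    assert result.p_value == pytest.approx(sps.chi2.sf(49 / 17, 1), rel=1e-6)
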