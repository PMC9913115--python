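"""Structured evaluation reports.

``build_report`` runs the whole evaluation calculus on a scored cohort and
returns a JSON-serialisable dict — the machine-readable source of truth;
``render_text`` derives the human-readable summary from it.  Internals stay
at full precision; the text rendering rounds to the conventional display
precisions (1 decimal for table rates, whole percent for strategy metrics,
2 decimals for the AUC).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from typing import Any

from . import __version__
from .cohort import Cohort
from .evaluate import (
    build_contingency,
    category_chi_square,
    discordance_summary,
    matched_category_logrank,
    recurrence_rates,
    strategy_metrics,
)
from .magee import CoefficientSet, default_coefficients
from .stratify import DEFAULT_CONFIG, RiskCategory, StratificationConfig

__all__ = ["build_report", "render_text"]

_CATS = [RiskCategory.VERY_LOW, RiskCategory.LOW, RiskCategory.HIGH]
_FOREGO_SETS = {
    "forego_very_low": {RiskCategory.VERY_LOW},
    "forego_very_low_and_low": {RiskCategory.VERY_LOW, RiskCategory.LOW},
}


def _rate_dict(rate) -> dict[str, Any]:
    return {
        "events": rate.events,
        "total": rate.total,
        "proportion": rate.proportion if rate.defined else None,
    }


def _config_hash(config: StratificationConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def build_report(
    cohort: Cohort,
    coeffs: CoefficientSet | None = None,
    config: StratificationConfig = DEFAULT_CONFIG,
    include_survival: bool = True,
) -> dict[str, Any]:
    """Full evaluation: tables, rates, chi-square, strategy metrics, log-rank."""
    coeffs = coeffs or default_coefficients()
    table = build_contingency(cohort, coeffs, config)
    rates = recurrence_rates(table)
    chis = category_chi_square(table)
    report: dict[str, Any] = {
        "meta": {
            "package_version": __version__,
            "n_patients": len(cohort),
            "config_hash": _config_hash(config),
            "config": asdict(config),
            "coefficient_sources": {
                eq_id: eq.source for eq_id, eq in coeffs.equations.items()
            },
        },
        "contingency": {
            "counts": table.counts.tolist(),
            "recurrence_counts": table.recurrence_counts.tolist(),
            "rows": [str(c) for c in _CATS],
            "columns": [str(c) for c in _CATS],
        },
        "recurrence_rates": {
            "amms": {str(c): _rate_dict(rates.amms[c]) for c in _CATS},
            "odx": {str(c): _rate_dict(rates.odx[c]) for c in _CATS},
            "pooled_lower_amms": _rate_dict(rates.pooled_lower_amms),
            "pooled_lower_odx": _rate_dict(rates.pooled_lower_odx),
            "overall": _rate_dict(rates.overall),
        },
        "discordance": {
            k: _rate_dict(v) for k, v in discordance_summary(table).items()
        },
        "chi_square_matched_categories": {
            str(c): {
                "statistic": chis[c].statistic,
                "p_value": chis[c].p_value,
                "df": chis[c].degrees_of_freedom,
            }
            for c in _CATS
        },
        "strategy_metrics": {},
    }
    for name, forego in _FOREGO_SETS.items():
        m = strategy_metrics(table, forego)
        report["strategy_metrics"][name] = {
            "sensitivity": m.sensitivity,
            "specificity": m.specificity,
            "ppv": m.ppv,
            "npv": m.npv,
            "auc": m.auc,
            "proportion_avoided": m.proportion_avoided,
            "counts": dict(m.counts),
            "undefined": sorted(m.undefined),
        }
    if include_survival:
        lr = matched_category_logrank(cohort, coeffs, config)
        report["log_rank_matched_categories"] = {
            str(c): {
                "statistic": None if lr[c].undefined else lr[c].statistic,
                "p_value": None if lr[c].undefined else lr[c].p_value,
                "undefined": lr[c].undefined,
            }
            for c in _CATS
        }
    return report


def render_text(report: dict[str, Any]) -> str:
    """Human-readable summary derived from a ``build_report`` dict."""
    lines = []
    meta = report["meta"]
    lines.append(
        f"RoMMa evaluation — {meta['n_patients']} patients "
        f"(romma {meta['package_version']}, config {meta['config_hash']})"
    )
    cont = report["contingency"]
    lines.append("")
    lines.append("Counts (rows aMMs, columns ODX):")
    header = "              " + "".join(f"{c:>10}" for c in cont["columns"]) + "     total"
    lines.append(header)
    for label, row in zip(cont["rows"], cont["counts"]):
        lines.append(f"  {label:<12}" + "".join(f"{v:>10}" for v in row) + f"{sum(row):>10}")
    lines.append("")
    lines.append("Recurrence rates:")
    rr = report["recurrence_rates"]
    for axis in ("amms", "odx"):
        parts = []
        for c in cont["rows"]:
            d = rr[axis][c]
            pct = "n/a" if d["proportion"] is None else f"{100 * d['proportion']:.1f}%"
            parts.append(f"{c} {d['events']}/{d['total']} ({pct})")
        lines.append(f"  {axis:<5}: " + ", ".join(parts))
    ov = rr["overall"]
    lines.append(f"  overall: {ov['events']}/{ov['total']} ({100 * ov['proportion']:.1f}%)")
    lines.append("")
    lines.append("Forego-testing strategies (predicting high ODX):")
    for name, m in report["strategy_metrics"].items():
        lines.append(
            f"  {name}: sensitivity {100 * m['sensitivity']:.0f}%, "
            f"specificity {100 * m['specificity']:.0f}%, PPV {100 * m['ppv']:.0f}%, "
            f"NPV {100 * m['npv']:.0f}%, AUC {m['auc']:.2f}, "
            f"avoid testing {100 * m['proportion_avoided']:.0f}%"
        )
    lines.append("")
    lines.append("Chi-square, recurrence in matched categories (aMMs vs ODX):")
    for c, d in report["chi_square_matched_categories"].items():
        lines.append(f"  {c}: X2 = {d['statistic']:.3f}, p = {d['p_value']:.2f}")
    if "log_rank_matched_categories" in report:
        lines.append("Log-rank, DFS in matched categories:")
        for c, d in report["log_rank_matched_categories"].items():
            if d["undefined"]:
                lines.append(f"  {c}: undefined")
            else:
                lines.append(f"  {c}: X2 = {d['statistic']:.3f}, p = {d['p_value']:.2f}")
    return "\n".join(lines) + "\n"
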