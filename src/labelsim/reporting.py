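"""Summarising Monte Carlo output into result tables.

Outputs follow the reporting conventions of the analysis: medians with 95%
uncertainty intervals (empirical 2.5th/97.5th percentiles across
iterations, linear-interpolation quantile definition), mortality figures
rounded to 2 significant figures and obesity-prevalence changes to 2
decimal places — rounding applied at render time only, with full precision
retained internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError


@dataclass(frozen=True)
class SummaryCell:
    """Median and 95% uncertainty interval of one output across iterations."""

    median: float
    ui_low: float
    ui_high: float
    units: str = ""

    def __post_init__(self) -> None:
        if not (self.ui_low <= self.median <= self.ui_high):
            raise ConfigurationError("UI must bracket the median")


@dataclass(frozen=True)
class EquityResult:
    """Deprivation-equity metrics of a policy.

    ``ratio`` is the median across iterations of the per-capita DPP ratio
    between the most (Q1) and least (Q5) deprived quintiles;
    ``probability_equitable`` the fraction of iterations in which the most
    deprived quintile benefits more per capita.
    """

    ratio: float
    probability_equitable: float
    n_degenerate: int = 0  # iterations with a zero-Q5 (infinite) raw ratio

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability_equitable <= 1.0:
            raise ConfigurationError("probability must lie in [0, 1]")


def summarize(values, units: str = "") -> SummaryCell:
    """Median and empirical 95% UI of a vector of per-iteration outputs."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ConfigurationError("cannot summarise an empty vector")
    med, lo, hi = np.percentile(values, [50.0, 2.5, 97.5],
                                method="linear")
    return SummaryCell(median=float(med), ui_low=float(lo), ui_high=float(hi),
                       units=units)


def prevalence_change_pp(scenario_prevalence, baseline_prevalence) -> float:
    """Scenario-minus-baseline obesity prevalence in percentage points."""
    return (np.asarray(scenario_prevalence, dtype=float)
            - np.asarray(baseline_prevalence, dtype=float)) * 100.0


def equity_metrics(dpp_q1, dpp_q5, person_years_q1, person_years_q5,
                   tie_weight: float = 0.5) -> EquityResult:
    """Per-capita DPP equity across the deprivation gradient.

    Per iteration: ``ratio = (DPP_Q1/PY_Q1) / (DPP_Q5/PY_Q5)``.  The
    equitable-policy probability is computed on the sign of the per-capita
    difference (robust to zero-Q5 iterations, which make the raw ratio
    infinite); exact ties contribute ``tie_weight`` each.  The median ratio
    is taken over iterations with a finite ratio.
    """
    py_q1 = np.asarray(person_years_q1, dtype=float)
    py_q5 = np.asarray(person_years_q5, dtype=float)
    if np.any(py_q1 <= 0) or np.any(py_q5 <= 0):
        raise ConfigurationError("person-years must be positive in Q1 and Q5")
    rate_q1 = np.asarray(dpp_q1, dtype=float) / py_q1
    rate_q5 = np.asarray(dpp_q5, dtype=float) / py_q5
    diff = rate_q1 - rate_q5
    prob = float(np.mean(np.where(diff > 0, 1.0,
                                  np.where(diff < 0, 0.0, tie_weight))))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = rate_q1 / rate_q5
    finite = np.isfinite(ratio)
    median_ratio = float(np.median(ratio[finite])) if finite.any() else math.nan
    return EquityResult(ratio=median_ratio, probability_equitable=prob,
                        n_degenerate=int((~finite).sum()))


def probability_of_outperformance(effect_a, effect_b) -> float:
    """Fraction of paired iterations where A's effect magnitude strictly
    exceeds B's (ties excluded from the numerator)."""
    a = np.abs(np.asarray(effect_a, dtype=float))
    b = np.abs(np.asarray(effect_b, dtype=float))
    if a.shape != b.shape:
        raise ConfigurationError("outperformance needs paired iterations")
    return float(np.mean(a > b))


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def format_mortality(x: float) -> str:
    """Death counts to 2 significant figures, thousands-separated."""
    r = round_sig(x, 2)
    if math.isfinite(r) and abs(r) >= 1 and float(r) == int(r):
        return f"{int(r):,}"
    return f"{r:,}"


def format_prevalence_pp(x: float) -> str:
    """Prevalence changes to 2 decimal places."""
    return f"{x:.2f}"


def _cell_text(cell: SummaryCell, fmt) -> str:
    return f"{fmt(cell.median)} ({fmt(cell.ui_low)}; {fmt(cell.ui_high)})"


def render_scenario_table(rows: dict) -> pd.DataFrame:
    """Component-by-scenario results table.

    ``rows`` maps a (component, scenario-label) pair to a dict with
    ``prevalence`` and ``dpp`` SummaryCells.  Missing cells render as an
    explicit gap marker rather than a silent zero.
    """
    records = []
    for (component, label), cells in rows.items():
        prev = cells.get("prevalence")
        dpps = cells.get("dpp")
        records.append({
            "component": component,
            "scenario": label,
            "obesity_prevalence_change_pp":
                _cell_text(prev, format_prevalence_pp) if prev else "—",
            "deaths_prevented_or_postponed":
                _cell_text(dpps, format_mortality) if dpps else "—",
        })
    return pd.DataFrame.from_records(records)


def render_equity_table(rows: dict) -> pd.DataFrame:
    """Deprivation-quintile results with the equity metrics.

    ``rows`` maps (component, scenario-label) to a dict with per-quintile
    ``prevalence_q1/q5`` and ``dpp_q1/q5`` SummaryCells plus ``equity``
    (an EquityResult).
    """
    records = []
    for (component, label), cells in rows.items():
        eq = cells.get("equity")
        for quintile in ("q1", "q5"):
            prev = cells.get(f"prevalence_{quintile}")
            dpps = cells.get(f"dpp_{quintile}")
            records.append({
                "component": component,
                "scenario": label,
                "imd": "Q1 (most deprived)" if quintile == "q1"
                       else "Q5 (least deprived)",
                "obesity_prevalence_change_pp":
                    _cell_text(prev, format_prevalence_pp) if prev else "—",
                "deaths_prevented_or_postponed":
                    _cell_text(dpps, format_mortality) if dpps else "—",
                "dpp_per_capita_ratio_q1_q5":
                    f"{eq.ratio:.2f}" if (eq and quintile == "q1") else "",
                "probability_equitable":
                    f"{eq.probability_equitable:.2f}"
                    if (eq and quintile == "q1") else "",
            })
    return pd.DataFrame.from_records(records)
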