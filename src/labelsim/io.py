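"""Structured-text configuration files and CSV export.

Scenario files are YAML mirroring the key-assumptions table: each scenario
names its consumer-behaviour effect, reformulation effect (both as percent
reductions with a 95% CI) and a coverage schedule in fractions.  Example::

    scenarios:
      my_label:
        consumer_effect: {point: 6.5, ci: [1.9, 11.1]}       # percent
        reformulation_effect: {point: 3.9, ci: [-5.0, 12.5]}  # percent
        coverage:
          - {from_year: 0, point: 0.51, ci: [0.49, 0.52]}
        components: both
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .errors import ConfigurationError
from .population import Population
from .scenarios import (
    CoverageSchedule,
    LabelPolicy,
    ScenarioSet,
)
from .uncertainty import UncertainQuantity


def _effect_from_dict(d: dict) -> UncertainQuantity:
    """Percent-reduction entry -> fraction-scale UncertainQuantity."""
    point = float(d["point"]) / 100.0
    lo, hi = (float(x) / 100.0 for x in d.get("ci", (d["point"], d["point"])))
    return UncertainQuantity(point, min(lo, hi), max(lo, hi))


def _coverage_from_list(items) -> CoverageSchedule:
    steps = []
    for item in items:
        point = float(item["point"])
        lo, hi = (float(x) for x in item.get("ci", (point, point)))
        steps.append((int(item.get("from_year", 0)),
                      UncertainQuantity(point, lo, hi, bounds=(0.0, 1.0))))
    return CoverageSchedule(steps=tuple(steps))


def scenarios_from_dict(data: dict) -> ScenarioSet:
    if "scenarios" not in data:
        raise ConfigurationError("scenario file needs a top-level 'scenarios' map")
    out = ScenarioSet()
    for name, entry in data["scenarios"].items():
        out.add(LabelPolicy(
            name=name,
            consumer_effect=_effect_from_dict(entry["consumer_effect"]),
            reformulation_effect=_effect_from_dict(entry["reformulation_effect"]),
            coverage=_coverage_from_list(entry["coverage"]),
            components=entry.get("components", "both"),
        ))
    return out


def load_scenarios(path) -> ScenarioSet:
    with open(path) as fh:
        return scenarios_from_dict(yaml.safe_load(fh))


def export_population_csv(population: Population, path) -> Path:
    """One row per individual: id, demographics, fixed quantiles, entry year."""
    path = Path(path)
    population.to_frame().to_csv(path, index=False)
    return path


def iteration_results_frame(results) -> pd.DataFrame:
    """Tidy per-iteration outputs: one row per (iteration, scenario)."""
    rows = []
    for it in results.iterations:
        for name in results.scenario_names():
            rows.append({
                "iteration": it.iteration,
                "scenario": name,
                "prevalence_change_pp": it.prevalence_change_pp(
                    name, results.config.reporting_year),
                "dpp": it.dpp(name) * results.config.scale_factor,
                "dpp_q1": it.dpp(name, imd=0) * results.config.scale_factor,
                "dpp_q5": it.dpp(name, imd=4) * results.config.scale_factor,
                "baseline_prevalence": it.scenarios["baseline"].prevalence[-1],
            })
    return pd.DataFrame(rows)
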