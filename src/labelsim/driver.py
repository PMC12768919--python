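"""Annual open-cohort loop, paired counterfactuals, and the Monte Carlo.

One *iteration* draws a full parameter set (policy effects, relative risks
per BMI unit, mortality trend slopes), regenerates the synthetic
population from an iteration-specific seed, and then traverses the horizon
year by year for every scenario.  All scenarios of an iteration walk the
identical individuals with identical person-year uniforms (common random
numbers), so scenario contrasts — prevalence changes, deaths prevented or
postponed — isolate the policy effect from sampling noise.

Each simulated year, per scenario: add the new 30-year-old entrants ->
evaluate baseline exposures (rank-preserving quantiles under the secular
trend) -> apply the policy's energy delta and advance the weight gap ->
look up the lagged BMI change and adjust cause-specific hazards ->
simulate deaths from the shared uniforms -> age/censor at 89.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from . import reporting
from .energy_balance import EnergyBalanceParams, gap_step
from .errors import ConfigurationError
from .exposure import PackagedShareParams, policy_energy_delta
from .mortality import (
    CAUSES,
    DeathLedger,
    RelativeRiskSet,
    annual_death_probabilities,
    default_relative_risks,
    dpp,
    simulate_vital_status,
)
from .population import (
    AGE_MAX,
    AGE_MIN,
    MortalityRateTable,
    PopulationConfig,
    add_entrants,
    default_rate_table,
    generate_population,
)
from .scenarios import (
    LabelPolicy,
    ParameterDraw,
    ScenarioSet,
    coverage_at,
    point_draw,
    sample_policy,
    scenario_rng,
)

# England adults aged 30-89, the real-population anchor for absolute counts
ENGLAND_ADULTS_30_89 = 35_800_000


@dataclass
class RunConfig:
    """Run-level configuration of the microsimulation."""

    master_seed: int = 1
    n_iterations: int = 200
    horizon: tuple = (2024, 2043)
    implementation_year: int = 2024
    population: PopulationConfig = field(default_factory=PopulationConfig)
    rate_table: MortalityRateTable = None
    rr_set: RelativeRiskSet = field(default_factory=default_relative_risks)
    shares: PackagedShareParams = field(default_factory=PackagedShareParams)
    energy_balance: EnergyBalanceParams = field(default_factory=EnergyBalanceParams)
    scale_factor: float = None  # real persons per simulated person
    resample_population: bool = True  # fresh population per iteration
    sample_policy_effects: bool = True
    sample_rr: bool = True
    sample_mortality_trend: bool = True
    reporting_year: int = None  # defaults to the final horizon year

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ConfigurationError("n_iterations must be >= 1")
        if self.horizon[0] > self.horizon[1]:
            raise ConfigurationError("horizon start must not exceed end")
        if self.rate_table is None:
            self.rate_table = default_rate_table(
                ref_year=self.horizon[0], horizon=tuple(self.horizon))
        if self.scale_factor is None:
            self.scale_factor = ENGLAND_ADULTS_30_89 / max(self.population.size, 1)
        if self.scale_factor <= 0:
            raise ConfigurationError("scale factor must be positive")
        if self.reporting_year is None:
            self.reporting_year = self.horizon[1]

    @property
    def years(self) -> range:
        return range(self.horizon[0], self.horizon[1] + 1)


@dataclass
class ScenarioResult:
    """Per-year outputs of one scenario within one iteration."""

    name: str
    prevalence: np.ndarray  # (T,) obesity prevalence among the alive 30-89
    prevalence_imd: np.ndarray  # (T, 5)
    ledger: DeathLedger
    person_years_imd: np.ndarray  # (5,)
    alive_start: np.ndarray  # (T,) alive & in age range at start of year
    entrants: np.ndarray  # (T,)
    deaths: np.ndarray  # (T,)
    aged_out: np.ndarray  # (T,) newly censored at the year's start


@dataclass
class IterationResult:
    """All scenario outputs of one Monte Carlo iteration (paired draws)."""

    iteration: int
    draw: ParameterDraw
    scenarios: dict  # name -> ScenarioResult
    year0: int

    def dpp(self, name: str, imd: int | None = None) -> float:
        return dpp(self.scenarios["baseline"].ledger,
                   self.scenarios[name].ledger, imd)

    def prevalence_change_pp(self, name: str, year: int | None = None,
                             imd: int | None = None) -> float:
        yi = -1 if year is None else year - self.year0
        if imd is None:
            s = self.scenarios[name].prevalence[yi]
            b = self.scenarios["baseline"].prevalence[yi]
        else:
            s = self.scenarios[name].prevalence_imd[yi, imd]
            b = self.scenarios["baseline"].prevalence_imd[yi, imd]
        return float((s - b) * 100.0)


def draw_parameters(config: RunConfig, scenarios: ScenarioSet,
                    iteration: int) -> ParameterDraw:
    """Sample the iteration's parameter set, reproducibly.

    Shared quantities (relative risks, mortality trends) are drawn from one
    stream keyed by (master seed, iteration); each scenario's effect draws
    come from a stream keyed additionally by the scenario *name*, so the
    draw for a given scenario is invariant to which other scenarios run.
    """
    ms = config.master_seed
    shared = np.random.default_rng(
        np.random.SeedSequence(entropy=ms, spawn_key=(iteration, 0)))
    rr = (config.rr_set.sample(shared) if config.sample_rr
          else config.rr_set.points())
    trend = (config.rate_table.sample_trends(shared)
             if config.sample_mortality_trend
             else config.rate_table.trend_points())
    policies = {}
    for name in sorted(scenarios):
        policy = scenarios[name]
        if policy.is_null or not config.sample_policy_effects:
            policies[name] = point_draw(policy)
        else:
            policies[name] = sample_policy(policy, scenario_rng(ms, iteration, name))
    pop_key = (iteration, 2) if config.resample_population else (0, 2)
    pop_seed = int(np.random.SeedSequence(entropy=ms, spawn_key=pop_key)
                   .generate_state(1)[0] & 0x7FFFFFFF)
    u_seed = int(np.random.SeedSequence(entropy=ms, spawn_key=(iteration, 3))
                 .generate_state(1)[0] & 0x7FFFFFFF)
    return ParameterDraw(iteration=iteration, policies=policies, rr=rr,
                         mortality_trend=np.asarray(trend, dtype=float),
                         population_seed=pop_seed, uniform_seed=u_seed)


def _grow(arr: np.ndarray, n_new: int, fill) -> np.ndarray:
    return np.concatenate([arr, np.full(n_new, fill, dtype=arr.dtype)])


def _year_uniforms(uniform_seed: int, year: int, n: int) -> np.ndarray:
    """Shared person-year uniforms: a function of (iteration seed, year)
    and the (scenario-independent) population layout only."""
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=uniform_seed, spawn_key=(year,)))
    return rng.random(n)


def run_iteration(population_seed: int, draw: ParameterDraw,
                  scenarios: ScenarioSet, config: RunConfig) -> IterationResult:
    """Simulate one iteration: every scenario over the full horizon."""
    if "baseline" not in scenarios:
        raise ConfigurationError("the baseline scenario must be included")
    popcfg = config.population
    years = list(config.years)
    T = len(years)
    lag = config.rr_set.lag_years
    rr = np.array([draw.rr[c] for c in CAUSES])

    pop = generate_population(popcfg, population_seed)

    names = list(scenarios)
    state = {}
    for name in names:
        state[name] = {
            "gap": np.zeros(pop.n),
            "alive": np.ones(pop.n, dtype=bool),
            "history": [],  # per-year delta-BMI arrays (scenario - baseline)
            "ledger": DeathLedger(years=(years[0], years[-1]),
                                  death_year=np.full(pop.n, -1, dtype=np.int32),
                                  death_cause=np.full(pop.n, -1, dtype=np.int8)),
            "prevalence": np.zeros(T),
            "prevalence_imd": np.zeros((T, 5)),
            "person_years_imd": np.zeros(5),
            "alive_start": np.zeros(T, dtype=np.int64),
            "entrants": np.zeros(T, dtype=np.int64),
            "deaths": np.zeros(T, dtype=np.int64),
            "aged_out": np.zeros(T, dtype=np.int64),
        }

    for ti, y in enumerate(years):
        if ti > 0:
            old_n = pop.n
            entrant_seed = np.random.SeedSequence(entropy=population_seed,
                                                  spawn_key=(y,))
            pop = add_entrants(pop, y, popcfg, entrant_seed)
            n_new = pop.n - old_n
            for st in state.values():
                st["gap"] = _grow(st["gap"], n_new, 0.0)
                st["alive"] = _grow(st["alive"], n_new, True)
                st["ledger"].death_year = _grow(st["ledger"].death_year, n_new, -1)
                st["ledger"].death_cause = _grow(st["ledger"].death_cause, n_new, -1)
                st["entrants"][ti] = n_new

        age = pop.age_in(y)
        in_range = age <= AGE_MAX  # lower bound holds by construction
        h2 = pop.height ** 2
        bmi_base = popcfg.bmi_spec.quantile_from_z(pop.z_bmi, age, pop.male,
                                                   pop.imd, y)
        intake_base = popcfg.intake_spec.quantile_from_z(pop.z_intake, age,
                                                         pop.male, pop.imd, y)
        rates_y = config.rate_table.project(y, draw.mortality_trend)
        age_idx = np.clip(age - AGE_MIN, 0, AGE_MAX - AGE_MIN)
        rate_ind = rates_y[:, age_idx, pop.male.astype(int), pop.imd.astype(int)]
        u_y = _year_uniforms(draw.uniform_seed, y, pop.n)

        for name in names:
            policy: LabelPolicy = scenarios[name]
            st = state[name]
            pdraw = draw.policies[name]
            newly_out = st["alive"] & (age == AGE_MAX + 1)
            st["aged_out"][ti] = int(newly_out.sum())
            at_risk = st["alive"] & in_range
            st["alive_start"][ti] = int(at_risk.sum())

            # policy-induced energy change vs the same-year baseline intake
            if y >= config.implementation_year and not policy.is_null:
                cov = coverage_at(policy, y - config.implementation_year, pdraw)
                delta_e = policy_energy_delta(
                    intake_base, pdraw.consumer_effect,
                    pdraw.reformulation_effect, cov, policy.components,
                    config.shares).delta_total
            else:
                delta_e = 0.0

            st["gap"] = gap_step(st["gap"], delta_e, config.energy_balance, 1.0)
            delta_bmi = st["gap"] / h2
            st["history"].append(delta_bmi)
            bmi_s = bmi_base + delta_bmi

            obese = bmi_s >= 30.0
            n_imd = np.bincount(pop.imd[at_risk], minlength=5).astype(float)
            n_obese_imd = np.bincount(pop.imd[at_risk & obese],
                                      minlength=5).astype(float)
            denom = at_risk.sum()
            st["prevalence"][ti] = (at_risk & obese).sum() / denom if denom else np.nan
            with np.errstate(invalid="ignore", divide="ignore"):
                st["prevalence_imd"][ti] = np.where(n_imd > 0,
                                                    n_obese_imd / n_imd, np.nan)
            st["person_years_imd"] += n_imd

            # lagged BMI change drives mortality multipliers
            if ti - lag >= 0:
                lagged = st["history"][ti - lag]
                if lagged.shape[0] < pop.n:  # entrants after that year: no delta
                    lagged = _grow(lagged, pop.n - lagged.shape[0], 0.0)
            else:
                lagged = np.zeros(pop.n)
            mult = np.power(rr[:, None], lagged[None, :])
            q, cause_cum = annual_death_probabilities(rate_ind, mult)
            died_any, cause_idx = simulate_vital_status(q, cause_cum, u_y)
            died = died_any & at_risk
            st["ledger"].record(y, died, cause_idx, pop.imd)
            st["alive"][died] = False
            st["deaths"][ti] = int(died.sum())

    results = {}
    for name in names:
        st = state[name]
        results[name] = ScenarioResult(
            name=name, prevalence=st["prevalence"],
            prevalence_imd=st["prevalence_imd"], ledger=st["ledger"],
            person_years_imd=st["person_years_imd"],
            alive_start=st["alive_start"], entrants=st["entrants"],
            deaths=st["deaths"], aged_out=st["aged_out"])
    return IterationResult(iteration=draw.iteration, draw=draw,
                           scenarios=results, year0=years[0])


def run_monte_carlo(config: RunConfig, scenarios: ScenarioSet,
                    progress: bool = False) -> list:
    """Run the full Monte Carlo: independent parameter draws feeding
    independent, order-invariant iterations."""
    if "baseline" not in scenarios:
        raise ConfigurationError("the baseline scenario must be included")
    out = []
    t0 = time.monotonic()
    for it in range(config.n_iterations):
        draw = draw_parameters(config, scenarios, it)
        out.append(run_iteration(draw.population_seed, draw, scenarios, config))
        if progress and (it + 1) % 10 == 0:
            rate = (time.monotonic() - t0) / (it + 1)
            print(f"  iteration {it + 1}/{config.n_iterations}"
                  f" ({rate:.1f}s/iter)", flush=True)
    return out


# ---------------------------------------------------------------------------
# high-level facade
# ---------------------------------------------------------------------------


class SimulationResults:
    """Container over per-iteration results with summary accessors."""

    def __init__(self, iterations: list, config: RunConfig,
                 scenarios: ScenarioSet):
        self.iterations = iterations
        self.config = config
        self.scenarios = scenarios

    @property
    def n_iterations(self) -> int:
        return len(self.iterations)

    def scenario_names(self):
        return [n for n in self.scenarios if n != "baseline"]

    def baseline_prevalence(self, year: int | None = None) -> np.ndarray:
        """Baseline obesity prevalence (fraction) per iteration."""
        yi = -1 if year is None else year - self.config.horizon[0]
        return np.array([it.scenarios["baseline"].prevalence[yi]
                         for it in self.iterations])

    def baseline_deaths(self, scaled: bool = True) -> np.ndarray:
        f = self.config.scale_factor if scaled else 1.0
        return np.array([it.scenarios["baseline"].ledger.total_deaths() * f
                         for it in self.iterations])

    def prevalence_changes_pp(self, name: str, year: int | None = None,
                              imd: int | None = None) -> np.ndarray:
        year = self.config.reporting_year if year is None else year
        return np.array([it.prevalence_change_pp(name, year, imd)
                         for it in self.iterations])

    def dpps(self, name: str, imd: int | None = None,
             scaled: bool = True) -> np.ndarray:
        f = self.config.scale_factor if scaled else 1.0
        return np.array([it.dpp(name, imd) * f for it in self.iterations])

    def equity(self, name: str) -> reporting.EquityResult:
        dpp_q1 = self.dpps(name, imd=0, scaled=False)
        dpp_q5 = self.dpps(name, imd=4, scaled=False)
        py_q1 = np.array([it.scenarios["baseline"].person_years_imd[0]
                          for it in self.iterations])
        py_q5 = np.array([it.scenarios["baseline"].person_years_imd[4]
                          for it in self.iterations])
        return reporting.equity_metrics(dpp_q1, dpp_q5, py_q1, py_q5)

    def summary(self) -> "pd.DataFrame":
        """One row per non-baseline scenario: headline outputs."""
        import pandas as pd

        rows = []
        for name in self.scenario_names():
            prev = reporting.summarize(self.prevalence_changes_pp(name),
                                       units="percentage points")
            dpps = reporting.summarize(self.dpps(name), units="deaths")
            rows.append({
                "scenario": name,
                "prevalence_change_pp_median": prev.median,
                "prevalence_change_pp_ui_low": prev.ui_low,
                "prevalence_change_pp_ui_high": prev.ui_high,
                "dpp_median": dpps.median,
                "dpp_ui_low": dpps.ui_low,
                "dpp_ui_high": dpps.ui_high,
            })
        return pd.DataFrame(rows)

    def manifest(self) -> dict:
        """Reproducibility manifest: seeds, sizes, and per-iteration keys."""
        return {
            "master_seed": self.config.master_seed,
            "n_iterations": self.config.n_iterations,
            "horizon": list(self.config.horizon),
            "population_size": self.config.population.size,
            "entrants_per_year": self.config.population.entrants_per_year,
            "scale_factor": self.config.scale_factor,
            "scenarios": sorted(self.scenarios),
            "iteration_seeds": [
                {"iteration": it.iteration,
                 "population_seed": it.draw.population_seed,
                 "uniform_seed": it.draw.uniform_seed}
                for it in self.iterations
            ],
        }


class Microsimulation:
    """Facade tying a run configuration to a scenario set.

    >>> sim = Microsimulation(RunConfig(n_iterations=20), scenarios)
    >>> results = sim.run()
    >>> results.summary()
    """

    def __init__(self, config: RunConfig, scenarios: ScenarioSet):
        if "baseline" not in scenarios:
            raise ConfigurationError("the baseline scenario must be included")
        self.config = config
        self.scenarios = scenarios

    def run(self, progress: bool = False) -> SimulationResults:
        iterations = run_monte_carlo(self.config, self.scenarios, progress)
        return SimulationResults(iterations, self.config, self.scenarios)
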