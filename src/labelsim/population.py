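"""Synthetic England-like adult population and mortality rate tables.

The study population is an open cohort of adults aged 30-89, stratified by
sex and Index of Multiple Deprivation (IMD) quintile (Q1 = most deprived).
Because the national microdata behind the original analysis (diet survey
exposure distributions, official population projections, 1981-2016 death
registrations) are not distributable, this module generates a population
with the same *structure* from parametric stand-ins:

* BMI and daily energy intake are distributional models conditional on age,
  sex, IMD and calendar year (lognormal by default, with an LMS/Box-Cox
  alternative family), with linear year-trends so recent secular drift
  continues over the simulated horizon.
* Each individual carries fixed exposure quantiles ``u_bmi`` and
  ``u_intake`` drawn from a Gaussian copula, so life-course trajectories
  are rank-preserving: the same person sits at the same percentile of the
  (drifting) cross-sectional distribution every year.
* Cause-specific mortality (CHD, stroke, other) is a Gompertz-like rate
  table by age/sex/IMD with a log-linear calendar trend whose slope is
  uncertain, standing in for a full stochastic mortality forecast.

Default parameter values are calibrated so that the 2024 baseline looks
like England: obesity prevalence near 28% overall with a deprivation
gradient (most-deprived quintile around 32.5%, least-deprived around
24.3%), mean intake in the 2000-2200 kcal/day range, and all-cause
mortality roughly doubling every 8 years of age.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .errors import ConfigurationError, DomainError
from .uncertainty import UncertainQuantity, exact

AGE_MIN, AGE_MAX = 30, 89
N_AGES = AGE_MAX - AGE_MIN + 1
SEXES = ("female", "male")
IMD_QUINTILES = ("Q1", "Q2", "Q3", "Q4", "Q5")  # Q1 most deprived
CAUSES = ("chd", "stroke", "other")

_Z_CLIP = 8.0  # keeps copula quantiles strictly inside (0, 1)


@dataclass(frozen=True)
class Stratum:
    """One (age, sex, IMD) cell of the population."""

    age: int
    sex: str
    imd: str

    def __post_init__(self) -> None:
        if not (AGE_MIN <= self.age <= AGE_MAX):
            raise DomainError(f"age {self.age} outside [{AGE_MIN}, {AGE_MAX}]")
        if self.sex not in SEXES:
            raise DomainError(f"sex must be one of {SEXES}")
        if self.imd not in IMD_QUINTILES:
            raise DomainError(f"imd must be one of {IMD_QUINTILES}")

    @property
    def male(self) -> int:
        return int(self.sex == "male")

    @property
    def imd_index(self) -> int:
        """0 = Q1 (most deprived) ... 4 = Q5 (least deprived)."""
        return IMD_QUINTILES.index(self.imd)


@dataclass(frozen=True)
class LinearPredictor:
    """Linear predictor over (age, sex, IMD, calendar year).

    Covariates are centred: age at 60 years, IMD at the middle quintile
    (index 2), and year at the distribution's reference year, so the intercept is
    the value for a 60-year-old woman in Q3 at the reference year.
    """

    intercept: float
    age: float = 0.0  # per year of (age - 60)
    male: float = 0.0  # offset for males
    imd: float = 0.0  # per quintile step of (imd_index - 2); + = higher for Q5
    year: float = 0.0  # per calendar year past the reference year

    def evaluate(self, age, male, imd_index, year, ref_year):
        return (
            self.intercept
            + self.age * (np.asarray(age, dtype=float) - 60.0)
            + self.male * np.asarray(male, dtype=float)
            + self.imd * (np.asarray(imd_index, dtype=float) - 2.0)
            + self.year * (np.asarray(year, dtype=float) - ref_year)
        )


@dataclass(frozen=True)
class DistributionSpec:
    """Distributional exposure model conditional on stratum and year.

    families
    --------
    ``"lognormal"``
        ``X = exp(mu + sigma * z)`` with ``z`` the standard normal quantile
        of ``u``; ``mu`` is the location predictor, ``log(sigma)`` the scale
        predictor (so sigma is positive for every covariate combination).
    ``"bccg"``
        Box-Cox Cole-Green (LMS) family, the workhorse of distributional
        growth/adiposity modelling: ``X = M * (1 + L*S*z)**(1/L)`` with
        median ``M = exp(mu)``, coefficient of variation ``S = sigma`` and
        power ``L = shape`` (``L -> 0`` recovers the lognormal).
    """

    family: str
    location: LinearPredictor
    scale: LinearPredictor
    shape: float = 0.0
    ref_year: int = 2024

    def __post_init__(self) -> None:
        if self.family not in ("lognormal", "bccg"):
            raise ConfigurationError(f"unknown family {self.family!r}")

    def _params(self, age, male, imd_index, year):
        mu = self.location.evaluate(age, male, imd_index, year, self.ref_year)
        sigma = np.exp(self.scale.evaluate(age, male, imd_index, year, self.ref_year))
        return mu, sigma

    def quantile_from_z(self, z, age, male, imd_index, year):
        """Vectorised quantile function taking standard-normal scores."""
        mu, sigma = self._params(age, male, imd_index, year)
        lam = self.shape
        if self.family == "lognormal" or lam == 0.0:
            return np.exp(mu + sigma * np.asarray(z, dtype=float))
        arg = 1.0 + lam * sigma * np.asarray(z, dtype=float)
        arg = np.maximum(arg, 1e-12)  # keeps the power map defined far in the tail
        return np.exp(mu) * arg ** (1.0 / lam)

    def median(self, age, male, imd_index, year):
        return self.quantile_from_z(0.0, age, male, imd_index, year)


def exposure_at(spec: DistributionSpec, u, stratum: Stratum, year: int):
    """Quantile ``u`` of the exposure distribution for a stratum and year.

    The same ``u`` evaluated across calendar years traces the individual's
    rank-preserving trajectory under the secular trend.
    """
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0.0) or np.any(u >= 1.0):
        raise DomainError("exposure quantile u must lie strictly in (0, 1)")
    if year < spec.ref_year:
        raise DomainError(f"year {year} precedes reference year {spec.ref_year}")
    z = ndtri(u)
    out = spec.quantile_from_z(z, stratum.age, stratum.male, stratum.imd_index, year)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# population container and generation
# ---------------------------------------------------------------------------


@dataclass
class Population:
    """Columnar store of individuals; one row per person.

    Exposure quantiles are kept both as uniforms (``u_*``) and as cached
    standard-normal scores (``z_*``) because the quantile functions are
    evaluated every simulated year.
    """

    birth_year: np.ndarray
    male: np.ndarray  # int8, 0 female / 1 male
    imd: np.ndarray  # int8, 0 = Q1 most deprived ... 4 = Q5
    height: np.ndarray  # metres, fixed over life
    u_bmi: np.ndarray
    u_intake: np.ndarray
    entry_year: np.ndarray

    z_bmi: np.ndarray = field(default=None)
    z_intake: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.z_bmi is None:
            self.z_bmi = ndtri(self.u_bmi) if self.n else np.empty(0)
        if self.z_intake is None:
            self.z_intake = ndtri(self.u_intake) if self.n else np.empty(0)

    @property
    def n(self) -> int:
        return self.birth_year.shape[0]

    def age_in(self, year: int) -> np.ndarray:
        return year - self.birth_year

    def extended(self, other: "Population") -> "Population":
        """New population with ``other``'s rows appended (originals untouched)."""
        cat = {
            name: np.concatenate([getattr(self, name), getattr(other, name)])
            for name in (
                "birth_year", "male", "imd", "height",
                "u_bmi", "u_intake", "entry_year", "z_bmi", "z_intake",
            )
        }
        return Population(**cat)

    def record(self, i: int) -> "IndividualRecord":
        return IndividualRecord(
            id=i,
            birth_year=int(self.birth_year[i]),
            sex=SEXES[int(self.male[i])],
            imd=IMD_QUINTILES[int(self.imd[i])],
            height=float(self.height[i]),
            u_bmi=float(self.u_bmi[i]),
            u_intake=float(self.u_intake[i]),
            entry_year=int(self.entry_year[i]),
        )

    def to_frame(self) -> pd.DataFrame:
        """One row per individual (static attributes)."""
        return pd.DataFrame(
            {
                "id": np.arange(self.n),
                "birth_year": self.birth_year,
                "sex": np.asarray(SEXES)[self.male.astype(int)],
                "imd": np.asarray(IMD_QUINTILES)[self.imd.astype(int)],
                "height_m": self.height,
                "u_bmi": self.u_bmi,
                "u_intake": self.u_intake,
                "entry_year": self.entry_year,
            }
        )


@dataclass(frozen=True)
class IndividualRecord:
    """Static attributes of one simulated person.

    Yearly weight/BMI/intake trajectories and vital status are produced by
    the simulation driver and attached to run results, not stored here: the
    same person is traversed under several counterfactual scenarios.
    """

    id: int
    birth_year: int
    sex: str
    imd: str
    height: float
    u_bmi: float
    u_intake: float
    entry_year: int


def _default_age_weights() -> np.ndarray:
    """Stylised England 30-89 age structure: flat to the mid-50s, then a
    smooth decline as cohort sizes and survivorship fall off."""
    ages = np.arange(AGE_MIN, AGE_MAX + 1)
    w = np.where(ages <= 55, 1.0, np.exp(-0.045 * (ages - 55)))
    return w / w.sum()


@dataclass
class PopulationConfig:
    """Generating configuration for the synthetic open cohort."""

    size: int = 50_000
    start_year: int = 2024
    bmi_spec: DistributionSpec = None
    intake_spec: DistributionSpec = None
    copula_rho: float = 0.25  # Gaussian copula corr between u_bmi and u_intake
    sex_weights: tuple = (0.51, 0.49)  # female, male
    imd_weights: tuple = (0.2, 0.2, 0.2, 0.2, 0.2)
    age_weights: np.ndarray = None
    height_mean: tuple = (1.618, 1.757)  # metres; female, male
    height_sd: tuple = (0.062, 0.068)
    height_bounds: tuple = (1.30, 2.10)
    entrants_per_year: int = None  # new 30-year-olds per simulated year

    def __post_init__(self) -> None:
        if self.bmi_spec is None:
            self.bmi_spec = default_bmi_spec()
        if self.intake_spec is None:
            self.intake_spec = default_intake_spec()
        if self.age_weights is None:
            self.age_weights = _default_age_weights()
        if self.entrants_per_year is None:
            # England: ~0.02 of the 30-89 adult stock turns 30 each year
            self.entrants_per_year = int(round(self.size * 0.0196))
        self.validate()

    def validate(self) -> None:
        if self.size < 0:
            raise ConfigurationError("population size must be non-negative")
        for name, w in (("sex_weights", self.sex_weights),
                        ("imd_weights", self.imd_weights),
                        ("age_weights", self.age_weights)):
            w = np.asarray(w, dtype=float)
            if np.any(w < 0) or not np.isclose(w.sum(), 1.0, atol=1e-8):
                raise ConfigurationError(f"{name} must be non-negative and sum to 1")
        if not -1.0 <= self.copula_rho <= 1.0:
            raise ConfigurationError("copula correlation must lie in [-1, 1]")
        if self.entrants_per_year < 0:
            raise ConfigurationError("entrant counts must be non-negative")

    def with_size(self, size: int) -> "PopulationConfig":
        return replace(self, size=size,
                       entrants_per_year=int(round(size * self.entrants_per_year
                                                   / max(self.size, 1))))


def default_bmi_spec() -> DistributionSpec:
    """Lognormal BMI model calibrated to a ~28% obesity baseline in 2024.

    The IMD slope reproduces the observed deprivation gradient in obesity
    (roughly 8 percentage points between extreme quintiles); the year trend
    continues the slow secular rise in adult BMI.
    """
    return DistributionSpec(
        family="lognormal",
        location=LinearPredictor(
            intercept=3.3122,  # median BMI ~27.4 kg/m2 for the reference cell
            age=0.0008,
            male=0.004,
            imd=-0.0106,  # BMI falls toward the least deprived quintile
            year=0.0006,  # slow continuing rise; recent adult BMI drift is nearly flat
        ),
        scale=LinearPredictor(intercept=np.log(0.160)),
        ref_year=2024,
    )


def default_intake_spec() -> DistributionSpec:
    """Lognormal daily energy intake (kcal/day), mean ~2000-2200 in 2024."""
    return DistributionSpec(
        family="lognormal",
        location=LinearPredictor(
            intercept=np.log(1925.0),
            age=-0.0020,
            male=0.165,
            imd=-0.004,  # slightly higher intake in more deprived quintiles
            year=-0.0010,  # continuing slow decline in reported energy intake
        ),
        scale=LinearPredictor(intercept=np.log(0.22)),
        ref_year=2024,
    )


def _draw_copula(rng: np.random.Generator, n: int, rho: float):
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + np.sqrt(max(0.0, 1.0 - rho * rho)) * rng.standard_normal(n)
    z1 = np.clip(z1, -_Z_CLIP, _Z_CLIP)
    z2 = np.clip(z2, -_Z_CLIP, _Z_CLIP)
    return z1, z2


def _draw_individuals(rng, n, config, ages, entry_year):
    male = (rng.random(n) < config.sex_weights[1]).astype(np.int8)
    imd = rng.choice(5, size=n, p=np.asarray(config.imd_weights, float)).astype(np.int8)
    z_bmi, z_intake = _draw_copula(rng, n, config.copula_rho)
    mean = np.asarray(config.height_mean)[male]
    sd = np.asarray(config.height_sd)[male]
    height = np.clip(mean + sd * rng.standard_normal(n), *config.height_bounds)
    return Population(
        birth_year=(entry_year - ages).astype(np.int32),
        male=male,
        imd=imd,
        height=height,
        u_bmi=ndtr(z_bmi),
        u_intake=ndtr(z_intake),
        entry_year=np.full(n, entry_year, dtype=np.int32),
        z_bmi=z_bmi,
        z_intake=z_intake,
    )


def generate_population(config: PopulationConfig, seed) -> Population:
    """Generate the initial cross-section of the open cohort.

    Deterministic given ``seed`` (an int or :class:`numpy.random.SeedSequence`).
    """
    config.validate()
    n = config.size
    if n == 0:
        e = np.empty(0)
        return Population(e.astype(np.int32), e.astype(np.int8), e.astype(np.int8),
                          e, e, e, e.astype(np.int32), e, e)
    rng = np.random.default_rng(seed)
    ages = rng.choice(np.arange(AGE_MIN, AGE_MAX + 1), size=n,
                      p=np.asarray(config.age_weights, float))
    return _draw_individuals(rng, n, config, ages, config.start_year)


def add_entrants(population: Population, year: int, config: PopulationConfig,
                 seed) -> Population:
    """Append the year's new 30-year-old entrants; existing rows untouched."""
    n_new = config.entrants_per_year
    if n_new == 0:
        return population
    rng = np.random.default_rng(seed)
    entrants = _draw_individuals(rng, n_new, config,
                                 np.full(n_new, AGE_MIN), year)
    return population.extended(entrants)


# ---------------------------------------------------------------------------
# mortality rate tables
# ---------------------------------------------------------------------------


@dataclass
class MortalityRateTable:
    """Cause-specific baseline mortality rates with a log-linear trend.

    ``rates[cause, age - 30, sex, imd]`` are events per person-year at the
    reference year.  Projection multiplies by ``exp(trend * (year - ref))``
    per cause; the trend slope is an :class:`UncertainQuantity` standing in
    for the uncertainty of a full mortality forecast.
    """

    rates: np.ndarray  # shape (3, 60, 2, 5)
    trend: dict  # cause -> UncertainQuantity (log slope per year)
    ref_year: int = 2024
    horizon: tuple = (2024, 2043)

    def __post_init__(self) -> None:
        if self.rates.shape != (len(CAUSES), N_AGES, 2, 5):
            raise ConfigurationError(
                f"rates must have shape {(len(CAUSES), N_AGES, 2, 5)}"
            )
        if np.any(self.rates < 0):
            raise ConfigurationError("mortality rates must be non-negative")

    def trend_points(self) -> np.ndarray:
        return np.array([self.trend[c].point for c in CAUSES])

    def sample_trends(self, rng: np.random.Generator) -> np.ndarray:
        return np.array([self.trend[c].sample(rng) for c in CAUSES])

    def project(self, year: int, sampled_trend) -> np.ndarray:
        """Rates for ``year`` under the sampled per-cause trend slopes."""
        lo, hi = self.horizon
        if not lo <= year <= hi:
            raise DomainError(f"year {year} outside horizon [{lo}, {hi}]")
        t = np.asarray(sampled_trend, dtype=float).reshape(len(CAUSES), 1, 1, 1)
        out = self.rates * np.exp(t * (year - self.ref_year))
        # rates stay valid annual hazards: probability 1-exp(-h) is then in [0,1]
        return np.clip(out, 0.0, None)


def project_rates(table: MortalityRateTable, year: int, sampled_trend):
    """Functional alias for :meth:`MortalityRateTable.project`."""
    return table.project(year, sampled_trend)


def default_rate_table(ref_year: int = 2024,
                       horizon: tuple = (2024, 2043)) -> MortalityRateTable:
    """Gompertz-like synthetic England rate table.

    All-cause mortality near 0.7% at age 60, doubling roughly every 8 years
    of age; CHD and stroke carry steeper age gradients and larger male and
    deprivation differentials than the residual "other" cause.  Trend slopes
    continue the long historical decline (fast for CVD, slower for the
    rest), each with an uncertain slope.
    """
    ages = np.arange(AGE_MIN, AGE_MAX + 1, dtype=float)
    # base rate at age 60 (female, middle quintile), Gompertz slope per cause
    base = {"chd": (9.0e-4, 0.105), "stroke": (5.0e-4, 0.110),
            "other": (5.6e-3, 0.092)}
    male_mult = {"chd": 1.6, "stroke": 1.15, "other": 1.25}
    imd_slope = {"chd": -0.16, "stroke": -0.12, "other": -0.13}  # per step toward Q5
    rates = np.zeros((len(CAUSES), N_AGES, 2, 5))
    imd_idx = np.arange(5, dtype=float)
    for ci, cause in enumerate(CAUSES):
        a0, b = base[cause]
        age_curve = a0 * np.exp(b * (ages - 60.0))
        for sex in (0, 1):
            s_mult = male_mult[cause] if sex else 1.0
            rates[ci, :, sex, :] = (
                age_curve[:, None] * s_mult
                * np.exp(imd_slope[cause] * (imd_idx - 2.0))[None, :]
            )
    trend = {
        "chd": UncertainQuantity(-0.030, -0.040, -0.020),
        "stroke": UncertainQuantity(-0.025, -0.035, -0.015),
        "other": UncertainQuantity(-0.010, -0.016, -0.004),
    }
    return MortalityRateTable(rates=rates, trend=trend,
                              ref_year=ref_year, horizon=horizon)


def fixed_trend_table(table: MortalityRateTable) -> MortalityRateTable:
    """Copy of ``table`` with trend uncertainty collapsed to the point."""
    return MortalityRateTable(
        rates=table.rates,
        trend={c: exact(q.point) for c, q in table.trend.items()},
        ref_year=table.ref_year,
        horizon=table.horizon,
    )
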