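"""Synthetic population: strata, copula, rank preservation, rate tables."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import labelsim as ls
from labelsim.errors import ConfigurationError, DomainError
from labelsim.population import (
    LinearPredictor,
    add_entrants,
    default_rate_table,
    exposure_at,
    project_rates,
)


class TestGeneratePopulation:
    def test_zero_size_yields_empty_population(self):
        cfg = ls.PopulationConfig(size=0, entrants_per_year=0)
        pop = ls.generate_population(cfg, seed=1)
        assert pop.n == 0

    def test_same_seed_reproduces_identical_individuals(self):
        cfg = ls.PopulationConfig(size=1_000)
        a = ls.generate_population(cfg, seed=7)
        b = ls.generate_population(cfg, seed=7)
        for f in ("birth_year", "male", "imd", "height", "u_bmi", "u_intake"):
            np.testing.assert_array_equal(getattr(a, f), getattr(b, f))

    def test_equal_stratum_weights_recovered(self):
        cfg = ls.PopulationConfig(size=100_000)
        pop = ls.generate_population(cfg, seed=3)
        freqs = np.bincount(pop.imd, minlength=5) / pop.n
        assert np.all(np.abs(freqs - 0.20) < 0.01)

    def test_quantiles_open_interval_heights_bounded(self, small_population):
        cfg, pop = small_population
        for u in (pop.u_bmi, pop.u_intake):
            assert np.all((u > 0.0) & (u < 1.0))
        lo, hi = cfg.height_bounds
        assert np.all((pop.height >= lo) & (pop.height <= hi))

    def test_exposures_strictly_positive(self, small_population):
        cfg, pop = small_population
        age = pop.age_in(2024)
        bmi = cfg.bmi_spec.quantile_from_z(pop.z_bmi, age, pop.male, pop.imd, 2024)
        intake = cfg.intake_spec.quantile_from_z(pop.z_intake, age, pop.male,
                                                 pop.imd, 2024)
        assert np.all(bmi > 0) and np.all(intake > 0)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ConfigurationError):
            ls.PopulationConfig(size=10, imd_weights=(0.5, 0.5, 0.5, 0.0, 0.0))
        with pytest.raises(ConfigurationError):
            ls.PopulationConfig(size=-5)


class TestCopula:
    def test_spearman_correlation_matches_configured_copula(self):
        """Gaussian copula rho maps to Spearman (6/pi) asin(rho/2)."""
        rho = 0.25
        cfg = ls.PopulationConfig(size=50_000, copula_rho=rho)
        pop = ls.generate_population(cfg, seed=5)
        age = pop.age_in(2024)
        bmi = cfg.bmi_spec.quantile_from_z(pop.z_bmi, age, pop.male, pop.imd, 2024)
        intake = cfg.intake_spec.quantile_from_z(pop.z_intake, age, pop.male,
                                                 pop.imd, 2024)
        expected = 6.0 / np.pi * np.arcsin(rho / 2.0)
        got = stats.spearmanr(bmi, intake).statistic
        assert abs(got - expected) < 0.03


class TestExposureAt:
    def test_median_of_lognormal_is_exp_location(self):
        spec = ls.DistributionSpec(
            family="lognormal",
            location=LinearPredictor(intercept=np.log(27.0)),
            scale=LinearPredictor(intercept=np.log(0.15)),
        )
        s = ls.Stratum(age=60, sex="female", imd="Q3")
        assert exposure_at(spec, 0.5, s, 2024) == pytest.approx(27.0)

    @given(u1=st.floats(0.01, 0.98), du=st.floats(0.005, 0.019))
    def test_monotone_in_quantile(self, u1, du):
        cfg = ls.PopulationConfig(size=0, entrants_per_year=0)
        s = ls.Stratum(age=45, sex="male", imd="Q1")
        assert (exposure_at(cfg.bmi_spec, u1, s, 2030)
                < exposure_at(cfg.bmi_spec, u1 + du, s, 2030))

    def test_zero_trend_gives_identical_values_across_years(self):
        spec = ls.DistributionSpec(
            family="lognormal",
            location=LinearPredictor(intercept=3.3, year=0.0),
            scale=LinearPredictor(intercept=np.log(0.16)),
        )
        s = ls.Stratum(age=50, sex="female", imd="Q2")
        assert exposure_at(spec, 0.7, s, 2024) == exposure_at(spec, 0.7, s, 2034)

    def test_rank_preservation_cross_section_matches_spec(self):
        """PIT check: mapping each generated value back through its own
        stratum-year CDF must give uniforms (KS test, alpha=0.01)."""
        cfg = ls.PopulationConfig(size=50_000)
        pop = ls.generate_population(cfg, seed=9)
        year = 2030
        age = pop.age_in(year)
        bmi = cfg.bmi_spec.quantile_from_z(pop.z_bmi, age, pop.male, pop.imd, year)
        mu, sigma = cfg.bmi_spec._params(age, pop.male, pop.imd, year)
        u_back = stats.norm.cdf((np.log(bmi) - mu) / sigma)
        # u_back should equal the original copula uniforms and be U(0,1)
        np.testing.assert_allclose(u_back, pop.u_bmi, atol=1e-9)
        assert stats.kstest(u_back, "uniform").pvalue > 0.01

    def test_u_outside_open_interval_rejected(self):
        cfg = ls.PopulationConfig(size=0, entrants_per_year=0)
        s = ls.Stratum(age=40, sex="female", imd="Q4")
        for bad in (0.0, 1.0, -0.2, 1.7):
            with pytest.raises(DomainError):
                exposure_at(cfg.bmi_spec, bad, s, 2025)

    def test_bccg_family_reduces_to_lognormal_at_zero_shape(self):
        loc = LinearPredictor(intercept=np.log(25.0))
        sc = LinearPredictor(intercept=np.log(0.2))
        ln = ls.DistributionSpec("lognormal", loc, sc)
        bc = ls.DistributionSpec("bccg", loc, sc, shape=0.0)
        s = ls.Stratum(age=60, sex="male", imd="Q3")
        for u in (0.1, 0.5, 0.9):
            assert exposure_at(bc, u, s, 2024) == pytest.approx(
                exposure_at(ln, u, s, 2024))


class TestStratum:
    @pytest.mark.parametrize("kwargs", [
        {"age": 29, "sex": "female", "imd": "Q1"},
        {"age": 90, "sex": "male", "imd": "Q5"},
        {"age": 50, "sex": "m", "imd": "Q1"},
        {"age": 50, "sex": "male", "imd": "Q6"},
    ])
    def test_invalid_strata_rejected(self, kwargs):
        with pytest.raises(DomainError):
            ls.Stratum(**kwargs)


class TestMortalityRates:
    def test_zero_trend_is_identity(self):
        table = default_rate_table()
        np.testing.assert_array_equal(project_rates(table, 2043, [0, 0, 0]),
                                      table.rates)

    def test_negative_trend_declines_monotonically(self):
        table = default_rate_table()
        r = project_rates(table, 2030, [-0.02, -0.02, -0.02])
        assert np.all(r < table.rates)

    def test_trend_closed_form_over_ten_years(self):
        table = default_rate_table()
        r = project_rates(table, 2034, [-0.02, -0.02, -0.02])
        np.testing.assert_allclose(r, table.rates * np.exp(-0.2), rtol=1e-12)

    def test_year_outside_horizon_rejected(self):
        table = default_rate_table()
        with pytest.raises(DomainError):
            project_rates(table, 2050, [0, 0, 0])

    def test_all_rates_give_valid_probabilities(self):
        table = default_rate_table()
        for year in (2024, 2043):
            r = project_rates(table, year, table.trend_points())
            q = -np.expm1(-r.sum(axis=0))
            assert np.all((q >= 0) & (q <= 1))


class TestAddEntrants:
    def test_zero_schedule_leaves_population_unchanged(self, small_population):
        cfg, pop = small_population
        cfg0 = ls.PopulationConfig(size=cfg.size, entrants_per_year=0)
        out = add_entrants(pop, 2025, cfg0, seed=1)
        assert out.n == pop.n

    def test_schedule_grows_population_by_exact_count(self, small_population):
        cfg, pop = small_population
        cfg500 = ls.PopulationConfig(size=cfg.size, entrants_per_year=500)
        out = add_entrants(pop, 2025, cfg500, seed=1)
        assert out.n == pop.n + 500
        assert np.all(out.birth_year[pop.n:] == 2025 - 30)
        assert np.all(out.entry_year[pop.n:] == 2025)
        # existing records untouched
        np.testing.assert_array_equal(out.u_bmi[:pop.n], pop.u_bmi)

    def test_entrants_deterministic_given_seed(self, small_population):
        cfg, pop = small_population
        a = add_entrants(pop, 2026, cfg, seed=123)
        b = add_entrants(pop, 2026, cfg, seed=123)
        np.testing.assert_array_equal(a.u_intake, b.u_intake)
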