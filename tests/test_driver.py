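"""Open-cohort loop, paired counterfactuals, Monte Carlo orchestration."""

import numpy as np
import pytest

import labelsim as ls
from labelsim.driver import draw_parameters, run_iteration
from labelsim.errors import ConfigurationError


def _cfg(size=3_000, iters=2, **kw):
    return ls.RunConfig(master_seed=5, n_iterations=iters,
                        population=ls.PopulationConfig(size=size), **kw)


class TestRunIteration:
    def test_baseline_only_gives_zero_contrasts(self, builtin):
        scen = builtin.subset(["baseline"])
        cfg = _cfg()
        draw = draw_parameters(cfg, scen, 0)
        res = run_iteration(draw.population_seed, draw, scen, cfg)
        assert res.dpp("baseline") == 0.0
        assert res.prevalence_change_pp("baseline") == 0.0

    def test_missing_baseline_rejected(self, builtin):
        scen = ls.ScenarioSet()
        scen.add(builtin["mandatory_TLL"])
        cfg = _cfg()
        with pytest.raises(ConfigurationError):
            run_iteration(1, draw_parameters(cfg, scen, 0), scen, cfg)

    def test_identical_seeds_bit_identical_results(self, builtin):
        scen = builtin.subset(["baseline", "mandatory_NWL"])
        cfg = _cfg()
        outs = []
        for _ in range(2):
            draw = draw_parameters(cfg, scen, 0)
            outs.append(run_iteration(draw.population_seed, draw, scen, cfg))
        a, b = outs
        for name in scen:
            np.testing.assert_array_equal(a.scenarios[name].prevalence,
                                          b.scenarios[name].prevalence)
            np.testing.assert_array_equal(a.scenarios[name].ledger.counts,
                                          b.scenarios[name].ledger.counts)
            np.testing.assert_array_equal(a.scenarios[name].ledger.death_year,
                                          b.scenarios[name].ledger.death_year)

    def test_open_cohort_accounting_identity(self, small_run):
        """alive(y+1) = alive(y) + entrants(y+1) - deaths(y) - aged_out(y+1),
        exactly, for every scenario and iteration."""
        cfg, scen, res = small_run
        for it in res.iterations:
            for s in it.scenarios.values():
                lhs = s.alive_start[1:]
                rhs = (s.alive_start[:-1] + s.entrants[1:]
                       - s.deaths[:-1] - s.aged_out[1:])
                np.testing.assert_array_equal(lhs, rhs)

    def test_scenario_order_invariance(self, builtin):
        cfg = _cfg()
        fwd = builtin.subset(["baseline", "mandatory_TLL", "mandatory_NWL"])
        rev = builtin.subset(["baseline", "mandatory_NWL", "mandatory_TLL"])
        d1 = draw_parameters(cfg, fwd, 0)
        d2 = draw_parameters(cfg, rev, 0)
        r1 = run_iteration(d1.population_seed, d1, fwd, cfg)
        r2 = run_iteration(d2.population_seed, d2, rev, cfg)
        for name in ("mandatory_TLL", "mandatory_NWL"):
            assert r1.dpp(name) == r2.dpp(name)
            np.testing.assert_array_equal(r1.scenarios[name].prevalence,
                                          r2.scenarios[name].prevalence)

    def test_stronger_policy_reduces_prevalence_more(self, builtin):
        """At point estimates the nutrient-warning label (12.9% x 51%)
        must beat the traffic light (6.5% x 25%) on the same draws."""
        scen = builtin.subset(["baseline", "mandatory_TLL", "mandatory_NWL"])
        cfg = _cfg(size=20_000, sample_policy_effects=False)
        draw = draw_parameters(cfg, scen, 0)
        res = run_iteration(draw.population_seed, draw, scen, cfg)
        assert (res.prevalence_change_pp("mandatory_NWL")
                <= res.prevalence_change_pp("mandatory_TLL") < 0.0)

    def test_policy_cannot_add_deaths_with_shared_draws(self, small_run):
        """Per individual: scenario death year is never earlier than the
        baseline death year when BMI only falls."""
        cfg, scen, res = small_run
        for it in res.iterations:
            base = it.scenarios["baseline"].ledger
            for name in ("mandatory_TLL", "mandatory_NWL"):
                led = it.scenarios[name].ledger
                both = (base.death_year >= 0) & (led.death_year >= 0)
                assert np.all(led.death_year[both] >= base.death_year[both])
                # scenario-only deaths would violate pairing
                assert not np.any((led.death_year >= 0) & (base.death_year < 0))


class TestMonteCarlo:
    def test_single_iteration_runs(self, builtin):
        scen = builtin.subset(["baseline", "mandatory_TLL"])
        res = ls.Microsimulation(_cfg(iters=1), scen).run()
        assert res.n_iterations == 1

    def test_same_seed_identical_collections(self, builtin):
        scen = builtin.subset(["baseline", "mandatory_TLL"])
        r1 = ls.Microsimulation(_cfg(size=2_000, iters=3), scen).run()
        r2 = ls.Microsimulation(_cfg(size=2_000, iters=3), scen).run()
        np.testing.assert_array_equal(r1.dpps("mandatory_TLL"),
                                      r2.dpps("mandatory_TLL"))
        np.testing.assert_array_equal(
            r1.prevalence_changes_pp("mandatory_TLL"),
            r2.prevalence_changes_pp("mandatory_TLL"))
        assert r1.manifest() == r2.manifest()

    def test_iterations_differ_under_resampling(self, small_run):
        cfg, scen, res = small_run
        prev = res.prevalence_changes_pp("mandatory_NWL")
        assert len(np.unique(prev)) > 1

    def test_scaling_population_doubles_death_counts(self, builtin):
        """Doubling the simulated population roughly doubles raw deaths and
        leaves prevalence unchanged within Monte Carlo error."""
        scen = builtin.subset(["baseline"])
        r1 = ls.Microsimulation(_cfg(size=4_000, iters=1), scen).run()
        r2 = ls.Microsimulation(_cfg(size=8_000, iters=1), scen).run()
        d1 = r1.baseline_deaths(scaled=False)[0]
        d2 = r2.baseline_deaths(scaled=False)[0]
        assert d2 / d1 == pytest.approx(2.0, rel=0.1)
        p1 = r1.baseline_prevalence()[0]
        p2 = r2.baseline_prevalence()[0]
        assert p1 == pytest.approx(p2, abs=0.02)

    def test_summary_frame_shape(self, small_run):
        cfg, scen, res = small_run
        df = res.summary()
        assert set(df["scenario"]) == {"mandatory_TLL", "mandatory_NWL"}
        assert (df["prevalence_change_pp_ui_low"]
                <= df["prevalence_change_pp_median"]).all()


class TestEquityAccessors:
    def test_equity_result_well_formed(self, small_run):
        cfg, scen, res = small_run
        eq = res.equity("mandatory_NWL")
        assert 0.0 <= eq.probability_equitable <= 1.0
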