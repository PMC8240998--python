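"""HIV acquisition, CD4 dynamics, ART and mortality risk."""

import numpy as np
import pytest

from conftest import make_adult_cohort
from hivncd import FixtureSpec, SimulationConfig, Simulation
from hivncd.hiv import (ArtSchedule, HivParams, acquire_hiv,
                        hiv_mortality_multiplier, initiate_art, progress_cd4)
from hivncd.rates import FEMALE, MALE, RateTable
from hivncd.synthetic import make_hiv_epidemic, make_parameter_set


class TestAcquisition:
    def test_zero_incidence_never_infected(self):
        pop = make_adult_cohort(2000)
        rng = np.random.default_rng(0)
        for step in range(24):
            acquire_hiv(pop, RateTable.constant(0.0), HivParams(),
                        2000 + step / 12, 1 / 12, rng)
        assert not pop.hiv[: pop.n].any()

    def test_constant_incidence_closed_form(self):
        # annual infection fraction among susceptibles ~ 1 - exp(-i)
        i, n = 0.05, 40_000
        pop = make_adult_cohort(n)
        rng = np.random.default_rng(1)
        for step in range(12):
            acquire_hiv(pop, RateTable.constant(i), HivParams(),
                        2000 + step / 12, 1 / 12, rng)
        frac = pop.hiv[: pop.n].mean()
        expected = 1 - np.exp(-i)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) < 3 * se

    def test_incidence_held_at_2017_level(self):
        # projection rows after 2017 equal the 2017 row
        inc, _ = make_hiv_epidemic(FixtureSpec())
        ages = np.array([27.0])
        sexes = np.array([FEMALE], dtype=np.int8)
        v2017 = inc.lookup(ages, sexes, 2017.5)
        for year in (2018.5, 2025.5, 2034.5):
            np.testing.assert_allclose(inc.lookup(ages, sexes, year), v2017)
        assert inc.lookup(ages, sexes, 1975.0)[0] == 0.0

    def test_cd4_assigned_at_seroconversion(self):
        pop = make_adult_cohort(5000)
        rng = np.random.default_rng(2)
        acquire_hiv(pop, RateTable.constant(5.0), HivParams(), 2000.0, 1.0, rng)
        plwh = pop.hiv[: pop.n]
        assert plwh.mean() > 0.9
        assert np.isfinite(pop.cd4[: pop.n][plwh]).all()
        assert (pop.cd4[: pop.n][plwh] >= 0).all()


class TestCd4:
    def test_linear_decline_rule(self):
        pop = make_adult_cohort(1, sex=MALE)
        pop.hiv[0] = True
        pop.cd4[0] = 500.0
        progress_cd4(pop, HivParams(cd4_decline_male=60.0), 1.0)
        assert pop.cd4[0] == pytest.approx(440.0)

    def test_on_art_non_decreasing_and_capped(self):
        pop = make_adult_cohort(1, sex=FEMALE)
        pop.hiv[0] = True
        pop.on_art[0] = True
        pop.art_start[0] = 2000.0
        pop.cd4[0] = 200.0
        prev = 200.0
        for k in range(80):
            progress_cd4(pop, HivParams(), 1 / 12)
            assert pop.cd4[0] >= prev - 1e-12
            prev = pop.cd4[0]
        assert prev <= HivParams().cd4_plateau + 1e-9

    def test_population_decline_slope_recovered(self):
        # regression of mean CD4 on time reproduces the configured slope
        pop = make_adult_cohort(3000, sex=MALE)
        n = pop.n
        pop.hiv[:n] = True
        pop.cd4[:n] = 600.0
        params = HivParams(cd4_decline_male=62.0)
        means = []
        for step in range(36):
            progress_cd4(pop, params, 1 / 12)
            means.append(pop.cd4[:n].mean())
        slope = np.polyfit(np.arange(36) / 12, means, 1)[0]
        assert slope == pytest.approx(-62.0, rel=0.01)


class TestArt:
    def test_zero_coverage_nobody_treated(self):
        pop = make_adult_cohort(500)
        pop.hiv[:100] = True
        pop.cd4[:100] = 300.0
        initiate_art(pop, ArtSchedule.none(), 2010.0, np.random.default_rng(0))
        assert not pop.on_art[: pop.n].any()

    def test_low_cd4_prioritized_when_slots_scarce(self):
        pop = make_adult_cohort(1000)
        n = pop.n
        pop.hiv[:n] = True
        rng = np.random.default_rng(3)
        pop.cd4[:n] = rng.uniform(50, 800, n)
        sched = ArtSchedule([2010.0], [0.3], [5000.0])
        initiate_art(pop, sched, 2010.0, rng)
        treated = pop.on_art[:n]
        assert treated.mean() == pytest.approx(0.3, abs=0.01)
        assert np.median(pop.cd4[:n][treated]) <= np.median(pop.cd4[:n][~treated])

    def test_plateau_coverage_reached_in_simulation(self, small_spec, small_params):
        from hivncd.synthetic import make_config
        cfg = make_config(small_spec, n_agents=4000, time_step=1 / 4,
                          end_year=2022.0, enable_cervical=False,
                          enable_depression=False, enable_cvd=False,
                          enabled_ncds=())
        res = Simulation(cfg, small_params).run()
        snap = res.prevalence[res.prevalence.year == 2022]
        plwh = snap[snap.hiv == 1]["pop"].sum()
        on_art = snap[snap.hiv == 1]["on_art"].sum()
        assert on_art / plwh == pytest.approx(0.73, abs=0.04)

    def test_coverage_non_decreasing_validated(self):
        with pytest.raises(ValueError):
            ArtSchedule([2000.0, 2001.0], [0.5, 0.3], [350.0, 350.0])


class TestMortalityMultiplier:
    def test_monotone_in_cd4_and_floored_at_one(self):
        pop = make_adult_cohort(4)
        pop.hiv[:3] = True
        pop.cd4[:3] = [50.0, 500.0, 600.0]
        pop.on_art[2] = True
        pop.art_start[2] = 1995.0  # long-term ART
        m = hiv_mortality_multiplier(pop, HivParams(), 2000.0)
        assert m[0] >= m[1] >= m[2] >= 1.0
        assert m[3] == 1.0  # HIV-negative

    def test_art_attenuates_excess(self):
        pop = make_adult_cohort(2)
        pop.hiv[:2] = True
        pop.cd4[:2] = 100.0
        pop.on_art[1] = True
        pop.art_start[1] = 1999.5  # on ART < 2 years
        m = hiv_mortality_multiplier(pop, HivParams(), 2000.0)
        assert m[1] < m[0]
        assert m[1] > 1.0

    def test_cd4_strata_survival_ordering(self):
        # cohorts stratified by CD4 must die in the expected order
        from hivncd.ncds import sample_deaths
        from hivncd.rates import MortalityModel
        rng = np.random.default_rng(4)
        pop = make_adult_cohort(9000)
        n = pop.n
        pop.hiv[:n] = True
        strata = np.repeat([100.0, 300.0, 600.0], n // 3)
        pop.cd4[:n] = strata
        mu = np.full(n, 0.01)
        for step in range(60):
            mult = hiv_mortality_multiplier(pop, HivParams(), 2000.0)
            sample_deaths(pop, mu, MortalityModel(), mult, 2000 + step / 12,
                          1 / 12, rng)
        surv = [pop.alive[:n][strata == s].mean() for s in (100.0, 300.0, 600.0)]
        assert surv[0] < surv[1] < surv[2]


class TestInvariants:
    def test_no_art_or_cd4_without_hiv(self, small_spec, small_params):
        from hivncd.synthetic import make_config
        cfg = make_config(small_spec, n_agents=2000, time_step=1 / 4,
                          start_year=1975.0, end_year=2005.0,
                          enable_cervical=False, enable_depression=False,
                          enable_cvd=False, enabled_ncds=())
        res = Simulation(cfg, small_params).run()
        pop = res.final_population
        n = pop.n
        neg = ~pop.hiv[:n]
        assert not pop.on_art[:n][neg].any()
        assert np.isnan(pop.cd4[:n][neg]).all()
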