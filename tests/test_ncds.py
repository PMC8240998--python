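"""NCD onset modifiers, CVD events, depression dynamics, death attribution."""

import numpy as np
import pytest

from conftest import make_adult_cohort
from hivncd.ncds import (IHD_TO_STROKE_RATIO, depression_step, onset_hazard,
                         sample_cvd_events, sample_deaths, sample_ncd_onsets)
from hivncd.population import CVD_IHD, CVD_NONE, CVD_STROKE
from hivncd.rates import (FEMALE, MALE, HazardModifierSet, MortalityModel,
                          NcdHazard, default_hazard_modifiers)

MODS = default_hazard_modifiers()


class TestOnsetHazard:
    def setup_method(self):
        self.pop = make_adult_cohort(4, age=40.0, sex=MALE, t0=2000.0)
        # agent 1: diabetes; agent 2: diabetes + hypertension + HIV; agent 3: none
        self.pop.onset["diabetes"][1] = 1995.0
        self.pop.onset["diabetes"][2] = 1995.0
        self.pop.onset["hypertension"][2] = 1996.0
        self.pop.hiv[2] = True
        self.pop.cd4[2] = 400.0

    def test_baseline_for_agent_without_conditions(self):
        h = NcdHazard("hypertension", -5.0, 0.03, min_age=18)
        out = onset_hazard(self.pop, h, MODS, 2000.0)
        assert out[0] == pytest.approx(np.exp(-5.0 + 0.03 * 40))

    def test_diabetes_multiplies_hypertension_hazard(self):
        h = NcdHazard("hypertension", -5.0, 0.03, min_age=18)
        out = onset_hazard(self.pop, h, MODS, 2000.0)
        assert out[1] == pytest.approx(1.440 * out[0])

    def test_ckd_modifiers_multiplicative(self):
        h = NcdHazard("ckd", -6.0, 0.03, min_age=18)
        out = onset_hazard(self.pop, h, MODS, 2000.0)
        assert out[2] == pytest.approx(out[0] * 1.450 * 1.469 * 2.04)

    def test_existing_condition_blocks_reonset(self):
        h = NcdHazard("diabetes", -6.0, 0.03, min_age=18)
        out = onset_hazard(self.pop, h, MODS, 2000.0)
        assert out[1] == 0.0 and out[2] == 0.0 and out[0] > 0

    def test_dead_agents_have_zero_hazard(self):
        self.pop.kill(np.array([0]), 1999.0, "background")
        h = NcdHazard("hypertension", -5.0, 0.03, min_age=18)
        assert onset_hazard(self.pop, h, MODS, 2000.0)[0] == 0.0


class TestCvd:
    def test_ihd_stroke_ratio_small_cohort(self):
        pop = make_adult_cohort(30_000, age=50.0)
        h = NcdHazard("stroke", np.log(0.01), 0.0, min_age=0)
        rng = np.random.default_rng(0)
        mm = MortalityModel(case_fatality={"stroke": 0.0, "ihd": 0.0})
        for step in range(5 * 4):
            sample_cvd_events(pop, h, HazardModifierSet(), mm, 2000 + step / 4,
                              1 / 4, rng)
        n = pop.n
        n_ihd = (pop.cvd_type[:n] == CVD_IHD).sum()
        n_stroke = (pop.cvd_type[:n] == CVD_STROKE).sum()
        ratio = n_ihd / n_stroke
        p = IHD_TO_STROKE_RATIO / (1 + IHD_TO_STROKE_RATIO)
        se_p = np.sqrt(p * (1 - p) / (n_ihd + n_stroke))
        se_ratio = se_p / (1 - p) ** 2
        assert abs(ratio - IHD_TO_STROKE_RATIO) < 3 * se_ratio

    def test_first_event_only(self):
        pop = make_adult_cohort(5000, age=50.0)
        h = NcdHazard("stroke", np.log(0.5), 0.0, min_age=0)
        rng = np.random.default_rng(1)
        mm = MortalityModel(case_fatality={"stroke": 0.0, "ihd": 0.0})
        dates = []
        for step in range(40):
            sample_cvd_events(pop, h, HazardModifierSet(), mm,
                              2000 + step / 4, 1 / 4, rng)
            dates.append(pop.cvd_date[: pop.n].copy())
        # once set, the event date never changes: exactly one lifetime event
        final = dates[-1]
        for d in dates:
            set_mask = ~np.isnan(d)
            np.testing.assert_array_equal(d[set_mask], final[set_mask])

    def test_case_fatality_one_kills_every_case(self):
        pop = make_adult_cohort(2000, age=50.0)
        h = NcdHazard("stroke", np.log(0.2), 0.0, min_age=0)
        mm = MortalityModel(case_fatality={"stroke": 1.0, "ihd": 1.0})
        rng = np.random.default_rng(2)
        hit, acute = sample_cvd_events(pop, h, HazardModifierSet(), mm,
                                       2000.0, 1.0, rng)
        assert len(hit) > 0
        np.testing.assert_array_equal(np.sort(hit), np.sort(acute))
        assert not pop.alive[hit].any()


class TestDepression:
    def test_zero_hazard_nobody_depressed(self):
        pop = make_adult_cohort(1000)
        h = NcdHazard("depression", -np.inf, 0.0)
        rng = np.random.default_rng(0)
        depression_step(pop, h, MODS, 0.5, 2000.0, 1 / 12, rng)
        assert np.isnan(pop.dep_end[: pop.n]).all()

    def test_infinite_duration_prevalence_equals_cumulative_incidence(self):
        pop = make_adult_cohort(5000)
        h = NcdHazard("depression", np.log(0.1), 0.0)
        rng = np.random.default_rng(1)
        for step in range(120):
            depression_step(pop, h, HazardModifierSet(), np.inf,
                            2000 + step / 12, 1 / 12, rng)
        n = pop.n
        ever = ~np.isnan(pop.onset["depression"][:n])
        active = pop.has_condition("depression", 2010.0)
        np.testing.assert_array_equal(ever, active)

    def test_steady_state_occupancy(self):
        # M/D/infinity: point prevalence ~ lambda d / (1 + lambda d)
        lam, dur, n = 0.2, 0.5, 20_000
        pop = make_adult_cohort(n)
        h = NcdHazard("depression", np.log(lam), 0.0)
        rng = np.random.default_rng(7)
        t = 2000.0
        for step in range(30 * 12):
            depression_step(pop, h, HazardModifierSet(), dur, t, 1 / 12, rng)
            t += 1 / 12
        in_episode = (~np.isnan(pop.dep_end[:n]) & (pop.dep_end[:n] > t)).mean()
        expected = lam * dur / (1 + lam * dur)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(in_episode - expected) < 3 * se + 0.002  # + discretization

    def test_recurrence_allowed(self):
        pop = make_adult_cohort(3000)
        h = NcdHazard("depression", np.log(2.0), 0.0)
        rng = np.random.default_rng(3)
        episodes = 0
        t = 2000.0
        for step in range(60):
            episodes += len(depression_step(pop, h, HazardModifierSet(), 0.25,
                                            t, 1 / 12, rng))
            t += 1 / 12
        assert episodes > pop.n  # more episodes than people -> recurrence


class TestDeathAttribution:
    def test_no_conditions_all_background(self):
        pop = make_adult_cohort(3000)
        rng = np.random.default_rng(0)
        dead, causes = sample_deaths(pop, np.full(pop.n, 0.5), MortalityModel(),
                                     np.ones(pop.n), 2000.0, 1.0, rng)
        assert len(dead) > 0
        assert (causes == "background").all()

    def test_single_condition_rr2_attribution_half(self):
        pop = make_adult_cohort(40_000)
        n = pop.n
        pop.onset["ckd"][:n] = 1990.0
        mm = MortalityModel(excess_rr={"ckd": 2.0})
        rng = np.random.default_rng(1)
        dead, causes = sample_deaths(pop, np.full(n, 0.05), mm, np.ones(n),
                                     2000.0, 1.0, rng)
        frac = (causes == "ckd").mean()
        se = np.sqrt(0.25 / len(dead))
        assert abs(frac - 0.5) < 3 * se

    def test_hazard_doubles_with_rr2(self):
        n = 200_000
        pop = make_adult_cohort(n)
        pop.onset["ckd"][:n] = 1990.0
        mm = MortalityModel(excess_rr={"ckd": 2.0})
        rng = np.random.default_rng(2)
        mu = 0.02
        dead, _ = sample_deaths(pop, np.full(n, mu), mm, np.ones(n),
                                2000.0, 1.0, rng)
        expected = 1 - np.exp(-2 * mu)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(len(dead) / n - expected) < 3 * se
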