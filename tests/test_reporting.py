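"""Burden reports: multimorbidity, standardized rates, aggregation, sweeps."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from conftest import make_adult_cohort
from hivncd import FixtureSpec, Simulation, make_parameter_set
from hivncd import reporting as rep
from hivncd.synthetic import make_config


def snapshot_frame(rows):
    """Hand-built snapshot rows: (year, age, sex, hiv, pop, **counts)."""
    df = pd.DataFrame(rows)
    for col in df.columns:
        if col not in ("year", "age", "sex", "hiv"):
            df[col] = df[col].astype(float)
    return df


class TestMultimorbidity:
    def test_hand_built_agents_exact_enumeration(self):
        # 10 adults: 3 hypertensive, 1 with past-year depression, 1 with an
        # old (expired) depressive episode, 1 with a CVD event -> 5 of 10
        pop = make_adult_cohort(10, age=40.0, t0=2020.0)
        pop.onset["hypertension"][[0, 1, 2]] = 2010.0
        pop.onset["depression"][3] = 2019.8
        pop.dep_end[3] = 2020.3
        pop.onset["depression"][4] = 2015.0
        pop.dep_end[4] = 2015.5  # expired years ago: not counted
        pop.cvd_type[5] = 1
        pop.cvd_date[5] = 2012.0
        frac = rep.multimorbidity_fraction_agents(pop, 2020.5)
        assert frac == 5 / 10

    def test_none_and_all(self):
        pop = make_adult_cohort(8, age=30.0, t0=2020.0)
        assert rep.multimorbidity_fraction_agents(pop, 2020.0) == 0.0
        pop.onset["hypertension"][:8] = 2019.0
        assert rep.multimorbidity_fraction_agents(pop, 2020.0) == 1.0

    def test_snapshot_level_and_stratum(self):
        df = snapshot_frame([
            dict(year=2018, age=30, sex=0, hiv=0, pop=100, any_ncd=40),
            dict(year=2018, age=30, sex=0, hiv=1, pop=10, any_ncd=8),
            dict(year=2018, age=10, sex=0, hiv=0, pop=50, any_ncd=0),
        ])
        assert rep.multimorbidity_fraction(df, 2018) == pytest.approx(48 / 110)
        assert rep.multimorbidity_fraction(df, 2018, hiv="plwh") == pytest.approx(0.8)

    def test_empty_stratum_flagged(self):
        df = snapshot_frame([dict(year=2018, age=30, sex=0, hiv=0, pop=10, any_ncd=1)])
        with pytest.raises(ValueError, match="empty stratum"):
            rep.multimorbidity_fraction(df, 2018, hiv="plwh")


class TestStandardizedRates:
    @staticmethod
    def flat_snapshot(p, pops=(100, 200, 300, 150, 80)):
        rows = []
        for (lo, _), n in zip(rep.ADULT_BANDS, pops):
            rows.append(dict(year=2018, age=lo + 1, sex=0, hiv=0, pop=n,
                             prev_diabetes=p * n))
        return snapshot_frame(rows)

    def test_flat_profile_asp_equals_p(self):
        snap = self.flat_snapshot(0.25)
        asp = rep.standardized_output_rates(snap, 2018, "diabetes")
        assert asp == pytest.approx(0.25)

    def test_asp_invariant_to_scale_factor(self):
        a = rep.standardized_output_rates(self.flat_snapshot(0.25), 2018, "diabetes")
        scaled = self.flat_snapshot(0.25)
        scaled[["pop", "prev_diabetes"]] *= 1000
        b = rep.standardized_output_rates(scaled, 2018, "diabetes")
        assert a == pytest.approx(b)

    def test_empty_band_raises(self):
        snap = self.flat_snapshot(0.2).iloc[1:]
        with pytest.raises(ValueError, match="empty age band"):
            rep.standardized_output_rates(snap, 2018, "diabetes")


class TestAggregateRuns:
    def frame(self, v):
        return snapshot_frame([dict(year=2018, age=30, sex=0, hiv=0,
                                    pop=v, any_ncd=v / 2)])

    def test_identical_reports_mean_equals_input_se_zero(self):
        mean, se = rep.aggregate_runs([self.frame(100)] * 4)
        assert mean["pop"].iloc[0] == 100
        assert (se[["pop", "any_ncd"]].values == 0).all()
        assert mean.attrs["n_runs"] == 4

    def test_two_reports_midpoint(self):
        mean, se = rep.aggregate_runs([self.frame(100), self.frame(200)])
        assert mean["pop"].iloc[0] == 150
        assert se["pop"].iloc[0] == pytest.approx(np.std([100, 200], ddof=1) / np.sqrt(2))

    def test_mismatched_columns_rejected(self):
        bad = self.frame(100).rename(columns={"any_ncd": "other"})
        with pytest.raises(ValueError, match="mismatched"):
            rep.aggregate_runs([self.frame(100), bad])


class TestFlows:
    @pytest.fixture(scope="class")
    def run(self):
        spec = FixtureSpec(seed=17, n_agents=2500)
        params = make_parameter_set(spec)
        cfg = make_config(spec, n_agents=2500, start_year=1990.0, end_year=2005.0,
                          time_step=1 / 4, enable_hiv=False, enable_cervical=False,
                          enable_depression=False, enable_cvd=False,
                          enable_mortality=False, enabled_ncds=("hypertension",))
        return Simulation(cfg, params).run()

    def test_new_cases_reconcile_with_prevalent_counts(self, run):
        # permanent condition, mortality off: prevalent(t+1) - prevalent(t)
        # equals incident cases during the year, exactly
        prev = run.prevalence.groupby("year")["prev_hypertension"].sum()
        for year in range(1991, 2006):
            cases = rep.new_cases_between(run, "hypertension", year - 1, year)
            assert prev.loc[year] - prev.loc[year - 1] == cases


class TestSensitivity:
    @pytest.fixture(scope="class")
    def setup(self):
        spec = FixtureSpec(seed=23, n_agents=3000)
        params = make_parameter_set(spec)
        cfg = make_config(spec, n_agents=3000, start_year=1980.0, end_year=2005.0,
                          time_step=1 / 2, enable_hiv=False, enable_cervical=False,
                          enable_cvd=False,
                          enabled_ncds=("hypertension", "diabetes"))
        return cfg, params

    def test_multiplier_one_identical_to_baseline(self, setup):
        cfg, params = setup
        out = rep.sensitivity_sweep(cfg, params, ["hypertension"], (1.0,))
        base = Simulation(cfg, params).run()
        pd.testing.assert_frame_equal(out[("hypertension", 1.0)].prevalence,
                                      base.prevalence)

    def test_lower_incidence_lowers_multimorbidity(self, setup):
        cfg, params = setup
        out = rep.sensitivity_sweep(cfg, params, ["hypertension"], (0.9, 1.0, 1.1))
        fracs = {m: rep.multimorbidity_fraction(out[("hypertension", m)].prevalence,
                                                2005)
                 for m in (0.9, 1.0, 1.1)}
        assert fracs[0.9] < fracs[1.1]
        assert fracs[0.9] <= fracs[1.0] <= fracs[1.1]

    def test_raising_one_hazard_leaves_independent_ncd_untouched(self, setup):
        # depression conditions nothing else and kills nobody, so doubling a
        # chronic NCD with no modeled link to it (high cholesterol) leaves the
        # depression draw stream, and hence its prevalence, byte-identical
        cfg, params = setup
        cfg = dataclasses.replace(cfg, enable_depression=True,
                                  enabled_ncds=("high_cholesterol",))
        base = Simulation(cfg, params).run()
        up = Simulation(dataclasses.replace(
            cfg, sensitivity={"high_cholesterol": 2.0}), params).run()
        a = base.prevalence.groupby("year")[["prev_depression", "prev_high_cholesterol"]].sum()
        b = up.prevalence.groupby("year")[["prev_depression", "prev_high_cholesterol"]].sum()
        pd.testing.assert_series_equal(a["prev_depression"], b["prev_depression"])
        assert b["prev_high_cholesterol"].loc[2005] > a["prev_high_cholesterol"].loc[2005]
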