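"""Self-contained, Kenya-like parameter fixtures.

Real runs of the model are driven by national vital statistics, programme
estimates of HIV incidence and ART scale-up, and burden-of-disease death
fractions.  None of those are redistributable here, so this module generates
*stylized* stand-ins that reproduce the qualitative features the model needs:
a young, growing population with declining fertility and mortality; a
generalized HIV epidemic that emerges around 1980, peaks in the mid-1990s and
plateaus near 3% adult prevalence under ART scale-up to the 90-90-90 level
(~73% of PLWH on treatment by 2020); and NCD onset hazards that rise
log-linearly with age, with known ground truth so the calibrator can be
validated by parameter recovery.  Headline national figures produced from
these fixtures are demonstrative, not estimates.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .cervical import CervicalRates
from .config import CANCERS, CHRONIC_NCDS, SimulationConfig
from .engine import InitialComposition, ParameterSet, Simulation
from .hiv import ArtSchedule, HivParams
from .rates import (FEMALE, MALE, HazardModifierSet, MortalityModel, NcdHazard,
                    RateTable, default_hazard_modifiers)

AGE_EDGES_5Y = np.arange(0, 90, 5, dtype=float)


@dataclass
class FixtureSpec:
    """Shape parameters of the synthetic study setting.

    ``n_agents`` is the simulated population at ``start_year``; with the
    default ``scale_factor`` of 120 persons per agent it represents a
    population of about 6 million in 1950 growing toward ~50 million by 2018.
    """

    seed: int = 0
    start_year: float = 1950.0
    end_year: float = 2035.0
    n_agents: int = 50_000
    scale_factor: float = 120.0
    # demography
    pyramid_decay: float = 0.035        # initial age-pyramid exp decay /year of age
    tfr_start: float = 7.5              # total fertility rate in 1950
    tfr_floor: float = 3.4
    tfr_decline: float = 0.025          # exponential approach to the floor /year
    mort_decline: float = 0.008         # background-mortality decline /year
    mort_floor: float = 0.55            # floor on the decline factor
    # HIV epidemic
    hiv_start: float = 1980.0
    hiv_peak_year: float = 1995.0
    hiv_peak_incidence: float = 0.0075  # per person-year at the age-shape peak
    hiv_plateau_incidence: float = 0.0025
    hiv_plateau_year: float = 2010.0
    art_ramp_start: float = 2004.0
    art_target: float = 0.73            # 0.9^3: the 90-90-90 treatment level
    art_target_year: float = 2020.0
    # NCD truth: ncd -> (intercept, slope, sex_offset, min_age)
    ncd_truth: Dict[str, Tuple[float, float, float, float]] = field(default_factory=dict)

    def __post_init__(self):
        if self.start_year >= self.end_year:
            raise ValueError("start_year must precede end_year")
        if self.n_agents <= 0:
            raise ValueError("n_agents must be positive")
        if self.hiv_start < self.start_year:
            raise ValueError("epidemic cannot start before the simulation")
        if not self.ncd_truth:
            self.ncd_truth = dict(DEFAULT_NCD_TRUTH)

    def to_yaml(self, path):
        d = asdict(self)
        d["ncd_truth"] = {k: list(v) for k, v in self.ncd_truth.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "FixtureSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["ncd_truth"] = {k: tuple(v) for k, v in d.get("ncd_truth", {}).items()}
        return cls(**d)


# Ground-truth log-linear age hazards, exp(intercept + slope*age [+ sex_offset
# for women]), zero below min_age.  Chosen so that age-band prevalence rises
# with age at magnitudes comparable to the pooled Kenyan survey estimates
# (hypertension ~14->52% across adult bands, diabetes a few percent, stroke
# incidence in the hundreds per 100,000 at older ages).
DEFAULT_NCD_TRUTH: Dict[str, Tuple[float, float, float, float]] = {
    "hypertension":      (-5.0, 0.035, 0.0, 18.0),
    "high_cholesterol":  (-5.9, 0.028, 0.1, 18.0),
    "diabetes":          (-8.3, 0.055, 0.0, 18.0),
    "ckd":               (-6.5, 0.035, 0.0, 18.0),
    "depression":        (-3.3, 0.000, 0.3, 15.0),
    "stroke":            (-13.0, 0.110, -0.1, 18.0),
    "breast_cancer":     (-11.0, 0.080, 0.0, 20.0),
    "colorectal_cancer": (-12.5, 0.095, 0.0, 20.0),
    "leukemia":          (-10.8, 0.030, 0.0, 0.0),
    "liver_cancer":      (-12.5, 0.085, 0.0, 20.0),
    "esophageal_cancer": (-12.8, 0.095, 0.0, 20.0),
    "prostate_cancer":   (-14.5, 0.125, 0.0, 35.0),
    "stomach_cancer":    (-12.6, 0.088, 0.0, 20.0),
    "other_cancer":      (-10.6, 0.065, 0.0, 0.0),
}

# Fertility distribution across maternal age bands 15-19 ... 45-49.
_ASFR_SHAPE = np.array([0.11, 0.23, 0.23, 0.19, 0.13, 0.08, 0.03])

# Relative HIV incidence by 5-year age band from 15-19 to 45-49 (0 elsewhere).
_HIV_AGE_SHAPE = np.array([0.4, 1.0, 1.2, 1.0, 0.7, 0.4, 0.2])
_HIV_SEX_MULT = {MALE: 0.8, FEMALE: 1.3}


def make_demography(spec: FixtureSpec):
    """Fertility and background-mortality rate tables plus the initial age/sex
    composition.  Mortality declines monotonically across periods; fertility
    stays above replacement so the population grows."""
    year_edges = np.arange(spec.start_year, spec.end_year + 1, 5.0)

    # fertility: births per woman-year by maternal age band
    fert = np.zeros((1, len(AGE_EDGES_5Y), len(year_edges)))
    band15 = int(np.searchsorted(AGE_EDGES_5Y, 15))
    for yi, y in enumerate(year_edges):
        tfr = spec.tfr_floor + (spec.tfr_start - spec.tfr_floor) * np.exp(
            -spec.tfr_decline * (y - spec.start_year))
        fert[0, band15:band15 + 7, yi] = tfr * _ASFR_SHAPE / 5.0
    fertility = RateTable(AGE_EDGES_5Y, year_edges, fert, by_sex=False)

    # background mortality: infant + middle-age + senescent components,
    # scaled down over calendar time
    mids = AGE_EDGES_5Y + 2.5
    base = 0.05 * np.exp(-mids / 1.5) + 0.0015 + 3.2e-5 * np.exp(0.092 * mids)
    mort = np.zeros((2, len(AGE_EDGES_5Y), len(year_edges)))
    for yi, y in enumerate(year_edges):
        decline = max(spec.mort_floor, 1.5 * np.exp(-spec.mort_decline * (y - spec.start_year)))
        mort[MALE, :, yi] = base * decline * 1.05
        mort[FEMALE, :, yi] = base * decline * 0.95
    mortality = RateTable(AGE_EDGES_5Y, year_edges, mort, by_sex=True)

    pyramid = np.exp(-spec.pyramid_decay * mids)
    composition = InitialComposition(AGE_EDGES_5Y, np.vstack([pyramid, pyramid]))
    return fertility, mortality, composition


def make_hiv_epidemic(spec: FixtureSpec):
    """Annual age/sex HIV incidence table plus the ART initiation schedule.

    Incidence is zero before the epidemic start, rises to a mid-1990s peak,
    declines to a plateau, and is held at its 2017 level thereafter (the
    stable-incidence projection assumption).  ART coverage among PLWH ramps
    linearly to the 90-90-90 level (73%) by the target year and holds."""
    years = np.arange(spec.start_year, spec.end_year + 1, 1.0)
    level = np.zeros(len(years))
    for i, y in enumerate(years):
        yy = min(y, 2017.0)  # post-2017 rows equal the 2017 row
        if yy < spec.hiv_start:
            level[i] = 0.0
        elif yy <= spec.hiv_peak_year:
            frac = (yy - spec.hiv_start) / (spec.hiv_peak_year - spec.hiv_start)
            level[i] = spec.hiv_peak_incidence * frac
        elif yy <= spec.hiv_plateau_year:
            frac = (yy - spec.hiv_peak_year) / (spec.hiv_plateau_year - spec.hiv_peak_year)
            level[i] = (spec.hiv_peak_incidence
                        + (spec.hiv_plateau_incidence - spec.hiv_peak_incidence) * frac)
        else:
            level[i] = spec.hiv_plateau_incidence
    inc = np.zeros((2, len(AGE_EDGES_5Y), len(years)))
    band15 = int(np.searchsorted(AGE_EDGES_5Y, 15))
    for sex in (MALE, FEMALE):
        for bi, shape in enumerate(_HIV_AGE_SHAPE):
            inc[sex, band15 + bi, :] = level * shape * _HIV_SEX_MULT[sex]
    incidence = RateTable(AGE_EDGES_5Y, years, inc, by_sex=True)

    cov = np.zeros(len(years))
    thr = np.zeros(len(years))
    for i, y in enumerate(years):
        if y >= spec.art_ramp_start:
            frac = min(1.0, (y - spec.art_ramp_start)
                       / (spec.art_target_year - spec.art_ramp_start))
            cov[i] = spec.art_target * frac
        if y < 2010:
            thr[i] = 200.0
        elif y < 2013:
            thr[i] = 350.0
        elif y < 2016:
            thr[i] = 500.0
        else:
            thr[i] = 5000.0  # treat-all
    schedule = ArtSchedule(years, cov, thr)
    return incidence, schedule


def make_cervical_rates(spec: FixtureSpec) -> CervicalRates:
    """Stage-transition rates giving HPV prevalence near 30% in young women
    and CIN2/3 in the mid single digits, before HIV modifiers."""
    return CervicalRates(
        acq_intercept=np.log(0.45) + 0.03 * 20.0,  # 0.45/yr at age 20
        acq_slope=-0.03,
        clearance=0.70,
        hpv_to_cin23=0.06,
        cin23_regression=0.20,
        cin23_to_cis=0.05,
        cis_to_cancer=0.10,
    )


def make_mortality_model(spec: FixtureSpec) -> MortalityModel:
    """Ground-truth excess death risks (the quantities the calibrator fits
    against cause-of-death fractions in a real application)."""
    rr = {"ckd": 2.5, "diabetes": 2.0, "stroke": 2.2, "ihd": 2.2,
          "cervical_cancer": 10.0}
    rr.update({c: 10.0 for c in CANCERS})
    return MortalityModel(excess_rr=rr, case_fatality={"stroke": 0.25, "ihd": 0.20})


def make_ncd_hazards(spec: FixtureSpec) -> Dict[str, NcdHazard]:
    return {ncd: NcdHazard(ncd, *params) for ncd, params in spec.ncd_truth.items()}


def make_parameter_set(spec: FixtureSpec) -> ParameterSet:
    """The full fixture: every parameter file the engine needs."""
    fertility, mortality, composition = make_demography(spec)
    incidence, schedule = make_hiv_epidemic(spec)
    return ParameterSet(
        fertility=fertility,
        mortality=mortality,
        init_composition=composition,
        hiv_incidence=incidence,
        art_schedule=schedule,
        hiv_params=HivParams(),
        ncd_hazards=make_ncd_hazards(spec),
        modifiers=default_hazard_modifiers(),
        mortality_model=make_mortality_model(spec),
        cervical_rates=make_cervical_rates(spec),
        depression_duration=0.5,
    )


def make_config(spec: FixtureSpec, **overrides) -> SimulationConfig:
    base = dict(seed=spec.seed, start_year=spec.start_year, end_year=spec.end_year,
                n_agents=spec.n_agents, scale_factor=spec.scale_factor)
    base.update(overrides)
    return SimulationConfig(**base)


ADULT_BANDS = ((18, 30), (30, 40), (40, 50), (50, 60), (60, None))


def make_ncd_truth_and_targets(spec: FixtureSpec, ncd: str = "hypertension",
                               n_sample: int = 3000, target_year: int = 2010,
                               calib_start: float = 1980.0,
                               time_step: float = 0.25,
                               bands=ADULT_BANDS, noise_seed: int = 1234):
    """Ground-truth hazard for one NCD plus prevalence targets obtained by
    running the simulator forward under that truth.

    The targets carry binomial sampling noise at sample size ``n_sample`` per
    band (normal-approximation 95% CIs), making the calibration problem
    solvable by construction but realistically noisy.  Returns
    ``(truth, targets, config, params)`` where config/params are the exact
    engine setup used to generate the targets (the calibrator should be run
    with the same setup so discretization bias cancels).
    """
    from .calibration import CalibrationTarget  # local import: no cycle at module load

    truth = NcdHazard(ncd, *spec.ncd_truth[ncd])
    params = make_parameter_set(spec)
    # fertility stays on: the youngest target bands must be populated at the
    # target year, which needs cohorts born after the calibration start
    config = make_config(
        spec, start_year=calib_start, end_year=float(target_year),
        time_step=time_step, enable_hiv=False, enable_cervical=False,
        enable_depression=False, enable_cvd=False,
        enabled_ncds=(ncd,),
    )
    result = Simulation(config, params).run()
    snap = result.prevalence[result.prevalence["year"] == target_year]
    rng = np.random.default_rng(noise_seed)
    targets = []
    for lo, hi in bands:
        m = (snap["age"] >= lo) & (snap["age"] < (hi if hi is not None else np.inf))
        pop = snap.loc[m, "pop"].sum()
        prev = snap.loc[m, f"prev_{ncd}"].sum() / pop
        obs = rng.binomial(n_sample, prev) / n_sample if n_sample else prev
        se = np.sqrt(max(obs * (1 - obs), 1e-9) / n_sample) if n_sample else 1e-3
        targets.append(CalibrationTarget(
            quantity="prevalence", ncd=ncd, age_lo=lo, age_hi=hi,
            value=float(obs), ci_low=float(max(obs - 1.96 * se, 0.0)),
            ci_high=float(min(obs + 1.96 * se, 1.0)), year=target_year))
    return truth, targets, config, params


def write_fixture_dir(spec: FixtureSpec, path):
    """Write the complete parameter-file set plus a manifest of the spec."""
    os.makedirs(path, exist_ok=True)
    make_parameter_set(spec).write_dir(path)
    spec.to_yaml(os.path.join(path, "fixture_manifest.yaml"))
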