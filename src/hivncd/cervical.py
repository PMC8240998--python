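"""Cervical natural history: HPV infection, precancerous lesions, cancer.

Women aged 15+ move along a five-stage chain

    susceptible <-> HPV -> CIN2/3 -> CIS -> cervical cancer

with clearance from HPV and regression from CIN2/3 back to susceptible, and
cancer absorbing.  Women living with HIV who are ART-naive or on ART for
under two years have elevated HPV acquisition (x1.63), reduced clearance
(x0.52) and faster HPV->CIN2/3 progression (x1.32); on ART for 2+ years they
behave as HIV-negative women.  Cervical cancer arises only through this
pathway, so its excess in women with HIV is emergent rather than imposed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .population import (CERV_CANCER, CERV_CIN23, CERV_CIS, CERV_HPV, CERV_NA,
                         CERV_SUSC, Population)
from .rates import FEMALE, HazardModifierSet

MIN_CERVICAL_AGE = 15.0


@dataclass
class CervicalRates:
    """Stage-transition rates per person-year.

    HPV acquisition is log-linear in age (declining with age in the default
    fixtures); the other transitions are age-constant.  All rates >= 0.
    """

    acq_intercept: float
    acq_slope: float
    clearance: float
    hpv_to_cin23: float
    cin23_regression: float
    cin23_to_cis: float
    cis_to_cancer: float

    def __post_init__(self):
        for name in ("clearance", "hpv_to_cin23", "cin23_regression",
                     "cin23_to_cis", "cis_to_cancer"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def acquisition(self, ages: np.ndarray) -> np.ndarray:
        h = np.exp(self.acq_intercept + self.acq_slope * ages)
        return np.where(ages >= MIN_CERVICAL_AGE, h, 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])

    def write_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "CervicalRates":
        return cls(**pd.read_csv(path).iloc[0].to_dict())


def hiv_cervical_modifiers(pop: Population, modifiers: HazardModifierSet,
                           t: float) -> np.ndarray:
    """Boolean mask of agents in the modifier-eligible HIV state (HIV-positive
    and ART-naive or on ART < 2 years)."""
    n = pop.n
    art_years = t - pop.art_start[:n]
    long_art = pop.on_art[:n] & (art_years >= 2.0)
    return pop.hiv[:n] & ~long_art


def cervical_step(pop: Population, rates: CervicalRates,
                  modifiers: HazardModifierSet, t: float, dt: float,
                  rng: np.random.Generator, only: Optional[np.ndarray] = None) -> np.ndarray:
    """Advance the cervical chain one step for all living women 15+.

    Returns indices of incident cervical cancers.  Transitions are drawn as
    competing exponential events discretized to the step: for each occupied
    stage the exit probability is 1-exp(-(sum of exit rates) dt) and the
    destination is chosen proportionally to the rates.
    """
    n = pop.n
    ages = pop.ages(t)
    women = pop.alive_mask() & (pop.cerv_stage[:n] != CERV_NA) & (ages >= MIN_CERVICAL_AGE)
    if only is not None:
        restrict = np.zeros(n, dtype=bool)
        restrict[only] = True
        women &= restrict
    if not women.any():
        return np.array([], dtype=int)
    mod = hiv_cervical_modifiers(pop, modifiers, t)
    r_acq_mult = modifiers.ratio("hpv_acquisition", "hiv_no_art2y")
    r_clr_mult = modifiers.ratio("hpv_clearance", "hiv_no_art2y")
    r_prog_mult = modifiers.ratio("hpv_to_cin23", "hiv_no_art2y")

    stage = pop.cerv_stage[:n]
    u = rng.random(n)
    new_cancer = []

    # susceptible -> HPV
    m = women & (stage == CERV_SUSC)
    if m.any():
        h = rates.acquisition(ages) * np.where(mod, r_acq_mult, 1.0)
        p = -np.expm1(-h * dt)
        hit = np.flatnonzero(m & (u < p))
        stage[hit] = CERV_HPV
        pop.cerv_entry[hit] = t

    # HPV -> cleared or CIN2/3 (competing)
    m = women & (stage == CERV_HPV) & (pop.cerv_entry[:n] < t)
    if m.any():
        h_clr = rates.clearance * np.where(mod, r_clr_mult, 1.0)
        h_prog = rates.hpv_to_cin23 * np.where(mod, r_prog_mult, 1.0)
        h_tot = h_clr + h_prog
        p = -np.expm1(-h_tot * dt)
        exit_ = m & (u < p)
        if exit_.any():
            v = rng.random(n)
            frac_prog = np.divide(h_prog, h_tot, out=np.zeros_like(h_tot),
                                  where=h_tot > 0)
            prog = exit_ & (v < frac_prog)
            clr = exit_ & ~prog
            stage[np.flatnonzero(prog)] = CERV_CIN23
            stage[np.flatnonzero(clr)] = CERV_SUSC
            pop.cerv_entry[np.flatnonzero(exit_)] = t

    # CIN2/3 -> regression or CIS (competing)
    m = women & (stage == CERV_CIN23) & (pop.cerv_entry[:n] < t)
    if m.any():
        h_tot = rates.cin23_regression + rates.cin23_to_cis
        p = -np.expm1(-h_tot * dt)
        exit_ = m & (u < p)
        if exit_.any():
            v = rng.random(n)
            frac_cis = rates.cin23_to_cis / h_tot if h_tot > 0 else 0.0
            cis = exit_ & (v < frac_cis)
            reg = exit_ & ~cis
            stage[np.flatnonzero(cis)] = CERV_CIS
            stage[np.flatnonzero(reg)] = CERV_SUSC
            pop.cerv_entry[np.flatnonzero(exit_)] = t

    # CIS -> cancer
    m = women & (stage == CERV_CIS) & (pop.cerv_entry[:n] < t)
    if m.any():
        p = -np.expm1(-rates.cis_to_cancer * dt)
        hit = np.flatnonzero(m & (u < p))
        if hit.size:
            stage[hit] = CERV_CANCER
            pop.cerv_entry[hit] = t
            pop.onset["cervical_cancer"][hit] = t
            new_cancer.append(hit)

    return np.concatenate(new_cancer) if new_cancer else np.array([], dtype=int)


def cervical_step_individual(pop: Population, i: int, rates: CervicalRates,
                             modifiers: HazardModifierSet, t: float, dt: float,
                             rng: np.random.Generator) -> np.ndarray:
    """Single-agent wrapper enforcing the female precondition."""
    if pop.cerv_stage[i] == CERV_NA:
        raise ValueError("cervical transitions are defined for female agents only")
    return cervical_step(pop, rates, modifiers, t, dt, rng, only=np.array([i]))


def equilibrium_check(rates: CervicalRates, modifiers: HazardModifierSet,
                      hiv_fraction: float, n_women: int = 20_000,
                      years: float = 60.0, dt: float = 1.0 / 12.0,
                      age_bands=((15, 25), (25, 30), (30, 35), (35, 40), (40, None)),
                      seed: int = 0) -> pd.DataFrame:
    """Simulate a stationary cohort of women (no mortality, fixed HIV mix,
    never on ART) and report HPV and CIN2/3 prevalence by age band and HIV
    status for comparison with pooled survey estimates."""
    rng = np.random.default_rng(seed)
    pop = Population(n_women)
    ages0 = rng.uniform(15.0, 60.0, n_women)
    t0 = 2000.0
    pop.add_agents(np.full(n_women, FEMALE, dtype=np.int8), t0 - ages0)
    idx = rng.random(n_women) < hiv_fraction
    pop.hiv[:n_women][idx] = True
    pop.sero[:n_women][idx] = t0
    pop.cd4[:n_women][idx] = 500.0
    t = t0
    steps = int(round(years / dt))
    for _ in range(steps):
        # hold ages fixed: stationary-age cohort (rejuvenate by birth shift)
        pop.birth[:n_women] += dt
        cervical_step(pop, rates, modifiers, t, dt, rng)
        t += dt
    ages = pop.ages(t)
    stage = pop.cerv_stage[:n_women]
    rows = []
    for lo, hi in age_bands:
        in_band = (ages >= lo) & (ages < (hi if hi is not None else np.inf))
        for label, mask in (("overall", in_band), ("plwh", in_band & pop.hiv[:n_women])):
            denom = mask.sum()
            rows.append({
                "age_lo": lo, "age_hi": hi, "stratum": label, "n": int(denom),
                "hpv_prev": float((mask & (stage == CERV_HPV)).sum() / denom) if denom else np.nan,
                "cin23_prev": float((mask & (stage == CERV_CIN23)).sum() / denom) if denom else np.nan,
            })
    return pd.DataFrame(rows)
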