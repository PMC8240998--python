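"""HIV acquisition, CD4 dynamics, ART initiation and HIV-attributable
mortality risk.

HIV incidence is an exogenous age/sex/year rate (as estimated by national
programmes), not a transmission model.  CD4 is tracked continuously: it is
drawn from an age-dependent distribution at seroconversion, declines linearly
at a sex-specific rate while untreated, and recovers toward a plateau on ART.
The multiplier on background mortality is looked up by CD4 stratum
(>=500 / 350-499 / 200-349 / <200 cells/uL) and attenuated with time on ART.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .population import Population
from .rates import FEMALE, MALE, RateTable

CD4_STRATA_EDGES = np.array([0.0, 200.0, 350.0, 500.0])  # lower edges of <200,200-349,350-499,>=500


@dataclass
class HivParams:
    """HIV natural-history and treatment-response parameters.

    Defaults are plausible for a generalized sub-Saharan African epidemic and
    are fully configurable; mortality multipliers are for ART-naive disease by
    CD4 stratum, ordered <200, 200-349, 350-499, >=500.
    """

    cd4_at_sero_mean: float = 570.0      # cells/uL at age 25
    cd4_at_sero_age_slope: float = -2.0  # cells/uL per year of age
    cd4_at_sero_sd: float = 150.0
    cd4_decline_male: float = 62.0       # cells/uL per year off ART
    cd4_decline_female: float = 56.0
    cd4_recovery_rate: float = 80.0      # cells/uL per year on ART
    cd4_plateau: float = 650.0
    mortality_multipliers: Tuple[float, float, float, float] = (15.0, 5.0, 2.5, 1.5)
    art_attenuation_lt2y: float = 0.5    # fraction of excess risk retained, ART <2y
    art_attenuation_ge2y: float = 0.2    # fraction retained on long-term ART

    def __post_init__(self):
        m = self.mortality_multipliers
        if any(x < 1 for x in m):
            raise ValueError("mortality multipliers must be >= 1")
        if not all(m[i] >= m[i + 1] for i in range(3)):
            raise ValueError("mortality multipliers must decrease with CD4")


@dataclass
class ArtSchedule:
    """Per-year ART eligibility threshold (cells/uL) and target coverage among
    people living with HIV.  Coverage must be non-decreasing up to its
    plateau; years past the last entry hold the final row."""

    years: np.ndarray
    coverage: np.ndarray
    threshold: np.ndarray

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=float)
        self.coverage = np.asarray(self.coverage, dtype=float)
        self.threshold = np.asarray(self.threshold, dtype=float)
        if np.any((self.coverage < 0) | (self.coverage > 1)):
            raise ValueError("coverage must be in [0,1]")
        if np.any(np.diff(self.coverage) < -1e-12):
            raise ValueError("coverage must be non-decreasing")

    def at(self, year: float) -> Tuple[float, float]:
        i = int(np.clip(np.searchsorted(self.years, year, side="right") - 1,
                        0, len(self.years) - 1))
        return float(self.coverage[i]), float(self.threshold[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "coverage": self.coverage,
                             "threshold": self.threshold})

    def write_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "ArtSchedule":
        df = pd.read_csv(path)
        return cls(df["year"].values, df["coverage"].values, df["threshold"].values)

    @classmethod
    def none(cls) -> "ArtSchedule":
        return cls(np.array([1950.0]), np.array([0.0]), np.array([0.0]))


# ----------------------------------------------------------------------
def acquire_hiv(pop: Population, incidence: RateTable, params: HivParams,
                t: float, dt: float, rng: np.random.Generator) -> np.ndarray:
    """Expose alive, HIV-negative agents to the incidence hazard for one step;
    seroconverters get a CD4 draw from the age-dependent distribution.
    Returns the indices of new infections."""
    n = pop.n
    at_risk = pop.alive_mask() & ~pop.hiv[:n]
    idx = np.flatnonzero(at_risk)
    if idx.size == 0:
        return idx
    ages = t - pop.birth[idx]
    haz = incidence.lookup(ages, pop.sex[idx], t)
    p = -np.expm1(-haz * dt)
    hit = idx[rng.random(idx.size) < p]
    if hit.size:
        pop.hiv[hit] = True
        pop.sero[hit] = t
        mean = params.cd4_at_sero_mean + params.cd4_at_sero_age_slope * (t - pop.birth[hit] - 25.0)
        cd4 = rng.normal(mean, params.cd4_at_sero_sd)
        pop.cd4[hit] = np.maximum(cd4, 50.0)
    return hit


def progress_cd4(pop: Population, params: HivParams, dt: float):
    """Linear CD4 decline off ART (sex-specific), recovery toward the plateau
    on ART; CD4 floored at 0."""
    n = pop.n
    plwh = pop.alive_mask() & pop.hiv[:n]
    off = plwh & ~pop.on_art[:n]
    on = plwh & pop.on_art[:n]
    decline = np.where(pop.sex[:n] == FEMALE, params.cd4_decline_female,
                       params.cd4_decline_male)
    pop.cd4[:n][off] = np.maximum(pop.cd4[:n][off] - decline[off] * dt, 0.0)
    pop.cd4[:n][on] = np.minimum(pop.cd4[:n][on] + params.cd4_recovery_rate * dt,
                                 np.maximum(params.cd4_plateau, pop.cd4[:n][on]))


def initiate_art(pop: Population, schedule: ArtSchedule, t: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Start ART among eligible PLWH until the year's target coverage is met,
    prioritizing the lowest CD4 counts; treatment is lifelong (no dropout).
    Returns indices of new initiations."""
    coverage, threshold = schedule.at(t)
    n = pop.n
    plwh = pop.alive_mask() & pop.hiv[:n]
    n_plwh = int(plwh.sum())
    if n_plwh == 0 or coverage <= 0:
        return np.array([], dtype=int)
    n_on = int((plwh & pop.on_art[:n]).sum())
    slots = int(round(coverage * n_plwh)) - n_on
    if slots <= 0:
        return np.array([], dtype=int)
    cand = np.flatnonzero(plwh & ~pop.on_art[:n])
    eligible = cand[pop.cd4[cand] <= threshold] if threshold > 0 else cand
    # universal-eligibility years: threshold encoded as a large number
    if eligible.size == 0:
        return np.array([], dtype=int)
    order = np.argsort(pop.cd4[eligible], kind="stable")
    chosen = eligible[order[:slots]]
    pop.on_art[chosen] = True
    pop.art_start[chosen] = t
    return chosen


def hiv_mortality_multiplier(pop: Population, params: HivParams, t: float) -> np.ndarray:
    """Multiplier (>=1) on background mortality for every agent (1 for the
    HIV-negative), increasing as CD4 falls and attenuated on ART."""
    n = pop.n
    mult = np.ones(n)
    plwh = pop.hiv[:n]
    if not plwh.any():
        return mult
    cd4 = pop.cd4[:n]
    stratum = np.clip(np.searchsorted(CD4_STRATA_EDGES, np.nan_to_num(cd4), side="right") - 1, 0, 3)
    # mortality_multipliers ordered <200, 200-349, 350-499, >=500
    m = np.array(params.mortality_multipliers)[stratum]
    art_years = t - pop.art_start[:n]
    atten = np.where(pop.on_art[:n],
                     np.where(art_years >= 2.0, params.art_attenuation_ge2y,
                              params.art_attenuation_lt2y),
                     1.0)
    mult = np.where(plwh, 1.0 + (m - 1.0) * atten, 1.0)
    return np.maximum(mult, 1.0)
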