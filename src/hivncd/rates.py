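"""Parameter containers: age/sex/period rate tables, hazard-ratio modifiers,
log-linear onset hazards, and the excess-mortality model.

All containers round-trip through tidy delimited text so the same readers
accept real surveillance extracts or the synthetic fixtures shipped with the
package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

MALE, FEMALE = 0, 1
SEX_LABELS = {"male": MALE, "female": FEMALE, "both": -1}


class RateTable:
    """Piecewise-constant rates (per person-year) on an age x sex x period grid.

    ``age_edges`` are ascending band lower edges (the last band is open);
    ``year_edges`` likewise for calendar periods.  Years before the first
    period use the first period's rates; years after the last use the last
    (which is how a projection holds rates constant at their final observed
    level).
    """

    def __init__(self, age_edges, year_edges, values, by_sex=True):
        self.age_edges = np.asarray(age_edges, dtype=float)
        self.year_edges = np.asarray(year_edges, dtype=float)
        values = np.asarray(values, dtype=float)
        self.by_sex = by_sex
        n_sex = 2 if by_sex else 1
        expect = (n_sex, len(self.age_edges), len(self.year_edges))
        if values.shape != expect:
            raise ValueError(f"values shape {values.shape} != expected {expect}")
        if np.any(values < 0):
            raise ValueError("rates must be nonnegative")
        if np.any(np.diff(self.age_edges) <= 0) or np.any(np.diff(self.year_edges) <= 0):
            raise ValueError("edges must be strictly ascending")
        self.values = values

    def lookup(self, ages: np.ndarray, sexes: np.ndarray, year: float) -> np.ndarray:
        ai = np.clip(np.searchsorted(self.age_edges, ages, side="right") - 1,
                     0, len(self.age_edges) - 1)
        yi = int(np.clip(np.searchsorted(self.year_edges, year, side="right") - 1,
                         0, len(self.year_edges) - 1))
        if self.by_sex:
            return self.values[sexes, ai, yi]
        return self.values[0, ai, yi]

    # -- delimited-text round trip -------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        sex_names = ("male", "female") if self.by_sex else ("both",)
        for si, sex in enumerate(sex_names):
            for ai, alo in enumerate(self.age_edges):
                ahi = self.age_edges[ai + 1] if ai + 1 < len(self.age_edges) else np.nan
                for yi, ylo in enumerate(self.year_edges):
                    yhi = self.year_edges[yi + 1] if yi + 1 < len(self.year_edges) else np.nan
                    rows.append((sex, alo, ahi, ylo, yhi, self.values[si, ai, yi]))
        return pd.DataFrame(rows, columns=["sex", "age_lo", "age_hi", "year_lo", "year_hi", "rate"])

    def write_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RateTable":
        sexes = sorted(df["sex"].unique())
        by_sex = sexes != ["both"]
        age_edges = np.sort(df["age_lo"].unique())
        year_edges = np.sort(df["year_lo"].unique())
        n_sex = 2 if by_sex else 1
        values = np.full((n_sex, len(age_edges), len(year_edges)), np.nan)
        for rec in df.itertuples():
            si = 0 if not by_sex else SEX_LABELS[rec.sex]
            ai = int(np.searchsorted(age_edges, rec.age_lo))
            yi = int(np.searchsorted(year_edges, rec.year_lo))
            values[si, ai, yi] = rec.rate
        if np.isnan(values).any():
            missing = np.argwhere(np.isnan(values))[0]
            raise ValueError(f"rate table incomplete: missing cell at index {tuple(missing)}")
        return cls(age_edges, year_edges, values, by_sex=by_sex)

    @classmethod
    def read_csv(cls, path) -> "RateTable":
        return cls.from_frame(pd.read_csv(path))

    @classmethod
    def constant(cls, rate: float, by_sex=False) -> "RateTable":
        n_sex = 2 if by_sex else 1
        return cls([0.0], [1900.0], np.full((n_sex, 1, 1), float(rate)), by_sex=by_sex)


@dataclass(frozen=True)
class ModifierEntry:
    outcome: str       # NCD whose onset hazard is modified
    condition: str     # pre-existing NCD id, or "hiv" (optionally ART-qualified)
    hazard_ratio: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None

    def __post_init__(self):
        if self.hazard_ratio <= 0:
            raise ValueError("hazard ratios must be positive")


class HazardModifierSet:
    """Hazard/risk ratios keyed by (outcome, conditioning state).

    Missing pairs default to 1.0.  Conditioning states are pre-existing NCD
    ids, ``hiv`` (any HIV infection), or ``hiv_no_art2y`` (HIV-positive and
    ART-naive or on ART for <2 years — the qualifier used for the cervical
    natural-history ratios).
    """

    def __init__(self, entries: Sequence[ModifierEntry] = ()):
        self._map: Dict[Tuple[str, str], float] = {}
        for e in entries:
            self._map[(e.outcome, e.condition)] = e.hazard_ratio
        self.entries = list(entries)

    def ratio(self, outcome: str, condition: str) -> float:
        return self._map.get((outcome, condition), 1.0)

    def conditions_for(self, outcome: str):
        return [(c, r) for (o, c), r in self._map.items() if o == outcome]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.outcome, e.condition, e.hazard_ratio, e.ci_low, e.ci_high) for e in self.entries],
            columns=["outcome", "condition", "hazard_ratio", "ci_low", "ci_high"],
        )

    def write_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "HazardModifierSet":
        df = pd.read_csv(path)
        entries = [
            ModifierEntry(
                outcome=str(r.outcome),
                condition=str(r.condition),
                hazard_ratio=float(r.hazard_ratio),
                ci_low=None if pd.isna(r.ci_low) else float(r.ci_low),
                ci_high=None if pd.isna(r.ci_high) else float(r.ci_high),
            )
            for r in df.itertuples()
        ]
        return cls(entries)


def default_hazard_modifiers() -> HazardModifierSet:
    """Hazard/risk ratios linking pre-existing conditions and HIV to NCD
    onset, as used in the default model configuration."""
    e = ModifierEntry
    return HazardModifierSet([
        # comorbidity links
        e("stroke", "diabetes", 2.431, 1.483, 2.492),
        e("stroke", "hypertension", 1.426, 0.498, 1.462),
        e("hypertension", "diabetes", 1.440, 1.419, 1.464),
        e("ckd", "diabetes", 1.450, 1.405, 2.415),
        e("ckd", "hypertension", 1.469, 1.426, 2.427),
        # HIV links
        e("hypertension", "hiv", 1.449),
        e("ckd", "hiv", 2.04),
        e("depression", "hiv", 3.1),
        # HIV -> non-cervical cancer risk ratios
        e("breast_cancer", "hiv", 0.7),
        e("colorectal_cancer", "hiv", 0.6),
        e("leukemia", "hiv", 1.2),
        e("liver_cancer", "hiv", 3.2),
        e("esophageal_cancer", "hiv", 1.2),
        e("prostate_cancer", "hiv", 0.5),
        e("stomach_cancer", "hiv", 0.7),
        e("other_cancer", "hiv", 1.2),
        # cervical natural history (ART-duration qualified)
        e("hpv_acquisition", "hiv_no_art2y", 1.63, 1.26, 2.11),
        e("hpv_clearance", "hiv_no_art2y", 0.52),
        e("hpv_to_cin23", "hiv_no_art2y", 1.32, 1.10, 1.58),
    ])


@dataclass
class NcdHazard:
    """Baseline onset hazard for one NCD, log-linear in age:

        h(age) = exp(intercept + slope * age + sex_offset * [female]),

    zero below ``min_age``.  ``sensitivity`` is the +/-10%-style multiplier
    applied in sensitivity analyses (1.0 in the base case).
    """

    ncd: str
    intercept: float
    slope: float
    sex_offset: float = 0.0
    min_age: float = 0.0
    sensitivity: float = 1.0

    def hazard(self, ages: np.ndarray, sexes: np.ndarray) -> np.ndarray:
        h = np.exp(self.intercept + self.slope * ages + self.sex_offset * (sexes == FEMALE))
        h = np.where(ages >= self.min_age, h, 0.0)
        return h * self.sensitivity

    def to_dict(self):
        return {
            "ncd": self.ncd, "intercept": self.intercept, "slope": self.slope,
            "sex_offset": self.sex_offset, "min_age": self.min_age,
        }


def write_ncd_hazards(hazards: Dict[str, NcdHazard], path):
    pd.DataFrame([h.to_dict() for h in hazards.values()]).to_csv(path, index=False)


def read_ncd_hazards(path) -> Dict[str, NcdHazard]:
    df = pd.read_csv(path)
    return {
        str(r.ncd): NcdHazard(str(r.ncd), float(r.intercept), float(r.slope),
                              float(r.sex_offset), float(r.min_age))
        for r in df.itertuples()
    }


@dataclass
class MortalityModel:
    """Cause-specific excess mortality.

    ``excess_rr`` multiplies the background all-cause hazard for each modeled
    fatal condition an individual carries; hypertension, high total
    cholesterol and depression are never independent causes of death and must
    not appear here.  Stroke and IHD additionally carry an instantaneous
    case-fatality probability at the moment of the event.
    """

    excess_rr: Dict[str, float] = field(default_factory=dict)
    case_fatality: Dict[str, float] = field(default_factory=dict)  # stroke/ihd

    NON_FATAL = ("hypertension", "high_cholesterol", "depression")

    def __post_init__(self):
        for cause, rr in self.excess_rr.items():
            if cause in self.NON_FATAL:
                raise ValueError(f"{cause} cannot be an independent cause of death")
            if rr < 1:
                raise ValueError(f"excess RR for {cause} must be >= 1, got {rr}")
        for ev, cf in self.case_fatality.items():
            if not 0 <= cf <= 1:
                raise ValueError(f"case fatality for {ev} must be in [0,1]")

    def to_frame(self) -> pd.DataFrame:
        rows = [("excess_rr", c, v) for c, v in self.excess_rr.items()]
        rows += [("case_fatality", c, v) for c, v in self.case_fatality.items()]
        return pd.DataFrame(rows, columns=["kind", "cause", "value"])

    def write_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "MortalityModel":
        df = pd.read_csv(path)
        rr = {str(r.cause): float(r.value) for r in df.itertuples() if r.kind == "excess_rr"}
        cf = {str(r.cause): float(r.value) for r in df.itertuples() if r.kind == "case_fatality"}
        return cls(excess_rr=rr, case_fatality=cf)
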