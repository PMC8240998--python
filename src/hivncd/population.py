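"""The agent population, stored column-wise for vectorized stepping.

Each simulated individual carries sex, birth date, vital status, HIV state
(seroconversion date, CD4 count, ART status), per-NCD onset dates, the most
recent depressive-episode window, at most one lifetime CVD event, and — for
women — a cervical natural-history stage.  The columns live in preallocated
numpy arrays that grow by doubling as births are appended, so a run never
reallocates per step.
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np
import pandas as pd

from .config import CHRONIC_NCDS, CANCERS
from .rates import MALE, FEMALE

# cervical stages
CERV_NA, CERV_SUSC, CERV_HPV, CERV_CIN23, CERV_CIS, CERV_CANCER = -1, 0, 1, 2, 3, 4
CERV_STAGE_NAMES = {CERV_SUSC: "susceptible", CERV_HPV: "hpv", CERV_CIN23: "cin2_3",
                    CERV_CIS: "cis", CERV_CANCER: "cervical_cancer"}

# CVD event types
CVD_NONE, CVD_STROKE, CVD_IHD = 0, 1, 2

ONSET_NCDS = CHRONIC_NCDS + CANCERS + ("depression", "stroke", "ihd", "cervical_cancer")


class Population:
    """Column-wise agent store.

    Onset dates are NaN until the event occurs; ``depression`` records the
    *latest* episode onset (episodes recur), all other onsets are first and
    only.  Dead agents keep their history frozen at ``death_date``.
    """

    def __init__(self, capacity: int):
        self.n = 0
        self._cap = max(int(capacity), 16)
        c = self._cap
        self.sex = np.zeros(c, dtype=np.int8)
        self.birth = np.full(c, np.nan)
        self.alive = np.zeros(c, dtype=bool)
        self.death = np.full(c, np.nan)
        self.cause = np.full(c, "", dtype=object)
        # HIV
        self.hiv = np.zeros(c, dtype=bool)
        self.sero = np.full(c, np.nan)
        self.cd4 = np.full(c, np.nan)
        self.on_art = np.zeros(c, dtype=bool)
        self.art_start = np.full(c, np.nan)
        # NCD onset dates
        self.onset: Dict[str, np.ndarray] = {k: np.full(c, np.nan) for k in ONSET_NCDS}
        self.dep_end = np.full(c, np.nan)      # end of latest depressive episode
        self.cvd_type = np.zeros(c, dtype=np.int8)
        self.cvd_date = np.full(c, np.nan)
        # cervical natural history (females only; CERV_NA for males)
        self.cerv_stage = np.full(c, CERV_NA, dtype=np.int8)
        self.cerv_entry = np.full(c, np.nan)

    # ------------------------------------------------------------------
    _GROWN = ("sex", "birth", "alive", "death", "cause", "hiv", "sero", "cd4",
              "on_art", "art_start", "dep_end", "cvd_type", "cvd_date",
              "cerv_stage", "cerv_entry")

    def _grow(self, need: int):
        new_cap = self._cap
        while new_cap < need:
            new_cap *= 2
        for name in self._GROWN:
            old = getattr(self, name)
            fill = self._fill_for(old)
            arr = np.full(new_cap, fill, dtype=old.dtype)
            arr[: self.n] = old[: self.n]
            setattr(self, name, arr)
        for k, old in self.onset.items():
            arr = np.full(new_cap, np.nan)
            arr[: self.n] = old[: self.n]
            self.onset[k] = arr
        self._cap = new_cap

    @staticmethod
    def _fill_for(arr):
        if arr.dtype == bool:
            return False
        if arr.dtype == np.int8:
            return CERV_NA if arr is None else 0
        if arr.dtype == object:
            return ""
        return np.nan

    def add_agents(self, sexes: np.ndarray, births: np.ndarray) -> np.ndarray:
        """Append newborns/initial agents; returns their index range."""
        k = len(sexes)
        if self.n + k > self._cap:
            self._grow(self.n + k)
        idx = np.arange(self.n, self.n + k)
        self.sex[idx] = sexes
        self.birth[idx] = births
        self.alive[idx] = True
        self.cerv_stage[idx] = np.where(sexes == FEMALE, CERV_SUSC, CERV_NA).astype(np.int8)
        # non-grown defaults are already NaN/False in fresh capacity, but the
        # capacity may be recycled across runs — reset explicitly
        self.death[idx] = np.nan
        self.cause[idx] = ""
        self.hiv[idx] = False
        self.sero[idx] = np.nan
        self.cd4[idx] = np.nan
        self.on_art[idx] = False
        self.art_start[idx] = np.nan
        self.dep_end[idx] = np.nan
        self.cvd_type[idx] = CVD_NONE
        self.cvd_date[idx] = np.nan
        self.cerv_entry[idx] = np.nan
        for arr in self.onset.values():
            arr[idx] = np.nan
        self.n += k
        return idx

    # ------------------------------------------------------------------
    def ages(self, t: float) -> np.ndarray:
        return t - self.birth[: self.n]

    def alive_mask(self) -> np.ndarray:
        return self.alive[: self.n]

    def has_condition(self, ncd: str, t: float) -> np.ndarray:
        """Active-condition mask at time t (length n).

        Chronic conditions and cancers are permanent from onset; depression is
        active while the latest episode covers the past 12 months; ``cvd``
        means any first CVD event ever.
        """
        n = self.n
        if ncd == "cvd":
            return self.cvd_type[:n] != CVD_NONE
        if ncd == "depression":
            end = self.dep_end[:n]
            return ~np.isnan(end) & (end > t - 1.0)
        if ncd == "hiv":
            return self.hiv[:n]
        if ncd == "cervical_cancer":
            return self.cerv_stage[:n] == CERV_CANCER
        onset = self.onset[ncd][:n]
        return ~np.isnan(onset) & (onset <= t)

    def kill(self, idx: np.ndarray, t: float, causes):
        self.alive[idx] = False
        self.death[idx] = t
        self.cause[idx] = causes

    # ------------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        n = self.n
        d = {
            "sex": np.where(self.sex[:n] == FEMALE, "female", "male"),
            "birth": self.birth[:n], "alive": self.alive[:n],
            "death": self.death[:n], "cause": self.cause[:n],
            "hiv": self.hiv[:n], "sero": self.sero[:n], "cd4": self.cd4[:n],
            "on_art": self.on_art[:n], "art_start": self.art_start[:n],
            "dep_end": self.dep_end[:n], "cvd_type": self.cvd_type[:n],
            "cvd_date": self.cvd_date[:n], "cerv_stage": self.cerv_stage[:n],
        }
        for k, arr in self.onset.items():
            d[f"onset_{k}"] = arr[:n]
        return pd.DataFrame(d)
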