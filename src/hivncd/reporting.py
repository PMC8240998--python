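"""Burden reports: multimorbidity, standardized rates, run averaging and
sensitivity sweeps.

All operations consume the tidy annual snapshots produced by the engine
(one row per year x single-year age x sex x HIV stratum) so any report can be
regenerated deterministically from stored run output.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import MULTIMORBIDITY_SET, SimulationConfig
from .engine import ParameterSet, SimResult, Simulation
from .epi_stats import PooledAgeProfile, StudyEstimate, direct_standardize
from .population import Population
from .who_standard import WHO_WORLD_STANDARD, StandardPopulation

ADULT_BANDS = ((18, 30), (30, 40), (40, 50), (50, 60), (60, None))
CERVICAL_BANDS = ((15, 25), (25, 30), (30, 35), (35, 40), (40, None))

_KEY = ["year", "age", "sex", "hiv"]


def _stratum_mask(df: pd.DataFrame, hiv: Optional[str]) -> pd.Series:
    if hiv is None or hiv == "all":
        return pd.Series(True, index=df.index)
    if hiv in ("plwh", "positive"):
        return df["hiv"] == 1
    if hiv in ("negative", "hiv_negative"):
        return df["hiv"] == 0
    raise ValueError(f"unknown HIV stratum {hiv!r}")


def multimorbidity_fraction(snapshot: pd.DataFrame, year: int,
                            hiv: Optional[str] = None,
                            min_age: float = 18.0) -> float:
    """Fraction of living adults in the stratum with >=1 NCD from the
    multimorbidity set (depression = episode in the past 12 months, CVD =
    ever after the first event, other conditions permanent from onset)."""
    df = snapshot[(snapshot["year"] == year) & (snapshot["age"] >= min_age)]
    df = df[_stratum_mask(df, hiv)]
    pop = df["pop"].sum()
    if pop == 0:
        raise ValueError(f"empty stratum: year={year}, hiv={hiv}")
    return float(df["any_ncd"].sum() / pop)


def multimorbidity_fraction_agents(pop: Population, t: float,
                                   ncds: Sequence[str] = MULTIMORBIDITY_SET,
                                   hiv: Optional[bool] = None,
                                   min_age: float = 18.0) -> float:
    """Same definition computed directly on an agent population (used for
    cross-checks against the snapshot-level computation)."""
    n = pop.n
    mask = pop.alive_mask() & (pop.ages(t) >= min_age)
    if hiv is not None:
        mask &= pop.hiv[:n] == hiv
    denom = mask.sum()
    if denom == 0:
        raise ValueError("empty stratum")
    any_ncd = np.zeros(n, dtype=bool)
    for c in ncds:
        any_ncd |= pop.has_condition(c, t)
    return float((mask & any_ncd).sum() / denom)


def age_profile(snapshot: pd.DataFrame, year: int, condition: str,
                bands: Sequence[Tuple] = ADULT_BANDS,
                hiv: Optional[str] = None, sex: Optional[int] = None,
                column: Optional[str] = None) -> PooledAgeProfile:
    """Age-band prevalence profile of one condition from a snapshot year.

    ``column`` overrides the snapshot column (e.g. ``hpv``/``cin23`` for
    cervical stage occupancy); otherwise ``prev_<condition>`` is used.
    """
    df = snapshot[snapshot["year"] == year]
    df = df[_stratum_mask(df, hiv)]
    if sex is not None:
        df = df[df["sex"] == sex]
    col = column if column is not None else f"prev_{condition}"
    ests = []
    for lo, hi in bands:
        m = (df["age"] >= lo) & (df["age"] < (hi if hi is not None else np.inf))
        popn = df.loc[m, "pop"].sum()
        if popn == 0:
            raise ValueError(f"empty age band {lo}-{hi} in year {year}")
        ests.append(StudyEstimate(age_lo=lo, age_hi=hi,
                                  point=float(df.loc[m, col].sum() / popn),
                                  source_id=f"model:{condition}"))
    return PooledAgeProfile(ests, scale="proportion", lower_age_bound=bands[0][0])


def standardized_output_rates(snapshot: pd.DataFrame, year: int, condition: str,
                              bands: Sequence[Tuple] = ADULT_BANDS,
                              hiv: Optional[str] = None,
                              sex: Optional[int] = None,
                              column: Optional[str] = None,
                              std: StandardPopulation = WHO_WORLD_STANDARD) -> float:
    """Direct age-standardized prevalence of a condition in a stratum."""
    prof = age_profile(snapshot, year, condition, bands, hiv, sex, column)
    return direct_standardize(prof, std)


def aggregate_runs(frames: Sequence[pd.DataFrame],
                   value_columns: Optional[Sequence[str]] = None
                   ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Element-wise mean and Monte Carlo standard error of the mean across
    replicate snapshot frames sharing the (year, age, sex, hiv) axes.

    Cells absent from a replicate (no agents) count as zero.  Returns
    ``(mean_frame, se_frame)``; both carry an ``n_runs`` attribute.
    """
    if not frames:
        raise ValueError("need at least one report")
    cols = (list(value_columns) if value_columns is not None
            else [c for c in frames[0].columns if c not in _KEY])
    for f in frames[1:]:
        if set(f.columns) != set(frames[0].columns):
            raise ValueError("replicate reports have mismatched columns")
    stacked = [f.set_index(_KEY)[cols] for f in frames]
    union = stacked[0].index
    for s in stacked[1:]:
        union = union.union(s.index)
    mats = np.stack([s.reindex(union, fill_value=0.0).values for s in stacked])
    mean = pd.DataFrame(mats.mean(axis=0), index=union, columns=cols).reset_index()
    k = len(frames)
    se_vals = (mats.std(axis=0, ddof=1) / np.sqrt(k)) if k > 1 else np.zeros_like(mats[0])
    se = pd.DataFrame(se_vals, index=union, columns=cols).reset_index()
    mean.attrs["n_runs"] = se.attrs["n_runs"] = k
    return mean, se


def population_count(snapshot: pd.DataFrame, year: int, scale_factor: float = 1.0,
                     min_age: float = 0.0, hiv: Optional[str] = None) -> float:
    df = snapshot[(snapshot["year"] == year) & (snapshot["age"] >= min_age)]
    df = df[_stratum_mask(df, hiv)]
    return float(df["pop"].sum() * scale_factor)


def new_cases_between(result: SimResult, ncd: str, year_lo: int, year_hi: int,
                      hiv: Optional[str] = None, min_age: float = 0.0) -> float:
    """Incident cases of one NCD over (year_lo, year_hi], in agents."""
    d = result.new_cases
    d = d[(d["ncd"] == ncd) & (d["year"] > year_lo) & (d["year"] <= year_hi)
          & (d["age"] >= min_age)]
    d = d[_stratum_mask(d, hiv)]
    return float(d["count"].sum())


def deaths_by_cause(result: SimResult, year_lo: int, year_hi: int,
                    hiv: Optional[str] = None) -> pd.Series:
    d = result.deaths
    d = d[(d["year"] > year_lo) & (d["year"] <= year_hi)]
    d = d[_stratum_mask(d, hiv)]
    return d.groupby("cause")["count"].sum().sort_values(ascending=False)


def sensitivity_sweep(config: SimulationConfig, params: ParameterSet,
                      ncds: Sequence[str],
                      multipliers: Sequence[float] = (0.9, 1.0, 1.1)
                      ) -> Dict[Tuple[str, float], SimResult]:
    """One run per (NCD, incidence multiplier), all with the same seed so the
    multiplier is the only difference; 1.0 runs are shared as the baseline."""
    out: Dict[Tuple[str, float], SimResult] = {}
    baseline = None
    for ncd in ncds:
        for m in multipliers:
            if m == 1.0:
                if baseline is None:
                    baseline = Simulation(config, params).run()
                out[(ncd, 1.0)] = baseline
                continue
            cfg = replace(config, sensitivity={**config.sensitivity, ncd: m})
            out[(ncd, m)] = Simulation(cfg, params).run()
    return out


def burden_summary(result: SimResult, year: int) -> pd.DataFrame:
    """One-line-per-condition summary for a snapshot year: adult prevalent
    count (agents and scaled persons) and crude adult prevalence."""
    snap = result.prevalence
    df = snap[(snap["year"] == year) & (snap["age"] >= 18)]
    adults = df["pop"].sum()
    rows = []
    prev_cols = [c for c in snap.columns if c.startswith("prev_")] + ["any_ncd"]
    for col in prev_cols:
        cnt = df[col].sum()
        rows.append({
            "condition": col.replace("prev_", ""),
            "adult_agents": cnt,
            "adult_persons": cnt * result.config.scale_factor,
            "crude_prevalence": cnt / adults if adults else np.nan,
        })
    return pd.DataFrame(rows)
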