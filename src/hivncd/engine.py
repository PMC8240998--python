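"""Discrete-time individual-based engine.

Each step of length ``dt`` applies, in fixed order: (1) HIV incidence,
(2) CD4 progression and ART initiation, (3) cervical natural-history
transitions, (4) chronic-NCD and cancer onsets, (5) depression episode
dynamics, (6) first CVD events with acute case fatality, (7) all-cause
mortality (background x HIV multiplier x condition excess risks),
(8) births, (9) aging (advancing the clock).  Every hazard h is converted to
a per-step probability 1 - exp(-h dt).

Randomness is organized as one master seed from which per-run and per-module
substreams are spawned, so a run is bit-reproducible and module toggles do
not perturb each other's draws.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .cervical import CervicalRates, cervical_step
from .config import CANCERS, CHRONIC_NCDS, MULTIMORBIDITY_SET, SimulationConfig
from .hiv import (ArtSchedule, HivParams, acquire_hiv, hiv_mortality_multiplier,
                  initiate_art, progress_cd4)
from .ncds import (depression_step, sample_cvd_events, sample_deaths,
                   sample_ncd_onsets)
from .population import CERV_CIN23, CERV_HPV, Population
from .rates import (FEMALE, MALE, HazardModifierSet, MortalityModel, NcdHazard,
                    RateTable, read_ncd_hazards, write_ncd_hazards)

# modules, in spawn order, each with its own RNG substream
_STREAMS = ("init", "hiv", "art", "cervical", "ncd", "depression", "cvd",
            "mortality", "births")


@dataclass
class InitialComposition:
    """Age/sex composition used to draw the starting population: band lower
    edges, band width, and a weight per (sex, band)."""

    age_edges: np.ndarray
    weights: np.ndarray  # shape (2, n_bands), rows male/female

    def __post_init__(self):
        self.age_edges = np.asarray(self.age_edges, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0) or self.weights.sum() <= 0:
            raise ValueError("composition weights must be nonnegative, not all zero")

    def sample(self, n: int, rng: np.random.Generator, width: float = 5.0):
        flat = self.weights.ravel() / self.weights.sum()
        cells = rng.choice(flat.size, size=n, p=flat)
        sexes = (cells // len(self.age_edges)).astype(np.int8)
        band = cells % len(self.age_edges)
        ages = self.age_edges[band] + rng.uniform(0, width, n)
        return sexes, ages

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for si, sex in enumerate(("male", "female")):
            for ai, lo in enumerate(self.age_edges):
                rows.append((sex, lo, self.weights[si, ai]))
        return pd.DataFrame(rows, columns=["sex", "age_lo", "weight"])

    def write_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "InitialComposition":
        df = pd.read_csv(path)
        edges = np.sort(df["age_lo"].unique())
        w = np.zeros((2, len(edges)))
        for r in df.itertuples():
            si = 0 if r.sex == "male" else 1
            w[si, int(np.searchsorted(edges, r.age_lo))] = r.weight
        return cls(edges, w)


@dataclass
class ParameterSet:
    """Everything a run needs besides the :class:`SimulationConfig`."""

    fertility: RateTable                 # births per woman-year, by age band
    mortality: RateTable                 # background all-cause, by age/sex
    init_composition: InitialComposition
    hiv_incidence: RateTable
    art_schedule: ArtSchedule
    hiv_params: HivParams
    ncd_hazards: Dict[str, NcdHazard]    # includes "stroke" and "depression"
    modifiers: HazardModifierSet
    mortality_model: MortalityModel
    cervical_rates: CervicalRates
    depression_duration: float = 0.5     # years per episode

    _FILES = {
        "fertility": "fertility.csv", "mortality": "mortality.csv",
        "init_composition": "init_composition.csv",
        "hiv_incidence": "hiv_incidence.csv", "art_schedule": "art_schedule.csv",
        "ncd_hazards": "ncd_hazards.csv", "modifiers": "hazard_modifiers.csv",
        "mortality_model": "mortality_model.csv",
        "cervical_rates": "cervical_rates.csv",
    }

    def write_dir(self, path):
        os.makedirs(path, exist_ok=True)
        self.fertility.write_csv(os.path.join(path, "fertility.csv"))
        self.mortality.write_csv(os.path.join(path, "mortality.csv"))
        self.init_composition.write_csv(os.path.join(path, "init_composition.csv"))
        self.hiv_incidence.write_csv(os.path.join(path, "hiv_incidence.csv"))
        self.art_schedule.write_csv(os.path.join(path, "art_schedule.csv"))
        write_ncd_hazards(self.ncd_hazards, os.path.join(path, "ncd_hazards.csv"))
        self.modifiers.write_csv(os.path.join(path, "hazard_modifiers.csv"))
        self.mortality_model.write_csv(os.path.join(path, "mortality_model.csv"))
        self.cervical_rates.write_csv(os.path.join(path, "cervical_rates.csv"))
        with open(os.path.join(path, "scalars.yaml"), "w") as fh:
            yaml.safe_dump({"depression_duration": self.depression_duration,
                            "hiv_params": self.hiv_params.__dict__ |
                            {"mortality_multipliers": list(self.hiv_params.mortality_multipliers)}},
                           fh)

    @classmethod
    def read_dir(cls, path) -> "ParameterSet":
        with open(os.path.join(path, "scalars.yaml")) as fh:
            scal = yaml.safe_load(fh)
        hp = dict(scal["hiv_params"])
        hp["mortality_multipliers"] = tuple(hp["mortality_multipliers"])
        return cls(
            fertility=RateTable.read_csv(os.path.join(path, "fertility.csv")),
            mortality=RateTable.read_csv(os.path.join(path, "mortality.csv")),
            init_composition=InitialComposition.read_csv(os.path.join(path, "init_composition.csv")),
            hiv_incidence=RateTable.read_csv(os.path.join(path, "hiv_incidence.csv")),
            art_schedule=ArtSchedule.read_csv(os.path.join(path, "art_schedule.csv")),
            hiv_params=HivParams(**hp),
            ncd_hazards=read_ncd_hazards(os.path.join(path, "ncd_hazards.csv")),
            modifiers=HazardModifierSet.read_csv(os.path.join(path, "hazard_modifiers.csv")),
            mortality_model=MortalityModel.read_csv(os.path.join(path, "mortality_model.csv")),
            cervical_rates=CervicalRates.read_csv(os.path.join(path, "cervical_rates.csv")),
            depression_duration=float(scal["depression_duration"]),
        )


# conditions tallied in annual snapshots
SNAPSHOT_CONDITIONS = CHRONIC_NCDS + CANCERS + ("depression", "cvd", "stroke", "ihd",
                                                "cervical_cancer")


@dataclass
class SimResult:
    """Annual snapshots plus event-flow tallies from one run.

    ``prevalence`` is tidy with one row per (year, age, sex, hiv) cell:
    population count, per-condition prevalent counts (columns ``prev_*``),
    count with >=1 NCD from the multimorbidity set, HPV/CIN2/3 stage counts
    for women, and count on ART.  ``deaths`` and ``new_cases`` tally events
    during the year ending at ``year``.  Counts are in agents; multiply by
    ``config.scale_factor`` for represented persons.
    """

    config: SimulationConfig
    prevalence: pd.DataFrame
    deaths: pd.DataFrame
    new_cases: pd.DataFrame
    events: Optional[pd.DataFrame]
    final_population: Population

    def events_csv_bytes(self) -> bytes:
        if self.events is None:
            raise ValueError("run with log_events=True to get an event log")
        return self.events.to_csv(index=False).encode()


class Simulation:
    def __init__(self, config: SimulationConfig, params: ParameterSet):
        self.config = config
        self.params = params

    # ------------------------------------------------------------------
    def run(self, seed: Optional[int] = None) -> SimResult:
        cfg, par = self.config, self.params
        seed = cfg.seed if seed is None else seed
        ss = np.random.SeedSequence(seed)
        rngs = {name: np.random.default_rng(s)
                for name, s in zip(_STREAMS, ss.spawn(len(_STREAMS)))}
        dt = cfg.time_step
        max_age = cfg.snapshot_max_age

        pop = Population(int(cfg.n_agents * 2))
        sexes, ages = par.init_composition.sample(cfg.n_agents, rngs["init"])
        pop.add_agents(sexes, cfg.start_year - ages)

        events: List[tuple] = []
        def log(idx, t, kind, detail=""):
            if cfg.log_events and len(idx):
                tt = round(t, 6)
                if np.ndim(detail) == 0:
                    events.extend((int(i), tt, kind, detail) for i in idx)
                else:
                    events.extend((int(i), tt, kind, d) for i, d in zip(idx, detail))

        # annual accumulators (age x sex x hiv)
        def _acc():
            return {}
        deaths_acc: Dict[str, np.ndarray] = {}
        cases_acc: Dict[str, np.ndarray] = {}

        def _tally(acc, key, idx, t):
            if len(idx) == 0:
                return
            a = acc.get(key)
            if a is None:
                a = acc[key] = np.zeros((max_age + 1, 2, 2))
            ag = np.clip((t - pop.birth[idx]).astype(int), 0, max_age)
            np.add.at(a, (ag, pop.sex[idx], pop.hiv[idx].astype(int)), 1)

        snapshots: List[pd.DataFrame] = []
        flows_deaths: List[pd.DataFrame] = []
        flows_cases: List[pd.DataFrame] = []

        def take_snapshot(year: int):
            n = pop.n
            alive = pop.alive_mask()
            ag = np.clip(pop.ages(year).astype(int), 0, max_age)
            g = (ag * 4 + pop.sex[:n] * 2 + pop.hiv[:n].astype(int))
            size = (max_age + 1) * 4
            def count(mask):
                return np.bincount(g[mask], minlength=size)
            base = count(alive)
            cols = {"pop": base}
            for c in SNAPSHOT_CONDITIONS:
                cols[f"prev_{c}"] = count(alive & pop.has_condition(c, year))
            any_mask = np.zeros(n, dtype=bool)
            for c in MULTIMORBIDITY_SET:
                any_mask |= pop.has_condition(c, year)
            cols["any_ncd"] = count(alive & any_mask)
            cols["hpv"] = count(alive & (pop.cerv_stage[:n] == CERV_HPV))
            cols["cin23"] = count(alive & (pop.cerv_stage[:n] == CERV_CIN23))
            cols["on_art"] = count(alive & pop.on_art[:n])
            ages_idx = np.repeat(np.arange(max_age + 1), 4)
            sex_idx = np.tile(np.repeat([0, 1], 2), max_age + 1)
            hiv_idx = np.tile([0, 1], (max_age + 1) * 2)
            df = pd.DataFrame({"year": year, "age": ages_idx, "sex": sex_idx,
                               "hiv": hiv_idx, **{k: v for k, v in cols.items()}})
            snapshots.append(df[df["pop"] > 0].copy())
            for acc, store, label in ((deaths_acc, flows_deaths, "cause"),
                                      (cases_acc, flows_cases, "ncd")):
                for key, a in acc.items():
                    nz = np.argwhere(a > 0)
                    if nz.size:
                        store.append(pd.DataFrame({
                            "year": year, label: key,
                            "age": nz[:, 0], "sex": nz[:, 1], "hiv": nz[:, 2],
                            "count": a[nz[:, 0], nz[:, 1], nz[:, 2]]}))
                acc.clear()

        start_year = int(round(cfg.start_year))
        take_snapshot(start_year)
        steps_per_year = int(round(1.0 / dt))
        n_years = int(round(cfg.end_year - cfg.start_year))
        t = cfg.start_year
        enabled = tuple(cfg.enabled_ncds)
        sens = cfg.sensitivity

        for year_i in range(n_years):
            year = start_year + year_i
            for _ in range(steps_per_year):
                n = pop.n
                # (1) HIV incidence
                if cfg.enable_hiv:
                    inf = acquire_hiv(pop, par.hiv_incidence, par.hiv_params,
                                      t, dt, rngs["hiv"])
                    log(inf, t, "hiv_infection")
                    _tally(cases_acc, "hiv", inf, t)
                    # (2) CD4 progression and ART initiation toward the
                    # year's coverage target
                    progress_cd4(pop, par.hiv_params, dt)
                    started = initiate_art(pop, par.art_schedule, t, rngs["art"])
                    log(started, t, "art_start")
                # (3) cervical transitions
                if cfg.enable_cervical:
                    cc = cervical_step(pop, par.cervical_rates, par.modifiers,
                                       t, dt, rngs["cervical"])
                    log(cc, t, "onset_cervical_cancer")
                    _tally(cases_acc, "cervical_cancer", cc, t)
                # (4) chronic NCD and cancer onsets
                for ncd in enabled:
                    haz = par.ncd_hazards.get(ncd)
                    if haz is None:
                        raise KeyError(f"no hazard parameters for NCD {ncd!r}")
                    if ncd in sens:
                        haz = NcdHazard(haz.ncd, haz.intercept, haz.slope,
                                        haz.sex_offset, haz.min_age,
                                        sensitivity=sens[ncd])
                    hit = sample_ncd_onsets(pop, haz, par.modifiers, t, dt, rngs["ncd"])
                    log(hit, t, f"onset_{ncd}")
                    _tally(cases_acc, ncd, hit, t)
                # (5) depression dynamics
                if cfg.enable_depression:
                    haz = par.ncd_hazards["depression"]
                    if "depression" in sens:
                        haz = NcdHazard(haz.ncd, haz.intercept, haz.slope,
                                        haz.sex_offset, haz.min_age,
                                        sensitivity=sens["depression"])
                    ep = depression_step(pop, haz, par.modifiers,
                                         par.depression_duration, t, dt,
                                         rngs["depression"])
                    log(ep, t, "depression_episode")
                    _tally(cases_acc, "depression", ep, t)
                # (6) CVD events with acute case fatality
                if cfg.enable_cvd:
                    haz = par.ncd_hazards["stroke"]
                    if "cvd" in sens:
                        haz = NcdHazard(haz.ncd, haz.intercept, haz.slope,
                                        haz.sex_offset, haz.min_age,
                                        sensitivity=sens["cvd"])
                    hit, acute = sample_cvd_events(
                        pop, haz, par.modifiers, par.mortality_model, t, dt,
                        rngs["cvd"], cfg.apply_stroke_modifiers_to_ihd,
                        mortality_on=cfg.enable_mortality)
                    log(hit, t, "cvd_event")
                    _tally(cases_acc, "cvd", hit, t)
                    if len(acute):
                        log(acute, t, "death", pop.cause[acute])
                        _tally(deaths_acc, "stroke", acute[pop.cause[acute] == "stroke"], t)
                        _tally(deaths_acc, "ihd", acute[pop.cause[acute] == "ihd"], t)
                # (7) all-cause mortality
                if cfg.enable_mortality:
                    ages = pop.ages(t)
                    mu = par.mortality.lookup(ages, pop.sex[:n], t)
                    hiv_mult = (hiv_mortality_multiplier(pop, par.hiv_params, t)
                                if cfg.enable_hiv else np.ones(n))
                    dead, causes = sample_deaths(pop, mu, par.mortality_model,
                                                 hiv_mult, t, dt, rngs["mortality"])
                    if len(dead):
                        log(dead, t, "death", causes)
                        for c in np.unique(causes):
                            _tally(deaths_acc, str(c), dead[causes == c], t)
                # (8) births
                if cfg.enable_fertility:
                    women = pop.alive_mask() & (pop.sex[:pop.n] == FEMALE)
                    widx = np.flatnonzero(women)
                    if widx.size:
                        f = par.fertility.lookup(t - pop.birth[widx],
                                                 pop.sex[widx], t)
                        pb = -np.expm1(-f * dt)
                        mothers = widx[rngs["births"].random(widx.size) < pb]
                        k = mothers.size
                        if k:
                            baby_sex = (rngs["births"].random(k) < 0.5).astype(np.int8)
                            new = pop.add_agents(baby_sex, np.full(k, t))
                            log(new, t, "birth")
                # (9) aging: advance the clock
                t += dt
            take_snapshot(year + 1)

        prevalence = pd.concat(snapshots, ignore_index=True)
        deaths = (pd.concat(flows_deaths, ignore_index=True)
                  if flows_deaths else pd.DataFrame(
                      columns=["year", "cause", "age", "sex", "hiv", "count"]))
        new_cases = (pd.concat(flows_cases, ignore_index=True)
                     if flows_cases else pd.DataFrame(
                         columns=["year", "ncd", "age", "sex", "hiv", "count"]))
        ev = None
        if cfg.log_events:
            ev = pd.DataFrame(events, columns=["id", "time", "event", "detail"])
            ev = ev.sort_values(["time", "id", "event"], kind="stable").reset_index(drop=True)
        return SimResult(cfg, prevalence, deaths, new_cases, ev, pop)

    # ------------------------------------------------------------------
    def run_replicates(self, n_runs: Optional[int] = None) -> List[SimResult]:
        """n_runs replicates with sub-seeds spawned from the master seed."""
        n_runs = self.config.n_runs if n_runs is None else n_runs
        child = np.random.SeedSequence(self.config.seed).spawn(n_runs)
        return [self.run(seed=int(c.generate_state(1)[0] % (2**31 - 1)))
                for c in child]
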