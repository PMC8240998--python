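"""Calibration of baseline incidence and excess mortality to targets.

The calibrator infers the log-linear age-hazard parameters of each NCD so
that simulated age-band prevalence (or incidence) matches observed targets,
and cause-specific excess death risks so that simulated cause-of-death
fractions match burden-of-disease style death fractions.  The objective is a
weighted sum of squared errors (weights = inverse squared CI half-widths)
evaluated on simulation output; the optimizer is derivative-free Nelder-Mead
over the log-hazard parameters with common random numbers across evaluations
(the same sub-seeds every evaluation), which makes the stochastic objective a
deterministic function of the parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .config import SimulationConfig
from .engine import ParameterSet, Simulation
from .rates import MortalityModel, NcdHazard

_Z = 1.959963984540054


@dataclass
class CalibrationTarget:
    """One observed quantity the model must match."""

    quantity: str              # prevalence | incidence | death_fraction | stage_prevalence
    ncd: str
    age_lo: float = 0.0
    age_hi: Optional[float] = None
    sex: Optional[str] = None
    hiv: Optional[str] = None
    value: float = 0.0
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    year: int = 2018

    def __post_init__(self):
        if self.value < 0:
            raise ValueError("target value must be nonnegative")
        if self.ci_low is not None and self.ci_high is not None:
            if not (self.ci_low <= self.value <= self.ci_high):
                raise ValueError("target CI must contain the value")

    @property
    def weight(self) -> float:
        if self.ci_low is not None and self.ci_high is not None and self.ci_high > self.ci_low:
            hw = (self.ci_high - self.ci_low) / 2.0
            return 1.0 / hw**2
        return 1.0


@dataclass
class CalibrationResult:
    fitted: object                    # NcdHazard or MortalityModel
    simulated: np.ndarray             # per-target simulated values at the optimum
    targets: Sequence[CalibrationTarget]
    loss: float
    loss_trace: List[float]           # best-so-far loss at each accepted improvement
    converged: bool
    n_evaluations: int
    seed: int

    def within_ci(self, halfwidths: float = 2.0) -> float:
        """Fraction of targets whose simulated value lies within the given
        number of CI half-widths of the observed value."""
        ok = 0
        for tgt, sim in zip(self.targets, self.simulated):
            if tgt.ci_low is None or tgt.ci_high is None:
                continue
            hw = (tgt.ci_high - tgt.ci_low) / 2.0
            ok += abs(sim - tgt.value) <= halfwidths * hw
        return ok / len(self.targets)


def _band_prevalence(snap: pd.DataFrame, ncd: str, targets) -> np.ndarray:
    out = []
    for tgt in targets:
        hi = tgt.age_hi if tgt.age_hi is not None else np.inf
        m = (snap["age"] >= tgt.age_lo) & (snap["age"] < hi)
        pop = snap.loc[m, "pop"].sum()
        out.append(snap.loc[m, f"prev_{ncd}"].sum() / pop if pop else 0.0)
    return np.array(out)


def prevalence_simulator(ncd: str, config: SimulationConfig, params: ParameterSet,
                         targets: Sequence[CalibrationTarget], seed: int,
                         n_reps: int = 1) -> Callable[[NcdHazard], np.ndarray]:
    """Build a CRN objective simulator: maps a candidate hazard to the
    simulated per-target prevalences, always with the same sub-seeds."""
    year = targets[0].year
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1))
             for s in np.random.SeedSequence(seed).spawn(n_reps)]

    def simulate(haz: NcdHazard) -> np.ndarray:
        new_params = replace(params, ncd_hazards={**params.ncd_hazards, ncd: haz})
        vals = []
        for s in seeds:
            res = Simulation(config, new_params).run(seed=s)
            snap = res.prevalence[res.prevalence["year"] == year]
            vals.append(_band_prevalence(snap, ncd, targets))
        return np.mean(vals, axis=0)

    return simulate


def fit_incidence(targets: Sequence[CalibrationTarget],
                  simulator: Callable[[NcdHazard], np.ndarray],
                  ncd: str,
                  x0: Tuple[float, float] = (-6.0, 0.04),
                  sex_offset: float = 0.0, min_age: float = 18.0,
                  max_iter: int = 120, seed: int = 0,
                  xatol: float = 2e-3, fatol: float = 1e-4) -> CalibrationResult:
    """Fit the log-linear age-hazard (intercept, slope) of one NCD to
    age-band targets by weighted least squares on simulation output.

    Non-convergence within the iteration budget yields a flagged result
    (``converged=False``), not an exception.  Deterministic given the
    simulator's seeds.
    """
    if len({t.age_lo for t in targets}) < 2:
        raise ValueError("need targets covering at least two age bands")
    w = np.array([t.weight for t in targets])
    w = w / w.sum()
    obs = np.array([t.value for t in targets])
    trace: List[float] = []
    n_eval = 0

    def loss(theta):
        nonlocal n_eval
        n_eval += 1
        haz = NcdHazard(ncd, float(theta[0]), float(theta[1]),
                        sex_offset=sex_offset, min_age=min_age)
        sim = simulator(haz)
        val = float(np.sum(w * (sim - obs) ** 2))
        if not trace or val < trace[-1]:
            trace.append(val)
        return val

    res = minimize(loss, np.asarray(x0, dtype=float), method="Nelder-Mead",
                   options={"maxiter": max_iter, "xatol": xatol, "fatol": fatol})
    fitted = NcdHazard(ncd, float(res.x[0]), float(res.x[1]),
                       sex_offset=sex_offset, min_age=min_age)
    return CalibrationResult(
        fitted=fitted, simulated=simulator(fitted), targets=list(targets),
        loss=float(res.fun), loss_trace=trace, converged=bool(res.success),
        n_evaluations=n_eval, seed=seed)


# ----------------------------------------------------------------------
def death_fraction_simulator(config: SimulationConfig, params: ParameterSet,
                             causes: Sequence[str], seed: int,
                             year_lo: int, year_hi: int,
                             case_fatality: Optional[Dict[str, float]] = None
                             ) -> Callable[[Dict[str, float]], np.ndarray]:
    """CRN simulator mapping candidate excess RRs (per cause) to the
    simulated fractions of deaths attributed to each cause over a year
    window."""
    s = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31 - 1))

    def simulate(rrs: Dict[str, float]) -> np.ndarray:
        mm = MortalityModel(
            excess_rr={**params.mortality_model.excess_rr, **rrs},
            case_fatality=case_fatality if case_fatality is not None
            else params.mortality_model.case_fatality)
        res = Simulation(config, replace(params, mortality_model=mm)).run(seed=s)
        d = res.deaths
        d = d[(d["year"] > year_lo) & (d["year"] <= year_hi)]
        total = d["count"].sum()
        if total == 0:
            return np.zeros(len(causes))
        return np.array([d.loc[d["cause"] == c, "count"].sum() / total
                         for c in causes])

    return simulate


def fit_excess_mortality(targets: Sequence[CalibrationTarget],
                         simulator: Callable[[Dict[str, float]], np.ndarray],
                         max_iter: int = 80, seed: int = 0) -> CalibrationResult:
    """Fit per-cause excess relative risks of death so simulated
    cause-of-death fractions match the targets.

    A target fraction of zero pins that cause's RR at 1 (no excess risk).
    RRs are parametrized as 1 + exp(theta) so the >=1 constraint holds
    throughout the search.  Hypertension, high total cholesterol and
    depression are rejected (never independent causes of death).
    """
    for t in targets:
        if t.quantity != "death_fraction":
            raise ValueError("fit_excess_mortality expects death_fraction targets")
        if t.ncd in MortalityModel.NON_FATAL:
            raise ValueError(f"{t.ncd} is not an independent cause of death")
    causes = [t.ncd for t in targets]
    obs = np.array([t.value for t in targets])
    w = np.array([t.weight for t in targets])
    w = w / w.sum()
    free = obs > 0
    trace: List[float] = []
    n_eval = 0

    def unpack(theta):
        rrs = {}
        j = 0
        for c, is_free in zip(causes, free):
            rrs[c] = 1.0 + float(np.exp(theta[j])) if is_free else 1.0
            j += is_free
        return rrs

    def loss(theta):
        nonlocal n_eval
        n_eval += 1
        sim = simulator(unpack(theta))
        val = float(np.sum(w * (sim - obs) ** 2))
        if not trace or val < trace[-1]:
            trace.append(val)
        return val

    x0 = np.zeros(int(free.sum()))
    if free.any():
        # a generously spread initial simplex: the objective is a step
        # function of the RRs at finite n, so tiny default steps would stall
        simplex = np.vstack([x0] + [x0 + 0.7 * e for e in np.eye(len(x0))])
        res = minimize(loss, x0, method="Nelder-Mead",
                       options={"maxiter": max_iter, "xatol": 5e-3,
                                "fatol": 1e-6, "initial_simplex": simplex})
        rrs = unpack(res.x)
        final_loss, success = float(res.fun), bool(res.success)
    else:
        rrs = unpack(x0)
        final_loss, success = float(np.sum(w * (simulator(rrs) - obs) ** 2)), True
    fitted = MortalityModel(excess_rr=rrs, case_fatality={})
    return CalibrationResult(
        fitted=fitted, simulated=simulator(rrs), targets=list(targets),
        loss=final_loss, loss_trace=trace, converged=success,
        n_evaluations=n_eval, seed=seed)
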