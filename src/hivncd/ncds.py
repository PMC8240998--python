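"""Noncommunicable-disease onset and mortality mechanics.

Onset hazards are baseline log-linear-in-age rates multiplied by hazard
ratios for pre-existing conditions and HIV (proportional-hazards convention:
modifiers combine multiplicatively).  Cardiovascular disease is modeled as a
first-ever event that is ischemic heart disease with 4x the incidence of
stroke, each with an instantaneous case fatality; survivors carry a chronic
excess death risk.  Depression recurs in episodes of fixed duration.
Hypertension, high total cholesterol and depression are never independent
causes of death; for each remaining condition a fixed excess relative risk
multiplies background mortality, and the cause of death is attributed in
proportion to each factor's excess contribution to the total hazard.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .config import CANCERS, CHRONIC_NCDS, FEMALE_ONLY_NCDS, MALE_ONLY_NCDS
from .population import CVD_IHD, CVD_NONE, CVD_STROKE, Population
from .rates import FEMALE, MALE, HazardModifierSet, MortalityModel, NcdHazard

IHD_TO_STROKE_RATIO = 4.0  # IHD incidence is 4x stroke incidence


def onset_hazard(pop: Population, haz: NcdHazard, modifiers: HazardModifierSet,
                 t: float) -> np.ndarray:
    """Per-person-year onset hazard for one NCD across the population:
    baseline age/sex hazard x product of hazard ratios for each conditioning
    state the agent carries x the sensitivity multiplier (in the baseline).
    Zero for agents who already have the condition or the wrong sex."""
    n = pop.n
    ages = pop.ages(t)
    h = haz.hazard(ages, pop.sex[:n])
    for condition, ratio in modifiers.conditions_for(haz.ncd):
        h = np.where(_condition_mask(pop, condition, t), h * ratio, h)
    if haz.ncd in FEMALE_ONLY_NCDS:
        h = np.where(pop.sex[:n] == FEMALE, h, 0.0)
    if haz.ncd in MALE_ONLY_NCDS:
        h = np.where(pop.sex[:n] == MALE, h, 0.0)
    already = pop.has_condition(haz.ncd, t) if haz.ncd != "depression" else np.zeros(n, bool)
    return np.where(pop.alive_mask() & ~already, h, 0.0)


def _condition_mask(pop: Population, condition: str, t: float) -> np.ndarray:
    n = pop.n
    if condition == "hiv":
        return pop.hiv[:n]
    if condition == "hiv_no_art2y":
        art_years = t - pop.art_start[:n]
        long_art = pop.on_art[:n] & (art_years >= 2.0)
        return pop.hiv[:n] & ~long_art
    return pop.has_condition(condition, t)


def sample_ncd_onsets(pop: Population, haz: NcdHazard, modifiers: HazardModifierSet,
                      t: float, dt: float, rng: np.random.Generator) -> np.ndarray:
    """Draw this step's onsets of a chronic NCD or cancer; returns indices."""
    h = onset_hazard(pop, haz, modifiers, t)
    p = -np.expm1(-h * dt)
    hit = np.flatnonzero(rng.random(pop.n) < p)
    if hit.size:
        pop.onset[haz.ncd][hit] = t
    return hit


def sample_cvd_events(pop: Population, stroke_haz: NcdHazard,
                      modifiers: HazardModifierSet, mortality: MortalityModel,
                      t: float, dt: float, rng: np.random.Generator,
                      apply_modifiers_to_ihd: bool = True,
                      mortality_on: bool = True) -> Tuple[np.ndarray, np.ndarray]:
    """First-ever CVD events for one step.

    The modified stroke hazard h sets the total CVD hazard h*(1 + 4); given an
    event, the type is IHD with probability 4/5.  With
    ``apply_modifiers_to_ihd=False`` the comorbidity modifiers scale only the
    stroke component and the IHD component keeps 4x the *baseline* stroke
    hazard.  Acute case fatality applies at the event.  Returns
    (event indices, acute-death indices).
    """
    n = pop.n
    h_stroke = onset_hazard(pop, stroke_haz, modifiers, t)
    no_event = pop.cvd_type[:n] == CVD_NONE
    h_stroke = np.where(no_event, h_stroke, 0.0)
    if apply_modifiers_to_ihd:
        h_ihd = IHD_TO_STROKE_RATIO * h_stroke
    else:
        base = stroke_haz.hazard(pop.ages(t), pop.sex[:n])
        h_ihd = np.where(pop.alive_mask() & no_event, IHD_TO_STROKE_RATIO * base, 0.0)
    h_tot = h_stroke + h_ihd
    p = -np.expm1(-h_tot * dt)
    u = rng.random(n)
    hit = np.flatnonzero(u < p)
    if hit.size == 0:
        return hit, hit
    frac_ihd = np.divide(h_ihd[hit], h_tot[hit], out=np.zeros(hit.size),
                         where=h_tot[hit] > 0)
    is_ihd = rng.random(hit.size) < frac_ihd
    pop.cvd_type[hit] = np.where(is_ihd, CVD_IHD, CVD_STROKE).astype(np.int8)
    pop.cvd_date[hit] = t
    pop.onset["ihd"][hit[is_ihd]] = t
    pop.onset["stroke"][hit[~is_ihd]] = t
    acute = np.array([], dtype=int)
    if mortality_on:
        cf = np.where(is_ihd, mortality.case_fatality.get("ihd", 0.0),
                      mortality.case_fatality.get("stroke", 0.0))
        dead = rng.random(hit.size) < cf
        acute = hit[dead]
        if acute.size:
            pop.kill(acute, t, np.where(is_ihd[dead], "ihd", "stroke"))
    return hit, acute


def depression_step(pop: Population, haz: NcdHazard, modifiers: HazardModifierSet,
                    episode_duration: float, t: float, dt: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Recurrent-depression dynamics: agents not currently in an episode may
    begin one via the (modified) onset hazard; an episode ends after the
    configured duration.  Returns indices of new episodes."""
    n = pop.n
    in_episode = ~np.isnan(pop.dep_end[:n]) & (pop.dep_end[:n] > t)
    h = onset_hazard(pop, haz, modifiers, t)
    h = np.where(in_episode, 0.0, h)
    p = -np.expm1(-h * dt)
    hit = np.flatnonzero(rng.random(n) < p)
    if hit.size:
        pop.onset["depression"][hit] = t
        pop.dep_end[hit] = t + episode_duration
    return hit


def death_hazard(pop: Population, background: np.ndarray, mortality: MortalityModel,
                 hiv_mult: np.ndarray, t: float):
    """Total death hazard and the per-agent attribution factors.

    Returns ``(hazard, factors)`` where ``factors`` is a list of
    (cause, multiplier array); the total hazard is background x hiv multiplier
    x the product of excess RRs of the fatal conditions present.
    """
    n = pop.n
    total = background * hiv_mult
    factors = []
    if np.any(hiv_mult > 1):
        factors.append(("hiv", hiv_mult))
    for cause, rr in mortality.excess_rr.items():
        has = pop.has_condition(cause, t)
        if has.any():
            mult = np.where(has, rr, 1.0)
            total = total * mult
            factors.append((cause, mult))
    return total, factors


def sample_deaths(pop: Population, background: np.ndarray, mortality: MortalityModel,
                  hiv_mult: np.ndarray, t: float, dt: float,
                  rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    """All-cause mortality for one step with cause attribution.

    A dying agent's cause is sampled with probability background/total for
    "background" and, for each condition factor r_c, a share of the excess
    (total - background) proportional to (r_c - 1).
    """
    n = pop.n
    haz, factors = death_hazard(pop, background, mortality, hiv_mult, t)
    haz = np.where(pop.alive_mask(), haz, 0.0)
    p = -np.expm1(-haz * dt)
    dead = np.flatnonzero(rng.random(n) < p)
    if dead.size == 0:
        return dead, np.array([], dtype=object)
    total = haz[dead]
    mu = background[dead]
    causes = np.full(dead.size, "background", dtype=object)
    if factors:
        excess = np.stack([f[1][dead] - 1.0 for f in factors])  # (k, m)
        excess = np.maximum(excess, 0.0)
        s = excess.sum(axis=0)
        p_bg = np.divide(mu, total, out=np.ones_like(mu), where=total > 0)
        u = rng.random(dead.size)
        cond = u >= p_bg  # death attributed to some condition
        with np.errstate(invalid="ignore", divide="ignore"):
            shares = np.where(s > 0, excess / np.where(s > 0, s, 1.0), 0.0)
        cum = np.cumsum(shares, axis=0)
        v = (u - p_bg) / np.where(1 - p_bg > 0, 1 - p_bg, 1.0)
        pick = (v[None, :] < cum).argmax(axis=0)
        names = np.array([f[0] for f in factors], dtype=object)
        causes = np.where(cond & (s > 0), names[pick], causes)
    pop.kill(dead, t, causes)
    return dead, causes
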