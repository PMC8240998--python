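"""Random-effects pooling of study estimates and direct age-standardization.

Two standard epidemiological computations used both on literature inputs and
on model output:

* :func:`pool_random_effects` — DerSimonian-Laird random-effects pooling of
  several study estimates of the same age-band prevalence or incidence.
* :func:`direct_standardize` — direct age-standardization of an age profile
  against the WHO World Standard Population, collapsing the 5-year standard
  bands onto the profile's (possibly irregular) bands with linear pro-rating
  of partial bands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .who_standard import WHO_WORLD_STANDARD, StandardPopulation, _OPEN_BAND_TOP

__all__ = [
    "StudyEstimate",
    "PooledAgeProfile",
    "pool_random_effects",
    "collapse_standard_weights",
    "direct_standardize",
    "read_study_table",
]

_Z = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class StudyEstimate:
    """One study's estimate for one age band.

    ``age_lo``/``age_hi`` delimit a closed-open interval in years; an
    open-ended top band uses ``age_hi=None``.  ``point`` and the confidence
    limits share a scale: a proportion in [0, 1] (internally; tables may print
    percent) or a rate per 100,000 person-years.
    """

    age_lo: float
    age_hi: Optional[float]
    point: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    n: Optional[float] = None
    source_id: str = ""
    scale: str = "proportion"  # proportion | rate_per_100k

    def __post_init__(self):
        if self.point < 0:
            raise ValueError("point estimate must be nonnegative")
        if self.scale == "proportion" and self.point > 1:
            raise ValueError("proportions must lie in [0, 1]")
        if self.ci_low is not None and self.ci_high is not None:
            if not (self.ci_low <= self.point <= self.ci_high):
                raise ValueError("CI must contain the point estimate")

    @property
    def se(self) -> float:
        """Within-study standard error: CI half-width / z when a CI is given,
        otherwise the binomial approximation from n (proportions only)."""
        if self.ci_low is not None and self.ci_high is not None and self.ci_high > self.ci_low:
            return (self.ci_high - self.ci_low) / (2.0 * _Z)
        if self.n is not None and self.scale == "proportion":
            p = min(max(self.point, 1e-12), 1 - 1e-12)
            return math.sqrt(p * (1 - p) / self.n)
        raise ValueError(
            f"study {self.source_id!r}: need a CI or n to derive a within-study variance"
        )


@dataclass
class PooledAgeProfile:
    """An ordered set of band estimates covering ages from ``lower_age_bound``
    upward; bands must be contiguous, non-overlapping and ascending."""

    estimates: Sequence[StudyEstimate]
    scale: str = "proportion"
    lower_age_bound: float = 18.0

    def __post_init__(self):
        if not self.estimates:
            raise ValueError("profile needs at least one band")
        est = sorted(self.estimates, key=lambda e: e.age_lo)
        if est[0].age_lo != self.lower_age_bound:
            raise ValueError(
                f"profile must start at lower_age_bound={self.lower_age_bound}, "
                f"got {est[0].age_lo}"
            )
        for a, b in zip(est[:-1], est[1:]):
            if a.age_hi is None or a.age_hi != b.age_lo:
                raise ValueError(f"bands have a gap or overlap at {a.age_hi}–{b.age_lo}")
        if est[-1].age_hi is not None:
            raise ValueError("top band must be open-ended (age_hi=None)")
        self.estimates = est

    @property
    def bands(self) -> list:
        return [(e.age_lo, e.age_hi) for e in self.estimates]

    @property
    def values(self) -> np.ndarray:
        return np.array([e.point for e in self.estimates], dtype=float)


def pool_random_effects(studies: Sequence[StudyEstimate]) -> StudyEstimate:
    """DerSimonian-Laird random-effects pool of several estimates of the same
    quantity.

    Within-study variances come from each study's CI (half-width / 1.96,
    squared) or from n via the binomial approximation.  The between-study
    variance tau^2 is the moment estimator floored at zero.  A single study is
    returned unchanged.
    """
    studies = list(studies)
    if not studies:
        raise ValueError("cannot pool an empty list of studies")
    scales = {s.scale for s in studies}
    if len(scales) > 1:
        raise ValueError(f"cannot pool mixed scales: {sorted(scales)}")
    if len(studies) == 1:
        return studies[0]

    eff = np.array([s.point for s in studies], dtype=float)
    var = np.array([s.se**2 for s in studies], dtype=float)
    # DerSimonian-Laird: inverse-variance fixed-effect mean, Cochran's Q,
    # moment estimator of tau^2 floored at 0, then random-effects weights
    w = 1.0 / var
    y_fe = float(np.sum(w * eff) / np.sum(w))
    q = float(np.sum(w * (eff - y_fe) ** 2))
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - (len(studies) - 1)) / c) if c > 0 else 0.0
    w_re = 1.0 / (var + tau2)
    pooled = float(np.sum(w_re * eff) / np.sum(w_re))
    se = float(np.sqrt(1.0 / np.sum(w_re)))
    first = studies[0]
    lo, hi = pooled - _Z * se, pooled + _Z * se
    if first.scale == "proportion":
        lo, hi = max(lo, 0.0), min(hi, 1.0)
        pooled = min(max(pooled, 0.0), 1.0)
    return StudyEstimate(
        age_lo=first.age_lo,
        age_hi=first.age_hi,
        point=pooled,
        ci_low=lo,
        ci_high=hi,
        source_id="pooled(" + ",".join(s.source_id for s in studies) + ")",
        scale=first.scale,
    )


def collapse_standard_weights(
    bands: Sequence[tuple],
    lower_age_bound: float,
    std: StandardPopulation = WHO_WORLD_STANDARD,
) -> np.ndarray:
    """Collapse a 5-year standard population onto coarser, contiguous bands.

    Each output weight is the sum of the standard's 5-year weights overlapping
    the band, partial bands pro-rated linearly; the result is renormalized to
    sum to 1 over ages ``lower_age_bound`` and above.
    """
    if not bands:
        raise ValueError("no bands given")
    bands = sorted(bands, key=lambda b: b[0])
    if bands[0][0] != lower_age_bound:
        raise ValueError("first band must start at the lower age bound")
    prev_hi = None
    out = []
    for lo, hi in bands:
        if prev_hi is not None and lo != prev_hi:
            raise ValueError(f"bands have a gap or overlap at {prev_hi}–{lo}")
        top = _OPEN_BAND_TOP if hi is None else hi
        out.append(std.band_overlap_weight(lo, top))
        prev_hi = hi
    w = np.array(out, dtype=float)
    return w / w.sum()


def direct_standardize(
    profile: PooledAgeProfile,
    std: StandardPopulation = WHO_WORLD_STANDARD,
) -> float:
    """Directly age-standardized estimate: the standard-weighted mean of the
    profile's band values, on the profile's own scale."""
    w = collapse_standard_weights(profile.bands, profile.lower_age_bound, std)
    return float(w @ profile.values)


def read_study_table(path) -> list:
    """Read a delimited study table with columns
    source_id, age_lo, age_hi, point, ci_low, ci_high, n, scale
    (age_hi and the optional columns may be empty)."""
    df = pd.read_csv(path)
    out = []
    for rec in df.to_dict("records"):
        def _opt(key):
            v = rec.get(key)
            return None if v is None or (isinstance(v, float) and math.isnan(v)) else v
        out.append(
            StudyEstimate(
                age_lo=float(rec["age_lo"]),
                age_hi=_opt("age_hi"),
                point=float(rec["point"]),
                ci_low=_opt("ci_low"),
                ci_high=_opt("ci_high"),
                n=_opt("n"),
                source_id=str(rec.get("source_id", "")),
                scale=str(rec.get("scale", "proportion")),
            )
        )
    return out
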