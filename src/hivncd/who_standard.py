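"""WHO World Standard Population (2000-2025 revision).

The direct method expresses an age-standardized prevalence or incidence as a
weighted mean of age-band-specific values, with weights taken from a fixed
reference age distribution so that estimates from populations with different
age structures are comparable.  The reference used throughout this package is
the WHO World Standard Population in 5-year bands up to 85+, expressed as
percentages summing to 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# 5-year band lower edges 0,5,...,85 (last band open-ended).
_WHO_EDGES = tuple(range(0, 90, 5))

# Weights (percent of standard population) for bands 0-4 ... 85+.
_WHO_WEIGHTS = (
    8.86, 8.69, 8.60, 8.47, 8.22, 7.93, 7.61, 7.15, 6.59,
    6.04, 5.37, 4.55, 3.72, 2.96, 2.21, 1.52, 0.91, 0.63,
)

# Nominal upper age used when pro-rating the open 85+ band; any value beyond
# the oldest simulated age gives identical results for bands closed below 85.
_OPEN_BAND_TOP = 120.0


@dataclass(frozen=True)
class StandardPopulation:
    """A standard age distribution in 5-year bands.

    ``edges[i]`` is the lower age of band i; the last band is open-ended.
    All weights must be positive.
    """

    edges: tuple = _WHO_EDGES
    weights: tuple = _WHO_WEIGHTS

    def __post_init__(self):
        if len(self.edges) != len(self.weights):
            raise ValueError("edges and weights must have equal length")
        if any(w <= 0 for w in self.weights):
            raise ValueError("standard-population weights must be positive")

    def band_overlap_weight(self, lo: float, hi: float) -> float:
        """Sum of standard weights overlapping [lo, hi), pro-rating partial
        5-year bands linearly (e.g. ages 18-19 contribute 2/5 of the 15-19
        weight)."""
        total = 0.0
        for i, e in enumerate(self.edges):
            e2 = self.edges[i + 1] if i + 1 < len(self.edges) else _OPEN_BAND_TOP
            overlap = max(0.0, min(hi, e2) - max(lo, e))
            total += self.weights[i] * overlap / (e2 - e)
        return total


WHO_WORLD_STANDARD = StandardPopulation()
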