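"""Run configuration for the microsimulation."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, Optional, Sequence

import yaml

# Chronic conditions with a single permanent onset.
CHRONIC_NCDS = ("hypertension", "high_cholesterol", "diabetes", "ckd")

# Non-cervical cancers (cervical cancer arises only through the HPV/CIN
# natural-history pathway).
CANCERS = (
    "breast_cancer", "colorectal_cancer", "leukemia", "liver_cancer",
    "esophageal_cancer", "prostate_cancer", "stomach_cancer", "other_cancer",
)

FEMALE_ONLY_NCDS = ("breast_cancer", "cervical_cancer")
MALE_ONLY_NCDS = ("prostate_cancer",)

# Conditions counted toward the ">=1 NCD" multimorbidity definition among
# adults: hypertension, high total cholesterol, diabetes, depression (episode
# in the last 12 months), CVD (ever), CKD, and any cancer.
MULTIMORBIDITY_SET = CHRONIC_NCDS + CANCERS + ("depression", "cvd", "cervical_cancer")


@dataclass
class SimulationConfig:
    """Knobs of one simulation run.

    ``time_step`` is in years (monthly by default).  ``n_agents`` is the
    number of simulated individuals at ``start_year``; each represents
    ``scale_factor`` real persons when counts are reported.  ``n_runs``
    replicate runs (distinct sub-seeds) are averaged by the reporting layer.
    ``sensitivity`` maps an NCD id to a baseline-incidence multiplier for
    +/-10% style sensitivity analyses.
    """

    seed: int = 0
    start_year: float = 1950.0
    end_year: float = 2035.0
    time_step: float = 1.0 / 12.0
    n_agents: int = 50_000
    scale_factor: float = 120.0
    n_runs: int = 100
    # module toggles
    enable_fertility: bool = True
    enable_mortality: bool = True
    enable_hiv: bool = True
    enable_cervical: bool = True
    enable_depression: bool = True
    enable_cvd: bool = True
    enabled_ncds: Sequence[str] = CHRONIC_NCDS + CANCERS
    # stroke-hazard comorbidity modifiers also scale the linked IHD hazard
    apply_stroke_modifiers_to_ihd: bool = True
    sensitivity: Dict[str, float] = field(default_factory=dict)
    log_events: bool = False
    snapshot_max_age: int = 100

    def __post_init__(self):
        if not (0 < self.time_step <= 1):
            raise ValueError("time_step must be in (0, 1]")
        if self.n_agents <= 0:
            raise ValueError("n_agents must be positive")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.start_year >= self.end_year:
            raise ValueError("start_year must precede end_year")

    def to_yaml(self, path):
        with open(path, "w") as fh:
            d = asdict(self)
            d["enabled_ncds"] = list(self.enabled_ncds)
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "enabled_ncds" in d:
            d["enabled_ncds"] = tuple(d["enabled_ncds"])
        return cls(**d)
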