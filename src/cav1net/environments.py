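"""Experimental environments: stimulus categories and level sampling.

The three tissue conditions (wild type, Disease A, Disease B) assign each of
the 29 extracellular stimuli a qualitative activity category.  Disease A is
an immunosuppressive milieu (most cytokine stimuli raised to High); Disease B
is the same but with IL-10 swept over its full 0-100 range, modeling varying
degrees of IL-10-controlled immunosuppression.

Categories map to activity-level subranges of [0, 100].  Two mappings are
provided: ``randomized`` (default) draws each simulation's level uniformly
from the category subrange, reconciling the categorical table with
per-simulation random levels; ``fixed`` pins each category to a single
representative level for reproducible single-variable sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional

import numpy as np

__all__ = [
    "EnvironmentSpec",
    "CONDITIONS",
    "CATEGORIES",
    "CATEGORY_RANGES",
    "FIXED_LEVELS",
    "TABLE1",
    "build_environment",
    "sample_environment",
    "fixed_environment",
]

CONDITIONS = ("Tissue_WT", "Tissue_DiseaseA", "Tissue_DiseaseB")

CATEGORIES = ("Zero", "Low", "Med", "MedHigh", "High", "FullRange")

#: category -> (low, high) subrange of [0, 100] for randomized sampling
CATEGORY_RANGES: Dict[str, tuple] = {
    "Zero": (0.0, 0.0),
    "Low": (0.0, 100.0 / 3.0),
    "Med": (100.0 / 3.0, 200.0 / 3.0),
    "MedHigh": (50.0, 250.0 / 3.0),
    "High": (200.0 / 3.0, 100.0),
    "FullRange": (0.0, 100.0),
}

#: category -> representative level for fixed mode (FullRange stays random:
#: it is defined as "anywhere in 0-100", not a set point)
FIXED_LEVELS: Dict[str, Optional[float]] = {
    "Zero": 0.0,
    "Low": 25.0,
    "Med": 50.0,
    "MedHigh": 75.0,
    "High": 90.0,
    "FullRange": None,
}

#: stimulus -> (Tissue_WT, Tissue_DiseaseA, Tissue_DiseaseB) categories
TABLE1: Dict[str, tuple] = {
    "Alpha_13L": ("Med", "High", "High"),
    "GalphaS_L": ("Med", "High", "High"),
    "APC": ("Med", "High", "High"),
    "CGC": ("Med", "MedHigh", "MedHigh"),
    "ECM": ("High", "High", "High"),
    "GP130": ("Zero", "Zero", "Zero"),
    "IFNB": ("Med", "Med", "Med"),
    "IFNG": ("Med", "Med", "Med"),
    "IFNGR1": ("Med", "Med", "Med"),
    "IFNGR2": ("Med", "Med", "Med"),
    "IL10": ("Med", "High", "FullRange"),
    "IL10RA": ("Med", "High", "High"),
    "IL10RB": ("Med", "Med", "Med"),
    "IL12": ("Med", "High", "High"),
    "IL15": ("Med", "High", "High"),
    "IL15RA": ("Med", "High", "High"),
    "IL18": ("Med", "High", "High"),
    "IL21": ("Med", "High", "High"),
    "IL22": ("Med", "High", "High"),
    "IL23": ("Med", "High", "High"),
    "IL27": ("Med", "High", "High"),
    "IL27RA": ("Med", "Med", "Med"),
    "IL2": ("Med", "High", "High"),
    "IL2RB": ("Med", "High", "High"),
    "IL4": ("Low", "Low", "Low"),
    "IL6": ("Low", "Low", "Low"),
    "IL6RA": ("Low", "Low", "Low"),
    "IL9": ("Low", "Low", "Low"),
    "TGFB": ("Low", "Low", "Low"),
}


@dataclass(frozen=True)
class EnvironmentSpec:
    """One condition's stimulus -> category assignment."""

    condition_name: str
    categories: Mapping[str, str]

    def __post_init__(self):
        object.__setattr__(self, "categories", dict(self.categories))
        for stim, cat in self.categories.items():
            if cat not in CATEGORIES:
                raise ValueError(f"unknown category {cat!r} for stimulus {stim!r}")


def build_environment(condition_name: str) -> EnvironmentSpec:
    """Environment spec for one of the three tissue conditions."""
    if condition_name not in CONDITIONS:
        raise ValueError(
            f"unknown condition {condition_name!r}; valid conditions: "
            + ", ".join(CONDITIONS))
    col = CONDITIONS.index(condition_name)
    return EnvironmentSpec(condition_name,
                           {stim: cats[col] for stim, cats in TABLE1.items()})


def sample_environment(spec: EnvironmentSpec,
                       rng: np.random.Generator,
                       mode: str = "randomized") -> Dict[str, float]:
    """Draw one simulation's activity levels from the spec's categories.

    ``randomized`` draws uniformly from each category's subrange; ``fixed``
    uses the representative level (FullRange is drawn uniformly in both
    modes).  Returns stimulus -> level in [0, 100].
    """
    if mode not in ("randomized", "fixed"):
        raise ValueError(f"unknown level mode {mode!r}")
    levels: Dict[str, float] = {}
    for stim, cat in spec.categories.items():
        if mode == "fixed" and FIXED_LEVELS[cat] is not None:
            levels[stim] = FIXED_LEVELS[cat]
            continue
        lo, hi = CATEGORY_RANGES[cat]
        levels[stim] = lo if lo == hi else float(rng.uniform(lo, hi))
    return levels


def fixed_environment(condition_name: str = "Tissue_WT") -> Dict[str, float]:
    """Deterministic levels for a condition (fixed mode, no FullRange draws).

    FullRange categories are pinned at 50 here; this helper exists for
    backgrounds of single-variable sweeps, which must be draw-free.
    """
    spec = build_environment(condition_name)
    levels = {}
    for stim, cat in spec.categories.items():
        fixed = FIXED_LEVELS[cat]
        levels[stim] = 50.0 if fixed is None else fixed
    return levels
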