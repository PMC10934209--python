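"""Seeded synthetic data: censored concentration tables with plant-part
structure, and exposure-factor populations.

True per-cell levels are lognormal — median ``location x part_multiplier``
with geometric sd ``spread`` — and are emitted as non-detects when they fall
below the per-analyte LOD, mimicking instrumental left-censoring.  The
uncensored truth is returned alongside so oracle tests can compare.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .analytes import ABBREVIATIONS, BY_ABBREVIATION, DEFAULT_LODS
from .exposure import ExposureFactors, FACTOR_KEYS
from .table import ConcentrationTable, PART_CLASSES

#: Qualitative part ordering: roots/stems accumulate most, fruits least.
DEFAULT_PART_MULTIPLIERS: Mapping[str, float] = {
    "root_stem": 3.0,
    "flower": 2.0,
    "fruit_seed": 1.0,
}


@dataclass
class ContaminationProfile:
    """Statistical profile of true contamination levels.

    location : per-analyte median of the true level, µg/kg (> 0)
    spread : per-analyte geometric sd (> 1)
    part_multiplier : location scaling per plant-part class
    lod : per-analyte detection limit, µg/kg (>= 0); truth below it -> nd
    noise_rsd : optional multiplicative measurement noise on detected
        values (relative sd); 0 disables it (the default)
    """

    location: Mapping[str, float]
    spread: Mapping[str, float]
    part_multiplier: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PART_MULTIPLIERS)
    )
    lod: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_LODS))
    noise_rsd: float = 0.0

    def __post_init__(self) -> None:
        for abbr, loc in self.location.items():
            if not loc > 0:
                raise ValueError(f"location[{abbr!r}] must be > 0")
        for abbr, s in self.spread.items():
            if not s > 1:
                raise ValueError(f"spread[{abbr!r}] must be > 1 (geometric sd)")
        for abbr, v in self.lod.items():
            if v < 0:
                raise ValueError(f"lod[{abbr!r}] must be >= 0")
        if self.noise_rsd < 0:
            raise ValueError("noise_rsd must be >= 0")

    @property
    def analytes(self) -> list[str]:
        return list(self.location)

    def censoring_probability(self, analyte: str, part: str) -> float:
        """Closed-form P(truth < lod) = Phi((ln lod - ln median)/ln spread)."""
        lod = self.lod[analyte]
        if lod <= 0:
            return 0.0
        median = self.location[analyte] * self.part_multiplier[part]
        z = (np.log(lod) - np.log(median)) / np.log(self.spread[analyte])
        return float(stats.norm.cdf(z))


def default_profile() -> ContaminationProfile:
    """A profile calibrated to the bundled survey's qualitative structure:
    low-ring analytes well above their LODs, high-ring analytes mostly
    censored."""
    ring_scale = {2: 6.0, 3: 6.0, 4: 2.0, 5: 0.5, 6: 0.2}
    location = {
        abbr: ring_scale[BY_ABBREVIATION[abbr].ring_count] * DEFAULT_LODS[abbr]
        for abbr in ABBREVIATIONS
    }
    spread = {abbr: 2.5 for abbr in ABBREVIATIONS}
    return ContaminationProfile(location=location, spread=spread)


def generate_concentration_table(
    profile: ContaminationProfile,
    herbs: Sequence[tuple[str, str]],
    seed: int | None = None,
) -> tuple[ConcentrationTable, pd.DataFrame]:
    """Draw a censored table plus its uncensored truth.

    ``herbs`` is a sequence of (herb_id, part_class) pairs.  Returns
    (table, truth) where ``truth`` holds the uncensored draws, µg/kg.
    """
    if not herbs:
        raise ValueError("herb list must be non-empty")
    if seed is None:
        raise ValueError("a seed is required for reproducibility")
    for herb, part in herbs:
        if part not in PART_CLASSES:
            raise ValueError(f"herb {herb!r}: part {part!r} not in {PART_CLASSES}")

    rng = np.random.default_rng(seed)
    analytes = profile.analytes
    herb_ids = [h for h, _ in herbs]
    parts = dict(herbs)
    if len(set(herb_ids)) != len(herb_ids):
        raise ValueError("duplicate herb ids in herb list")

    medians = np.array(
        [
            [profile.location[a] * profile.part_multiplier[parts[h]] for a in analytes]
            for h in herb_ids
        ]
    )
    sigmas = np.array([np.log(profile.spread[a]) for a in analytes])
    truth = np.exp(np.log(medians) + rng.standard_normal(medians.shape) * sigmas)
    observed = truth.copy()
    if profile.noise_rsd > 0:
        observed = observed * (
            1.0 + rng.standard_normal(observed.shape) * profile.noise_rsd
        )
        observed = np.clip(observed, 0.0, None)
    lods = np.array([profile.lod[a] for a in analytes])
    detected = truth >= lods[None, :]

    values = pd.DataFrame(
        np.where(detected, observed, np.nan), index=herb_ids, columns=analytes
    )
    table = ConcentrationTable(
        values=values,
        detected=pd.DataFrame(detected, index=herb_ids, columns=analytes),
        parts=parts,
        lods=dict(profile.lod),
    )
    truth_df = pd.DataFrame(truth, index=herb_ids, columns=analytes)
    return table, truth_df


def generate_exposure_population(
    factors: Sequence[ExposureFactors],
    n: int,
    seed: int | None = None,
) -> dict[str, pd.DataFrame]:
    """n joint draws of the six exposure factors per age group.

    Point factors give constant columns; truncation on any spec is
    respected.  Returns {group label: n x 6 frame}.
    """
    if n <= 0:
        raise ValueError("n must be >= 1")
    if seed is None:
        raise ValueError("a seed is required for reproducibility")
    rng = np.random.default_rng(seed)
    out: dict[str, pd.DataFrame] = {}
    for group in factors:
        cols = {key: group.spec(key).sample(n, rng) for key in FACTOR_KEYS}
        out[group.group] = pd.DataFrame(cols, columns=list(FACTOR_KEYS))
    return out
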