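"""Diagnostic isomer-ratio source apportionment.

Three ratios — Flt/(Flt+Pyr), Ant/(Ant+Phe), BaA/(BaA+Chry) — are banded
against conventional literature cut points to label the likely PAH origin
(petrogenic vs. combustion) per herb, and exported as crossplot coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .table import ConcentrationTable

#: Conventional literature cut points.  Intervals are lower-closed: the
#: middle band includes its lower bound (e.g. flt = 0.4 -> fossil_fuel).
DEFAULT_THRESHOLDS: Mapping[str, Mapping[str, float]] = {
    "flt": {"petroleum_below": 0.4, "biomass_coal_above": 0.5},
    "ant": {"petroleum_below": 0.1},
    "baa": {"petroleum_below": 0.2, "combustion_above": 0.35},
}

_RATIO_PAIRS = {"flt": ("Flt", "Pyr"), "ant": ("Ant", "Phe"), "baa": ("BaA", "Chry")}

INDETERMINATE = "indeterminate"


@dataclass
class RatioProfile:
    """Per-herb diagnostic ratios and their source labels.

    A ratio is ``None`` (undefined) when the imputed denominator pair sums
    to zero — e.g. both members non-detected under the zero policy.
    """

    herb: str
    flt_ratio: float | None
    ant_ratio: float | None
    baa_ratio: float | None
    labels: dict[str, str] = field(default_factory=dict)
    composite: str = ""

    def ratios(self) -> dict[str, float | None]:
        return {"flt": self.flt_ratio, "ant": self.ant_ratio, "baa": self.baa_ratio}


def diagnostic_ratios(
    table: ConcentrationTable, herb: str, nd_policy: str = "zero"
) -> RatioProfile:
    """Compute the three isomer ratios for one herb.

    Each ratio is num/(num+den) on policy-imputed concentrations; a zero
    denominator yields an undefined ratio, never 0/0.
    """
    row = table.concentrations(herb, nd_policy)
    out: dict[str, float | None] = {}
    for key, (num, den) in _RATIO_PAIRS.items():
        total = float(row[num]) + float(row[den])
        out[key] = float(row[num]) / total if total > 0 else None
    return RatioProfile(
        herb=herb, flt_ratio=out["flt"], ant_ratio=out["ant"], baa_ratio=out["baa"]
    )


def classify_source(
    profile: RatioProfile,
    thresholds: Mapping[str, Mapping[str, float]] = DEFAULT_THRESHOLDS,
) -> dict[str, str]:
    """Band each ratio into a source label and set the composite description.

    flt: <0.4 petroleum | [0.4, 0.5] fossil_fuel_combustion | >0.5
    biomass_coal_combustion.  ant: <0.1 petroleum | >=0.1 combustion.
    baa: <0.2 petroleum | [0.2, 0.35] mixed | >0.35 combustion.
    Undefined ratios are labelled ``indeterminate``.
    """
    flt_t, ant_t, baa_t = thresholds["flt"], thresholds["ant"], thresholds["baa"]
    if not flt_t["petroleum_below"] < flt_t["biomass_coal_above"]:
        raise ValueError("flt thresholds must be increasing")
    if not baa_t["petroleum_below"] < baa_t["combustion_above"]:
        raise ValueError("baa thresholds must be increasing")

    labels: dict[str, str] = {}
    r = profile.flt_ratio
    if r is None:
        labels["flt"] = INDETERMINATE
    elif r < flt_t["petroleum_below"]:
        labels["flt"] = "petroleum"
    elif r <= flt_t["biomass_coal_above"]:
        labels["flt"] = "fossil_fuel_combustion"
    else:
        labels["flt"] = "biomass_coal_combustion"

    r = profile.ant_ratio
    if r is None:
        labels["ant"] = INDETERMINATE
    else:
        labels["ant"] = "petroleum" if r < ant_t["petroleum_below"] else "combustion"

    r = profile.baa_ratio
    if r is None:
        labels["baa"] = INDETERMINATE
    elif r < baa_t["petroleum_below"]:
        labels["baa"] = "petroleum"
    elif r <= baa_t["combustion_above"]:
        labels["baa"] = "mixed"
    else:
        labels["baa"] = "combustion"

    defined = [v for v in labels.values() if v != INDETERMINATE]
    profile.labels = labels
    profile.composite = " + ".join(defined) if defined else INDETERMINATE
    return labels


def crossplot_coordinates(profiles: Sequence[RatioProfile]) -> pd.DataFrame:
    """Long-format crossplot table: x = flt ratio, y = baa or ant ratio.

    Points with an undefined coordinate are omitted.  Columns:
    herb, panel ('baa' or 'ant'), x, y.
    """
    rows = []
    for p in profiles:
        if p.flt_ratio is None:
            continue
        for panel, y in (("baa", p.baa_ratio), ("ant", p.ant_ratio)):
            if y is None:
                continue
            rows.append({"herb": p.herb, "panel": panel, "x": p.flt_ratio, "y": y})
    return pd.DataFrame(rows, columns=["herb", "panel", "x", "y"])


def combustion_dominance(ring_shares: Mapping[str, float] | None) -> str | None:
    """Convenience heuristic from the ring-class shares: 2-3-ring dominance
    suggests petrogenic origin, >=4-ring dominance suggests combustion."""
    if ring_shares is None:
        return None
    low = ring_shares.get("2-3", math.nan)
    high = ring_shares.get("4", 0.0) + ring_shares.get("5-6", 0.0)
    if math.isnan(low):
        return None
    return "petrogenic_dominant" if low > high else "combustion_dominant"


def apportion_sources(
    table: ConcentrationTable,
    nd_policy: str = "zero",
    thresholds: Mapping[str, Mapping[str, float]] = DEFAULT_THRESHOLDS,
) -> list[RatioProfile]:
    """Ratios + classification for every herb in the table."""
    profiles = []
    for herb in table.herbs:
        profile = diagnostic_ratios(table, herb, nd_policy)
        classify_source(profile, thresholds)
        profiles.append(profile)
    return profiles
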