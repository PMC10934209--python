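"""Deterministic risk scoring: BaP toxic-equivalent concentration and the
incremental lifetime cancer risk (ILCR) intake model with risk banding."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .analytes import TefScheme, default_tef_scheme
from .exposure import ExposureFactors
from .table import ConcentrationTable

#: Risk bands: <1e-6 negligible, [1e-6, 1e-4] potential, >1e-4 unacceptable.
NEGLIGIBLE_BELOW = 1e-6
UNACCEPTABLE_ABOVE = 1e-4

BANDS = ("negligible", "potential", "unacceptable")


@dataclass
class TeqResult:
    """BaP-equivalent concentration of a mixture.

    ``teq`` = sum(C_i * TEF_i) / scale_divisor; ``contributions`` retain the
    per-analyte addends (same unit as teq).  With C_i in µg/kg and the
    default divisor of 1000 the result is in mg/kg BaP-equivalents —
    ``unit_note`` records the divisor actually applied.
    """

    herb: str
    teq: float
    contributions: dict[str, float]
    unit_note: str


@dataclass
class IlcrResult:
    herb: str
    group: str
    ilcr: float
    band: str


def teq_bap(
    concentrations: pd.Series,
    tefs: TefScheme | None = None,
) -> TeqResult:
    """TEF-weighted sum of already-imputed concentrations, scaled.

    ``concentrations`` is a per-analyte series (non-detects imputed upstream
    by the caller's nd policy).  Every analyte must be in the TEF scheme.
    """
    tefs = tefs if tefs is not None else default_tef_scheme()
    missing = [a for a in concentrations.index if a not in tefs.tefs]
    if missing:
        raise KeyError(f"analyte(s) missing from TEF scheme: {missing}")
    contributions = {
        abbr: float(concentrations[abbr]) * tefs[abbr] / tefs.scale_divisor
        for abbr in concentrations.index
    }
    return TeqResult(
        herb=str(concentrations.name) if concentrations.name else "",
        teq=float(sum(contributions.values())),
        contributions=contributions,
        unit_note=f"BaP-equivalents: (µg/kg x TEF) / {tefs.scale_divisor:g}",
    )


def teq_for_herb(
    table: ConcentrationTable,
    herb: str,
    tefs: TefScheme | None = None,
    nd_policy: str = "zero",
) -> TeqResult:
    """TEQ of one herb's row under an explicit non-detect policy."""
    result = teq_bap(table.concentrations(herb, nd_policy), tefs)
    result.herb = herb
    return result


def band(ilcr_value: float) -> str:
    """Risk band of an ILCR value; boundaries 1e-6 and 1e-4 are 'potential'."""
    if not ilcr_value >= 0:
        raise ValueError(f"ILCR must be finite and >= 0, got {ilcr_value!r}")
    if ilcr_value < NEGLIGIBLE_BELOW:
        return "negligible"
    if ilcr_value <= UNACCEPTABLE_ABOVE:
        return "potential"
    return "unacceptable"


def ilcr(teq: TeqResult, factors: ExposureFactors) -> IlcrResult:
    """ILCR = TEQ x DR x CSF x EF x ED / (BW x AT) with point factors."""
    f = factors.point_values()
    value = teq.teq * f["dr"] * f["csf"] * f["ef"] * f["ed"] / (f["bw"] * f["at"])
    return IlcrResult(herb=teq.herb, group=factors.group, ilcr=value, band=band(value))


def risk_table(
    table: ConcentrationTable,
    groups: list[ExposureFactors],
    tefs: TefScheme | None = None,
    nd_policy: str = "zero",
) -> pd.DataFrame:
    """Per-herb x per-group deterministic ILCR table with bands."""
    rows = []
    for herb in table.herbs:
        teq = teq_for_herb(table, herb, tefs, nd_policy)
        for factors in groups:
            res = ilcr(teq, factors)
            rows.append(
                {
                    "herb": herb,
                    "group": factors.group,
                    "teq": teq.teq,
                    "ilcr": res.ilcr,
                    "band": res.band,
                }
            )
    return pd.DataFrame(rows, columns=["herb", "group", "teq", "ilcr", "band"])
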