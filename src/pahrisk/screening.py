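"""Contamination screening: detection rates, total burdens, per-analyte
extremes, ring-class distribution, regulatory flags and the cross-herb
chi-squared test on detection counts."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .analytes import BY_ABBREVIATION, PAH4, RING_CLASSES, TefScheme, default_tef_scheme
from .table import ConcentrationTable

#: Regulatory limits, µg/kg: BaP (cereal-type foods) and the PAH4 marker sum.
DEFAULT_LIMITS: Mapping[str, float] = {"bap_limit": 5.0, "pah4_limit": 35.0}


def detection_rate(table: ConcentrationTable, herb: str) -> float:
    """Fraction of the panel's analytes detected for ``herb``."""
    table.require_herb(herb)
    flags = table.detected.loc[herb]
    return float(flags.sum()) / float(len(flags))


def total_pahs(table: ConcentrationTable, herb: str, nd_policy: str = "zero") -> float:
    """Sum of concentrations (µg/kg) over the panel with non-detects imputed
    per ``nd_policy`` (``zero``, ``half_lod`` or ``lod``)."""
    return float(table.concentrations(herb, nd_policy).sum())


def analyte_extremes(
    table: ConcentrationTable, analyte: str
) -> tuple[float | None, float | None, int]:
    """(min, max, n_detected) over detected cells of one analyte column.

    Extremes are ``None`` when the analyte was never detected.
    """
    if analyte not in table.values.columns:
        raise KeyError(f"unknown analyte: {analyte!r}")
    col = table.values[analyte]
    det = table.detected[analyte].astype(bool)
    n = int(det.sum())
    if n == 0:
        return None, None, 0
    vals = col[det]
    return float(vals.min()), float(vals.max()), n


def ring_class_shares(
    table: ConcentrationTable,
    herb: str,
    basis: str = "concentration",
    tefs: TefScheme | None = None,
    nd_policy: str = "zero",
) -> dict[str, float] | None:
    """Shares of the total burden over ring classes {2-3, 4, 5-6}.

    ``basis`` is ``concentration`` or ``teq`` (concentration x TEF).
    Returns ``None`` when the herb's total is zero (shares undefined).
    """
    if basis not in ("concentration", "teq"):
        raise ValueError("basis must be 'concentration' or 'teq'")
    row = table.concentrations(herb, nd_policy)
    if basis == "teq":
        tefs = tefs if tefs is not None else default_tef_scheme()
        row = pd.Series(
            {abbr: row[abbr] * tefs[abbr] for abbr in row.index}, dtype=float
        )
    total = float(row.sum())
    if total == 0.0:
        return None
    shares = {}
    for cls, rings in RING_CLASSES.items():
        members = [a for a in row.index if BY_ABBREVIATION[a].ring_count in rings]
        shares[cls] = float(row[members].sum()) / total
    return shares


def regulatory_flags(
    table: ConcentrationTable,
    herb: str,
    limits: Mapping[str, float] = DEFAULT_LIMITS,
) -> dict[str, bool]:
    """Strict-inequality exceedance flags against the BaP and PAH4 limits."""
    table.require_herb(herb)
    bap_limit = float(limits["bap_limit"])
    pah4_limit = float(limits["pah4_limit"])
    bap_detected = bool(table.detected.loc[herb, "BaP"])
    bap_value = float(table.values.loc[herb, "BaP"]) if bap_detected else 0.0
    row = table.concentrations(herb, "zero")
    pah4_sum = float(row[list(PAH4)].sum())
    return {
        "bap_exceeds": bap_detected and bap_value > bap_limit,
        "pah4_exceeds": pah4_sum > pah4_limit,
    }


def detection_chi2(table: ConcentrationTable) -> tuple[float, int, float]:
    """Pearson chi-squared over the herbs x {detected, not-detected} counts.

    Returns (statistic, df, p) with df = #herbs - 1; no continuity
    correction, matching the textbook statistic.
    """
    if len(table.herbs) < 2:
        raise ValueError("chi-squared test needs at least 2 herbs")
    n_analytes = len(table.analytes)
    if n_analytes == 0:
        raise ValueError("table has no analyte columns")
    detected = table.detected.sum(axis=1).to_numpy(dtype=float)
    counts = np.column_stack([detected, n_analytes - detected])
    if counts.sum(axis=1).min() == 0:
        raise ValueError("a herb with zero total analytes is not testable")
    if np.allclose(counts[:, 0], counts[0, 0]):
        return 0.0, len(table.herbs) - 1, 1.0
    stat, p, df, _ = stats.chi2_contingency(counts, correction=False)
    return float(stat), int(df), float(p)


@dataclass
class ScreeningReport:
    """Everything the screening stage produces, keyed by herb."""

    detection_rates: dict[str, float]
    totals: dict[str, float]
    extremes: dict[str, tuple[float | None, float | None, int]]
    ring_shares_concentration: dict[str, dict[str, float] | None]
    ring_shares_teq: dict[str, dict[str, float] | None]
    flags: dict[str, dict[str, bool]]
    chi2: tuple[float, int, float]
    nd_policy: str = "zero"
    limits: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_LIMITS))

    def to_frame(self) -> pd.DataFrame:
        """Per-herb summary as a tidy frame (one row per herb)."""
        rows = []
        for herb in self.detection_rates:
            shares_c = self.ring_shares_concentration[herb] or {}
            shares_t = self.ring_shares_teq[herb] or {}
            rows.append(
                {
                    "herb": herb,
                    "detection_rate": self.detection_rates[herb],
                    "total_pahs": self.totals[herb],
                    **{f"share_{k}_conc": shares_c.get(k, math.nan) for k in RING_CLASSES},
                    **{f"share_{k}_teq": shares_t.get(k, math.nan) for k in RING_CLASSES},
                    **self.flags[herb],
                }
            )
        return pd.DataFrame(rows).set_index("herb")


def screen_table(
    table: ConcentrationTable,
    nd_policy: str = "zero",
    tefs: TefScheme | None = None,
    limits: Mapping[str, float] = DEFAULT_LIMITS,
) -> ScreeningReport:
    """Run the full screening stage over a table."""
    tefs = tefs if tefs is not None else default_tef_scheme()
    return ScreeningReport(
        detection_rates={h: detection_rate(table, h) for h in table.herbs},
        totals={h: total_pahs(table, h, nd_policy) for h in table.herbs},
        extremes={a: analyte_extremes(table, a) for a in table.analytes},
        ring_shares_concentration={
            h: ring_class_shares(table, h, "concentration", tefs, nd_policy)
            for h in table.herbs
        },
        ring_shares_teq={
            h: ring_class_shares(table, h, "teq", tefs, nd_policy)
            for h in table.herbs
        },
        flags={h: regulatory_flags(table, h, limits) for h in table.herbs},
        chi2=detection_chi2(table),
        nd_policy=nd_policy,
        limits=dict(limits),
    )
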