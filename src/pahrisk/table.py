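"""Censored herb x analyte concentration tables.

Non-detects ("nd" cells) are first-class: a non-detect stores *no* numeric
value — every downstream computation chooses an explicit imputation policy
(``zero``, ``half_lod`` or ``lod``).  Stored concentrations are µg/kg.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .analytes import ABBREVIATIONS, DEFAULT_LODS

PART_CLASSES = ("root_stem", "flower", "fruit_seed")
ND_POLICIES = ("zero", "half_lod", "lod")


@dataclass
class ConcentrationTable:
    """Herb x analyte matrix with detection flags.

    ``values`` holds NaN wherever ``detected`` is False; detected cells are
    finite and non-negative.  ``parts`` maps each herb to its plant-part
    class (one of ``root_stem``, ``flower``, ``fruit_seed``).
    """

    values: pd.DataFrame
    detected: pd.DataFrame
    parts: Mapping[str, str]
    rsd: pd.DataFrame | None = None
    lods: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_LODS))

    def __post_init__(self) -> None:
        if list(self.values.index) != list(self.detected.index) or list(
            self.values.columns
        ) != list(self.detected.columns):
            raise ValueError("values and detected must share index and columns")
        unknown = [c for c in self.values.columns if c not in ABBREVIATIONS]
        if unknown:
            raise ValueError(f"unknown analyte column(s): {unknown}")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate herb id(s): {dupes}")
        for herb in self.values.index:
            if herb not in self.parts:
                raise ValueError(f"missing plant-part class for herb {herb!r}")
            if self.parts[herb] not in PART_CLASSES:
                raise ValueError(
                    f"herb {herb!r}: part {self.parts[herb]!r} not in {PART_CLASSES}"
                )
        det = self.detected.to_numpy(dtype=bool)
        vals = self.values.to_numpy(dtype=float)
        bad = det & ~(np.isfinite(vals) & (vals >= 0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                "detected cell must be finite and >= 0 at "
                f"(herb={self.values.index[i]!r}, analyte={self.values.columns[j]!r})"
            )

    @property
    def herbs(self) -> list[str]:
        return list(self.values.index)

    @property
    def analytes(self) -> list[str]:
        return list(self.values.columns)

    def require_herb(self, herb: str) -> None:
        if herb not in self.values.index:
            raise KeyError(f"unknown herb: {herb!r}")

    def concentrations(self, herb: str, nd_policy: str = "zero") -> pd.Series:
        """Row of imputed concentrations for ``herb`` under a non-detect policy."""
        self.require_herb(herb)
        if nd_policy not in ND_POLICIES:
            raise ValueError(f"nd_policy must be one of {ND_POLICIES}")
        row = self.values.loc[herb].astype(float).copy()
        nd = ~self.detected.loc[herb].astype(bool)
        if nd_policy == "zero":
            row[nd] = 0.0
        else:
            missing = [a for a in self.analytes if a not in self.lods]
            if missing:
                raise ValueError(
                    f"nd_policy {nd_policy!r} needs LODs; missing for {missing}"
                )
            scale = 0.5 if nd_policy == "half_lod" else 1.0
            for abbr in row.index[nd]:
                row[abbr] = scale * self.lods[abbr]
        return row

    def to_csv(self, path: str, nd_token: str = "nd") -> None:
        """Write in the canonical dialect: header ``herb,part,<analytes>``,
        non-detects as ``nd_token``, floats at shortest round-trip precision.
        """
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["herb", "part", *self.analytes])
            for herb in self.herbs:
                cells = []
                for abbr in self.analytes:
                    if self.detected.loc[herb, abbr]:
                        cells.append(repr(float(self.values.loc[herb, abbr])))
                    else:
                        cells.append(nd_token)
                writer.writerow([herb, self.parts[herb], *cells])


def read_concentration_table(
    path: str,
    nd_token: str = "nd",
    lods: Mapping[str, float] | None = None,
) -> ConcentrationTable:
    """Read a delimited herb x analyte table.

    Expects a header row ``herb,part,<analyte abbreviations>`` with optional
    trailing ``<abbreviation>_rsd`` columns; cells are concentrations in
    µg/kg or the ``nd_token``.  Column and row order are preserved.

    Raises
    ------
    ValueError
        On an unknown analyte abbreviation, a duplicate herb id, or a
        negative concentration (reported with its cell coordinates).
    """
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise ValueError(f"{path}: empty file")
    header = [h.strip() for h in rows[0]]
    if len(header) < 3 or header[0] != "herb" or header[1] != "part":
        raise ValueError(f"{path}: header must start with 'herb,part'")
    analyte_cols = [h for h in header[2:] if not h.endswith("_rsd")]
    rsd_cols = [h for h in header[2:] if h.endswith("_rsd")]
    unknown = [c for c in analyte_cols if c not in ABBREVIATIONS]
    if unknown:
        raise ValueError(f"{path}: unknown analyte abbreviation(s): {unknown}")
    col_pos = {name: i for i, name in enumerate(header)}

    herbs: list[str] = []
    parts: dict[str, str] = {}
    values: list[list[float]] = []
    detected: list[list[bool]] = []
    rsd_rows: list[list[float]] = []
    for line_no, row in enumerate(rows[1:], start=2):
        if not row or all(not c.strip() for c in row):
            continue
        herb = row[0].strip()
        if herb in parts:
            raise ValueError(f"{path}: duplicate herb id {herb!r}")
        parts[herb] = row[1].strip()
        herbs.append(herb)
        vrow, drow = [], []
        for abbr in analyte_cols:
            cell = row[col_pos[abbr]].strip()
            if cell == nd_token:
                vrow.append(np.nan)
                drow.append(False)
            else:
                value = float(cell)
                if value < 0:
                    raise ValueError(
                        f"{path}: negative concentration at "
                        f"(herb={herb!r}, analyte={abbr!r}, line {line_no})"
                    )
                vrow.append(value)
                drow.append(True)
        values.append(vrow)
        detected.append(drow)
        if rsd_cols:
            rrow = []
            for col in rsd_cols:
                cell = row[col_pos[col]].strip()
                rrow.append(np.nan if cell in ("", "-", nd_token) else float(cell))
            rsd_rows.append(rrow)

    vdf = pd.DataFrame(values, index=herbs, columns=analyte_cols, dtype=float)
    ddf = pd.DataFrame(detected, index=herbs, columns=analyte_cols, dtype=bool)
    rdf = None
    if rsd_cols:
        rdf = pd.DataFrame(
            rsd_rows,
            index=herbs,
            columns=[c[: -len("_rsd")] for c in rsd_cols],
            dtype=float,
        )
    return ConcentrationTable(
        values=vdf,
        detected=ddf,
        parts=parts,
        rsd=rdf,
        lods=dict(lods) if lods is not None else dict(DEFAULT_LODS),
    )


def build_table(
    concentrations: Mapping[str, Mapping[str, float | None]],
    parts: Mapping[str, str],
    analytes: Sequence[str] | None = None,
    lods: Mapping[str, float] | None = None,
) -> ConcentrationTable:
    """Construct a table from nested mappings; ``None`` marks a non-detect."""
    analytes = list(analytes) if analytes is not None else list(ABBREVIATIONS)
    herbs = list(concentrations)
    vals = pd.DataFrame(index=herbs, columns=analytes, dtype=float)
    det = pd.DataFrame(False, index=herbs, columns=analytes, dtype=bool)
    for herb, row in concentrations.items():
        for abbr, value in row.items():
            if value is not None:
                vals.loc[herb, abbr] = float(value)
                det.loc[herb, abbr] = True
    return ConcentrationTable(
        values=vals,
        detected=det,
        parts=dict(parts),
        lods=dict(lods) if lods is not None else dict(DEFAULT_LODS),
    )
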