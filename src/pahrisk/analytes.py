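"""Registry of the 16 EPA priority PAHs and toxic-equivalency schemes.

The registry carries, per analyte: the conventional abbreviation used as the
column key in every table, CAS number, aromatic ring count, Nisbet–LaGoy
toxic equivalency factor (TEF, benzo[a]pyrene = 1) and membership in the
EU "PAH4" regulatory marker set {BaA, Chry, BbF, BaP}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping


@dataclass(frozen=True)
class AnalyteDescriptor:
    """One polycyclic aromatic hydrocarbon.

    Attributes
    ----------
    name : full compound name
    abbreviation : short key, e.g. ``"Phe"``
    cas : CAS registry number
    ring_count : number of fused aromatic rings, in ``{2..6}``
    tef : toxic equivalency factor relative to benzo[a]pyrene
    in_pah4 : whether the analyte belongs to the EU PAH4 marker set
    """

    name: str
    abbreviation: str
    cas: str
    ring_count: int
    tef: float
    in_pah4: bool = False

    def __post_init__(self) -> None:
        if self.ring_count not in {2, 3, 4, 5, 6}:
            raise ValueError(f"{self.abbreviation}: ring_count must be in 2..6")
        if self.tef < 0:
            raise ValueError(f"{self.abbreviation}: tef must be >= 0")


#: Canonical ordered registry of the 16 EPA priority PAHs.
EPA16: tuple[AnalyteDescriptor, ...] = (
    AnalyteDescriptor("Naphthalene", "Naph", "91-20-3", 2, 0.001),
    AnalyteDescriptor("Acenaphthylene", "Acy", "208-96-8", 3, 0.001),
    AnalyteDescriptor("Acenaphthene", "Ace", "83-32-9", 3, 0.001),
    AnalyteDescriptor("Fluorene", "Flu", "86-73-7", 3, 0.001),
    AnalyteDescriptor("Phenanthrene", "Phe", "85-01-8", 3, 0.001),
    AnalyteDescriptor("Anthracene", "Ant", "120-12-7", 3, 0.01),
    AnalyteDescriptor("Fluoranthene", "Flt", "206-44-0", 4, 0.001),
    AnalyteDescriptor("Pyrene", "Pyr", "129-00-0", 4, 0.001),
    AnalyteDescriptor("Benz[a]anthracene", "BaA", "56-55-3", 4, 0.1, True),
    AnalyteDescriptor("Chrysene", "Chry", "218-01-9", 4, 0.01, True),
    AnalyteDescriptor("Benzo[b]fluoranthene", "BbF", "205-99-2", 5, 0.1, True),
    AnalyteDescriptor("Benzo[k]fluoranthene", "bkF", "207-08-9", 5, 0.1),
    AnalyteDescriptor("Benzo[a]pyrene", "BaP", "50-32-8", 5, 1.0, True),
    AnalyteDescriptor("Indeno[1,2,3-c,d]pyrene", "Ind(cd)P", "193-39-5", 6, 0.1),
    AnalyteDescriptor("Dibenz[a,h]anthracene", "DahA", "53-70-3", 5, 1.0),
    AnalyteDescriptor("Benzo[g,h,i]perylene", "BghiP", "191-24-2", 6, 0.01),
)

#: Abbreviations in canonical order — the required column order of tables.
ABBREVIATIONS: tuple[str, ...] = tuple(a.abbreviation for a in EPA16)

#: Abbreviation -> descriptor lookup.
BY_ABBREVIATION: Mapping[str, AnalyteDescriptor] = {
    a.abbreviation: a for a in EPA16
}

#: The PAH4 regulatory marker subset (EU 835/2011, limit 35 µg/kg).
PAH4: tuple[str, ...] = tuple(a.abbreviation for a in EPA16 if a.in_pah4)

#: Instrumental limits of detection (µg/kg) for the default survey method,
#: used by the ``half_lod``/``lod`` non-detect policies and the synthetic
#: generator defaults.
DEFAULT_LODS: Mapping[str, float] = {
    "Naph": 6.81, "Acy": 5.20, "Ace": 5.68, "Flu": 5.14,
    "Phe": 6.35, "Ant": 4.96, "Flt": 5.13, "Pyr": 5.33,
    "BaA": 5.60, "Chry": 5.54, "BbF": 6.99, "bkF": 6.75,
    "BaP": 8.14, "Ind(cd)P": 5.72, "DahA": 6.25, "BghiP": 7.70,
}

#: Ring classes used by the screening module's distribution summaries.
RING_CLASSES: Mapping[str, tuple[int, ...]] = {
    "2-3": (2, 3),
    "4": (4,),
    "5-6": (5, 6),
}


@dataclass(frozen=True)
class TefScheme:
    """A toxic-equivalency weighting: abbreviation -> TEF plus the divisor
    applied to the weighted sum (default 1000, matching the conventional
    reporting scale of BaP-equivalent concentrations).
    """

    tefs: Mapping[str, float] = field(
        default_factory=lambda: {a.abbreviation: a.tef for a in EPA16}
    )
    scale_divisor: float = 1000.0

    def __post_init__(self) -> None:
        missing = [abbr for abbr in ABBREVIATIONS if abbr not in self.tefs]
        if missing:
            raise ValueError(f"TEF scheme missing analytes: {missing}")
        bad = {k: v for k, v in self.tefs.items() if not v > 0}
        if bad:
            raise ValueError(f"TEFs must be > 0: {bad}")
        if not self.scale_divisor > 0:
            raise ValueError("scale_divisor must be > 0")

    def __getitem__(self, abbreviation: str) -> float:
        return self.tefs[abbreviation]


def default_tef_scheme() -> TefScheme:
    """Nisbet–LaGoy TEFs with the conventional divisor of 1000."""
    return TefScheme()
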