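"""Exposure-factor configuration: point values or parametric distributions.

Lognormal specs are parameterized by ARITHMETIC mean and sd (the reporting
convention of risk tables) and converted to log-scale parameters internally.
Truncation is applied by inverse-CDF restriction, preserving reproducibility
of seeded draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Mapping

import numpy as np
import yaml
from scipy import stats

FAMILIES = ("point", "normal", "lognormal", "uniform", "triangular")

#: Required exposure-factor keys and their meaning/units.
FACTOR_KEYS = ("dr", "csf", "ef", "ed", "bw", "at")


def lognormal_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Convert arithmetic (mean, sd) of a lognormal to (log-location, log-shape).

    shape^2 = ln(1 + (sd/mean)^2); location = ln(mean) - shape^2 / 2.
    """
    if not mean > 0:
        raise ValueError("lognormal arithmetic mean must be > 0")
    if sd < 0:
        raise ValueError("lognormal arithmetic sd must be >= 0")
    shape_sq = np.log1p((sd / mean) ** 2)
    location = np.log(mean) - shape_sq / 2.0
    return float(location), float(np.sqrt(shape_sq))


def lognormal_to_moments(location: float, shape: float) -> tuple[float, float]:
    """Inverse of :func:`lognormal_from_moments`."""
    mean = np.exp(location + shape**2 / 2.0)
    sd = mean * np.sqrt(np.expm1(shape**2))
    return float(mean), float(sd)


@dataclass(frozen=True)
class DistributionSpec:
    """Family + parameters (+ optional truncation) for a stochastic input.

    params by family:
      point       value
      normal      mean, sd        (arithmetic)
      lognormal   mean, sd        (ARITHMETIC moments, converted internally)
      uniform     low, high
      triangular  low, mode, high
    """

    family: str
    params: Mapping[str, float]
    truncation: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; must be in {FAMILIES}")
        p = dict(self.params)
        need = {
            "point": ["value"],
            "normal": ["mean", "sd"],
            "lognormal": ["mean", "sd"],
            "uniform": ["low", "high"],
            "triangular": ["low", "mode", "high"],
        }[self.family]
        missing = [k for k in need if k not in p]
        if missing:
            raise ValueError(f"{self.family} spec missing parameter(s) {missing}")
        if self.family in ("normal", "lognormal") and not p["sd"] > 0:
            raise ValueError(f"{self.family} sd must be > 0")
        if self.family == "lognormal" and not p["mean"] > 0:
            raise ValueError("lognormal mean must be > 0")
        if self.family in ("uniform", "triangular") and not p["low"] < p["high"]:
            raise ValueError(f"{self.family} requires low < high")
        if self.family == "triangular" and not p["low"] <= p["mode"] <= p["high"]:
            raise ValueError("triangular requires low <= mode <= high")
        if self.truncation is not None:
            lo, hi = self.truncation
            if not lo < hi:
                raise ValueError("truncation requires low < high")

    @classmethod
    def point(cls, value: float) -> "DistributionSpec":
        return cls("point", {"value": float(value)})

    @property
    def is_point(self) -> bool:
        return self.family == "point"

    def frozen(self):
        """The scipy frozen distribution for a stochastic family."""
        p = self.params
        if self.family == "normal":
            return stats.norm(loc=p["mean"], scale=p["sd"])
        if self.family == "lognormal":
            location, shape = lognormal_from_moments(p["mean"], p["sd"])
            return stats.lognorm(s=shape, scale=np.exp(location))
        if self.family == "uniform":
            return stats.uniform(loc=p["low"], scale=p["high"] - p["low"])
        if self.family == "triangular":
            low, mode, high = p["low"], p["mode"], p["high"]
            return stats.triang(
                c=(mode - low) / (high - low), loc=low, scale=high - low
            )
        raise ValueError(f"family {self.family!r} has no distribution")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` values; truncation restricts the inverse CDF."""
        if n <= 0:
            raise ValueError("n must be >= 1")
        if self.is_point:
            return np.full(n, float(self.params["value"]))
        dist = self.frozen()
        lo_cdf, hi_cdf = 0.0, 1.0
        if self.truncation is not None:
            lo, hi = self.truncation
            lo_cdf, hi_cdf = float(dist.cdf(lo)), float(dist.cdf(hi))
            if not hi_cdf > lo_cdf:
                raise ValueError(
                    f"truncation {self.truncation} excludes all probability mass"
                )
        u = rng.uniform(lo_cdf, hi_cdf, size=n)
        return np.asarray(dist.ppf(u), dtype=float)

    def mean(self) -> float:
        if self.is_point:
            return float(self.params["value"])
        if self.truncation is None:
            return float(self.frozen().mean())
        # moments of a truncated family are not needed analytically anywhere;
        # estimate by quadrature over the restricted CDF range
        dist = self.frozen()
        lo, hi = self.truncation
        lo_cdf, hi_cdf = dist.cdf(lo), dist.cdf(hi)
        u = np.linspace(lo_cdf, hi_cdf, 20001)[1:-1]
        return float(np.mean(dist.ppf(u)))


FactorValue = "DistributionSpec | float"


@dataclass(frozen=True)
class ExposureFactors:
    """Per-age-group exposure factors for the intake risk model.

    dr  daily herbal intake, g/day
    csf cancer slope factor, (mg/kg.day)^-1
    ef  exposure frequency, days/year (<= 366)
    ed  exposure duration, years
    bw  body weight, kg
    at  averaging time, days
    """

    group: str
    dr: DistributionSpec
    csf: DistributionSpec
    ef: DistributionSpec
    ed: DistributionSpec
    bw: DistributionSpec
    at: DistributionSpec

    def __post_init__(self) -> None:
        for key in FACTOR_KEYS:
            spec: DistributionSpec = getattr(self, key)
            if spec.is_point and not spec.params["value"] > 0:
                raise ValueError(f"{self.group}.{key}: must be strictly positive")
        if self.ef.is_point and self.ef.params["value"] > 366:
            raise ValueError(f"{self.group}.ef: exposure frequency exceeds 366 d/yr")

    def spec(self, key: str) -> DistributionSpec:
        return getattr(self, key)

    def point_values(self) -> dict[str, float]:
        """All six factors as scalars; raises if any factor is stochastic."""
        out = {}
        for key in FACTOR_KEYS:
            spec = self.spec(key)
            if not spec.is_point:
                raise ValueError(f"{self.group}.{key} is stochastic, not a point")
            out[key] = float(spec.params["value"])
        return out


def _parse_spec(raw: Any, where: str) -> DistributionSpec:
    if isinstance(raw, (int, float)):
        if not float(raw) > 0:
            raise ValueError(f"{where}: must be strictly positive, got {raw}")
        return DistributionSpec.point(float(raw))
    if isinstance(raw, dict):
        if "family" not in raw:
            raise ValueError(f"{where}: distribution spec needs a 'family' key")
        family = raw["family"]
        trunc = raw.get("truncation")
        params = {
            k: float(v)
            for k, v in raw.items()
            if k not in ("family", "truncation")
        }
        try:
            return DistributionSpec(
                family,
                params,
                truncation=tuple(float(x) for x in trunc) if trunc else None,
            )
        except ValueError as exc:
            raise ValueError(f"{where}: {exc}") from exc
    raise ValueError(f"{where}: expected a number or a mapping, got {type(raw).__name__}")


def parse_exposure_group(block: Mapping[str, Any], where: str = "") -> ExposureFactors:
    if "group" not in block:
        raise ValueError(f"{where or 'group block'}: missing 'group' label")
    label = str(block["group"])
    specs = {}
    for key in FACTOR_KEYS:
        if key not in block:
            raise ValueError(f"{where or label}.{key}: missing required key")
        specs[key] = _parse_spec(block[key], f"{where or label}.{key}")
    return ExposureFactors(group=label, **specs)


def read_exposure_config(path: str) -> list[ExposureFactors]:
    """Read a YAML exposure configuration.

    Layout::

        groups:
          - group: adult
            dr: 5.0
            csf: 7.3
            ef: 365
            ed: {family: normal, mean: 30, sd: 5, truncation: [1, 70]}
            bw: 60
            at: 25550
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "groups" not in doc:
        raise ValueError(f"{path}: expected a top-level 'groups' list")
    groups = doc["groups"]
    if not isinstance(groups, list) or not groups:
        raise ValueError(f"{path}: 'groups' must be a non-empty list")
    out = []
    for i, block in enumerate(groups):
        out.append(parse_exposure_group(block, where=f"groups[{i}]"))
    return out


def read_tef_config(path: str):
    """Read a TEF override YAML: ``tefs: {<abbr>: <tef>, ...}`` plus an
    optional ``scale_divisor``."""
    from .analytes import TefScheme, default_tef_scheme

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: expected a mapping")
    base = dict(default_tef_scheme().tefs)
    base.update({str(k): float(v) for k, v in (doc.get("tefs") or {}).items()})
    return TefScheme(tefs=base, scale_divisor=float(doc.get("scale_divisor", 1000.0)))
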