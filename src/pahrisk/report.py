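"""Serialization of pipeline products to delimited (CSV) or structured
(JSON) text."""

from __future__ import annotations

import dataclasses
import json
from typing import Any

import numpy as np
import pandas as pd

from .montecarlo import MCResult
from .screening import ScreeningReport
from .sources import RatioProfile
from .table import ConcentrationTable

FORMATS = ("delimited", "structured")


def _to_frame(results: Any) -> pd.DataFrame:
    if isinstance(results, pd.DataFrame):
        return results
    if isinstance(results, ScreeningReport):
        return results.to_frame()
    if isinstance(results, (list, tuple)):
        if all(isinstance(r, RatioProfile) for r in results) and results:
            return pd.DataFrame(
                [
                    {
                        "herb": p.herb,
                        "flt_ratio": p.flt_ratio,
                        "ant_ratio": p.ant_ratio,
                        "baa_ratio": p.baa_ratio,
                        **{f"label_{k}": v for k, v in p.labels.items()},
                        "composite": p.composite,
                    }
                    for p in results
                ]
            )
        return pd.DataFrame(list(results))
    if isinstance(results, dict):
        return pd.DataFrame(results)
    raise TypeError(f"cannot tabulate {type(results).__name__}")


class _Encoder(json.JSONEncoder):
    def default(self, o: Any):
        if isinstance(o, MCResult):
            return o.to_dict()
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, pd.DataFrame):
            return {
                "columns": list(o.columns),
                "index": list(o.index),
                "data": o.to_numpy().tolist(),
            }
        if isinstance(o, pd.Series):
            return dict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        return super().default(o)


def write_report(results: Any, path: str, format: str = "delimited") -> None:
    """Write any pipeline product to ``path``.

    ``delimited`` tabulates the product to CSV at full (round-trip) float
    precision; ``structured`` serializes to JSON.  An empty result set
    yields a header-only / empty-document file, not an error.
    """
    if format not in FORMATS:
        raise ValueError(f"format must be one of {FORMATS}")
    if format == "delimited":
        if isinstance(results, ConcentrationTable):
            results.to_csv(path)
            return
        frame = _to_frame(results)
        index = frame.index.name is not None or not isinstance(
            frame.index, pd.RangeIndex
        )
        frame.to_csv(path, index=index)
        return
    with open(path, "w") as fh:
        json.dump(results, fh, cls=_Encoder, indent=2)
        fh.write("\n")
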