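"""Delimited-text I/O for growth curves, proportions and landscapes.

CSV dialects (UTF-8, header required, decimal point):

* growth curves: ``time_days, volume_mm3, spheroid_id, group``
* proportions:   ``time_days, fraction_parental, group``
* regrowth landscapes: ``lambda_P, lambda_RR, time_to_trigger_days,
  regrowth_days, censored, reason``

Values round-trip exactly: floats are written with shortest-repr
precision, which Python parses back to the identical double.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import SchemaError
from .fitting import ProportionObservation
from .growth import GrowthCurve
from .radiation import RegrowthResult

__all__ = [
    "read_growth_curves",
    "write_growth_curves",
    "read_proportions",
    "write_proportions",
    "write_landscape",
    "read_landscape",
    "write_manifest",
]

_CURVE_COLUMNS = ["time_days", "volume_mm3", "spheroid_id", "group"]
_PROP_COLUMNS = ["time_days", "fraction_parental", "group"]


def _check_columns(df: pd.DataFrame, required: Sequence[str],
                   path) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")


def read_growth_curves(path) -> list[GrowthCurve]:
    """Read growth curves, one :class:`GrowthCurve` per spheroid_id."""
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, _CURVE_COLUMNS, path)
    if df.empty:
        raise SchemaError(f"{path}: no rows")
    curves = []
    for (group, sid), sub in df.groupby(["group", "spheroid_id"], sort=True):
        sub = sub.sort_values("time_days")
        curves.append(GrowthCurve(sub["time_days"].to_numpy(float),
                                  sub["volume_mm3"].to_numpy(float),
                                  label=str(sid), group=str(group)))
    return curves


def write_growth_curves(curves: Sequence[GrowthCurve], path) -> None:
    rows = []
    for c in curves:
        for t, v in zip(c.times, c.volumes):
            rows.append((repr(float(t)), repr(float(v)), c.label, c.group))
    df = pd.DataFrame(rows, columns=_CURVE_COLUMNS)
    df.to_csv(path, index=False)


def read_proportions(path) -> list[ProportionObservation]:
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, _PROP_COLUMNS, path)
    return [
        ProportionObservation(time=float(r.time_days),
                              fraction_P=float(r.fraction_parental),
                              group=str(r.group))
        for r in df.itertuples()
    ]


def write_proportions(props: Sequence[ProportionObservation], path) -> None:
    rows = [(repr(float(o.time)), repr(float(o.fraction_P)), o.group)
            for o in props]
    pd.DataFrame(rows, columns=_PROP_COLUMNS).to_csv(path, index=False)


def write_landscape(results: Sequence[RegrowthResult], path) -> None:
    rows = [
        (r.lambda_P, r.lambda_RR, r.time_to_trigger, r.regrowth_time,
         r.censored, r.reason)
        for r in results
    ]
    pd.DataFrame(rows, columns=[
        "lambda_P", "lambda_RR", "time_to_trigger_days", "regrowth_days",
        "censored", "reason",
    ]).to_csv(path, index=False)


def read_landscape(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False,
                     na_values=["nan", ""],
                     float_precision="round_trip")
    _check_columns(df, ["lambda_P", "lambda_RR", "regrowth_days",
                        "censored"], path)
    return df


def write_manifest(path, **entries) -> None:
    """Write a provenance manifest (config, seed, package version) as JSON."""
    from . import __version__

    payload = {"ecospheroid_version": __version__}
    payload.update(entries)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True,
                                     default=str))
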