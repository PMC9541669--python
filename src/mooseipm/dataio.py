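"""File formats and configuration.

The unit-year CSV has one row per management unit and year.  Calendar-year
labels follow the survey convention: the "winter of year t" spans December
of t-1 through February of t, so a row holds that winter's aerial survey
together with the following fall's hunt (harvest report, hunter sightings,
effort).  Missing values are empty fields; the header is required.

The YAML configuration file has sections ``priors``, ``fit``, ``design``
and ``elasticity`` whose keys mirror the corresponding dataclasses.
"""

from __future__ import annotations

import os
from dataclasses import fields, replace

import numpy as np
import pandas as pd
import yaml

from .exceptions import MooseIPMError, SchemaError
from .inference import FitConfig, PriorConfig
from .synthetic_data import SyntheticDesign, TrueParams

SCHEMA = [
    "unit_id", "year", "area_km2", "aerial_estimate", "aerial_se",
    "survey_conducted", "hunter_moose_seen", "days_hunted",
    "tags_issued_bull", "tags_issued_cow", "tags_issued_calf",
    "reported_harvest_bull", "reported_harvest_cow", "reported_harvest_calf",
    "respondents_bull", "respondents_cow", "respondents_calf",
    "reported_success_bull", "reported_success_cow", "reported_success_calf",
    "canids_per_day", "deer_per_day", "snow_index", "bear_density",
]

_COUNT_COLS = [c for c in SCHEMA if c.startswith(("tags_issued", "reported_harvest",
                                                  "respondents", "hunter_moose"))]


def write_dataset(df: pd.DataFrame, path: str) -> None:
    """Write a unit-year table in the canonical column order (UTF-8 CSV)."""
    missing = [c for c in SCHEMA if c not in df.columns]
    if missing:
        raise SchemaError(f"dataset missing columns: {missing}")
    df[SCHEMA].to_csv(path, index=False)


def read_dataset(path: str, min_surveys: int = 2) -> pd.DataFrame:
    """Read and validate a unit-year CSV.

    Units with fewer than `min_surveys` aerial surveys are listed in
    ``df.attrs["flagged_units"]``; they are excluded later, at fit time.
    """
    if not os.path.exists(path):
        raise MooseIPMError(f"dataset file not found: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise MooseIPMError(f"empty dataset file: {path}") from None
    if df.empty:
        raise MooseIPMError(f"dataset has a header but no rows: {path}")
    missing = [c for c in SCHEMA if c not in df.columns]
    if missing:
        raise SchemaError(f"dataset missing columns: {missing}")
    for col in _COUNT_COLS:
        vals = df[col].dropna()
        if (vals < 0).any():
            raise SchemaError(f"negative counts in column {col!r}")
    for col in [c for c in SCHEMA if c.startswith("reported_success")]:
        vals = df[col].dropna()
        if ((vals < 0) | (vals > 1)).any():
            raise SchemaError(f"success rate outside [0, 1] in column {col!r}")
    conducted = df[df["survey_conducted"] == 1]
    bad = conducted[(conducted["aerial_estimate"] <= 0)
                    | (conducted["aerial_se"] < 0)]
    if len(bad):
        raise SchemaError("conducted surveys need estimate > 0 and se >= 0 "
                          f"(rows {bad.index.tolist()[:5]} ...)")
    n_surv = df.groupby("unit_id")["survey_conducted"].sum()
    df.attrs["flagged_units"] = sorted(n_surv[n_surv < min_surveys].index)
    return df


def _build(cls, section: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise SchemaError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    coerced = {k: (tuple(v) if isinstance(v, list) else v)
               for k, v in section.items()}
    return cls(**coerced)


def load_config(path: str) -> dict:
    """Load a YAML config into dataclasses.

    Returns {"priors": PriorConfig, "fit": FitConfig,
    "design": SyntheticDesign, "elasticity": dict}.
    Absent sections get package defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    design_raw = dict(raw.get("design", {}))
    params_raw = design_raw.pop("params", {})
    design = _build(SyntheticDesign, design_raw)
    if params_raw:
        design = replace(design, params=_build(TrueParams, params_raw))
    return {
        "priors": _build(PriorConfig, raw.get("priors", {})),
        "fit": _build(FitConfig, raw.get("fit", {})),
        "design": design,
        "elasticity": {"deltas": tuple(raw.get("elasticity", {}).get(
            "deltas", (0.01, 0.05, 0.10)))},
    }


def default_config_path() -> str:
    """Path of the example configuration shipped with the package."""
    return os.path.join(os.path.dirname(__file__), "example_config.yaml")
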