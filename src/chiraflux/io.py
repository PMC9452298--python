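"""Schema-checked CSV interchange.

All pipeline inputs and outputs are plain CSV with a one-line schema
header comment (``# chiraflux:<schema> v1``) and ISO-8601 timestamps plus
a fractional ``doy`` column.  Reads validate required columns, strictly
increasing timestamps and unit consistency; writes and reads round-trip.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd


class SchemaError(ValueError):
    """A file does not match its declared schema."""


#: required columns per schema (beyond the time index)
SCHEMAS: dict[str, tuple[str, ...]] = {
    "forcing": ("doy", "par", "temp", "rh", "pressure", "soil_moisture",
                "vpd", "stage"),
    "tracer": ("doy", "sf6", "injection"),
    "co2": ("doy", "co2_inside", "co2_outside"),
    "vmr": ("doy", "vmr", "uncertainty", "unit", "compound"),
    "isotopes": ("compound", "context", "doy", "time", "ratio_13_12"),
    "er_series": ("er_pct_h",),
    "truth_series": ("doy", "er_pct_h", "a_real", "nee_true", "co2_true"),
    "flux": ("nee", "resp", "a", "vpd"),
}

UNITS_NOTE = {
    "forcing": "par umol m-2 s-1; temp degC; rh %; pressure Pa; "
               "soil_moisture % vol; vpd kPa",
    "tracer": "sf6 ppt",
    "co2": "co2 ppm",
    "vmr": "vmr/uncertainty in the tagged unit (ppt or ppb)",
    "isotopes": "ratio_13_12 dimensionless 13C/12C",
    "er_series": "er_pct_h % per hour",
    "truth_series": "a_real/nee_true umol m-2 s-1; co2 ppm; er % per hour",
    "flux": "nee/resp/a umol m-2 s-1; vpd kPa",
}


def slug(name: str) -> str:
    """Filesystem-safe compound slug: (-)-a-pinene -> minus_a_pinene."""
    s = name.replace("(-)-", "minus_").replace("(+)-", "plus_")
    return re.sub(r"[^A-Za-z0-9]+", "_", s).strip("_")


def _write(df: pd.DataFrame, path: Path, schema: str,
           time_index: bool = True) -> Path:
    path = Path(path)
    missing = [c for c in SCHEMAS[schema] if c not in df.columns]
    if missing:
        raise SchemaError(f"{schema}: missing columns {missing}")
    with open(path, "w") as fh:
        fh.write(f"# chiraflux:{schema} v1\n")
        fh.write(f"# units: {UNITS_NOTE[schema]}\n")
        out = df.copy()
        if time_index:
            out.index = out.index.strftime("%Y-%m-%dT%H:%M:%S")
            out.index.name = "time"
        out.to_csv(fh, index=time_index)
    return path


def _read(path: Path, schema: str, time_index: bool = True) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"missing input file: {path}")
    with open(path) as fh:
        header = fh.readline().strip()
    m = re.match(r"#\s*chiraflux:(\w+)\s+v(\d+)", header)
    if not m or m.group(1) != schema:
        raise SchemaError(f"{path}: expected schema {schema!r}, "
                          f"found header {header!r}")
    df = pd.read_csv(path, comment="#")
    missing = [c for c in SCHEMAS[schema] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if time_index:
        if "time" not in df.columns:
            raise SchemaError(f"{path}: missing time column")
        df["time"] = pd.to_datetime(df["time"])
        if not df["time"].is_monotonic_increasing or df["time"].duplicated().any():
            raise SchemaError(f"{path}: timestamps must be strictly increasing")
        df = df.set_index("time")
    if schema == "vmr" and df["unit"].nunique() > 1:
        raise SchemaError(
            f"{path}: mixed units {sorted(df['unit'].unique())} in one series")
    return df


def write_forcing(df, path):
    return _write(df, path, "forcing")


def read_forcing(path):
    df = _read(path, "forcing")
    df["stage"] = df["stage"].fillna("").astype(str)
    return df


def write_tracer(df, path):
    return _write(df, path, "tracer")


def read_tracer(path):
    return _read(path, "tracer")


def write_co2(df, path):
    return _write(df, path, "co2")


def read_co2(path):
    return _read(path, "co2")


def write_vmr(df, path):
    return _write(df, path, "vmr")


def read_vmr(path):
    return _read(path, "vmr")


def write_isotopes(df, path):
    return _write(df, path, "isotopes", time_index=False)


def read_isotopes(path):
    df = _read(path, "isotopes", time_index=False)
    df["time"] = pd.to_datetime(df["time"])
    return df


def write_er_series(df, path):
    return _write(df, path, "er_series")


def read_er_series(path):
    return _read(path, "er_series")


def write_truth_series(df, path):
    return _write(df, path, "truth_series")


def read_truth_series(path):
    return _read(path, "truth_series")


def write_flux(df, path):
    return _write(df, path, "flux")


def read_flux(path):
    return _read(path, "flux")
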