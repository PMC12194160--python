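"""CSV readers and writers for the tabular inputs and report tables.

All tables are UTF-8 CSV with a header row. Column names:

- climate: year, month, tm, tmin, tmax, precip, spei
- counts: species, year, month, count
- nests: species, year, n_nests
- vegetation cover: year, percent_cover
"""

from __future__ import annotations

from os import PathLike

import pandas as pd

from . import timeseries as ts

COVER_COLUMNS = ["year", "percent_cover"]


def read_climate(path: str | PathLike) -> pd.DataFrame:
    """Read and validate a monthly climate table."""
    df = pd.read_csv(path, encoding="utf-8")
    return ts.validate_climate(df)


def write_climate(df: pd.DataFrame, path: str | PathLike) -> None:
    df[ts.CLIMATE_COLUMNS].to_csv(path, index=False, encoding="utf-8")


def read_counts(path: str | PathLike) -> pd.DataFrame:
    """Read and validate a monthly per-species count table."""
    df = pd.read_csv(path, encoding="utf-8")
    return ts.validate_counts(df)


def write_counts(df: pd.DataFrame, path: str | PathLike) -> None:
    df[ts.COUNT_COLUMNS].to_csv(path, index=False, encoding="utf-8")


def read_nests(path: str | PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    missing = set(ts.NEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"nest table missing columns: {sorted(missing)}")
    if (df["n_nests"] < 0).any():
        raise ValueError("negative nest counts")
    if df.duplicated(["species", "year"]).any():
        raise ValueError("duplicate species x year nest records")
    return df.sort_values(["species", "year"]).reset_index(drop=True)


def write_nests(df: pd.DataFrame, path: str | PathLike) -> None:
    df[ts.NEST_COLUMNS].to_csv(path, index=False, encoding="utf-8")


def read_cover(path: str | PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    missing = set(COVER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cover table missing columns: {sorted(missing)}")
    if not df["percent_cover"].between(0, 100).all():
        raise ValueError("percent_cover outside [0, 100]")
    return df.sort_values("year").reset_index(drop=True)


def write_cover(df: pd.DataFrame, path: str | PathLike) -> None:
    df[COVER_COLUMNS].to_csv(path, index=False, encoding="utf-8")
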