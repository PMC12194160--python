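"""Monthly climate and count series: seasons, seasonal aggregation, rolling windows.

The yearly cycle is split into a wintering season (September-February) and a
breeding season (March-August). A wintering season spans two calendar years
and is labeled by the calendar year of its September start, so wintering
season ``t`` runs from September of year ``t`` to February of year ``t+1``.

Month indexing is 1-based (1 = January) throughout, including the "location"
labels of climate windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

WINTERING = "wintering"
BREEDING = "breeding"
SEASONS = (WINTERING, BREEDING)

WINTERING_MONTHS = (9, 10, 11, 12, 1, 2)
BREEDING_MONTHS = (3, 4, 5, 6, 7, 8)

#: Calendar month in which each season ends. Breeding ends in August of the
#: season-year itself; wintering ends in February of the following year.
SEASON_END_MONTH = {WINTERING: 2, BREEDING: 8}

CLIMATE_VARIABLES = ("tm", "tmin", "tmax", "precip", "spei")

CLIMATE_COLUMNS = ["year", "month"] + list(CLIMATE_VARIABLES)
COUNT_COLUMNS = ["species", "year", "month", "count"]
NEST_COLUMNS = ["species", "year", "n_nests"]


def assign_season(month: int) -> str:
    """Map a calendar month to its season.

    September-February is wintering; March-August is breeding.
    """
    if not 1 <= int(month) <= 12 or month != int(month):
        raise ValueError(f"month must be an integer in 1..12, got {month!r}")
    return BREEDING if 3 <= month <= 8 else WINTERING


def season_year(year: int, month: int) -> int:
    """Season-year label for a (year, month) pair.

    Breeding months keep their calendar year. Wintering months September-
    December keep theirs; January and February belong to the wintering
    season that started the previous September.
    """
    if assign_season(month) == BREEDING:
        return int(year)
    return int(year) if month >= 9 else int(year) - 1


def season_end_calendar_year(season: str, season_yr: int) -> int:
    """Calendar year containing the season's final month."""
    if season not in SEASONS:
        raise ValueError(f"unknown season {season!r}")
    return int(season_yr) + (1 if season == WINTERING else 0)


def rolling_aggregate(values, duration: int, agg: str = "mean") -> np.ndarray:
    """Rolling mean or sum over consecutive-month blocks.

    Output element ``i`` aggregates input elements ``i .. i+duration-1``, so
    the output has length ``len(values) - duration + 1``. A missing value
    anywhere inside a window makes that window's output NaN.
    """
    values = np.asarray(values, dtype=float)
    if duration < 1:
        raise ValueError("duration must be >= 1")
    if duration > values.size:
        raise ValueError(
            f"duration {duration} exceeds series length {values.size}"
        )
    if agg not in ("mean", "sum"):
        raise ValueError(f"agg must be 'mean' or 'sum', got {agg!r}")
    roller = pd.Series(values).rolling(duration, min_periods=duration)
    out = (roller.mean() if agg == "mean" else roller.sum()).to_numpy()
    return out[duration - 1 :]


@dataclass(frozen=True)
class SeasonalAbundance:
    """Seasonal abundance of one species in one season-year.

    ``value`` is the arithmetic mean of the season's available monthly
    counts; ``complete`` is True only when all six months were present.
    """

    species: str
    season: str
    season_year: int
    value: float
    n_months: int
    complete: bool


def seasonal_abundance(
    counts: pd.DataFrame,
    season: str,
    *,
    drop_incomplete: bool = False,
) -> pd.DataFrame:
    """Per-species seasonal abundance: mean of the season's monthly counts.

    Parameters
    ----------
    counts
        MonthlyCount table with columns species, year, month, count.
    season
        ``"wintering"`` or ``"breeding"``.
    drop_incomplete
        If True, season-years with fewer than six observed months are
        dropped instead of flagged.

    Returns
    -------
    DataFrame with columns species, season, season_year, value, n_months,
    complete — one row per species x season-year that has at least one
    observed month.
    """
    if season not in SEASONS:
        raise ValueError(f"unknown season {season!r}")
    df = counts.copy()
    df["season"] = df["month"].map(assign_season)
    df = df[df["season"] == season]
    if df.empty:
        warnings.warn(f"no counts fall in season {season!r}", stacklevel=2)
        return pd.DataFrame(
            columns=["species", "season", "season_year", "value", "n_months", "complete"]
        )
    df["season_year"] = [
        season_year(y, m) for y, m in zip(df["year"], df["month"])
    ]
    grouped = (
        df.groupby(["species", "season_year"])["count"]
        .agg(value="mean", n_months="size")
        .reset_index()
    )
    grouped["season"] = season
    grouped["complete"] = grouped["n_months"] == 6
    n_partial = int((~grouped["complete"]).sum())
    if n_partial:
        warnings.warn(
            f"{n_partial} {season} season-year(s) have fewer than 6 months "
            "and are flagged incomplete",
            stacklevel=2,
        )
    if drop_incomplete:
        grouped = grouped[grouped["complete"]]
    cols = ["species", "season", "season_year", "value", "n_months", "complete"]
    return grouped[cols].sort_values(["species", "season_year"]).reset_index(drop=True)


def validate_climate(climate: pd.DataFrame) -> pd.DataFrame:
    """Check MonthlyClimateSeries invariants; returns the sorted frame.

    Requires unique, contiguous (year, month) pairs, tmin <= tm <= tmax and
    precip >= 0 in every record.
    """
    missing = set(CLIMATE_COLUMNS) - set(climate.columns)
    if missing:
        raise ValueError(f"climate table missing columns: {sorted(missing)}")
    df = climate.sort_values(["year", "month"]).reset_index(drop=True)
    idx = df["year"].to_numpy() * 12 + (df["month"].to_numpy() - 1)
    if len(np.unique(idx)) != len(idx):
        raise ValueError("duplicate (year, month) records in climate series")
    if len(idx) > 1 and not np.all(np.diff(idx) == 1):
        raise ValueError("climate series has gaps: (year, month) not contiguous")
    if not df["month"].between(1, 12).all():
        raise ValueError("month outside 1..12")
    bad_t = ~((df["tmin"] <= df["tm"]) & (df["tm"] <= df["tmax"]))
    if bad_t.any():
        raise ValueError(f"tmin <= tm <= tmax violated in {int(bad_t.sum())} record(s)")
    if (df["precip"] < 0).any():
        raise ValueError("negative precipitation")
    return df


def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Check MonthlyCount invariants; returns the sorted frame."""
    missing = set(COUNT_COLUMNS) - set(counts.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    df = counts.sort_values(["species", "year", "month"]).reset_index(drop=True)
    c = df["count"].to_numpy()
    if np.any(c < 0) or not np.allclose(c, np.round(c)):
        raise ValueError("counts must be non-negative integers")
    if df.duplicated(["species", "year", "month"]).any():
        raise ValueError("duplicate species x year x month records")
    return df
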