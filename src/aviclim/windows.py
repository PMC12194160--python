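"""Candidate climate time-windows and the best-window Spearman scan.

A candidate window is an aggregation rule for one climatic variable: a block
of ``duration`` consecutive months (1-12) ending in a given calendar month,
where temperatures and the drought index are averaged and precipitation is
summed. Windows are anchored to a season: the twelve end-month positions
step back one month at a time from the season's final month (February for
wintering, August for breeding), so candidate end months reach into the
calendar year before the season's reference year. Twelve durations times
twelve positions gives 144 candidates per variable.

For every species x season the scan computes each candidate's value per
season-year, correlates it with seasonal abundance by Spearman rank
correlation, and keeps the candidate with the largest absolute coefficient;
the best-correlated variable is then chosen across the five climatic
variables. Because the best of 144 correlations is selected, the winning
p-value is optimistic (a selection effect); no multiplicity correction is
applied, and reports carry this caveat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import timeseries as ts
from .errors import NoResultError, UndefinedCorrelationError

#: Tie-break priority when two variables reach the same |rho|.
VARIABLE_PRIORITY = ("spei", "tmax", "tm", "tmin", "precip")


def aggregation_for(variable: str) -> str:
    """Months are summed for precipitation, averaged for everything else."""
    if variable not in ts.CLIMATE_VARIABLES:
        raise ValueError(f"unknown climatic variable {variable!r}")
    return "sum" if variable == "precip" else "mean"


@dataclass(frozen=True)
class CandidateWindow:
    """One aggregation rule: variable, duration, end month and year offset.

    ``end_month`` labels the window by its last month (1 = January).
    ``year_offset`` places that month relative to the season's reference
    calendar year (the year containing the season's final month): 0 for the
    reference year itself, -1 for the year before.
    """

    variable: str
    duration: int
    end_month: int
    year_offset: int = 0
    agg: str = field(init=False)

    def __post_init__(self):
        if not 1 <= self.duration <= 12:
            raise ValueError("duration must be in 1..12")
        if not 1 <= self.end_month <= 12:
            raise ValueError("end_month must be in 1..12")
        if self.year_offset not in (0, -1):
            raise ValueError("year_offset must be 0 (focal) or -1 (previous)")
        object.__setattr__(self, "agg", aggregation_for(self.variable))


@dataclass(frozen=True)
class WindowScanResult:
    """Best window for one species x season x variable."""

    species: str
    season: str
    variable: str
    window: CandidateWindow
    rho: float
    p_value: float
    n_years: int


def enumerate_windows(
    variable: str,
    season: str = ts.BREEDING,
    *,
    duplicate_year_anchors: bool = False,
) -> list[CandidateWindow]:
    """All candidate windows for one variable, anchored to a season.

    The twelve end positions step back one month at a time from the season's
    final month, so each calendar month appears exactly once as an end month
    and the set has 12 durations x 12 positions = 144 members.

    With ``duplicate_year_anchors=True`` every end month is instead anchored
    in both the focal and the previous year (288 candidates), an alternative
    reading of running the same window set in two calendar years.
    """
    aggregation_for(variable)  # validates the variable name
    ref_month = ts.SEASON_END_MONTH[season]
    windows: list[CandidateWindow] = []
    if duplicate_year_anchors:
        for offset in (0, -1):
            for end_month in range(1, 13):
                for duration in range(1, 13):
                    windows.append(
                        CandidateWindow(variable, duration, end_month, offset)
                    )
        return windows
    for steps_back in range(12):
        end_month = (ref_month - 1 - steps_back) % 12 + 1
        offset = 0 if end_month <= ref_month else -1
        for duration in range(1, 13):
            windows.append(CandidateWindow(variable, duration, end_month, offset))
    return windows


def steps_back(window: CandidateWindow, season: str) -> int:
    """Recency of a window's end month: 0 = the season's final month."""
    ref_month = ts.SEASON_END_MONTH[season]
    return ref_month - (window.year_offset * 12 + window.end_month)


def window_months(window: CandidateWindow, season: str, season_yr: int):
    """The (year, month) pairs a window covers for one season-year."""
    ref_year = ts.season_end_calendar_year(season, season_yr)
    end_year = ref_year + window.year_offset
    end_idx = end_year * 12 + (window.end_month - 1)
    return [
        (idx // 12, idx % 12 + 1)
        for idx in range(end_idx - window.duration + 1, end_idx + 1)
    ]


def window_value(
    climate: pd.DataFrame,
    window: CandidateWindow,
    season_yr: int,
    season: str = ts.BREEDING,
) -> float:
    """Aggregate one window for one season-year; NaN if the span is missing.

    The window covers ``duration`` months ending at ``end_month`` of the
    season's reference calendar year plus ``year_offset``, aggregated with
    the variable's rule (sum for precipitation, mean otherwise).
    """
    months = window_months(window, season, season_yr)
    idx = climate["year"].to_numpy() * 12 + (climate["month"].to_numpy() - 1)
    lookup = pd.Series(climate[window.variable].to_numpy(), index=idx)
    wanted = [y * 12 + (m - 1) for y, m in months]
    if not all(w in lookup.index for w in wanted):
        return float("nan")
    vals = lookup.loc[wanted].to_numpy(dtype=float)
    if np.isnan(vals).any():
        return float("nan")
    return float(vals.sum() if window.agg == "sum" else vals.mean())


def window_value_series(
    climate: pd.DataFrame,
    window: CandidateWindow,
    season_years,
    season: str = ts.BREEDING,
) -> np.ndarray:
    """Vectorized :func:`window_value` over many season-years."""
    idx = climate["year"].to_numpy() * 12 + (climate["month"].to_numpy() - 1)
    order = np.argsort(idx)
    idx = idx[order]
    vals = climate[window.variable].to_numpy(dtype=float)[order]
    # contiguity is a series invariant, so positional slicing is safe
    start = idx[0]
    out = np.full(len(season_years), np.nan)
    for i, sy in enumerate(season_years):
        ref_year = ts.season_end_calendar_year(season, int(sy))
        end = (ref_year + window.year_offset) * 12 + (window.end_month - 1)
        lo, hi = end - window.duration + 1 - start, end + 1 - start
        if lo < 0 or hi > len(vals):
            continue
        block = vals[lo:hi]
        if np.isnan(block).any():
            continue
        out[i] = block.sum() if window.agg == "sum" else block.mean()
    return out


def spearman_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a t-approximation p-value.

    Missing pairs are deleted pairwise; at least four complete pairs are
    required. Either input having zero variance raises
    :class:`UndefinedCorrelationError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 4:
        raise ValueError(f"need >= 4 complete pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in an input")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def scan_best_window(
    abundance: pd.DataFrame,
    climate: pd.DataFrame,
    variable: str,
    *,
    season: str | None = None,
    min_years: int = 8,
    duplicate_year_anchors: bool = False,
) -> WindowScanResult:
    """Exhaustive scan: the candidate window best correlated with abundance.

    Parameters
    ----------
    abundance
        Seasonal abundance rows for a single species and season (columns
        species, season, season_year, value).
    climate
        Monthly climate table covering the windows' spans.
    variable
        Which climatic variable to scan.
    season
        Season anchoring the candidate set; inferred from ``abundance``
        when omitted.

    Ties in |rho| are broken deterministically: shorter duration, then more
    recent end month, then focal year before previous year.
    """
    species = abundance["species"].unique()
    if len(species) != 1:
        raise ValueError("scan expects abundance rows for exactly one species")
    if season is None:
        seasons = abundance["season"].unique()
        if len(seasons) != 1:
            raise ValueError("abundance mixes seasons; pass season explicitly")
        season = seasons[0]
    sy = abundance["season_year"].to_numpy()
    ab = abundance["value"].to_numpy(dtype=float)

    best: tuple | None = None
    for window in enumerate_windows(
        variable, season, duplicate_year_anchors=duplicate_year_anchors
    ):
        wv = window_value_series(climate, window, sy, season)
        keep = ~(np.isnan(wv) | np.isnan(ab))
        if keep.sum() < min_years:
            continue
        try:
            rho, p = spearman_correlation(ab[keep], wv[keep])
        except UndefinedCorrelationError:
            continue
        key = (
            -abs(rho),
            window.duration,
            steps_back(window, season),
            -window.year_offset,
        )
        if best is None or key < best[0]:
            best = (key, window, rho, p, int(keep.sum()))
    if best is None:
        raise NoResultError(
            f"no defined candidate for {species[0]}/{season}/{variable}"
        )
    _, window, rho, p, n = best
    return WindowScanResult(str(species[0]), season, variable, window, rho, p, n)


def select_best_variable(results) -> WindowScanResult:
    """Across per-variable scan results, keep the largest |rho|.

    Exact ties are broken by a fixed priority order (spei, tmax, tm, tmin,
    precip) with a warning.
    """
    results = [r for r in results if r is not None]
    if not results:
        raise NoResultError("no scan result to select from")
    prio = {v: i for i, v in enumerate(VARIABLE_PRIORITY)}
    ranked = sorted(results, key=lambda r: (-abs(r.rho), prio[r.variable]))
    if len(ranked) > 1 and abs(ranked[0].rho) == abs(ranked[1].rho):
        warnings.warn(
            f"|rho| tie between {ranked[0].variable} and {ranked[1].variable}; "
            f"keeping {ranked[0].variable} by priority order",
            stacklevel=2,
        )
    return ranked[0]


def scan_table(results) -> pd.DataFrame:
    """Best-window results as a report table (one row per result).

    Columns mirror a best-window summary: season, species, corr_coef, p,
    variable, window_duration, window_location, year_offset, n_years. The
    p-values are not adjusted for the 144-candidate selection.
    """
    rows = [
        {
            "season": r.season,
            "species": r.species,
            "corr_coef": r.rho,
            "p": r.p_value,
            "variable": r.variable,
            "window_duration": r.window.duration,
            "window_location": r.window.end_month,
            "year_offset": r.window.year_offset,
            "n_years": r.n_years,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
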