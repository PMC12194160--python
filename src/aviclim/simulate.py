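"""Seeded synthetic inputs with the statistical structure the analysis assumes.

The generator emulates an 18-year (2002-2019) monthly survey of four
waterbird species at a Mediterranean wetland:

- monthly climate with a sinusoidal temperature cycle around a mean annual
  temperature of 18.7 degC, a wet season October-February, and a first-order
  autoregressive drought index standardized to mean 0 / sd 1;
- overdispersed monthly counts whose log-mean is a seasonal baseline plus a
  climate effect acting through one known "true" window plus a vegetation
  effect, with variance phi * mu (gamma-Poisson mixture, the same variance
  function the quasi-Poisson fit assumes);
- yearly nest counts (Poisson around species-specific linear trends) and a
  yearly vegetation-cover series with a linear +2.7 %/yr trend.

One leading burn-in climate year is always generated so that windows
reaching into the previous calendar year are defined for the first study
year. All randomness flows through one numpy Generator (PCG64) seeded from
the config, so identical configs give identical tables on any platform.
The true parameters are emitted in a manifest so recovery tests can score
against them without re-deriving anything.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import timeseries as ts
from .vegetation import ReflectanceRaster
from .windows import CandidateWindow, window_value_series

DEFAULT_TRUE_WINDOW = CandidateWindow("spei", 12, 3, 0)


@dataclass(frozen=True)
class SpeciesConfig:
    """Abundance process for one species.

    Log-means are on the scale of monthly counts; ``beta`` multiplies the
    true window's value for months falling in ``window_season``;
    ``veg_effect`` multiplies mean-centered percent vegetation cover;
    ``phi`` is the count variance/mean ratio (>= 1).
    """

    name: str
    wintering_log_mean: float
    breeding_log_mean: float
    true_window: CandidateWindow | None = None
    window_season: str = ts.BREEDING
    beta: float = 0.0
    veg_effect: float = 0.0
    phi: float = 3.0
    nest_base: float = 10.0
    nest_slope: float = 0.0

    def __post_init__(self):
        if self.phi < 1.0:
            raise ValueError("phi must be >= 1")
        if self.window_season not in ts.SEASONS:
            raise ValueError(f"unknown season {self.window_season!r}")


def default_species() -> tuple[SpeciesConfig, ...]:
    """Four species spanning the abundance magnitudes of the study design.

    One species carries the true climate signal: a 12-month drought-index
    window ending in March of the focal breeding year with effect 0.446.
    One species responds to vegetation cover instead.
    """
    return (
        SpeciesConfig("A_nyroca", 6.55, 4.43, nest_base=22.0, nest_slope=0.4),
        SpeciesConfig(
            "O_leucocephala", 4.69, 3.32,
            true_window=DEFAULT_TRUE_WINDOW, beta=0.446,
            nest_base=10.0,
        ),
        SpeciesConfig(
            "M_angustirostris", 2.56, 1.06, veg_effect=0.015,
            nest_base=6.0, nest_slope=0.3,
        ),
        SpeciesConfig("P_porphyrio", 2.45, 1.87, nest_base=0.6, nest_slope=0.05),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Full study design: years, species processes, climate and vegetation."""

    n_years: int = 18
    start_year: int = 2002
    lead_years: int = 1
    species: tuple[SpeciesConfig, ...] = field(default_factory=default_species)
    # climate
    mean_annual_temp: float = 18.7
    temp_amplitude: float = 8.0       # degC, peak in August
    temp_noise_sd: float = 1.0
    diurnal_half_range: float = 5.0   # degC between tm and tmin/tmax
    wet_months: tuple[int, ...] = (10, 11, 12, 1, 2)
    wet_gamma: tuple[float, float] = (2.0, 40.0)   # shape, scale (mm)
    dry_gamma: tuple[float, float] = (1.0, 8.0)
    spei_ar1: float = 0.8
    # vegetation cover (percent)
    veg_intercept: float = 30.0
    veg_slope: float = 2.7            # %/yr
    veg_noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.n_years < 2:
            raise ValueError("n_years must be >= 2")
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ValueError("species labels must be unique")

    @property
    def study_years(self) -> range:
        return range(self.start_year, self.start_year + self.n_years)

    @property
    def climate_years(self) -> range:
        return range(self.start_year - self.lead_years, self.start_year + self.n_years)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def generate_climate(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Monthly climate series over the lead + study years.

    Temperatures follow a cosine annual cycle peaking in August; tmin/tmax
    bracket tm by a strictly positive half-range, so the ordering invariant
    holds by construction. Precipitation is gamma-distributed with a wet
    October-February profile. The drought index is an AR(1) series
    standardized over the whole span to mean 0 and sd 1.
    """
    rng = config.rng() if rng is None else rng
    years = np.repeat(list(config.climate_years), 12)
    months = np.tile(np.arange(1, 13), len(config.climate_years))
    n = years.size

    cycle = config.mean_annual_temp + config.temp_amplitude * np.cos(
        2 * np.pi * (months - 8) / 12
    )
    tm = cycle + rng.normal(0, config.temp_noise_sd, n)
    half = np.abs(rng.normal(config.diurnal_half_range, 0.5, n)) + 0.1
    tmin = tm - half
    tmax = tm + half

    wet = np.isin(months, config.wet_months)
    precip = np.where(
        wet,
        rng.gamma(config.wet_gamma[0], config.wet_gamma[1], n),
        rng.gamma(config.dry_gamma[0], config.dry_gamma[1], n),
    )

    innov = rng.normal(0, 1, n)
    spei = np.empty(n)
    spei[0] = innov[0]
    for i in range(1, n):
        spei[i] = config.spei_ar1 * spei[i - 1] + innov[i]
    spei = (spei - spei.mean()) / spei.std()

    df = pd.DataFrame(
        {
            "year": years,
            "month": months,
            "tm": tm,
            "tmin": tmin,
            "tmax": tmax,
            "precip": precip,
            "spei": spei,
        }
    )
    return ts.validate_climate(df)


def generate_vegetation(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Yearly percent cover: linear trend plus noise, clipped to [0, 100]."""
    rng = config.rng() if rng is None else rng
    years = np.array(list(config.study_years))
    cover = (
        config.veg_intercept
        + config.veg_slope * (years - config.start_year)
        + rng.normal(0, config.veg_noise_sd, years.size)
    )
    return pd.DataFrame(
        {"year": years, "percent_cover": np.clip(cover, 0.0, 100.0)}
    )


def _overdispersed_poisson(
    rng: np.random.Generator, mu: np.ndarray, phi: float
) -> np.ndarray:
    """Counts with mean mu and variance phi * mu (gamma-Poisson mixture)."""
    mu = np.asarray(mu, dtype=float)
    if phi <= 1.0:
        return rng.poisson(mu)
    shape = mu / (phi - 1.0)
    lam = rng.gamma(shape, phi - 1.0)
    return rng.poisson(lam)


def generate_counts(
    config: SimulationConfig,
    climate: pd.DataFrame,
    vegetation: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Monthly per-species counts over the study years.

    log mu = seasonal baseline + beta * (true-window value for the month's
    season-year) + veg_effect * centered cover; counts are drawn with
    variance phi * mu. Species without a true window get no climate term.
    """
    rng = config.rng() if rng is None else rng
    veg = vegetation.set_index("year")["percent_cover"]
    veg_centered = veg - veg.mean()

    records = []
    for sp in config.species:
        wvals: dict[int, float] = {}
        if sp.true_window is not None:
            sys_needed = sorted(
                {
                    ts.season_year(y, m)
                    for y in config.study_years
                    for m in range(1, 13)
                    if ts.assign_season(m) == sp.window_season
                }
            )
            vals = window_value_series(
                climate, sp.true_window, sys_needed, sp.window_season
            )
            # a season-year whose span predates the climate series borrows
            # the earliest defined value (leading burn-in year)
            filled = pd.Series(vals, index=sys_needed).bfill().ffill()
            wvals = filled.to_dict()
        for year in config.study_years:
            for month in range(1, 13):
                season = ts.assign_season(month)
                base = (
                    sp.wintering_log_mean
                    if season == ts.WINTERING
                    else sp.breeding_log_mean
                )
                eta = base
                if sp.true_window is not None and season == sp.window_season:
                    eta += sp.beta * wvals[ts.season_year(year, month)]
                if sp.veg_effect != 0.0:
                    eta += sp.veg_effect * float(veg_centered.loc[year])
                mu = np.exp(eta)
                count = int(_overdispersed_poisson(rng, np.array([mu]), sp.phi)[0])
                records.append((sp.name, year, month, count))
    df = pd.DataFrame(records, columns=ts.COUNT_COLUMNS)
    return ts.validate_counts(df)


def generate_nests(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Yearly nest counts per species: Poisson around a linear year trend."""
    rng = config.rng() if rng is None else rng
    records = []
    for sp in config.species:
        for year in config.study_years:
            mean = max(sp.nest_base + sp.nest_slope * (year - config.start_year), 0.05)
            records.append((sp.name, year, int(rng.poisson(mean))))
    return pd.DataFrame(records, columns=ts.NEST_COLUMNS)


def generate_raster(
    year: int,
    true_fraction: float,
    shape: tuple[int, int] = (60, 60),
    seed: int = 0,
) -> tuple[ReflectanceRaster, float]:
    """A reflectance raster with a planted fraction of vegetated pixels.

    Among interior (masked) pixels, round(true_fraction * n) pixels get an
    NDVI drawn above 0.3 and the rest below 0.1; border pixels are outside
    the mask. Returns the raster and the exactly realized fraction.
    """
    if not 0.0 <= true_fraction <= 1.0:
        raise ValueError("true_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    mask = np.zeros(shape, dtype=bool)
    mask[1:-1, 1:-1] = True
    n = int(mask.sum())
    n_veg = int(round(true_fraction * n))
    target = np.empty(n)
    target[:n_veg] = rng.uniform(0.35, 0.85, n_veg)
    target[n_veg:] = rng.uniform(-0.05, 0.08, n - n_veg)
    rng.shuffle(target)

    red = np.full(shape, 0.2)
    nir = np.full(shape, 0.2)
    # invert NDVI = (nir - red)/(nir + red) at fixed red
    nir[mask] = red[mask] * (1 + target) / (1 - target)
    raster = ReflectanceRaster(nir=nir, red=red, mask=mask, year=int(year))
    return raster, n_veg / n


def manifest(config: SimulationConfig) -> dict:
    """True parameters as a plain dict (YAML-serializable sidecar)."""
    out = asdict(config)
    out["species"] = []
    for sp in config.species:
        d = asdict(sp)
        if sp.true_window is not None:
            d["true_window"] = {
                "variable": sp.true_window.variable,
                "duration": sp.true_window.duration,
                "end_month": sp.true_window.end_month,
                "year_offset": sp.true_window.year_offset,
            }
        out["species"].append(d)
    return out


def write_manifest(config: SimulationConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest(config), fh, sort_keys=False)
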