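"""End-to-end orchestration: trends, window scan, variable selection, GLMs.

The full analysis runs, in order:

1. linear year-trend fits for each climate variable (annual mean, or annual
   sum for precipitation) and for vegetation cover;
2. the species-difference likelihood-ratio test on monthly counts;
3. per-species seasonal trend GLMs (quasi-Poisson, linear and quadratic
   year) on monthly counts;
4. the best-window Spearman scan per species x season x climatic variable
   and selection of the best variable;
5. a collinearity (VIF) screen and the additive climate + vegetation
   quasi-Poisson model per species x season, using the windows selected in
   step 4 (the GLM stage never re-scans).

Outputs are a pure function of (inputs, config, seed); report tables are
written as CSV next to a plain-text run log.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, glm, io, simulate, windows
from . import timeseries as ts
from .errors import AviclimError


@dataclass
class AnalysisReport:
    """All report tables plus run metadata and per-stage errors."""

    trend_table: pd.DataFrame | None = None
    lr_table: pd.DataFrame | None = None
    seasonal_trend_table: pd.DataFrame | None = None
    best_window_table: pd.DataFrame | None = None
    glm_table: pd.DataFrame | None = None
    vif_table: pd.DataFrame | None = None
    metadata: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)
    log_lines: list = field(default_factory=list)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tables = {
            "trends.csv": self.trend_table,
            "species_lr_test.csv": self.lr_table,
            "seasonal_trends.csv": self.seasonal_trend_table,
            "best_windows.csv": self.best_window_table,
            "glm_summary.csv": self.glm_table,
            "vif.csv": self.vif_table,
        }
        for name, table in tables.items():
            if table is not None:
                table.to_csv(outdir / name, index=False, encoding="utf-8")
        with open(outdir / "run_log.txt", "w", encoding="utf-8") as fh:
            fh.write("\n".join(self.log_lines) + "\n")
        with open(outdir / "metadata.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.metadata, fh, sort_keys=False)


def load_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    if "inputs" not in cfg and "synthetic" not in cfg:
        raise ValueError("config needs an 'inputs' or a 'synthetic' section")
    return cfg


def _load_inputs(cfg: dict):
    if "inputs" in cfg:
        paths = cfg["inputs"]
        for key in ("climate", "counts"):
            if key not in paths:
                raise FileNotFoundError(f"config inputs missing required {key!r} file")
        climate = io.read_climate(paths["climate"])
        counts = io.read_counts(paths["counts"])
        nests = io.read_nests(paths["nests"]) if "nests" in paths else None
        cover = io.read_cover(paths["cover"]) if "cover" in paths else None
        return climate, counts, nests, cover
    syn = dict(cfg.get("synthetic") or {})
    sim_cfg = simulate.SimulationConfig(
        n_years=int(syn.get("n_years", 18)),
        start_year=int(syn.get("start_year", 2002)),
        seed=int(syn.get("seed", 0)),
    )
    rng = sim_cfg.rng()
    climate = simulate.generate_climate(sim_cfg, rng)
    cover = simulate.generate_vegetation(sim_cfg, rng)
    counts = simulate.generate_counts(sim_cfg, climate, cover, rng)
    nests = simulate.generate_nests(sim_cfg, rng)
    return climate, counts, nests, cover


def _annual_climate(climate: pd.DataFrame, variable: str) -> pd.DataFrame:
    agg = "sum" if variable == "precip" else "mean"
    return climate.groupby("year")[variable].agg(agg).reset_index()


def run_full_analysis(config_path) -> AnalysisReport:
    """Execute every stage; stage failures are recorded, not fatal.

    ``config_path`` is a YAML file naming input CSVs (climate, counts,
    optionally nests and cover) or requesting synthetic generation with a
    seed.
    """
    cfg = load_config(config_path)
    report = AnalysisReport()
    t0 = time.time()

    def log(msg: str) -> None:
        report.log_lines.append(f"[{time.time() - t0:7.2f}s] {msg}")

    climate, counts, nests, cover = _load_inputs(cfg)
    log(
        f"inputs loaded: {len(climate)} climate rows, {len(counts)} count rows"
        + (f", {len(nests)} nest rows" if nests is not None else "")
        + (f", {len(cover)} cover rows" if cover is not None else "")
    )
    species_list = sorted(counts["species"].unique())
    study_years = sorted(
        set(counts["year"].unique())
    )
    duplicate_anchors = str(cfg.get("window_variant", "standard")) == "duplicate_year_anchors"

    with open(config_path, "rb") as fh:
        cfg_hash = hashlib.sha256(fh.read()).hexdigest()[:16]
    report.metadata = {
        "package_version": __version__,
        "config_hash": cfg_hash,
        "seed": (cfg.get("synthetic") or {}).get("seed"),
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "species": species_list,
        "window_variant": "duplicate_year_anchors" if duplicate_anchors else "standard",
        "scan_caveat": (
            "best-window p-values are the maximum of 144 correlations per "
            "variable and are not adjusted for selection"
        ),
    }

    # --- stage 1: climate and vegetation trends -------------------------
    try:
        rows = []
        for var in ts.CLIMATE_VARIABLES:
            yearly = _annual_climate(climate[climate["year"].isin(study_years)], var)
            for quad in (False, True):
                tr = glm.fit_trend(yearly["year"], yearly[var], glm.GAUSSIAN, quad)
                rows.append(
                    {
                        "response": var,
                        "quadratic": quad,
                        "slope": tr.slope,
                        "t": tr.t_statistic,
                        "p": tr.p_value,
                        "quad_coef": tr.quad_coef,
                        "quad_t": tr.quad_t,
                        "quad_p": tr.quad_p,
                    }
                )
        if cover is not None:
            for quad in (False, True):
                tr = glm.fit_trend(
                    cover["year"], cover["percent_cover"], glm.GAUSSIAN, quad
                )
                rows.append(
                    {
                        "response": "vegetation_cover",
                        "quadratic": quad,
                        "slope": tr.slope,
                        "t": tr.t_statistic,
                        "p": tr.p_value,
                        "quad_coef": tr.quad_coef,
                        "quad_t": tr.quad_t,
                        "quad_p": tr.quad_p,
                    }
                )
        report.trend_table = pd.DataFrame(rows)
        log("stage trends: done")
    except Exception as exc:  # noqa: BLE001 - stage isolation
        report.errors["trends"] = repr(exc)
        log(f"stage trends FAILED: {exc!r}")

    # --- stage 2: species-difference LR test ----------------------------
    try:
        chi2, df, p, f_stat, p_f = glm.likelihood_ratio_species_test(counts)
        report.lr_table = pd.DataFrame(
            [
                {
                    "test": "species_difference",
                    "chi2": chi2,
                    "df": df,
                    "p_chi2": p,
                    "F": f_stat,
                    "p_F": p_f,
                }
            ]
        )
        log(f"stage species LR test: chi2={chi2:.1f}, df={df}")
    except Exception as exc:  # noqa: BLE001
        report.errors["species_lr"] = repr(exc)
        log(f"stage species LR test FAILED: {exc!r}")

    # --- stage 3: per-species seasonal trend GLMs -----------------------
    try:
        rows = []
        monthly = counts.copy()
        monthly["season"] = monthly["month"].map(ts.assign_season)
        monthly["season_year"] = [
            ts.season_year(y, m) for y, m in zip(monthly["year"], monthly["month"])
        ]
        for sp in species_list:
            for season in ts.SEASONS:
                sub = monthly[
                    (monthly["species"] == sp) & (monthly["season"] == season)
                ]
                for quad in (False, True):
                    tr = glm.fit_trend(
                        sub["season_year"], sub["count"], glm.QUASIPOISSON, quad
                    )
                    rows.append(
                        {
                            "species": sp,
                            "season": season,
                            "quadratic": quad,
                            "slope": tr.slope,
                            "t": tr.t_statistic,
                            "p": tr.p_value,
                            "quad_coef": tr.quad_coef,
                            "quad_t": tr.quad_t,
                            "quad_p": tr.quad_p,
                            "dispersion": tr.fit.dispersion,
                        }
                    )
        if nests is not None:
            for sp in species_list:
                sub = nests[nests["species"] == sp]
                if sub.empty or sub["n_nests"].sum() == 0:
                    rows.append(
                        {
                            "species": sp, "season": "nests", "quadratic": False,
                            "slope": np.nan, "t": np.nan, "p": np.nan,
                            "quad_coef": np.nan, "quad_t": np.nan,
                            "quad_p": np.nan, "dispersion": np.nan,
                        }
                    )
                    continue
                for quad in (False, True):
                    tr = glm.fit_trend(
                        sub["year"], sub["n_nests"], glm.QUASIPOISSON, quad
                    )
                    rows.append(
                        {
                            "species": sp,
                            "season": "nests",
                            "quadratic": quad,
                            "slope": tr.slope,
                            "t": tr.t_statistic,
                            "p": tr.p_value,
                            "quad_coef": tr.quad_coef,
                            "quad_t": tr.quad_t,
                            "quad_p": tr.quad_p,
                            "dispersion": tr.fit.dispersion,
                        }
                    )
        report.seasonal_trend_table = pd.DataFrame(rows)
        log("stage seasonal trends: done")
    except Exception as exc:  # noqa: BLE001
        report.errors["seasonal_trends"] = repr(exc)
        log(f"stage seasonal trends FAILED: {exc!r}")

    # --- stage 4: window scan + variable selection ----------------------
    selected: dict[tuple[str, str], windows.WindowScanResult] = {}
    try:
        for season in ts.SEASONS:
            abund = ts.seasonal_abundance(counts, season, drop_incomplete=True)
            for sp in species_list:
                sub = abund[abund["species"] == sp]
                per_var = []
                for var in ts.CLIMATE_VARIABLES:
                    try:
                        per_var.append(
                            windows.scan_best_window(
                                sub,
                                climate,
                                var,
                                season=season,
                                duplicate_year_anchors=duplicate_anchors,
                            )
                        )
                    except AviclimError as exc:
                        log(f"scan {sp}/{season}/{var} skipped: {exc}")
                best = windows.select_best_variable(per_var)
                selected[(sp, season)] = best
        report.best_window_table = windows.scan_table(
            [selected[k] for k in sorted(selected)]
        )
        report.metadata["n_candidates_per_variable"] = len(
            windows.enumerate_windows(
                "spei", duplicate_year_anchors=duplicate_anchors
            )
        )
        log(f"stage window scan: {len(selected)} species x season rows")
    except Exception as exc:  # noqa: BLE001
        report.errors["window_scan"] = repr(exc)
        log(f"stage window scan FAILED: {exc!r}")

    # --- stage 5: additive climate + vegetation GLMs --------------------
    try:
        glm_rows = []
        vif_rows = []
        monthly = counts.copy()
        monthly["season"] = monthly["month"].map(ts.assign_season)
        monthly["season_year"] = [
            ts.season_year(y, m) for y, m in zip(monthly["year"], monthly["month"])
        ]
        include_veg = bool(cfg.get("include_vegetation", True)) and cover is not None
        cover_by_year = (
            cover.set_index("year")["percent_cover"] if cover is not None else None
        )
        for (sp, season), best in sorted(selected.items()):
            sub = monthly[
                (monthly["species"] == sp) & (monthly["season"] == season)
            ].copy()
            sys_ = sorted(sub["season_year"].unique())
            wv = windows.window_value_series(climate, best.window, sys_, season)
            wmap = dict(zip(sys_, wv))
            sub["climate_value"] = sub["season_year"].map(wmap)
            if include_veg:
                sub["veg"] = sub["season_year"].map(cover_by_year)
            sub = sub.dropna(subset=["climate_value"] + (["veg"] if include_veg else []))
            fit, vifs = glm.fit_climate_vegetation_model(
                sub["count"],
                sub["climate_value"],
                sub["veg"] if include_veg else None,
            )
            frame = fit.summary_frame()
            frame.insert(0, "Species", sp)
            frame.insert(1, "Season", season)
            frame["Term"] = frame["Term"].replace(
                {"climate": f"Climate [{best.variable}]", "vegetation": "Vegetation"}
            )
            glm_rows.append(frame)
            if vifs is not None:
                for term, value in vifs.items():
                    vif_rows.append(
                        {"species": sp, "season": season, "term": term, "vif": value}
                    )
        report.glm_table = (
            pd.concat(glm_rows, ignore_index=True) if glm_rows else None
        )
        report.vif_table = pd.DataFrame(vif_rows) if vif_rows else None
        log("stage additive GLMs: done")
    except Exception as exc:  # noqa: BLE001
        report.errors["glm"] = repr(exc)
        log(f"stage additive GLMs FAILED: {exc!r}")

    log("analysis complete")
    return report
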