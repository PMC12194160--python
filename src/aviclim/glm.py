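"""Quasi-Poisson and Gaussian model fitting plus the supporting test battery.

The workhorse is a log-link quasi-Poisson GLM: point estimates are the
Poisson maximum-likelihood estimates, and standard errors are inflated by
sqrt(phi) where phi is the Pearson chi-square dispersion X^2 / (n - p).
Inference uses t statistics on the residual degrees of freedom, with Wald
t-based 95% confidence intervals.

Also provided: the Cameron-Trivedi overdispersion test (the auxiliary
regression behind AER-style dispersion testing), a Poisson likelihood-ratio
test for species differences (with a dispersion-scaled F variant, since a
quasi-likelihood has no true likelihood ratio), linear/quadratic year-trend
fits, the additive climate + vegetation abundance model, and variance
inflation factors for collinearity screening.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import gammaln

from .errors import ConvergenceError, SingularDesignError

QUASIPOISSON = "quasipoisson"
GAUSSIAN = "gaussian"

IRLS_TOL = 1e-8
IRLS_MAXITER = 100


@dataclass(frozen=True)
class GlmFit:
    """Coefficients and inference for one fitted model."""

    family: str
    terms: tuple[str, ...]
    coefficients: np.ndarray
    std_errors: np.ndarray
    statistics: np.ndarray  # t on df_residual
    p_values: np.ndarray
    conf_lower: np.ndarray
    conf_upper: np.ndarray
    dispersion: float
    n_obs: int
    df_residual: int
    deviance: float
    loglik_poisson: float  # Poisson log-likelihood at phi = 1 (NaN for gaussian)

    def coef(self, term: str) -> float:
        return float(self.coefficients[self.terms.index(term)])

    def ci(self, term: str) -> tuple[float, float]:
        i = self.terms.index(term)
        return float(self.conf_lower[i]), float(self.conf_upper[i])

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Term": self.terms,
                "Estimate": self.coefficients,
                "LCI": self.conf_lower,
                "UCI": self.conf_upper,
                "Std. Error": self.std_errors,
                "Statistic": self.statistics,
                "p": self.p_values,
            }
        )


@dataclass(frozen=True)
class TrendResult:
    """Linear (optionally quadratic) year-trend fit for a yearly series."""

    family: str
    slope: float
    slope_se: float
    t_statistic: float
    p_value: float
    quadratic: bool
    quad_coef: float
    quad_t: float
    quad_p: float
    year_center: float
    fit: GlmFit


def _check_design(X: np.ndarray, n_obs: int) -> None:
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if n_obs <= X.shape[1]:
        raise ValueError("need more observations than predictors")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularDesignError("design matrix is rank deficient")


def poisson_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    """Poisson log-likelihood sum(y log mu - mu - log y!)."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(mu), 0.0)
    return float(np.sum(term - mu - gammaln(y + 1)))


def fit_quasipoisson(y, X, terms=None) -> GlmFit:
    """Log-link quasi-Poisson GLM fit by IRLS.

    Point estimates equal the Poisson MLE; standard errors are Poisson SEs
    times sqrt(phi) with phi = Pearson X^2/(n - p); t statistics and 95%
    Wald intervals use n - p degrees of freedom.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise ValueError("y must be non-negative integer counts")
    _check_design(X, y.size)
    if terms is None:
        terms = tuple(f"x{i}" for i in range(X.shape[1]))
    terms = tuple(terms)

    model = sm.GLM(y, X, family=sm.families.Poisson())
    with warnings.catch_warnings():
        # a deviance of ~0 (counts fitted exactly) is benign for log-linear
        # count models, not true separation
        warnings.filterwarnings("ignore", message="Perfect separation")
        res = model.fit(maxiter=IRLS_MAXITER, tol=IRLS_TOL)
    if not res.converged:
        raise ConvergenceError(
            f"IRLS did not converge in {IRLS_MAXITER} iterations"
        )
    df_resid = int(y.size - X.shape[1])
    phi = float(res.pearson_chi2) / df_resid
    if phi <= 0:
        warnings.warn(
            "zero Pearson dispersion (degenerate counts); flooring phi",
            stacklevel=2,
        )
        phi = np.finfo(float).tiny
    # quasi-Poisson: Poisson MLE point estimates, SEs inflated by sqrt(phi)
    se = np.asarray(res.bse, dtype=float) * np.sqrt(phi)
    coef = np.asarray(res.params, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, coef / se, 0.0)
    pvals = 2 * stats.t.sf(np.abs(tvals), df_resid)
    tq = stats.t.ppf(0.975, df_resid)
    return GlmFit(
        family=QUASIPOISSON,
        terms=terms,
        coefficients=coef,
        std_errors=se,
        statistics=tvals,
        p_values=pvals,
        conf_lower=coef - tq * se,
        conf_upper=coef + tq * se,
        dispersion=phi,
        n_obs=int(y.size),
        df_residual=df_resid,
        deviance=float(res.deviance),
        loglik_poisson=poisson_loglik(y, res.fittedvalues),
    )


def fit_gaussian(y, X, terms=None) -> GlmFit:
    """Ordinary least squares packaged in the same result container."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    _check_design(X, y.size)
    if terms is None:
        terms = tuple(f"x{i}" for i in range(X.shape[1]))
    res = sm.OLS(y, X).fit()
    ci = res.conf_int()
    coef = np.asarray(res.params, dtype=float)
    se = np.asarray(res.bse, dtype=float)
    # a flat series fits exactly up to rounding: report t = 0, p = 1 for
    # its zero coefficients instead of a 0/0 artifact
    tvals = np.asarray(res.tvalues, dtype=float)
    pvals = np.asarray(res.pvalues, dtype=float)
    scale = max(1.0, float(np.abs(y).max()))
    degenerate = (se <= 1e-12 * scale) & (np.abs(coef) <= 1e-10 * scale)
    tvals = np.where(degenerate, 0.0, tvals)
    pvals = np.where(degenerate, 1.0, pvals)
    return GlmFit(
        family=GAUSSIAN,
        terms=tuple(terms),
        coefficients=coef,
        std_errors=se,
        statistics=tvals,
        p_values=pvals,
        conf_lower=np.asarray(ci, dtype=float)[:, 0],
        conf_upper=np.asarray(ci, dtype=float)[:, 1],
        dispersion=float(res.mse_resid),
        n_obs=int(y.size),
        df_residual=int(res.df_resid),
        deviance=float(res.ssr),
        loglik_poisson=float("nan"),
    )


def overdispersion_test(y, X) -> tuple[float, float, float]:
    """Cameron-Trivedi test of Var(y) = (1 + alpha) mu against the Poisson.

    Fits the Poisson model, then regresses ((y - mu)^2 - y)/mu on mu without
    an intercept; the one-sided z test of the slope alpha > 0 detects
    overdispersion under a variance linear in the mean.

    Returns (z statistic, one-sided p-value, alpha estimate).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    _check_design(X, y.size)
    res = sm.GLM(y, X, family=sm.families.Poisson()).fit(
        maxiter=IRLS_MAXITER, tol=IRLS_TOL
    )
    mu = np.asarray(res.fittedvalues, dtype=float)
    aux = ((y - mu) ** 2 - y) / mu
    aux_fit = sm.OLS(aux, mu).fit()
    alpha = float(aux_fit.params[0])
    z = float(aux_fit.params[0] / aux_fit.bse[0])
    p = float(stats.norm.sf(z))
    return z, p, alpha


def likelihood_ratio_species_test(
    counts: pd.DataFrame,
) -> tuple[float, int, float, float, float]:
    """Do species differ in abundance? Poisson LR test plus an F variant.

    Compares a count ~ species model against the intercept-only null using
    the Poisson log-likelihood (what an lrtest on quasi-Poisson fits
    computes numerically; a quasi-likelihood has no true LR, hence the
    dispersion-scaled F statistic is reported alongside).

    Returns (chi2, df, p_chi2, F, p_F).
    """
    species = pd.Categorical(counts["species"])
    k = len(species.categories)
    if k < 2:
        raise ValueError("need at least two species")
    y = counts["count"].to_numpy(dtype=float)
    X1 = np.column_stack(
        [np.ones(y.size)]
        + [(species.codes == c).astype(float) for c in range(1, k)]
    )
    X0 = np.ones((y.size, 1))
    full = fit_quasipoisson(y, X1)
    null = fit_quasipoisson(y, X0)
    chi2 = 2 * (full.loglik_poisson - null.loglik_poisson)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    f_stat = (chi2 / df) / full.dispersion
    p_f = float(stats.f.sf(f_stat, df, full.df_residual))
    return float(chi2), df, p, float(f_stat), p_f


def fit_trend(
    years,
    values,
    family: str = GAUSSIAN,
    quadratic: bool = False,
) -> TrendResult:
    """Trend of a yearly series on (centered) year, optionally quadratic.

    Gaussian OLS for climate and vegetation responses, quasi-Poisson for
    count responses. Year is centered at its mean before squaring so the
    linear and quadratic terms are near-orthogonal.
    """
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    n_params = 3 if quadratic else 2
    if len(np.unique(years)) < n_params + 1:
        raise ValueError("too few distinct years for the requested trend")
    center = float(years.mean())
    yc = years - center
    cols = [np.ones_like(yc), yc] + ([yc**2] if quadratic else [])
    terms = ["intercept", "year"] + (["year2"] if quadratic else [])
    X = np.column_stack(cols)
    if family == GAUSSIAN:
        fit = fit_gaussian(values, X, terms)
    elif family == QUASIPOISSON:
        fit = fit_quasipoisson(values, X, terms)
    else:
        raise ValueError(f"unknown family {family!r}")
    i = terms.index("year")
    qi = terms.index("year2") if quadratic else None
    return TrendResult(
        family=family,
        slope=float(fit.coefficients[i]),
        slope_se=float(fit.std_errors[i]),
        t_statistic=float(fit.statistics[i]),
        p_value=float(fit.p_values[i]),
        quadratic=quadratic,
        quad_coef=float(fit.coefficients[qi]) if quadratic else float("nan"),
        quad_t=float(fit.statistics[qi]) if quadratic else float("nan"),
        quad_p=float(fit.p_values[qi]) if quadratic else float("nan"),
        year_center=center,
        fit=fit,
    )


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per predictor: 1/(1 - R^2_j).

    Each predictor is regressed (with an intercept) on the remaining ones.
    Perfect collinearity yields +inf with a warning.
    """
    X = pd.DataFrame(X)
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least two predictors")
    out = {}
    for col in X.columns:
        others = X.drop(columns=[col]).to_numpy(dtype=float)
        design = np.column_stack([np.ones(len(X)), others])
        target = X[col].to_numpy(dtype=float)
        r2 = sm.OLS(target, design).fit().rsquared
        if r2 >= 1.0 - 1e-12:
            warnings.warn(f"predictor {col!r} perfectly collinear", stacklevel=2)
            out[col] = float("inf")
        else:
            out[col] = 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def fit_climate_vegetation_model(
    counts,
    climate_values,
    vegetation_cover=None,
) -> tuple[GlmFit, pd.Series | None]:
    """Additive quasi-Poisson model: count ~ climate (+ vegetation).

    ``climate_values`` is the selected best-window value aligned to each
    count; ``vegetation_cover`` (percent) may be omitted for the
    climate-only variant. Returns the fit and the predictors' VIFs (None
    when only one predictor is present).
    """
    y = np.asarray(counts, dtype=float)
    climate_values = np.asarray(climate_values, dtype=float)
    cols = {"climate": climate_values}
    if vegetation_cover is not None:
        cols["vegetation"] = np.asarray(vegetation_cover, dtype=float)
    pred = pd.DataFrame(cols)
    vifs = vif(pred) if pred.shape[1] >= 2 else None
    if vifs is not None and np.isinf(vifs).any():
        raise SingularDesignError("perfectly collinear climate/vegetation")
    X = np.column_stack([np.ones(y.size)] + [pred[c] for c in pred.columns])
    used_terms = ("intercept",) + tuple(pred.columns)
    fit = fit_quasipoisson(y, X, used_terms)
    return fit, vifs
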