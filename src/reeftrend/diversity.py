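"""Community diversity indices and their trends against the baseline bin.

Per-sample species richness S, Shannon-Weiner diversity H' (natural log) and
Pielou evenness J' = H'/ln S are computed from the density matrix.  Temporal
change in each index is tested with a linear mixed model — year bin as a
fixed factor, site as a random intercept, optional z-scored depth/longitude
covariates — followed by Dunnett many-to-one comparisons of every bin
against the pre-disturbance baseline.

The Dunnett adjustment is computed from the joint multivariate-t
distribution of the contrast statistics (correlation taken from the fitted
model's covariance), evaluated by scrambled-Sobol quasi-Monte Carlo with a
fixed seed; it is shared with the delta-index sub-model contrasts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc
import statsmodels.api as sm

from .survey_io import PRE_BIN, CommunityMatrix, zscored_covariates
from .synthetic import year_bin_order

logger = logging.getLogger("reeftrend")


# ---------------------------------------------------------------------------
# indices
# ---------------------------------------------------------------------------

def indices(matrix: CommunityMatrix) -> pd.DataFrame:
    """Per-sample S, H', J' and total density.

    H' uses natural logs; J' is missing (NaN) for samples with fewer than
    two taxa, where evenness is undefined.
    """
    x = matrix.densities.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("negative densities")
    total = x.sum(axis=1)
    s = (x > 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(total[:, None] > 0, x / np.where(total[:, None] > 0, total[:, None], 1.0), 0.0)
        plogp = np.where(p > 0, p * np.log(p), 0.0)
        h = -plogp.sum(axis=1)
        j = np.where(s >= 2, h / np.where(s >= 2, np.log(np.maximum(s, 2)), 1.0), np.nan)
    return pd.DataFrame({"S": s, "H": h, "J": j, "total_density": total},
                        index=matrix.densities.index)


# ---------------------------------------------------------------------------
# linear mixed model trend fit
# ---------------------------------------------------------------------------

@dataclass
class TrendFit:
    """REML mixed-model fit of one index against year bin.

    ``estimates``/``se`` are adjusted per-bin means at covariate z = 0;
    ``contrasts`` are bin-minus-reference estimates with their joint
    covariance, which is what the Dunnett step consumes.
    """

    response: str
    reference: str
    bins: list[str]
    estimates: pd.Series
    se: pd.Series
    contrasts: pd.Series
    contrast_cov: pd.DataFrame
    df_resid: float
    site_sd: float
    resid_sd: float
    boundary: bool
    log_response: bool = False
    n_obs: int = 0
    extra: dict = field(default_factory=dict)


def _fit_mixedlm(y: np.ndarray, X: np.ndarray, groups: np.ndarray):
    """REML MixedLM fit with an optimizer fallback for hard cases."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=groups)
        try:
            return model.fit(reml=True)
        except np.linalg.LinAlgError:
            return model.fit(reml=True, method="powell")


def _design(meta: pd.DataFrame, reference: str, covariates: bool):
    bins = year_bin_order(meta["year_bin"].astype(str).unique())
    if reference not in bins:
        raise ValueError(f"reference bin {reference!r} absent from data")
    others = [b for b in bins if b != reference]
    X = pd.DataFrame({"Intercept": 1.0}, index=meta.index)
    for b in others:
        X[f"bin[{b}]"] = (meta["year_bin"].astype(str) == b).astype(float)
    if covariates:
        z = zscored_covariates(meta)
        X["depth_z"] = z["depth_z"]
        X["lon_z"] = z["lon_z"]
    return X, bins, others


def trend_lmm(values: pd.Series, meta: pd.DataFrame,
              reference: str = PRE_BIN,
              covariates: bool = True,
              log_response: bool = False,
              response_name: str = "index") -> TrendFit:
    """Fit index ~ year_bin + depth_z + lon_z + (1 | site) by REML.

    Rows with missing values are dropped.  With ``log_response`` the model
    is fit to ln(values); estimates stay on the log scale (back-transform at
    reporting time).  A site variance estimated at (numerically) zero is
    retained but flagged as a boundary fit.
    """
    y = pd.Series(values).astype(float)
    keep = y.notna()
    if log_response:
        if (y[keep] <= 0).any():
            raise ValueError("log_response requires strictly positive values")
        y = np.log(y)
    y, meta = y[keep], meta.loc[keep]
    if meta["site"].nunique() < 2:
        raise ValueError("trend model needs at least 2 sites")
    X, bins, others = _design(meta, reference, covariates)

    result = _fit_mixedlm(y.to_numpy(), X.to_numpy(), meta["site"].to_numpy())
    beta = pd.Series(result.fe_params, index=X.columns)
    cov = pd.DataFrame(result.cov_params()[:len(X.columns), :len(X.columns)],
                       index=X.columns, columns=X.columns)

    # adjusted means at z = 0: L beta with L = intercept (+ bin dummy)
    est, se = {}, {}
    for b in bins:
        L = np.zeros(len(X.columns))
        L[0] = 1.0
        if b != reference:
            L[X.columns.get_loc(f"bin[{b}]")] = 1.0
        est[b] = float(L @ beta.to_numpy())
        se[b] = float(np.sqrt(L @ cov.to_numpy() @ L))

    cnames = [f"bin[{b}]" for b in others]
    contrasts = beta[cnames]
    contrasts.index = others
    ccov = cov.loc[cnames, cnames]
    ccov.index = ccov.columns = others

    sigma2_site = float(np.asarray(result.cov_re).ravel()[0]) if result.k_re else 0.0
    boundary = sigma2_site < 1e-8
    if boundary:
        logger.info("trend fit for %s: site variance at boundary (~0)", response_name)
    df_resid = max(len(y) - X.shape[1] - meta["site"].nunique() + 1, 2)
    return TrendFit(
        response=response_name, reference=reference, bins=bins,
        estimates=pd.Series(est), se=pd.Series(se),
        contrasts=contrasts, contrast_cov=ccov,
        df_resid=float(df_resid),
        site_sd=float(np.sqrt(max(sigma2_site, 0.0))),
        resid_sd=float(np.sqrt(result.scale)),
        boundary=boundary, log_response=log_response, n_obs=int(len(y)),
    )


# ---------------------------------------------------------------------------
# Dunnett many-to-one comparisons
# ---------------------------------------------------------------------------

def _corr_from_cov(cov: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.clip(np.diag(cov), 1e-300, None))
    r = cov / np.outer(d, d)
    r = np.nan_to_num(r, nan=0.0, posinf=0.0, neginf=0.0)
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def _max_abs_t_sample(corr: np.ndarray, df: float, seed: int,
                      log2_n: int = 13) -> np.ndarray:
    """QMC sample of max_j |T_j| for T multivariate-t(corr, df)."""
    k = corr.shape[0]
    w, v = np.linalg.eigh(corr)
    L = v * np.sqrt(np.clip(w, 0.0, None))
    sob = qmc.Sobol(d=k + 1, scramble=True, seed=int(seed))
    u = np.clip(sob.random_base2(m=log2_n), 1e-12, 1 - 1e-12)
    z = stats.norm.ppf(u[:, :k]) @ L.T
    if np.isfinite(df):
        s = np.sqrt(stats.chi2.ppf(u[:, k], df) / df)
        z = z / s[:, None]
    return np.abs(z).max(axis=1)


def dunnett_pvalues(t_stats: np.ndarray, corr: np.ndarray, df: float,
                    seed: int = 0, log2_n: int = 13):
    """Two-sided Dunnett-adjusted p-values for many-to-one contrasts.

    Returns ``(p_adjusted, critical)`` where ``critical`` is the 95%
    simultaneous critical value of max|T|.  Adjusted p-values are never
    smaller than the raw two-sided t p-values.
    """
    t_stats = np.atleast_1d(np.asarray(t_stats, dtype=float))
    raw = 2 * stats.t.sf(np.abs(t_stats), df) if np.isfinite(df) \
        else 2 * stats.norm.sf(np.abs(t_stats))
    if len(t_stats) == 1:
        crit = stats.t.ppf(0.975, df) if np.isfinite(df) else stats.norm.ppf(0.975)
        return raw, float(crit)
    maxabs = _max_abs_t_sample(np.asarray(corr, dtype=float), df, seed, log2_n)
    p_adj = np.array([(maxabs >= abs(t)).mean() for t in t_stats])
    p_adj = np.maximum(p_adj, raw)
    return np.minimum(p_adj, 1.0), float(np.quantile(maxabs, 0.95))


def dunnett(fit: TrendFit, seed: int = 0, log2_n: int = 13) -> pd.DataFrame:
    """Dunnett comparisons of every bin against the fit's reference bin.

    Returns one row per non-reference bin: contrast estimate, SE, t, raw and
    adjusted p, and simultaneous 95% confidence limits.
    """
    est = fit.contrasts.to_numpy()
    se = np.sqrt(np.diag(fit.contrast_cov.to_numpy()))
    t = est / se
    corr = _corr_from_cov(fit.contrast_cov.to_numpy())
    p_adj, crit = dunnett_pvalues(t, corr, fit.df_resid, seed=seed, log2_n=log2_n)
    raw = 2 * stats.t.sf(np.abs(t), fit.df_resid)
    return pd.DataFrame({
        "bin": fit.contrasts.index,
        "estimate": est, "se": se, "t": t,
        "p_raw": raw, "p_dunnett": p_adj,
        "ci_lo": est - crit * se, "ci_hi": est + crit * se,
    }).set_index("bin")


def trend_summary(matrix: CommunityMatrix, covariates: bool = True,
                  reference: str = PRE_BIN, seed: int = 0) -> pd.DataFrame:
    """Indices + trend tests for S, H, J and log total density in one table."""
    idx = indices(matrix)
    rows = []
    specs = [("S", False), ("H", False), ("J", False), ("total_density", True)]
    for name, logr in specs:
        vals = idx[name]
        if logr:
            vals = vals.where(vals > 0)
        fit = trend_lmm(vals, matrix.meta, reference=reference,
                        covariates=covariates, log_response=logr,
                        response_name=name)
        dn = dunnett(fit, seed=seed)
        for b in fit.bins:
            row = {"response": name, "bin": b,
                   "estimate": fit.estimates[b], "se": fit.se[b],
                   "log_scale": logr, "boundary": fit.boundary}
            if b != reference:
                row.update(p_raw=dn.loc[b, "p_raw"], p_dunnett=dn.loc[b, "p_dunnett"])
            rows.append(row)
    return pd.DataFrame(rows)
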