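"""Environmental association of morph frequency with spatial GLS.

Per-grid-cell morph frequencies (by default the dominant dark-background
class at the B locus) are regressed on abiotic covariates — annual mean
temperature (bio01), solar radiation (bio20), annual precipitation (bio12)
and soil moisture index (bio28) — using generalized least squares whose
residual correlation decays exponentially with the Euclidean distance
between cell centres, corr(e_i, e_j) = exp(-d_ij / rho), and whose variance
weights are the inverse of the number of records per cell. All 2^4 covariate
subsets (15 models plus a null) are compared by AIC, alongside weighted
correlation / regression screens and VIF collinearity diagnostics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg, optimize, stats
from sklearn.base import BaseEstimator

COVARIATES = ("bio01", "bio20", "bio12", "bio28")

ENV_COLUMNS = [
    "lon_idx", "lat_idx", "y", "n_records",
    "bio01", "bio20", "bio12", "bio28", "centre_lon", "centre_lat",
]


def validate_env_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ENV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"env table missing column(s): {missing}")
    if (df["n_records"] < 1).any():
        raise ValueError("each cell needs at least one record")
    if ((df["y"] < 0) | (df["y"] > 1)).any():
        raise ValueError("morph frequency must lie in [0, 1]")
    return df


# ---------------------------------------------------------------------------
# screens


def weighted_pearson(x, y, w=None):
    """Weighted moment correlation with a t-approximation p-value (df = n-2)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    w = np.ones_like(x) if w is None else np.asarray(w, float)
    if np.any(w < 0) or not np.any(w > 0):
        raise ValueError("weights must be non-negative and not all zero")
    w = w / w.sum()
    mx, my = np.sum(w * x), np.sum(w * y)
    cov = np.sum(w * (x - mx) * (y - my))
    vx = np.sum(w * (x - mx) ** 2)
    vy = np.sum(w * (y - my) ** 2)
    if vx == 0 or vy == 0:
        raise ValueError("zero variance")
    r = float(np.clip(cov / np.sqrt(vx * vy), -1.0, 1.0))
    df = len(x) - 2
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, float(p)


def weighted_linreg(y, X, w=None):
    """Weighted least squares of y on X (intercept added).

    Returns a dict with beta, se, p per coefficient and R^2; weights are
    typically the per-cell record counts.
    """
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != len(y):
        X = X.T
    design = sm.add_constant(X)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("design matrix is rank deficient")
    w = np.ones(len(y)) if w is None else np.asarray(w, float)
    res = sm.WLS(np.asarray(y, float), design, weights=w).fit()
    return {
        "beta": res.params,
        "se": res.bse,
        "p": res.pvalues,
        "r_squared": float(res.rsquared),
    }


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per covariate: 1 / (1 - R^2_j) from
    regressing covariate j on the others (with intercept). Perfect
    collinearity reports inf."""
    X = pd.DataFrame(X)
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least two covariates")
    out = {}
    for j, col in enumerate(X.columns):
        others = sm.add_constant(X.drop(columns=col).to_numpy())
        r2 = sm.OLS(X[col].to_numpy(), others).fit().rsquared
        out[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


# ---------------------------------------------------------------------------
# GLS with exponential spatial correlation


def _correlation_matrix(coords, weights, rho, nugget=0.0, distance="euclidean"):
    """C with C_ii = v_i and C_ij = sqrt(v_i v_j) (1-nugget) exp(-d_ij/rho)."""
    coords = np.asarray(coords, float)
    if distance == "euclidean":
        d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    elif distance == "greatcircle":
        from .geodesy import gc_distance
        n = len(coords)
        d = np.zeros((n, n))
        for i in range(n):
            d[i] = gc_distance(
                (coords[i, 1], coords[i, 0]), (coords[:, 1], coords[:, 0])
            )
    else:
        raise ValueError("distance must be 'euclidean' or 'greatcircle'")
    v = np.asarray(weights, float)
    sv = np.sqrt(np.outer(v, v))
    C = sv * (1.0 - nugget) * np.exp(-d / rho)
    np.fill_diagonal(C, v)
    return C


def gls_loglik(beta, sigma2, rho, y, X, coords, weights, nugget=0.0,
               distance="euclidean"):
    """Gaussian log-likelihood at explicit (beta, sigma2, rho).

    Sigma_ij = sigma2 * sqrt(v_i v_j) exp(-d_ij/rho) off-diagonal and
    sigma2 * v_i on the diagonal, v_i = 1/n_i.
    """
    if rho <= 0 or sigma2 <= 0:
        raise ValueError("rho and sigma2 must be positive")
    C = _correlation_matrix(coords, weights, rho, nugget, distance)
    n = len(y)
    r = np.asarray(y, float) - np.asarray(X, float) @ np.asarray(beta, float)
    try:
        L = linalg.cholesky(sigma2 * C, lower=True)
    except linalg.LinAlgError as e:
        raise ValueError(
            f"covariance not positive definite (cond ~ {np.linalg.cond(C):.2e})"
        ) from e
    z = linalg.solve_triangular(L, r, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return float(-0.5 * (n * np.log(2.0 * np.pi) + logdet + z @ z))


def gls_loglik_cells(beta, sigma2, rho, cells: pd.DataFrame, formula=(),
                     **kwargs) -> float:
    """gls_loglik evaluated on an env-cell table for a covariate subset."""
    cells = validate_env_table(cells)
    formula = tuple(formula)
    X = np.column_stack(
        [np.ones(len(cells))]
        + [cells[c].to_numpy() for c in formula]
    )
    return gls_loglik(
        beta, sigma2, rho,
        cells["y"].to_numpy(), X,
        cells[["centre_lon", "centre_lat"]].to_numpy(),
        1.0 / cells["n_records"].to_numpy(),
        **kwargs,
    )


@dataclass
class GLSFit:
    formula: tuple  # covariate names; () = null (intercept-only) model
    beta: np.ndarray  # intercept first
    se: np.ndarray
    range_param: float  # rho
    sigma2: float
    logL: float
    aic: float
    term_names: tuple = ()


class ExponentialGLS(BaseEstimator):
    """GLS with exponential spatial residual correlation and 1/n weights.

    The likelihood is profiled: for each candidate range rho, beta and
    sigma2 have closed forms, and a bounded 1-D search maximizes the profile
    over rho. ML (not REML) is used so AIC is comparable across mean
    structures.

    Parameters
    ----------
    distance : {"euclidean", "greatcircle"}
        Inter-cell distance for the correlation: Euclidean in raw degrees
        on (lon, lat), or great-circle km.
    nugget : float in [0, 1)
        Optional discontinuity at zero distance (0 = pure exponential).
    rho_bounds : (lo, hi) or None
        Search range for rho; defaults to (1e-4, 4) x max inter-cell distance.

    Attributes
    ----------
    coef_, se_ : coefficients (intercept first) and Wald standard errors
    rho_, sigma2_, logL_, aic_ : fitted correlation range, variance scale,
        log-likelihood and AIC (k = #coefficients + 2 for sigma2 and rho)
    """

    def __init__(self, distance="euclidean", nugget=0.0, rho_bounds=None):
        self.distance = distance
        self.nugget = nugget
        self.rho_bounds = rho_bounds

    def fit(self, X, y, coords=None, sample_weight=None):
        """Fit to design X (no intercept column; may be empty), response y,
        cell-centre coords (n, 2) as (lon, lat), and sample_weight = records
        per cell (variance weights are their inverse)."""
        y = np.asarray(y, float)
        n = len(y)
        X = np.asarray(X, float).reshape(n, -1)
        design = np.column_stack([np.ones(n), X])
        if coords is None:
            raise ValueError("coords is required")
        coords = np.asarray(coords, float)
        n_rec = np.ones(n) if sample_weight is None else np.asarray(sample_weight, float)
        v = 1.0 / n_rec
        dmax = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)).max()
        lo, hi = self.rho_bounds or (max(1e-4, 1e-4 * dmax), 4.0 * dmax)

        def profile(rho):
            C = _correlation_matrix(coords, v, rho, self.nugget, self.distance)
            try:
                L = linalg.cholesky(C, lower=True)
            except linalg.LinAlgError:
                return np.inf, None
            Xw = linalg.solve_triangular(L, design, lower=True)
            yw = linalg.solve_triangular(L, y, lower=True)
            beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
            r = yw - Xw @ beta
            sigma2 = float(r @ r) / n
            sigma2 = max(sigma2, 1e-300)
            logdet = 2.0 * np.sum(np.log(np.diag(L)))
            ll = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + n + logdet)
            return -ll, (beta, sigma2, Xw, L)

        res = optimize.minimize_scalar(
            lambda r: profile(r)[0], bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-4 * dmax},
        )
        if not np.isfinite(res.fun):
            raise RuntimeError("GLS profile likelihood optimization failed")
        nll, (beta, sigma2, Xw, L) = profile(res.x)
        cov_beta = sigma2 * np.linalg.inv(Xw.T @ Xw)
        self.coef_ = beta
        self.se_ = np.sqrt(np.diag(cov_beta))
        self.rho_ = float(res.x)
        self.sigma2_ = sigma2
        self.logL_ = float(-nll)
        k = len(beta) + 2
        self.aic_ = -2.0 * self.logL_ + 2.0 * k
        self.n_ = n
        return self

    def predict(self, X):
        X = np.asarray(X, float).reshape(-1, len(self.coef_) - 1)
        return np.column_stack([np.ones(len(X)), X]) @ self.coef_


def fit_gls(cells: pd.DataFrame, formula=(), **kwargs) -> GLSFit:
    """Fit one covariate combination to an env-cell table.

    ``formula`` is an iterable of covariate names (empty = null model).
    """
    cells = validate_env_table(cells)
    formula = tuple(formula)
    if len(cells) < len(formula) + 3:
        raise ValueError("too few cells for this formula")
    X = cells[list(formula)].to_numpy() if formula else np.empty((len(cells), 0))
    est = ExponentialGLS(**kwargs).fit(
        X, cells["y"].to_numpy(),
        coords=cells[["centre_lon", "centre_lat"]].to_numpy(),
        sample_weight=cells["n_records"].to_numpy(),
    )
    return GLSFit(
        formula=formula,
        beta=est.coef_,
        se=est.se_,
        range_param=est.rho_,
        sigma2=est.sigma2_,
        logL=est.logL_,
        aic=est.aic_,
        term_names=("intercept",) + formula,
    )


def model_grid(cells: pd.DataFrame, covariates=COVARIATES, **kwargs) -> pd.DataFrame:
    """Fit the null model and every covariate subset; rank by AIC.

    Returns one row per model with the fit (or its error) and a flag for the
    five best-fitting models.
    """
    rows = []
    for r in range(len(covariates) + 1):
        for combo in itertools.combinations(covariates, r):
            row = {"formula": combo, "n_covariates": r}
            try:
                fit = fit_gls(cells, combo, **kwargs)
                row.update(aic=fit.aic, logL=fit.logL, rho=fit.range_param,
                           fit=fit, error=None)
            except (ValueError, RuntimeError) as e:
                row.update(aic=np.inf, logL=np.nan, rho=np.nan, fit=None,
                           error=str(e))
            rows.append(row)
    df = pd.DataFrame(rows).sort_values(
        ["aic", "n_covariates"], kind="stable"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df["top5"] = df["rank"] <= 5
    return df


def screens(cells: pd.DataFrame, covariates=COVARIATES) -> pd.DataFrame:
    """Per-covariate association screens against the morph frequency:
    weighted and unweighted Pearson correlation and a weighted pairwise
    linear regression."""
    cells = validate_env_table(cells)
    y = cells["y"].to_numpy()
    w = cells["n_records"].to_numpy()
    rows = []
    for cov in covariates:
        x = cells[cov].to_numpy()
        r_w, p_w = weighted_pearson(x, y, w)
        r_u, p_u = weighted_pearson(x, y, None)
        reg = weighted_linreg(y, x[:, None], w)
        rows.append({
            "covariate": cov,
            "pearson_weighted_r": r_w, "pearson_weighted_p": p_w,
            "pearson_unweighted_r": r_u, "pearson_unweighted_p": p_u,
            "linreg_slope": reg["beta"][1], "linreg_p": reg["p"][1],
            "linreg_r_squared": reg["r_squared"],
        })
    return pd.DataFrame(rows).set_index("covariate")


def criteria_report(grid_result: pd.DataFrame, screen_table: pd.DataFrame,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Three-way verdict per covariate.

    (i) present in all of the five best-fitting models; (ii) effect
    significantly different from zero (Wald) in the best model containing
    it; (iii) significant in the pairwise linear model and the unweighted
    Pearson correlation. The verdict is the conjunction.
    """
    top5 = grid_result[grid_result["top5"]]
    rows = []
    for cov in screen_table.index:
        in_all_top5 = all(cov in f for f in top5["formula"])
        effect_sig = False
        with_cov = grid_result[
            grid_result["formula"].apply(lambda f: cov in f) & grid_result["error"].isna()
        ]
        if len(with_cov):
            fit = with_cov.iloc[0]["fit"]  # best-ranked model containing it
            j = fit.term_names.index(cov)
            z = fit.beta[j] / fit.se[j]
            effect_sig = bool(2.0 * stats.norm.sf(abs(z)) < alpha)
        screens_sig = bool(
            screen_table.loc[cov, "linreg_p"] < alpha
            and screen_table.loc[cov, "pearson_unweighted_p"] < alpha
        )
        rows.append({
            "covariate": cov,
            "in_all_top5": bool(in_all_top5),
            "effect_significant": effect_sig,
            "screens_significant": screens_sig,
            "verdict": bool(in_all_top5 and effect_sig and screens_sig),
        })
    return pd.DataFrame(rows).set_index("covariate")
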