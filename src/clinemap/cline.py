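"""One-dimensional geographic cline models.

The central shape is the four-parameter sigmoid used throughout hybrid-zone
analysis, f(x) = 1 / (1 + exp(-4 (x - c) / w)), with centre c (the position
of the 0.5 crossing) and width w (inverse of the maximum slope, times 4).
Optional exponential tails attach beyond distances deltaL / deltaR from the
centre with slope ratios tauL / tauR (the Szymura-Barton family), and
optional scaling maps the shape onto [pmin, pmax]:

    p(x) = pmin + (pmax - pmin) * f(x)

Six model variants combine scaling in {none, fixed, free} with tails in
{none, both}. Fits are by bounded maximum likelihood (multi-start L-BFGS-B)
on a binomial likelihood over grid-cell allele frequencies, compared by
small-sample-corrected AIC, with posterior uncertainty from a Metropolis
sampler in independent chains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator

FREQ_CLAMP = 1e-6

SCALINGS = ("none", "fixed", "free")
TAILS = ("none", "both")


@dataclass(frozen=True)
class ClineModelSpec:
    """One of the six model variants: scaling x tails."""

    scaling: str = "none"
    tails: str = "none"

    def __post_init__(self) -> None:
        if self.scaling not in SCALINGS:
            raise ValueError(f"scaling must be one of {SCALINGS}")
        if self.tails not in TAILS:
            raise ValueError(f"tails must be one of {TAILS}")

    @property
    def k(self) -> int:
        """Number of free parameters."""
        return 2 + (2 if self.scaling == "free" else 0) + (4 if self.tails == "both" else 0)


@dataclass(frozen=True)
class ClineParams:
    c: float  # centre, km along transect
    w: float  # width, km
    pmin: float = 0.0
    pmax: float = 1.0
    deltaL: float = 0.0  # left tail onset distance from centre, km
    deltaR: float = 0.0
    tauL: float = 1.0  # tail slope ratios; 1 = smooth continuation
    tauR: float = 1.0

    def validate(self) -> None:
        if not self.w > 0:
            raise ValueError("width must be positive")
        if not 0.0 <= self.pmin < self.pmax <= 1.0:
            raise ValueError("need 0 <= pmin < pmax <= 1")
        if self.deltaL < 0 or self.deltaR < 0:
            raise ValueError("tail onsets must be >= 0")
        if not (0.0 <= self.tauL <= 1.0 and 0.0 <= self.tauR <= 1.0):
            raise ValueError("tail slope ratios must lie in [0, 1]")


def _shape(x, c, w, dL, dR, tL, tR, tails: str):
    """Unscaled cline shape f(x) in [0, 1], vectorized over x."""
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore", invalid="ignore"):
        f = 1.0 / (1.0 + np.exp(-4.0 * (x - c) / w))
        if tails == "both":
            left = x < c - dL
            right = x > c + dR
            if np.any(left):
                base = 1.0 / (1.0 + np.exp(4.0 * dL / w))
                rate = 4.0 * tL / w / (1.0 + np.exp(-4.0 * dL / w))
                f = np.where(left, base * np.exp(rate * (x - c + dL)), f)
            if np.any(right):
                base = 1.0 / (1.0 + np.exp(4.0 * dR / w))
                rate = 4.0 * tR / w / (1.0 + np.exp(-4.0 * dR / w))
                f = np.where(right, 1.0 - base * np.exp(-rate * (x - c - dR)), f)
    return f


def cline_value(x, params: ClineParams, spec: ClineModelSpec = ClineModelSpec()):
    """Expected allele frequency p(x) at position(s) x km along the transect."""
    params.validate()
    f = _shape(
        x, params.c, params.w, params.deltaL, params.deltaR,
        params.tauL, params.tauR, spec.tails,
    )
    p = params.pmin + (params.pmax - params.pmin) * f
    return p if np.ndim(x) else float(p)


def _xqn(cells, allele_counts: str = "2n"):
    """Extract (position, frequency, allele count) arrays from projected cells."""
    x = np.array([c.along_km for c in cells], dtype=float)
    q = np.array([c.q_hat for c in cells], dtype=float)
    n = np.array([c.n_scored for c in cells], dtype=float)
    if allele_counts == "2n":
        n = 2.0 * n
    elif allele_counts != "n":
        raise ValueError("allele_counts must be '2n' or 'n'")
    return x, q, n


def log_likelihood(params: ClineParams, spec: ClineModelSpec, cells,
                   allele_counts: str = "2n") -> float:
    """Binomial log-likelihood of per-cell frequencies under a cline.

    Each cell contributes m_i * [q_i ln p(x_i) + (1 - q_i) ln(1 - p(x_i))]
    where m_i is the allele count (2 * n_scored by default) and p is clamped
    away from 0/1 so observed fixed frequencies stay finite.
    """
    x, q, m = _xqn(cells, allele_counts)
    return _loglik_arrays(x, q, m, params, spec)


def _loglik_arrays(x, q, m, params: ClineParams, spec: ClineModelSpec) -> float:
    p = np.clip(cline_value(x, params, spec), FREQ_CLAMP, 1.0 - FREQ_CLAMP)
    return float(np.sum(m * (q * np.log(p) + (1.0 - q) * np.log(1.0 - p))))


def aicc(logL: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: -2 logL + 2k + 2k(k+1)/(n - k - 1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * logL + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


# ---------------------------------------------------------------------------
# internal parameter vector <-> ClineParams


class _ParamSpace:
    """Maps the free-parameter vector of one model variant onto ClineParams.

    The ML optimizer uses a smooth box for free scaling — (pmin, s) with
    pmax = pmin + (1 - pmin) * s — while the MCMC works on the raw (pmin,
    pmax) pair with the ordering enforced by the prior support.
    """

    def __init__(self, spec: ClineModelSpec, x, q):
        self.spec = spec
        self.span = float(np.max(x) - np.min(x))
        if self.span <= 0:
            raise ValueError("cells must span a positive distance")
        self.x_lo = float(np.min(x)) - self.span
        self.x_hi = float(np.max(x)) + self.span
        self.w_hi = 4.0 * self.span
        self.d_hi = 2.0 * self.span
        if spec.scaling == "fixed":
            self.fixed_pmin = float(np.min(q))
            self.fixed_pmax = float(np.max(q))
            if not self.fixed_pmin < self.fixed_pmax:
                raise ValueError("fixed scaling undefined: observed frequencies constant")
        self.names = ["c", "w"]
        if spec.scaling == "free":
            self.names += ["pmin", "pmax"]
        if spec.tails == "both":
            self.names += ["deltaL", "deltaR", "tauL", "tauR"]

    @property
    def k(self) -> int:
        return len(self.names)

    def _base(self) -> dict:
        if self.spec.scaling == "fixed":
            return {"pmin": self.fixed_pmin, "pmax": self.fixed_pmax}
        return {}

    # -- ML box (smooth reparameterization for free scaling)
    def ml_bounds(self):
        b = [(self.x_lo, self.x_hi), (1e-2, self.w_hi)]
        if self.spec.scaling == "free":
            b += [(0.0, 1.0 - 1e-3), (1e-3, 1.0)]  # pmin, s
        if self.spec.tails == "both":
            b += [(0.0, self.d_hi), (0.0, self.d_hi), (0.0, 1.0), (0.0, 1.0)]
        return b

    def ml_to_params(self, v) -> ClineParams:
        d = {"c": v[0], "w": v[1], **self._base()}
        i = 2
        if self.spec.scaling == "free":
            pmin, s = v[i], v[i + 1]
            d["pmin"] = pmin
            d["pmax"] = pmin + (1.0 - pmin) * s
            i += 2
        if self.spec.tails == "both":
            d["deltaL"], d["deltaR"], d["tauL"], d["tauR"] = v[i:i + 4]
        return ClineParams(**d)

    def ml_starts(self, x, q, n_starts: int = 10):
        """Dispersed deterministic starting points across the box."""
        x_lo, x_hi = float(np.min(x)), float(np.max(x))
        centres = np.linspace(x_lo, x_hi, n_starts)
        widths = np.geomspace(self.span / 20.0, self.w_hi / 2.0, n_starts)
        starts = []
        for c0, w0 in zip(centres, np.roll(widths, n_starts // 2)):
            v = [c0, w0]
            if self.spec.scaling == "free":
                pmin0 = max(0.0, float(np.min(q)) - 0.05)
                pmax0 = min(1.0, float(np.max(q)) + 0.05)
                s0 = (pmax0 - pmin0) / (1.0 - pmin0) if pmin0 < 1 else 0.5
                v += [pmin0, float(np.clip(s0, 1e-3, 1.0))]
            if self.spec.tails == "both":
                v += [self.span / 4.0, self.span / 4.0, 0.5, 0.5]
            starts.append(np.array(v))
        return starts

    # -- MCMC support (raw parameters, uniform priors)
    def prior_bounds(self):
        b = [(self.x_lo, self.x_hi), (1e-6, self.w_hi)]
        if self.spec.scaling == "free":
            b += [(0.0, 1.0), (0.0, 1.0)]
        if self.spec.tails == "both":
            b += [(0.0, self.d_hi), (0.0, self.d_hi), (0.0, 1.0), (0.0, 1.0)]
        return np.array(b)

    def raw_to_params(self, v) -> ClineParams:
        d = {"c": v[0], "w": v[1], **self._base()}
        i = 2
        if self.spec.scaling == "free":
            d["pmin"], d["pmax"] = v[i], v[i + 1]
            i += 2
        if self.spec.tails == "both":
            d["deltaL"], d["deltaR"], d["tauL"], d["tauR"] = v[i:i + 4]
        return ClineParams(**d)

    def params_to_raw(self, p: ClineParams):
        v = [p.c, p.w]
        if self.spec.scaling == "free":
            v += [p.pmin, p.pmax]
        if self.spec.tails == "both":
            v += [p.deltaL, p.deltaR, p.tauL, p.tauR]
        return np.array(v)

    def in_support(self, V) -> np.ndarray:
        """Vectorized prior-support indicator for a (walkers, k) array."""
        b = self.prior_bounds()
        ok = np.all((V >= b[:, 0]) & (V <= b[:, 1]), axis=1)
        if self.spec.scaling == "free":
            ok &= V[:, 2] < V[:, 3]
        return ok


def _batch_loglik(V, space: _ParamSpace, x, q, m) -> np.ndarray:
    """Log-likelihood for each row of a (walkers, k) raw-parameter array."""
    spec = space.spec
    c = V[:, [0]]
    w = V[:, [1]]
    i = 2
    if spec.scaling == "free":
        pmin, pmax = V[:, [i]], V[:, [i + 1]]
        i += 2
    elif spec.scaling == "fixed":
        pmin, pmax = space.fixed_pmin, space.fixed_pmax
    else:
        pmin, pmax = 0.0, 1.0
    if spec.tails == "both":
        dL, dR = V[:, [i]], V[:, [i + 1]]
        tL, tR = V[:, [i + 2]], V[:, [i + 3]]
    xr = x[None, :]
    with np.errstate(over="ignore", invalid="ignore"):
        f = 1.0 / (1.0 + np.exp(-4.0 * (xr - c) / w))
        if spec.tails == "both":
            eL = np.exp(4.0 * dL / w)
            left = xr < c - dL
            fL = (1.0 / (1.0 + eL)) * np.exp(
                4.0 * tL / w / (1.0 + 1.0 / eL) * (xr - c + dL)
            )
            eR = np.exp(4.0 * dR / w)
            right = xr > c + dR
            fR = 1.0 - (1.0 / (1.0 + eR)) * np.exp(
                -4.0 * tR / w / (1.0 + 1.0 / eR) * (xr - c - dR)
            )
            f = np.where(left, fL, np.where(right, fR, f))
    p = np.clip(pmin + (pmax - pmin) * f, FREQ_CLAMP, 1.0 - FREQ_CLAMP)
    return np.sum(m[None, :] * (q[None, :] * np.log(p) + (1.0 - q[None, :]) * np.log1p(-p)), axis=1)


# ---------------------------------------------------------------------------
# maximum likelihood


def _fit_ml_oriented(spec, x, q, m, n_starts=10):
    space = _ParamSpace(spec, x, q)
    bounds = space.ml_bounds()

    def nll(v):
        return -_loglik_arrays(x, q, m, space.ml_to_params(v), spec)

    best = None
    for v0 in space.ml_starts(x, q, n_starts):
        try:
            res = optimize.minimize(nll, v0, method="L-BFGS-B", bounds=bounds)
        except (ValueError, FloatingPointError):  # pragma: no cover
            continue
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError("cline ML fit failed from every start")
    params = space.ml_to_params(best.x)
    if params.w > 0.95 * space.w_hi:
        warnings.warn(
            "fitted cline width at the upper bound: no cline signal in the data "
            "(width effectively unbounded)",
            RuntimeWarning,
        )
    return params, -best.fun, space


def _orientation(x, q, m) -> bool:
    """True when frequency increases along the transect (weighted slope >= 0)."""
    xm = np.average(x, weights=m)
    qm = np.average(q, weights=m)
    return float(np.sum(m * (x - xm) * (q - qm))) >= 0.0


def fit_ml(spec: ClineModelSpec, cells, allele_counts: str = "2n", n_starts: int = 10):
    """Multi-start bounded ML fit.

    Decreasing clines are fitted on the complement frequency so that width is
    always positive; returns (params, logL, increasing).
    """
    x, q, m = _xqn(cells, allele_counts)
    if len(x) < spec.k + 1:
        raise ValueError(f"need at least {spec.k + 1} cells for this model")
    increasing = _orientation(x, q, m)
    q_fit = q if increasing else 1.0 - q
    params, logL, _ = _fit_ml_oriented(spec, x, q_fit, m, n_starts)
    return params, logL, increasing


# ---------------------------------------------------------------------------
# Metropolis MCMC


def _gelman_rubin(chains: np.ndarray) -> float:
    """Potential scale reduction factor over (n_chains, n_draws) samples."""
    m, n = chains.shape
    means = chains.mean(axis=1)
    W = chains.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W <= 0:
        return 1.0
    var_hat = (n - 1) / n * W + B / n
    return float(np.sqrt(var_hat / W))


def _run_metropolis(space, x, q, m, start, chains, burn_in, generations, rng):
    """Vectorized Metropolis over independent chains with burn-in adaptation.

    Joint Gaussian proposals with per-parameter scales; a per-chain global
    scale factor is tuned toward ~30% acceptance every 100 burn-in
    generations and frozen afterwards.
    """
    k = space.k
    b = space.prior_bounds()
    prior_range = b[:, 1] - b[:, 0]
    base_scale = 0.05 * prior_range
    factor = np.ones(chains)

    cur = np.tile(start, (chains, 1))
    jitter = 0.01 * prior_range
    for attempt in range(100):
        cand = cur + rng.normal(size=cur.shape) * jitter
        ok = space.in_support(cand)
        cur[ok] = cand[ok]
        if attempt > 3:
            break
    cur_lp = np.where(space.in_support(cur), _batch_loglik(cur, space, x, q, m), -np.inf)

    draws = np.empty((chains, generations, k))
    accepts = np.zeros(chains)
    window_acc = np.zeros(chains)

    total = burn_in + generations
    for t in range(total):
        prop = cur + rng.normal(size=cur.shape) * (base_scale * factor[:, None])
        ok = space.in_support(prop)
        prop_lp = np.full(chains, -np.inf)
        if np.any(ok):
            prop_lp[ok] = _batch_loglik(prop[ok], space, x, q, m)
        accept = np.log(rng.random(chains)) < prop_lp - cur_lp
        cur[accept] = prop[accept]
        cur_lp[accept] = prop_lp[accept]
        if t < burn_in:
            window_acc += accept
            if (t + 1) % 100 == 0:
                rate = window_acc / 100.0
                factor *= np.exp(rate - 0.30)
                factor = np.clip(factor, 1e-3, 1e3)
                window_acc[:] = 0.0
        else:
            draws[:, t - burn_in, :] = cur
            accepts += accept
    return draws, accepts / generations


def mcmc_sample(
    spec: ClineModelSpec,
    cells,
    chains: int = 3,
    burn_in: int = 10_000,
    generations: int = 100_000,
    seed: int | None = None,
    allele_counts: str = "2n",
    ml_start: ClineParams | None = None,
    increasing: bool | None = None,
):
    """Posterior sampling for one cline model.

    Independent Metropolis chains start from the ML estimate (jittered per
    chain) under uniform priors: c over the data span widened by one span on
    each side, w in (0, 4 span], tail onsets in [0, 2 span], slope ratios and
    scale parameters in [0, 1] with pmin < pmax. Returns a dict with the
    pooled post-burn-in draws (DataFrame), per-chain acceptance rates,
    Gelman-Rubin R-hat per parameter, and any convergence warnings.
    """
    x, q, m = _xqn(cells, allele_counts)
    if increasing is None:
        increasing = _orientation(x, q, m)
    q_fit = q if increasing else 1.0 - q
    if ml_start is None:
        ml_start, _, _ = _fit_ml_oriented(spec, x, q_fit, m)
    space = _ParamSpace(spec, x, q_fit)
    start = space.params_to_raw(ml_start)
    start = np.clip(start, space.prior_bounds()[:, 0], space.prior_bounds()[:, 1])
    rng = np.random.default_rng(seed)
    draws, acc = _run_metropolis(
        space, x, q_fit, m, start, chains, burn_in, generations, rng
    )
    rhat = {
        name: _gelman_rubin(draws[:, :, j]) for j, name in enumerate(space.names)
    }
    warn_msgs = [
        f"R-hat {v:.3f} > 1.1 for parameter {k!r}: chains may not have converged"
        for k, v in rhat.items()
        if v > 1.1
    ]
    for msg in warn_msgs:
        warnings.warn(msg, RuntimeWarning)
    pooled = pd.DataFrame(
        draws.reshape(chains * generations, space.k), columns=space.names
    )
    return {
        "draws": pooled,
        "acceptance": acc,
        "rhat": rhat,
        "warnings": warn_msgs,
        "space": space,
        "increasing": increasing,
    }


def credible_region(posterior: pd.DataFrame, x_grid, spec: ClineModelSpec,
                    space: _ParamSpace, increasing: bool = True,
                    max_curves: int = 2000, rng=None):
    """95% credible intervals for centre and width plus the pointwise
    2.5/97.5% envelope of the fitted frequency (the fuzzy cline region)."""
    if len(posterior) < 1000:
        raise ValueError("need at least 1000 retained draws")
    centre_ci = tuple(np.percentile(posterior["c"], [2.5, 97.5]))
    width_ci = tuple(np.percentile(posterior["w"], [2.5, 97.5]))
    rng = np.random.default_rng(rng)
    idx = (
        rng.choice(len(posterior), size=max_curves, replace=False)
        if len(posterior) > max_curves
        else np.arange(len(posterior))
    )
    x_grid = np.asarray(x_grid, dtype=float)
    curves = np.empty((len(idx), len(x_grid)))
    V = posterior.to_numpy()
    for r, i in enumerate(idx):
        p = cline_value(x_grid, space.raw_to_params(V[i]), spec)
        curves[r] = p if increasing else 1.0 - p
    lo, med, hi = np.percentile(curves, [2.5, 50.0, 97.5], axis=0)
    envelope = pd.DataFrame({"x_km": x_grid, "p_lo": lo, "p_med": med, "p_hi": hi})
    return centre_ci, width_ci, envelope


# ---------------------------------------------------------------------------
# estimator


class ClineFitter(BaseEstimator):
    """Geographic cline estimator over projected grid-cell frequencies.

    Parameters
    ----------
    scaling : {"none", "fixed", "free"}
        Asymptote handling: the sigmoid spans [0, 1], the observed frequency
        extremes, or two free parameters.
    tails : {"none", "both"}
        Whether exponential tails attach on both sides of the centre.
    allele_counts : {"2n", "n"}
        Effective binomial count per cell: alleles (2 x scored individuals)
        or individuals.
    run_mcmc : bool
        Whether :meth:`fit` also draws the posterior (needed for credible
        intervals and the envelope).
    chains, burn_in, generations, seed
        Metropolis sampler schedule.

    Attributes
    ----------
    params_ : ClineParams — maximum-likelihood estimates
    logL_, aicc_ : float
    increasing_ : bool — orientation of the fitted cline along the transect
    posterior_ : DataFrame of pooled post-burn-in draws (if run_mcmc)
    centre_ci_, width_ci_ : 95% credible intervals (km)
    rhat_, acceptance_ : convergence diagnostics
    """

    def __init__(self, scaling="none", tails="none", allele_counts="2n",
                 run_mcmc=True, chains=3, burn_in=10_000, generations=100_000,
                 seed=None, n_starts=10):
        self.scaling = scaling
        self.tails = tails
        self.allele_counts = allele_counts
        self.run_mcmc = run_mcmc
        self.chains = chains
        self.burn_in = burn_in
        self.generations = generations
        self.seed = seed
        self.n_starts = n_starts

    def _spec(self) -> ClineModelSpec:
        return ClineModelSpec(scaling=self.scaling, tails=self.tails)

    def fit(self, X, y, sample_weight=None):
        """Fit to positions X (km along transect), frequencies y, with
        sample_weight = scored individuals per cell (default 1)."""
        x = np.asarray(X, dtype=float).reshape(-1)
        q = np.asarray(y, dtype=float)
        n = (np.ones_like(x) if sample_weight is None
             else np.asarray(sample_weight, dtype=float))
        if not (len(x) == len(q) == len(n)):
            raise ValueError("X, y and sample_weight must have equal length")
        if np.any((q < 0) | (q > 1)):
            raise ValueError("frequencies must lie in [0, 1]")
        cells = [_Cell(xi, qi, ni) for xi, qi, ni in zip(x, q, n)]
        spec = self._spec()
        self.params_, self.logL_, self.increasing_ = fit_ml(
            spec, cells, self.allele_counts, self.n_starts
        )
        self.aicc_ = aicc(self.logL_, spec.k, len(cells))
        self.n_cells_ = len(cells)
        if self.run_mcmc:
            res = mcmc_sample(
                spec, cells,
                chains=self.chains, burn_in=self.burn_in,
                generations=self.generations, seed=self.seed,
                allele_counts=self.allele_counts,
                ml_start=self.params_, increasing=self.increasing_,
            )
            self.posterior_ = res["draws"]
            self.acceptance_ = res["acceptance"]
            self.rhat_ = res["rhat"]
            self.mcmc_warnings_ = res["warnings"]
            self._space = res["space"]
            self.centre_ci_ = tuple(np.percentile(self.posterior_["c"], [2.5, 97.5]))
            self.width_ci_ = tuple(np.percentile(self.posterior_["w"], [2.5, 97.5]))
        return self

    def predict(self, X):
        """Fitted frequency at positions X, in the data's original orientation."""
        p = cline_value(np.asarray(X, dtype=float), self.params_, self._spec())
        return p if self.increasing_ else 1.0 - p

    def envelope(self, x_grid, max_curves: int = 2000):
        """Fuzzy-cline credible band (requires run_mcmc=True)."""
        _, _, env = credible_region(
            self.posterior_, x_grid, self._spec(), self._space,
            increasing=self.increasing_, max_curves=max_curves,
            rng=self.seed,
        )
        return env

    def report(self) -> dict:
        """JSON-serializable summary of the fit."""
        out = {
            "model": {"scaling": self.scaling, "tails": self.tails},
            "increasing": bool(self.increasing_),
            "ml_params": {k: float(v) for k, v in vars(self.params_).items()},
            "logL": float(self.logL_),
            "aicc": float(self.aicc_),
            "n_cells": int(self.n_cells_),
        }
        if hasattr(self, "posterior_"):
            out["posterior"] = {
                col: {
                    "median": float(self.posterior_[col].median()),
                    "q2.5": float(np.percentile(self.posterior_[col], 2.5)),
                    "q97.5": float(np.percentile(self.posterior_[col], 97.5)),
                }
                for col in self.posterior_.columns
            }
            out["rhat"] = {k: float(v) for k, v in self.rhat_.items()}
            out["acceptance"] = [float(a) for a in self.acceptance_]
            out["warnings"] = list(self.mcmc_warnings_)
        return out


@dataclass(frozen=True)
class _Cell:
    along_km: float
    q_hat: float
    n_scored: float


def fitter_from_cells(cells, **kwargs) -> ClineFitter:
    """Fit a ClineFitter directly to projected cells."""
    x = [c.along_km for c in cells]
    q = [c.q_hat for c in cells]
    n = [c.n_scored for c in cells]
    return ClineFitter(**kwargs).fit(x, q, sample_weight=n)


def compare_models(cells, allele_counts: str = "2n", n_starts: int = 10) -> pd.DataFrame:
    """Fit all six scaling x tails variants by ML and rank them by AICc.

    Ties (within numerical noise) break toward fewer parameters. A model
    that fails to fit is reported with its error, never fatal.
    """
    rows = []
    for scaling in SCALINGS:
        for tails in TAILS:
            spec = ClineModelSpec(scaling=scaling, tails=tails)
            row = {"scaling": scaling, "tails": tails, "k": spec.k}
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    params, logL, inc = fit_ml(spec, cells, allele_counts, n_starts)
                row.update(
                    logL=logL,
                    aicc=aicc(logL, spec.k, len(cells)),
                    params=params,
                    increasing=inc,
                    error=None,
                )
            except (ValueError, RuntimeError) as e:
                row.update(logL=np.nan, aicc=np.inf, params=None,
                           increasing=None, error=str(e))
            rows.append(row)
    df = pd.DataFrame(rows)
    df = df.sort_values(["aicc", "k"], kind="stable").reset_index(drop=True)
    df["best"] = False
    df.loc[0, "best"] = True
    return df


def centre_offset(fit_a: ClineFitter, fit_b: ClineFitter, rng=None) -> dict:
    """Distance between two cline centres with a posterior interval.

    The point offset is |median c_A - median c_B|; the interval comes from
    the 2.5-97.5% quantiles of differences of independently paired posterior
    draws, oriented so the median difference is non-negative.
    """
    ca = fit_a.posterior_["c"].to_numpy()
    cb = fit_b.posterior_["c"].to_numpy()
    rng = np.random.default_rng(rng)
    npairs = min(len(ca), len(cb), 100_000)
    d = rng.choice(ca, npairs, replace=False) - rng.choice(cb, npairs, replace=False)
    if np.median(d) < 0:
        d = -d
    lo, hi = np.percentile(d, [2.5, 97.5])
    return {
        "offset_km": abs(float(np.median(ca)) - float(np.median(cb))),
        "interval_km": (float(lo), float(hi)),
    }
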