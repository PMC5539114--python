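"""Daily Bayesian hierarchical Gaussian-process regression of PM2.5 on AOD.

Model, per day, at monitoring sites i = 1..n:

    y_i = beta0 + beta1 * AOD_i + omega_i + eps_i,
    omega ~ MVN(0, sigma2 * R(phi)),   eps_i ~ N(0, tau2) iid,

with R(phi) the correlation matrix of the chosen family (spherical by
default) over Euclidean distances in degrees.  Integrating omega out,
y ~ MVN(X beta, sigma2*R + tau2*I), which is the marginal likelihood the
sampler targets.

Priors: beta bivariate normal; tau2 and sigma2 inverse gamma with shape 2
(infinite prior variance); phi uniform on a positive interval.  Inference
is Metropolis-within-Gibbs: beta has a conjugate normal full conditional
and is Gibbs-updated; log sigma2, log tau2 and logit-scaled phi take
Gaussian random-walk Metropolis-Hastings steps with Jacobian corrections,
proposal scales adapted toward 25-50% acceptance during burn-in and frozen
afterwards.  Default run length is 5,000 iterations with a 3,000-iteration
burn-in, retaining iterations 3,000..5,000 (2,001 draws).

The spatial random effects are recovered by composition sampling from
their exact conditional normal given each retained draw, and the
posterior-predictive field uses the exact per-draw conditional moments of
y at new locations (Rao-Blackwellized over omega), so with a single fixed
draw the predictor collapses to the classical GLS/kriging closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import cdist, pdist, squareform

from .variogram import VariogramModel, correlation, empirical_variogram, fit_variogram

__all__ = [
    "GPparams",
    "PriorSpec",
    "PosteriorChains",
    "SpatialEffectsDraws",
    "PredictionField",
    "default_priors",
    "log_marginal_likelihood",
    "log_posterior",
    "mh_sample",
    "recover_spatial_effects",
    "posterior_predict",
    "single_draw_chain",
    "fit_day",
    "GPDayFit",
]

_LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class GPparams:
    """One parameter state of the daily model."""

    beta0: float
    beta1: float
    sigma2: float
    tau2: float
    phi: float

    def __post_init__(self) -> None:
        if self.sigma2 <= 0:
            raise ValueError(f"sigma2 must be positive, got {self.sigma2}")
        if self.tau2 <= 0:
            raise ValueError(f"tau2 must be positive, got {self.tau2}")
        if self.phi <= 0:
            raise ValueError(f"phi must be positive, got {self.phi}")


@dataclass(frozen=True)
class PriorSpec:
    """Priors: normal beta, IG(shape 2) variances, uniform decay.

    With shape 2 the inverse-gamma prior mean equals its scale and the
    prior variance is infinite, keeping the variance priors weakly
    informative while centered on a supplied estimate (typically from a
    variogram fit of the day's data).
    """

    beta_mean: np.ndarray
    beta_cov: np.ndarray
    tau2_scale: float
    sigma2_scale: float
    phi_lower: float
    phi_upper: float
    tau2_shape: float = 2.0
    sigma2_shape: float = 2.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "beta_mean", np.asarray(self.beta_mean, dtype=float))
        object.__setattr__(self, "beta_cov", np.asarray(self.beta_cov, dtype=float))
        if self.beta_mean.shape != (2,) or self.beta_cov.shape != (2, 2):
            raise ValueError("beta prior must be bivariate (mean (2,), cov (2,2))")
        if self.tau2_scale <= 0 or self.sigma2_scale <= 0:
            raise ValueError("inverse-gamma scales must be positive")
        if not (0 < self.phi_lower < self.phi_upper):
            raise ValueError(
                f"phi bounds must satisfy 0 < lower < upper, got ({self.phi_lower}, {self.phi_upper})"
            )

    def in_support(self, p: GPparams) -> bool:
        return (
            p.sigma2 > 0
            and p.tau2 > 0
            and self.phi_lower <= p.phi <= self.phi_upper
        )


def _log_invgamma(x: float, shape: float, scale: float) -> float:
    """log density of InvGamma(shape, scale) at x > 0."""
    if x <= 0:
        return -np.inf
    return shape * math.log(scale) - math.lgamma(shape) - (shape + 1.0) * math.log(x) - scale / x


def default_priors(
    day: pd.DataFrame, vg: VariogramModel | None = None
) -> PriorSpec:
    """Data-scale default priors for one day.

    beta ~ N(0, 1e6 I) (essentially flat).  The inverse-gamma scales are
    taken from a spherical variogram fit of the day's OLS-detrended PM2.5
    (prior mean = the variogram estimate; detrending on AOD first keeps the
    covariate's short-range structure from inflating the apparent nugget)
    or from a supplied model; otherwise from sample-variance moments.  phi
    is uniform between 1/(2 d_max) and 1/(0.05 d_max) with d_max the
    maximum pairwise site distance, so the effective range may span from
    5% of the domain to twice its diameter.
    """
    coords = day[["lon", "lat"]].to_numpy()
    d_max = float(pdist(coords).max())
    if vg is None:
        try:
            y = day["pm25"].to_numpy(dtype=float)
            X = np.column_stack([np.ones(len(day)), day["aod"].to_numpy(dtype=float)])
            resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
            emp = empirical_variogram(coords, resid)
            vg = fit_variogram(emp, "spherical")
        except (ValueError, RuntimeError):
            vg = None
    if vg is not None:
        sigma2_scale = max(vg.sigma2, 1e-6)
        tau2_scale = max(vg.tau2, 0.05 * vg.sigma2, 1e-6)
    else:
        v = float(np.var(day["pm25"].to_numpy()))
        sigma2_scale = max(0.8 * v, 1e-6)
        tau2_scale = max(0.2 * v, 1e-6)
    return PriorSpec(
        beta_mean=np.zeros(2),
        beta_cov=1e6 * np.eye(2),
        tau2_scale=tau2_scale,
        sigma2_scale=sigma2_scale,
        phi_lower=1.0 / (2.0 * d_max),
        phi_upper=1.0 / (0.05 * d_max),
    )


def _day_arrays(day: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    coords = day[["lon", "lat"]].to_numpy(dtype=float)
    y = day["pm25"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(day)), day["aod"].to_numpy(dtype=float)])
    return coords, y, X


def _chol_cov(R: np.ndarray, sigma2: float, tau2: float):
    """Cholesky of sigma2*R + tau2*I, with one jitter retry."""
    cov = sigma2 * R
    idx = np.diag_indices_from(cov)
    cov[idx] += tau2
    try:
        return cho_factor(cov, lower=True, check_finite=False)
    except np.linalg.LinAlgError:
        jitter = 1e-8 * sigma2
        cov[idx] += jitter
        try:
            return cho_factor(cov, lower=True, check_finite=False)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"covariance factorization failed even with jitter {jitter}"
            ) from exc


def _mvn_logpdf_chol(resid: np.ndarray, chol) -> float:
    n = len(resid)
    alpha = cho_solve(chol, resid, check_finite=False)
    logdet = 2.0 * float(np.sum(np.log(np.diag(chol[0]))))
    return -0.5 * (n * _LOG2PI + logdet + float(resid @ alpha))


def log_marginal_likelihood(
    day: pd.DataFrame, p: GPparams, family: str = "spherical"
) -> float:
    """Log density of y under MVN(X beta, sigma2*R(phi) + tau2*I)."""
    coords, y, X = _day_arrays(day)
    if len(y) < 2:
        raise ValueError("need at least 2 sites")
    D = squareform(pdist(coords))
    R = np.asarray(correlation(family, D, p.phi))
    chol = _chol_cov(R, p.sigma2, p.tau2)
    resid = y - X @ np.array([p.beta0, p.beta1])
    return _mvn_logpdf_chol(resid, chol)


def log_posterior(
    day: pd.DataFrame, p: GPparams, priors: PriorSpec, family: str = "spherical"
) -> float:
    """Unnormalized log posterior; -inf outside the prior support."""
    if not priors.in_support(p):
        return -np.inf
    ll = log_marginal_likelihood(day, p, family)
    beta = np.array([p.beta0, p.beta1])
    dev = beta - priors.beta_mean
    Vinv = np.linalg.inv(priors.beta_cov)
    lp_beta = -0.5 * float(dev @ Vinv @ dev) - 0.5 * float(
        np.linalg.slogdet(2.0 * np.pi * priors.beta_cov)[1]
    )
    lp = (
        lp_beta
        + _log_invgamma(p.tau2, priors.tau2_shape, priors.tau2_scale)
        + _log_invgamma(p.sigma2, priors.sigma2_shape, priors.sigma2_scale)
        - math.log(priors.phi_upper - priors.phi_lower)
    )
    return ll + lp


@dataclass
class PosteriorChains:
    """MH draws of the daily parameters with burn-in bookkeeping.

    Iterations are numbered 1..n_iter; retained draws are the iterations
    >= burn_in (inclusive), so 5,000 iterations with burn-in 3,000 retain
    exactly 2,001 draws.
    """

    beta0: np.ndarray
    beta1: np.ndarray
    sigma2: np.ndarray
    tau2: np.ndarray
    phi: np.ndarray
    burn_in: int
    acceptance: dict
    proposal_scales: dict
    seed: int
    family: str = "spherical"
    accept_flags: dict | None = None  # per-iteration 0/1 per MH block

    @property
    def n_iter(self) -> int:
        return len(self.beta0)

    @property
    def n_retained(self) -> int:
        return self.n_iter - self.burn_in + 1

    def retained(self) -> pd.DataFrame:
        sl = slice(self.burn_in - 1, None)
        return pd.DataFrame(
            {
                "beta0": self.beta0[sl],
                "beta1": self.beta1[sl],
                "sigma2": self.sigma2[sl],
                "tau2": self.tau2[sl],
                "phi": self.phi[sl],
            }
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "iteration": np.arange(1, self.n_iter + 1),
                "beta0": self.beta0,
                "beta1": self.beta1,
                "sigma2": self.sigma2,
                "tau2": self.tau2,
                "phi": self.phi,
            }
        )
        if self.accept_flags is not None:
            for k, v in self.accept_flags.items():
                df[f"accept_{k}"] = v
        df["retained"] = df["iteration"] >= self.burn_in
        return df

    def posterior_means(self) -> GPparams:
        r = self.retained()
        return GPparams(*(float(r[c].mean()) for c in ("beta0", "beta1", "sigma2", "tau2", "phi")))


def single_draw_chain(p: GPparams, family: str = "spherical") -> PosteriorChains:
    """A degenerate one-draw chain holding fixed parameters.

    Useful for plug-in prediction and for checking that the posterior
    predictive collapses to the classical GLS/kriging form when the
    parameters are fixed.
    """
    one = lambda v: np.array([v], dtype=float)
    return PosteriorChains(
        one(p.beta0), one(p.beta1), one(p.sigma2), one(p.tau2), one(p.phi),
        burn_in=1, acceptance={}, proposal_scales={}, seed=0, family=family,
    )


def mh_sample(
    day: pd.DataFrame,
    priors: PriorSpec | None = None,
    n_iter: int = 5000,
    burn_in: int = 3000,
    seed: int = 0,
    family: str = "spherical",
    proposal_scales: dict | None = None,
    min_sites: int = 10,
) -> PosteriorChains:
    """Metropolis-within-Gibbs sampler for the daily model.

    beta is drawn from its exact conjugate normal full conditional given
    (sigma2, tau2, phi); the covariance parameters take scalar Gaussian
    random-walk MH steps on log sigma2, log tau2 and logit-scaled phi with
    the appropriate Jacobian terms.  Proposal scales adapt toward ~35%
    acceptance during burn-in only.  Deterministic given the seed.
    """
    if len(day) < min_sites:
        raise ValueError(f"day has {len(day)} sites; at least {min_sites} required")
    if not 1 <= burn_in <= n_iter:
        raise ValueError(f"burn_in must lie in [1, n_iter], got {burn_in}")
    coords, y, X = _day_arrays(day)
    if priors is None:
        priors = default_priors(day)
    n = len(y)
    D = squareform(pdist(coords))
    rng = np.random.default_rng(seed)
    V0inv = np.linalg.inv(priors.beta_cov)
    V0inv_m0 = V0inv @ priors.beta_mean

    scales = {"sigma2": 0.5, "tau2": 0.5, "phi": 0.5}
    if proposal_scales:
        scales.update(proposal_scales)
    a, b = priors.phi_lower, priors.phi_upper

    # initial state: prior centers
    sigma2 = priors.sigma2_scale
    tau2 = priors.tau2_scale
    phi = 0.5 * (a + b)
    beta = np.linalg.lstsq(X, y, rcond=None)[0]

    def corr(ph):
        return np.asarray(correlation(family, D, ph))

    R = corr(phi)
    chol = _chol_cov(R.copy(), sigma2, tau2)

    def loglik(chol_, beta_):
        return _mvn_logpdf_chol(y - X @ beta_, chol_)

    ll = loglik(chol, beta)

    chains = {k: np.empty(n_iter) for k in ("beta0", "beta1", "sigma2", "tau2", "phi")}
    acc = {"sigma2": 0, "tau2": 0, "phi": 0}
    acc_win = {"sigma2": 0, "tau2": 0, "phi": 0}
    flags = {k: np.zeros(n_iter, dtype=np.int8) for k in acc}
    adapt_every = 50

    for it in range(n_iter):
        # --- beta: conjugate Gibbs given the current covariance ---
        SinvX = cho_solve(chol, X, check_finite=False)
        Sinvy = cho_solve(chol, y, check_finite=False)
        A = X.T @ SinvX + V0inv
        bvec = X.T @ Sinvy + V0inv_m0
        La = np.linalg.cholesky(A)
        mean = np.linalg.solve(A, bvec)
        z = rng.standard_normal(2)
        beta = mean + np.linalg.solve(La.T, z)
        ll = loglik(chol, beta)

        # --- sigma2: RW on log scale ---
        prop = sigma2 * math.exp(scales["sigma2"] * rng.standard_normal())
        chol_p = _chol_cov(R.copy(), prop, tau2)
        ll_p = loglik(chol_p, beta)
        loga = (
            ll_p - ll
            + _log_invgamma(prop, priors.sigma2_shape, priors.sigma2_scale)
            - _log_invgamma(sigma2, priors.sigma2_shape, priors.sigma2_scale)
            + math.log(prop) - math.log(sigma2)  # log-scale Jacobian
        )
        if math.log(rng.random()) < loga:
            sigma2, chol, ll = prop, chol_p, ll_p
            acc["sigma2"] += 1
            acc_win["sigma2"] += 1
            flags["sigma2"][it] = 1

        # --- tau2: RW on log scale ---
        prop = tau2 * math.exp(scales["tau2"] * rng.standard_normal())
        chol_p = _chol_cov(R.copy(), sigma2, prop)
        ll_p = loglik(chol_p, beta)
        loga = (
            ll_p - ll
            + _log_invgamma(prop, priors.tau2_shape, priors.tau2_scale)
            - _log_invgamma(tau2, priors.tau2_shape, priors.tau2_scale)
            + math.log(prop) - math.log(tau2)
        )
        if math.log(rng.random()) < loga:
            tau2, chol, ll = prop, chol_p, ll_p
            acc["tau2"] += 1
            acc_win["tau2"] += 1
            flags["tau2"][it] = 1

        # --- phi: RW on logit((phi-a)/(b-a)) ---
        u = math.log(phi - a) - math.log(b - phi)
        u_p = u + scales["phi"] * rng.standard_normal()
        phi_p = a + (b - a) / (1.0 + math.exp(-u_p))
        if a < phi_p < b:
            R_p = corr(phi_p)
            chol_p = _chol_cov(R_p.copy(), sigma2, tau2)
            ll_p = loglik(chol_p, beta)
            # uniform prior cancels; Jacobian of the logit transform
            loga = (
                ll_p - ll
                + math.log(phi_p - a) + math.log(b - phi_p)
                - math.log(phi - a) - math.log(b - phi)
            )
            if math.log(rng.random()) < loga:
                phi, R, chol, ll = phi_p, R_p, chol_p, ll_p
                acc["phi"] += 1
                acc_win["phi"] += 1
                flags["phi"][it] = 1

        # --- burn-in proposal adaptation ---
        if (it + 1) % adapt_every == 0 and (it + 1) < burn_in:
            for k in scales:
                rate = acc_win[k] / adapt_every
                scales[k] *= math.exp(np.clip(rate - 0.35, -0.5, 0.5))
                acc_win[k] = 0

        chains["beta0"][it] = beta[0]
        chains["beta1"][it] = beta[1]
        chains["sigma2"][it] = sigma2
        chains["tau2"][it] = tau2
        chains["phi"][it] = phi

    for k, v in acc.items():
        if v == 0:
            raise RuntimeError(
                f"no accepted {k} proposals in {n_iter} iterations; "
                f"rescale the proposal (current scale {scales[k]:.3g})"
            )
    acceptance = {k: {"count": v, "rate": v / n_iter} for k, v in acc.items()}
    return PosteriorChains(
        chains["beta0"], chains["beta1"], chains["sigma2"], chains["tau2"], chains["phi"],
        burn_in=burn_in, acceptance=acceptance, proposal_scales=dict(scales),
        seed=seed, family=family, accept_flags=flags,
    )


@dataclass
class SpatialEffectsDraws:
    """Per-site spatial-random-effect draws, one row per retained iteration."""

    omega: np.ndarray  # (n_draws, n_sites)
    site_ids: np.ndarray

    @property
    def mean(self) -> np.ndarray:
        """Daily mean effect per site (omega-bar)."""
        return self.omega.mean(axis=0)


class _DrawCache:
    """Caches R and Cholesky factors keyed by the exact parameter floats.

    MH chains repeat states after rejections, so exact-key caching removes
    most refactorizations during composition sampling and prediction.
    """

    def __init__(self, D: np.ndarray, family: str):
        self.D = D
        self.family = family
        self._R: dict[float, np.ndarray] = {}
        self._chol: dict[tuple, object] = {}

    def R(self, phi: float) -> np.ndarray:
        if phi not in self._R:
            if len(self._R) > 64:
                self._R.clear()
            self._R[phi] = np.asarray(correlation(self.family, self.D, phi))
        return self._R[phi]

    def chol(self, sigma2: float, tau2: float, phi: float):
        key = (sigma2, tau2, phi)
        if key not in self._chol:
            if len(self._chol) > 64:
                self._chol.clear()
            self._chol[key] = _chol_cov(self.R(phi).copy(), sigma2, tau2)
        return self._chol[key]


def recover_spatial_effects(
    day: pd.DataFrame,
    chains: PosteriorChains,
    seed: int = 0,
    thin: int = 1,
) -> SpatialEffectsDraws:
    """Composition-sample omega from its conditional for each retained draw.

    Given (beta, sigma2, tau2, phi), with S = sigma2*R and Sigma = S + tau2*I,

        omega | y ~ N( S Sigma^-1 (y - X beta),  S - S Sigma^-1 S ).

    A 1e-10*sigma2 diagonal jitter stabilizes the conditional factor in the
    small-nugget limit.
    """
    coords, y, X = _day_arrays(day)
    ret = chains.retained()
    if thin > 1:
        ret = ret.iloc[::thin].reset_index(drop=True)
    n = len(y)
    D = squareform(pdist(coords))
    cache = _DrawCache(D, chains.family)
    rng = np.random.default_rng(seed)
    out = np.empty((len(ret), n))
    chol_cond_cache: dict[tuple, tuple] = {}
    for j, row in enumerate(ret.itertuples(index=False)):
        key = (row.sigma2, row.tau2, row.phi)
        if key in chol_cond_cache:
            SinvS, Lc = chol_cond_cache[key]
        else:
            S = row.sigma2 * cache.R(row.phi)
            chol = cache.chol(*key)
            SinvS = cho_solve(chol, S, check_finite=False)  # Sigma^-1 S
            cond = S - S @ SinvS
            cond[np.diag_indices_from(cond)] += 1e-10 * row.sigma2
            Lc = np.linalg.cholesky(cond)
            if len(chol_cond_cache) > 64:
                chol_cond_cache.clear()
            chol_cond_cache[key] = (SinvS, Lc)
        resid = y - X @ np.array([row.beta0, row.beta1])
        mean = SinvS.T @ resid
        out[j] = mean + Lc @ rng.standard_normal(n)
    return SpatialEffectsDraws(out, day["site_id"].to_numpy())


@dataclass
class PredictionField:
    """Posterior-predictive PM2.5 at target cells."""

    lon: np.ndarray
    lat: np.ndarray
    aod: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    lo95: np.ndarray
    hi95: np.ndarray
    sd_process: np.ndarray  # predictive sd excluding the nugget
    cell_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (np.all(self.lo95 <= self.mean + 1e-12) and np.all(self.mean <= self.hi95 + 1e-12)):
            raise ValueError("interval bounds must bracket the mean")

    def to_frame(self) -> pd.DataFrame:
        d = {
            "lon": self.lon, "lat": self.lat, "aod": self.aod,
            "mean": self.mean, "sd": self.sd, "lo95": self.lo95, "hi95": self.hi95,
            "sd_process": self.sd_process,
        }
        if self.cell_id is not None:
            d = {"cell_id": self.cell_id, **d}
        return pd.DataFrame(d)


def posterior_predict(
    day: pd.DataFrame,
    chains: PosteriorChains,
    new_coords: np.ndarray,
    new_aod: np.ndarray,
    thin: int = 1,
    include_nugget: bool = True,
    cell_id: np.ndarray | None = None,
) -> PredictionField:
    """Posterior-predictive mean/sd/interval of PM2.5 at new locations.

    For each retained draw the exact conditional moments of y* given the
    data and that draw are used (omega integrated analytically):

        E[y*]   = beta0 + beta1*AOD* + c' Sigma^-1 (y - X beta)
        Var[y*] = sigma2 + tau2 - c' Sigma^-1 c        (per cell)

    with c = sigma2 * rho(distances to the data sites).  Across draws the
    field mean is the average of conditional means and the predictive
    variance follows the law of total variance; 95% bounds use a normal
    approximation of the draw mixture.  ``include_nugget=False`` drops tau2
    for mean-surface (rather than new-observation) uncertainty; the
    nugget-free sd is always reported alongside.

    A target coincident with a data site is handled exactly: as tau2 -> 0
    the conditional mean collapses to the observed value there.
    """
    coords, y, X = _day_arrays(day)
    new_coords = np.atleast_2d(np.asarray(new_coords, dtype=float))
    new_aod = np.asarray(new_aod, dtype=float)
    m = len(new_coords)
    ret = chains.retained()
    if thin > 1:
        ret = ret.iloc[::thin].reset_index(drop=True)
    D = squareform(pdist(coords))
    Dx = cdist(coords, new_coords)  # (n, m)
    cache = _DrawCache(D, chains.family)
    n_draws = len(ret)
    means = np.empty((n_draws, m))
    vars_proc = np.empty((n_draws, m))
    tau2s = ret["tau2"].to_numpy()
    cross_cache: dict[float, np.ndarray] = {}
    for j, row in enumerate(ret.itertuples(index=False)):
        if row.phi not in cross_cache:
            if len(cross_cache) > 64:
                cross_cache.clear()
            cross_cache[row.phi] = np.asarray(correlation(chains.family, Dx, row.phi))
        c = row.sigma2 * cross_cache[row.phi]  # (n, m)
        chol = cache.chol(row.sigma2, row.tau2, row.phi)
        resid = y - X @ np.array([row.beta0, row.beta1])
        alpha = cho_solve(chol, resid, check_finite=False)
        Sc = cho_solve(chol, c, check_finite=False)  # Sigma^-1 c
        means[j] = row.beta0 + row.beta1 * new_aod + c.T @ alpha
        vars_proc[j] = np.maximum(row.sigma2 - np.einsum("ij,ij->j", c, Sc), 0.0)
    var_within_proc = vars_proc.mean(axis=0)
    var_between = means.var(axis=0)
    mean = means.mean(axis=0)
    sd_process = np.sqrt(var_within_proc + var_between)
    var_total = var_within_proc + var_between + (tau2s.mean() if include_nugget else 0.0)
    sd = np.sqrt(var_total)
    return PredictionField(
        lon=new_coords[:, 0], lat=new_coords[:, 1], aod=new_aod,
        mean=mean, sd=sd, lo95=mean - 1.96 * sd, hi95=mean + 1.96 * sd,
        sd_process=sd_process, cell_id=cell_id,
    )


@dataclass
class GPDayFit:
    """Convenience bundle: a fitted daily model that can predict."""

    day: pd.DataFrame
    chains: PosteriorChains
    priors: PriorSpec

    def predict(self, coords: np.ndarray, aod: np.ndarray, thin: int = 1) -> PredictionField:
        return posterior_predict(self.day, self.chains, coords, aod, thin=thin)

    def fitted_values(self, thin: int = 1) -> np.ndarray:
        """In-sample fitted values beta0 + beta1*AOD_i + omega-bar_i."""
        coords, _, _ = _day_arrays(self.day)
        pf = posterior_predict(
            self.day, self.chains, coords, self.day["aod"].to_numpy(), thin=thin
        )
        return pf.mean


def fit_day(
    day: pd.DataFrame,
    n_iter: int = 5000,
    burn_in: int = 3000,
    seed: int = 0,
    family: str = "spherical",
    priors: PriorSpec | None = None,
    min_sites: int = 10,
) -> GPDayFit:
    """Build priors (variogram-informed) and run the sampler for one day."""
    if priors is None:
        priors = default_priors(day)
    chains = mh_sample(
        day, priors, n_iter=n_iter, burn_in=burn_in, seed=seed,
        family=family, min_sites=min_sites,
    )
    return GPDayFit(day, chains, priors)
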