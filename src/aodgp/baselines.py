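"""Comparison models: daily GWR and a year-long linear mixed-effects model.

GWR (geographically weighted regression) fits, per day, a locally weighted
least-squares line PM2.5 = beta0(s) + beta1(s)*AOD at every target location
with Gaussian kernel weights w_i = exp(-(d_i/b)^2 / 2); the fixed bandwidth
b (degrees) is selected per day by minimizing leave-one-out cross-validated
squared prediction error over a candidate grid with golden-section
refinement.

The LME model pools all days: PM2.5_{i,t} = (mu + mu'_t) + (beta + beta'_t)
AOD_{i,t} + eps_{i,t}, with the daily random intercept/slope pair drawn
from N(0, Psi1).  It is fitted by maximum likelihood via statsmodels'
MixedLM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import cdist

__all__ = [
    "GWRModel",
    "LMEModel",
    "gwr_select_bandwidth",
    "gwr_fit_predict",
    "lme_fit",
    "lme_predict",
]


# ----------------------------------------------------------------- GWR ----


@dataclass
class GWRModel:
    """A fitted daily GWR: bandwidth plus per-location coefficients."""

    bandwidth: float
    coords: np.ndarray
    beta0: np.ndarray
    beta1: np.ndarray

    def __post_init__(self) -> None:
        if self.bandwidth <= 0:
            raise ValueError(f"bandwidth must be positive, got {self.bandwidth}")


def _batch_wls(coords, aod, y, targets, bandwidth, loo: bool = False):
    """Local Gaussian-kernel WLS lines at every target, batched.

    Returns (beta0, beta1) arrays with NaN where the local system is
    singular (fewer than two effectively weighted points, or no local AOD
    contrast).  With ``loo=True`` the targets are the sites themselves and
    each site is excluded from its own fit.
    """
    d = cdist(targets, coords)
    w = np.exp(-0.5 * (d / bandwidth) ** 2)
    if loo:
        np.fill_diagonal(w, 0.0)
    # normal-equation blocks, one 2x2 system per target
    s0 = w.sum(axis=1)
    s1 = w @ aod
    s2 = w @ (aod * aod)
    t0 = w @ y
    t1 = w @ (aod * y)
    det = s0 * s2 - s1 * s1
    scale = np.maximum(s0 * s2, 1e-300)
    wmax = np.maximum(w.max(axis=1), 1e-300)
    support = (w > 1e-12 * wmax[:, None]).sum(axis=1)
    ok = (det > 1e-12 * scale) & (support >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        b0 = np.where(ok, (s2 * t0 - s1 * t1) / det, np.nan)
        b1 = np.where(ok, (s0 * t1 - s1 * t0) / det, np.nan)
    return b0, b1


def _loocv_sse(coords, aod, y, bandwidth):
    b0, b1 = _batch_wls(coords, aod, y, coords, bandwidth, loo=True)
    pred = b0 + b1 * aod
    ok = np.isfinite(pred)
    if not np.any(ok):
        return np.inf
    # rescale so partial-support bandwidths compare fairly
    return float(np.sum((y[ok] - pred[ok]) ** 2) * len(y) / ok.sum())


def gwr_select_bandwidth(
    day: pd.DataFrame, candidates: np.ndarray | None = None, refine: bool = True
) -> float:
    """Pick the Gaussian-kernel bandwidth minimizing LOOCV squared error.

    The default candidate grid is log-spaced from the median nearest-
    neighbour spacing up to the site-cloud diameter.  After the grid scan
    the winner is refined by bounded golden-section search between its
    neighbouring candidates.  Deterministic for fixed inputs.
    """
    if len(day) < 5:
        raise ValueError(f"GWR bandwidth selection needs >= 5 sites, got {len(day)}")
    coords = day[["lon", "lat"]].to_numpy(dtype=float)
    aod = day["aod"].to_numpy(dtype=float)
    y = day["pm25"].to_numpy(dtype=float)
    if candidates is None:
        dmat = cdist(coords, coords)
        np.fill_diagonal(dmat, np.inf)
        lo = max(np.median(dmat.min(axis=1)), 1e-6)
        hi = max(dmat[np.isfinite(dmat)].max(), 2 * lo)
        candidates = np.geomspace(lo, hi, 10)
    scores = np.array([_loocv_sse(coords, aod, y, b) for b in candidates])
    if not np.any(np.isfinite(scores)):
        raise RuntimeError("all candidate bandwidths yield singular local fits")
    k = int(np.argmin(scores))
    best = float(candidates[k])
    if refine and len(candidates) > 1:
        lo = candidates[max(k - 1, 0)]
        hi = candidates[min(k + 1, len(candidates) - 1)]
        if hi > lo:
            res = minimize_scalar(
                lambda b: _loocv_sse(coords, aod, y, b),
                bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-3 * (hi - lo)},
            )
            if np.isfinite(res.fun) and res.fun <= scores[k]:
                best = float(res.x)
    return best


def gwr_fit_predict(
    day: pd.DataFrame,
    bandwidth: float,
    targets: pd.DataFrame,
) -> tuple[np.ndarray, GWRModel]:
    """Predict PM2.5 at targets by local WLS lines; NaN where singular.

    ``targets`` needs columns lon, lat, aod.  Returns (predictions, model
    with per-target local coefficients).  A local fit whose effective
    sample cannot support a line (fewer than two weighted points, or
    constant local AOD) yields a NaN prediction rather than an error.
    """
    if bandwidth <= 0:
        raise ValueError(f"bandwidth must be positive, got {bandwidth}")
    coords = day[["lon", "lat"]].to_numpy(dtype=float)
    aod = day["aod"].to_numpy(dtype=float)
    y = day["pm25"].to_numpy(dtype=float)
    tc = targets[["lon", "lat"]].to_numpy(dtype=float)
    ta = targets["aod"].to_numpy(dtype=float)
    b0, b1 = _batch_wls(coords, aod, y, tc, bandwidth)
    preds = b0 + b1 * ta
    return preds, GWRModel(bandwidth, tc, b0, b1)


# ----------------------------------------------------------------- LME ----


@dataclass
class LMEModel:
    """Fixed intercept/slope, daily random effects, their covariance Psi1."""

    mu: float
    beta: float
    psi1: np.ndarray          # 2x2 covariance of (mu'_t, beta'_t)
    sigma2_eps: float
    ranef: pd.DataFrame       # index day id; columns mu_t, beta_t
    loglike: float
    converged: bool

    def __post_init__(self) -> None:
        if self.psi1.shape != (2, 2):
            raise ValueError("Psi1 must be 2x2")
        if not np.allclose(self.psi1, self.psi1.T, atol=1e-8):
            raise ValueError("Psi1 must be symmetric")
        if np.linalg.eigvalsh(self.psi1).min() < -1e-8:
            raise ValueError("Psi1 must be positive semi-definite")


def lme_fit(data: pd.DataFrame, day_col: str = "date") -> LMEModel:
    """ML fit of the daily random-intercept-and-slope model.

    ``data`` needs columns pm25, aod and ``day_col``.  Fitted with
    statsmodels MixedLM (ML, not REML); empirical-Bayes daily effects are
    returned per day.  Raises on hard non-convergence.
    """
    import statsmodels.api as sm

    days = data[day_col].astype(str)
    if days.nunique() < 2:
        raise ValueError("LME needs at least 2 days")
    if data.groupby(days).size().min() < 2:
        raise ValueError("every day needs at least 2 matchups")
    y = data["pm25"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(data)), data["aod"].to_numpy(dtype=float)])
    model = sm.MixedLM(y, X, groups=days.to_numpy(), exog_re=X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=False, method=["lbfgs", "cg"])
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(f"LME fit failed: {exc}") from exc
    if not np.all(np.isfinite(res.fe_params)):
        raise RuntimeError(
            f"LME fit did not converge (last params {res.fe_params}, "
            f"gradient norm unavailable)"
        )
    re = pd.DataFrame(res.random_effects).T
    re.columns = ["mu_t", "beta_t"]
    psi1 = np.asarray(res.cov_re)
    psi1 = 0.5 * (psi1 + psi1.T)
    # clip tiny negative eigenvalues from boundary fits
    evals, evecs = np.linalg.eigh(psi1)
    psi1 = (evecs * np.maximum(evals, 0.0)) @ evecs.T
    return LMEModel(
        mu=float(res.fe_params[0]),
        beta=float(res.fe_params[1]),
        psi1=psi1,
        sigma2_eps=float(res.scale),
        ranef=re,
        loglike=float(res.llf),
        converged=bool(res.converged),
    )


def lme_predict(
    model: LMEModel, day_ids, aod
) -> tuple[np.ndarray, np.ndarray]:
    """Predict (mu+mu'_t) + (beta+beta'_t)*AOD per record.

    Unseen day ids fall back to the fixed-effects line; the second return
    value flags those records.
    """
    day_ids = pd.Series(day_ids).astype(str)
    aod = np.asarray(aod, dtype=float)
    if len(day_ids) != len(aod):
        raise ValueError("day_ids and aod must have equal length")
    mu_t = day_ids.map(model.ranef["mu_t"]).to_numpy(dtype=float)
    beta_t = day_ids.map(model.ranef["beta_t"]).to_numpy(dtype=float)
    fallback = ~np.isfinite(mu_t)
    mu_t = np.where(fallback, 0.0, mu_t)
    beta_t = np.where(fallback, 0.0, beta_t)
    preds = (model.mu + mu_t) + (model.beta + beta_t) * aod
    return preds, fallback
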