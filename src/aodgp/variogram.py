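"""Spatial correlation families and variogram analysis.

The daily spatial model assumes a zero-mean Gaussian process with covariance
``K(h) = sigma2 * rho(h; phi)`` where ``h`` is the Euclidean distance between
two locations in decimal degrees and ``phi`` is the spatial decay (1/phi is
the effective range, the distance beyond which correlation is negligible —
for the spherical family it is exactly zero there).

Four correlation families are supported: spherical, Matérn, Gaussian and
linear.  The spherical family is

    rho(h; phi) = 1 - 1.5*h*phi + 0.5*(h*phi)**3   for 0 < h < 1/phi
                = 0                                 for h >= 1/phi
                = 1                                 at h = 0.

Empirical semivariograms use the classical Matheron estimator, and the four
families are fitted to it by equally weighted (unit weight per bin) ordinary
least squares; the family with the smallest sum of squared residuals is
selected.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, special
from scipy.spatial.distance import pdist

__all__ = [
    "FAMILIES",
    "correlation",
    "VariogramModel",
    "EmpiricalVariogram",
    "empirical_variogram",
    "fit_variogram",
    "select_family",
]

#: Supported families, in tie-break preference order.
FAMILIES: tuple[str, ...] = ("spherical", "matern", "gaussian", "linear")


def correlation(family: str, h, phi: float, nu: float | None = None) -> np.ndarray:
    """Correlation ``rho(h; phi[, nu])`` for one of the four families.

    Parameters
    ----------
    family
        One of ``spherical``, ``matern``, ``gaussian``, ``linear``.
    h
        Distance(s), degrees; must be non-negative.
    phi
        Spatial decay, 1/degrees; ``1/phi`` is the effective range.
    nu
        Matérn smoothness.  Required for the Matérn family and rejected for
        the others (the spherical family has no smoothness parameter).
    """
    h = np.asarray(h, dtype=float)
    if phi <= 0:
        raise ValueError(f"phi must be positive, got {phi}")
    if np.any(h < 0):
        raise ValueError("distances must be non-negative")
    if family == "matern":
        if nu is None:
            raise ValueError("the matern family requires a smoothness nu")
        if nu <= 0:
            raise ValueError(f"nu must be positive, got {nu}")
    elif nu is not None:
        raise ValueError(f"the {family} family has no smoothness parameter (nu was supplied)")

    t = h * phi
    if family == "spherical":
        rho = np.where(t < 1.0, 1.0 - 1.5 * t + 0.5 * t**3, 0.0)
    elif family == "gaussian":
        rho = np.exp(-(t**2))
    elif family == "linear":
        rho = np.clip(1.0 - t, 0.0, None)
    elif family == "matern":
        rho = np.ones_like(t)
        pos = t > 0
        tp = t[pos]
        rho[pos] = (2.0 ** (1.0 - nu) / special.gamma(nu)) * tp**nu * special.kv(nu, tp)
        # kv underflows to 0 for large arguments, which is the correct limit
        rho = np.nan_to_num(rho, nan=0.0)
    else:
        raise ValueError(f"unknown correlation family {family!r}")
    return rho if rho.shape else float(rho)


@dataclass(frozen=True)
class VariogramModel:
    """A fitted variogram: nugget + partial sill times (1 - correlation)."""

    family: str
    tau2: float   # nugget
    sigma2: float  # partial sill
    phi: float    # decay, 1/degrees
    nu: float | None = None
    ssr: float | None = None  # attained sum of squared residuals of the fit

    def __post_init__(self) -> None:
        if self.sigma2 <= 0:
            raise ValueError(f"sigma2 must be positive, got {self.sigma2}")
        if self.tau2 < 0:
            raise ValueError(f"tau2 must be non-negative, got {self.tau2}")
        if self.phi <= 0:
            raise ValueError(f"phi must be positive, got {self.phi}")
        if self.family == "matern" and (self.nu is None or self.nu <= 0):
            raise ValueError("matern requires nu > 0")
        if self.family != "matern" and self.nu is not None:
            raise ValueError(f"{self.family} has no smoothness parameter")

    @property
    def effective_range(self) -> float:
        return 1.0 / self.phi

    @property
    def sill(self) -> float:
        return self.tau2 + self.sigma2

    def correlation(self, h) -> np.ndarray:
        return correlation(self.family, h, self.phi, self.nu)

    def semivariance(self, h) -> np.ndarray:
        """gamma(h) = tau2 + sigma2*(1 - rho(h)) for h > 0; gamma(0) = 0."""
        h = np.asarray(h, dtype=float)
        g = self.tau2 + self.sigma2 * (1.0 - correlation(self.family, h, self.phi, self.nu))
        g = np.where(h == 0.0, 0.0, g)
        return g if g.shape else float(g)

    def to_json(self) -> str:
        return json.dumps(
            {"family": self.family, "tau2": self.tau2, "sigma2": self.sigma2,
             "phi": self.phi, "nu": self.nu, "ssr": self.ssr}
        )

    @classmethod
    def from_json(cls, s: str) -> "VariogramModel":
        d = json.loads(s)
        return cls(**d)


@dataclass(frozen=True)
class EmpiricalVariogram:
    """Binned Matheron semivariances."""

    bin_centers: np.ndarray
    gamma: np.ndarray
    counts: np.ndarray
    max_lag: float

    def __post_init__(self) -> None:
        if np.any(self.gamma < 0):
            raise ValueError("semivariances must be non-negative")
        if np.any(self.counts < 1):
            raise ValueError("retained bins must have at least one pair")
        if np.any(np.diff(self.bin_centers) <= 0):
            raise ValueError("bins must be sorted ascending")

    @property
    def n_bins(self) -> int:
        return len(self.bin_centers)


def empirical_variogram(
    coords: np.ndarray,
    values: np.ndarray,
    n_bins: int = 15,
    max_lag: float | None = None,
) -> EmpiricalVariogram:
    """Classical Matheron semivariogram on equal-width distance bins.

    ``gamma(bin) = sum (z_i - z_j)^2 / (2 N_pairs)`` over pairs whose
    separation falls in the bin.  Empty bins are dropped.  The default max
    lag is half the maximum pairwise distance.
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(coords) < 2:
        raise ValueError("need at least 2 points for a variogram")
    d = pdist(coords)
    dmax = d.max()
    if dmax == 0:
        raise ValueError("all points are coincident; variogram undefined")
    if max_lag is None:
        max_lag = dmax / 2.0
    if max_lag <= 0:
        raise ValueError(f"max_lag must be positive, got {max_lag}")
    sq = pdist(values[:, None], metric="sqeuclidean")
    edges = np.linspace(0.0, max_lag, n_bins + 1)
    idx = np.digitize(d, edges) - 1  # bin index; outside [0, n_bins) dropped
    keep = (idx >= 0) & (idx < n_bins) & (d > 0)
    counts = np.bincount(idx[keep], minlength=n_bins)
    sums = np.bincount(idx[keep], weights=sq[keep], minlength=n_bins)
    nonempty = counts > 0
    gamma = sums[nonempty] / (2.0 * counts[nonempty])
    centers = 0.5 * (edges[:-1] + edges[1:])[nonempty]
    return EmpiricalVariogram(centers, gamma, counts[nonempty], float(max_lag))


def _fit_one(emp: EmpiricalVariogram, family: str, nu: float | None):
    """Bounded least squares from one deterministic multi-start family."""
    h = emp.bin_centers
    g = emp.gamma
    sill0 = max(g.max(), 1e-12)
    # method-of-moments range: first lag reaching 95% of the apparent sill
    above = np.nonzero(g >= 0.95 * g.max())[0]
    range0 = h[above[0]] if len(above) else h[-1]
    range0 = max(range0, h[0])

    def resid(theta):
        tau2, sigma2, phi = theta[:3]
        nu_ = theta[3] if len(theta) > 3 else nu
        model = tau2 + sigma2 * (1.0 - correlation(family, h, phi, nu_ if family == "matern" else None))
        return model - g

    lo = [0.0, 1e-10 * sill0, 1e-3 / emp.max_lag]
    hi = [2.0 * sill0, 4.0 * sill0, 1e3 / h[0]]
    # 5 deterministic starts seeded from method-of-moments
    starts = [
        [0.0, sill0, 1.0 / range0],
        [0.1 * sill0, 0.9 * sill0, 1.0 / range0],
        [0.3 * sill0, 0.7 * sill0, 1.0 / range0],
        [0.0, sill0, 2.0 / range0],
        [0.0, sill0, 0.5 / range0],
    ]
    best = None
    for s0 in starts:
        x0 = np.clip(s0, lo, hi)
        try:
            res = optimize.least_squares(resid, x0, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError(f"variogram fit failed to converge for family {family!r}")
    tau2, sigma2, phi = best.x
    ssr = float(2.0 * best.cost)  # least_squares cost = 0.5 * SSR
    return VariogramModel(family, float(tau2), float(max(sigma2, 1e-12)), float(phi),
                          nu if family == "matern" else None, ssr)


def fit_variogram(emp: EmpiricalVariogram, family: str) -> VariogramModel:
    """Fit one family to an empirical variogram by unit-weight OLS.

    Minimizes the unweighted sum of squared residuals between binned
    Matheron semivariances and the model curve over (tau2, sigma2, phi)
    — plus nu for the Matérn family, which is profiled over a fixed grid
    {0.5, 1.0, 1.5, 2.5} to tame the nu/phi ridge, then kept at the best
    grid value.  Returns the model with its attained SSR.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose one of {FAMILIES}")
    min_bins = 4 if family == "matern" else 3
    if emp.n_bins < min_bins:
        raise ValueError(f"need >= {min_bins} retained bins to fit {family!r}, got {emp.n_bins}")
    if family == "matern":
        fits = []
        for nu in (0.5, 1.0, 1.5, 2.5):
            try:
                fits.append(_fit_one(emp, family, nu))
            except RuntimeError:
                continue
        if not fits:
            raise RuntimeError("matern fit failed for every nu on the grid")
        return min(fits, key=lambda m: m.ssr)
    return _fit_one(emp, family, None)


def select_family(
    emp: EmpiricalVariogram, families: Sequence[str] = FAMILIES
) -> VariogramModel:
    """Fit the candidate families and return the minimum-SSR model.

    Ties (SSR equal to within a 1e-9 relative tolerance) are broken by the
    preference order spherical > matern > gaussian > linear.
    """
    fits: list[VariogramModel] = []
    errors: list[str] = []
    for fam in families:
        try:
            fits.append(fit_variogram(emp, fam))
        except (RuntimeError, ValueError) as exc:
            errors.append(f"{fam}: {exc}")
    if not fits:
        raise RuntimeError("all variogram family fits failed: " + "; ".join(errors))
    ssr_min = min(m.ssr for m in fits)
    tol = 1e-9 * max(ssr_min, 1e-300) + 1e-15
    tied = [m for m in fits if m.ssr <= ssr_min + tol]
    tied.sort(key=lambda m: FAMILIES.index(m.family))
    return tied[0]
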