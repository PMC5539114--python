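"""Synthetic daily PM2.5/AOD matchup generator with known ground truth.

The generator emulates the statistical structure the daily spatial model
assumes: at monitoring site i,

    PM2.5_i = beta0 + beta1 * AOD_i + omega_i + eps_i,

with ``omega`` a zero-mean Gaussian process with covariance
``sigma2 * rho(h; phi)`` over Euclidean distance in degrees, and
``eps ~ N(0, tau2)`` iid (the nugget).  Gridded AOD fields are spatially
correlated random fields with cloud-driven, spatially clumped missingness,
floored at -0.05 (satellite retrievals allow small negative AOD down to
that value).

Default magnitudes mimic a polluted study year: annual mean PM2.5 near
68 µg/m³ at AOD near 0.77.  Default truth (beta0=20, beta1=70, sigma2=400,
tau2=25, phi=1/3 per degree, spherical) gives a marginal PM2.5 spread in
the tens of µg/m³.  AOD fields default to a within-day spatial standard
deviation of 0.4 (variance 0.16) with a 1° effective range — the annual
tabulated AOD spread (~0.63) also contains day-to-day variation, so the
single-day spatial spread is set smaller.

Everything is a pure function of its inputs and the integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.distance import squareform, pdist

from .grids import GridSpec
from .variogram import correlation

__all__ = [
    "TruthParams",
    "SyntheticDay",
    "generate_aod_field",
    "apply_cloud_mask",
    "generate_day",
    "generate_days",
    "AOD_FLOOR",
]

#: Lower clip for synthetic AOD, matching the small negative retrievals the
#: Dark Target algorithm permits.
AOD_FLOOR = -0.05


@dataclass(frozen=True)
class TruthParams:
    """Generating parameters of the daily spatial model.

    beta0: µg/m³ intercept; beta1: µg/m³ per AOD unit; sigma2: partial sill
    (µg/m³)²; tau2: nugget (µg/m³)²; phi: spatial decay, 1/degrees
    (1/phi = effective range).
    """

    beta0: float = 20.0
    beta1: float = 70.0
    sigma2: float = 400.0
    tau2: float = 25.0
    phi: float = 1.0 / 3.0
    family: str = "spherical"

    def __post_init__(self) -> None:
        if self.sigma2 < 0:
            raise ValueError(f"sigma2 must be non-negative, got {self.sigma2}")
        if self.tau2 < 0:
            raise ValueError(f"tau2 must be non-negative, got {self.tau2}")
        if self.phi <= 0:
            raise ValueError(f"phi must be positive, got {self.phi}")


@dataclass(frozen=True)
class SyntheticDay:
    """One synthetic day: the matchup table plus everything the generator knew.

    ``matchups`` has columns site_id, lon, lat, date, pm25, aod.  ``omega``
    is the true spatial random effect at each site (µg/m³), ``eps`` the
    nugget noise actually drawn, ``aod_field`` the full gridded AOD before
    cloud masking (shape grid.shape), ``mask`` the boolean cloud mask
    (True = missing).  Regenerating with the same seed reproduces
    bit-identical output.
    """

    matchups: pd.DataFrame
    omega: np.ndarray
    eps: np.ndarray
    aod_field: np.ndarray
    mask: np.ndarray
    truth: TruthParams
    grid: GridSpec
    date: str
    seed: int

    def __post_init__(self) -> None:
        if self.aod_field.shape != self.grid.shape or self.mask.shape != self.grid.shape:
            raise ValueError("aod_field and mask must have the grid's shape")
        if len(self.omega) != len(self.matchups):
            raise ValueError("omega length must equal number of sites")

    @property
    def n_sites(self) -> int:
        return len(self.matchups)

    def masked_aod(self) -> np.ndarray:
        """Gridded AOD with cloud-masked cells set to NaN."""
        out = self.aod_field.copy()
        out[self.mask] = np.nan
        return out


def _grf(grid: GridSpec, sigma2: float, phi: float, family: str, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean stationary Gaussian random field on the grid.

    Sampled by 2-D circulant embedding: the covariance is laid out on a
    torus twice the grid size, diagonalized by FFT, and any (small) negative
    embedding eigenvalues are clipped to zero, which makes the sample
    covariance approximate rather than exact but keeps the sill within a
    few percent for the ranges used here.
    """
    if sigma2 == 0.0:
        return np.zeros(grid.shape)
    ny, nx = grid.shape
    my, mx = 2 * ny, 2 * nx
    dy = np.minimum(np.arange(my), my - np.arange(my)) * grid.cell_size
    dx = np.minimum(np.arange(mx), mx - np.arange(mx)) * grid.cell_size
    h = np.hypot(dy[:, None], dx[None, :])
    cov = sigma2 * np.asarray(correlation(family, h, phi))
    lam = np.fft.fft2(cov).real
    lam = np.maximum(lam, 0.0)
    xi = rng.standard_normal((my, mx)) + 1j * rng.standard_normal((my, mx))
    z = np.fft.fft2(np.sqrt(lam) * xi) / np.sqrt(mx * my)
    # real and imaginary parts are two independent fields with covariance cov
    return np.ascontiguousarray(z.real[:ny, :nx])


def generate_aod_field(
    grid: GridSpec,
    mean: float = 0.77,
    sigma2: float = 0.16,
    phi: float = 1.0,
    family: str = "spherical",
    seed: int = 0,
) -> np.ndarray:
    """Spatially correlated gridded AOD, clipped below at the -0.05 floor.

    Parameters
    ----------
    mean
        Field mean AOD; must be >= -0.05.
    sigma2, phi, family
        Variance, decay (1/degrees) and correlation family of the spatial
        structure.  ``sigma2 = 0`` gives a constant field.
    """
    if sigma2 < 0:
        raise ValueError(f"sigma2 must be non-negative, got {sigma2}")
    if mean < AOD_FLOOR:
        raise ValueError(f"mean AOD must be >= {AOD_FLOOR}, got {mean}")
    rng = np.random.default_rng(seed)
    field = mean + _grf(grid, sigma2, phi, family, rng)
    return np.maximum(field, AOD_FLOOR)


def apply_cloud_mask(
    field: np.ndarray,
    grid: GridSpec,
    coverage: float,
    clump_scale: float = 0.5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Mask a fraction of cells, spatially clumped like cloud decks.

    A uniform noise image is smoothed with a Gaussian kernel of standard
    deviation ``clump_scale`` degrees (0 = independent cells) and
    thresholded at its ``coverage`` sample quantile, so the masked fraction
    matches the request to within one cell.  Returns (masked field with NaN
    in masked cells, boolean mask).
    """
    if not 0.0 <= coverage <= 1.0:
        raise ValueError(f"coverage must be in [0, 1], got {coverage}")
    field = np.asarray(field, dtype=float)
    if field.shape != grid.shape:
        raise ValueError(f"field shape {field.shape} does not match grid {grid.shape}")
    rng = np.random.default_rng(seed)
    if coverage == 0.0:
        mask = np.zeros(grid.shape, dtype=bool)
    elif coverage == 1.0:
        mask = np.ones(grid.shape, dtype=bool)
    else:
        noise = rng.random(grid.shape)
        if clump_scale > 0:
            noise = ndimage.gaussian_filter(noise, sigma=clump_scale / grid.cell_size, mode="wrap")
        thresh = np.quantile(noise, coverage)
        mask = noise <= thresh
    out = field.copy()
    out[mask] = np.nan
    return out, mask


def _draw_omega(coords: np.ndarray, truth: TruthParams, rng: np.random.Generator) -> np.ndarray:
    """Draw the spatial random effect at the sites by dense factorization."""
    n = len(coords)
    if truth.sigma2 == 0.0:
        return np.zeros(n)
    dmat = squareform(pdist(coords))
    cov = truth.sigma2 * np.asarray(correlation(truth.family, dmat, truth.phi))
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            f"site covariance is not positive definite (sigma2={truth.sigma2}, "
            f"phi={truth.phi}, family={truth.family}); duplicate coordinates?"
        ) from exc
    return chol @ rng.standard_normal(n)


def generate_day(
    grid: GridSpec,
    n_sites: int,
    truth: TruthParams | None = None,
    date: str = "2013-01-01",
    seed: int = 0,
    aod_mean: float = 0.77,
    aod_sigma2: float = 0.16,
    aod_phi: float = 1.0,
    aod_family: str = "spherical",
    cloud_coverage: float = 0.3,
    cloud_clump_scale: float = 0.5,
) -> SyntheticDay:
    """Generate one day's matchup set with its full ground truth.

    Sites occupy distinct cloud-free grid cells (at most one monitor per
    cell; duplicate coordinates are thereby impossible), jittered uniformly
    within the cell.  Each site's AOD is its cell value; PM2.5 follows the
    daily spatial model exactly, with the drawn omega and nugget noise
    recorded for recovery tests.
    """
    if n_sites < 2:
        raise ValueError(f"need at least 2 sites, got {n_sites}")
    truth = truth or TruthParams()
    ss = np.random.SeedSequence(seed)
    s_aod, s_cloud, s_sites, s_omega, s_eps = ss.spawn(5)

    aod_field = generate_aod_field(grid, aod_mean, aod_sigma2, aod_phi, aod_family,
                                   seed=s_aod)
    _, mask = apply_cloud_mask(aod_field, grid, cloud_coverage, cloud_clump_scale,
                               seed=s_cloud)
    clear = np.flatnonzero(~mask.ravel())
    if len(clear) < n_sites:
        raise ValueError(
            f"only {len(clear)} cloud-free cells for {n_sites} sites; "
            "reduce cloud_coverage or enlarge the grid"
        )
    rng_sites = np.random.default_rng(s_sites)
    cells = np.sort(rng_sites.choice(clear, size=n_sites, replace=False))
    centers = grid.cell_centers()[cells]
    jitter = rng_sites.uniform(-0.45, 0.45, size=(n_sites, 2)) * grid.cell_size
    coords = centers + jitter

    omega = _draw_omega(coords, truth, np.random.default_rng(s_omega))
    eps = np.sqrt(truth.tau2) * np.random.default_rng(s_eps).standard_normal(n_sites)
    aod = aod_field.ravel()[cells]
    pm25 = truth.beta0 + truth.beta1 * aod + omega + eps

    matchups = pd.DataFrame(
        {
            "site_id": [f"s{k:04d}" for k in range(n_sites)],
            "lon": coords[:, 0],
            "lat": coords[:, 1],
            "date": date,
            "pm25": pm25,
            "aod": aod,
        }
    )
    return SyntheticDay(matchups, omega, eps, aod_field, mask, truth, grid, date, seed)


def generate_days(
    grid: GridSpec,
    n_days: int,
    n_sites: int,
    truth: TruthParams | None = None,
    start_date: str = "2013-01-01",
    seed: int = 0,
    beta0_day_sd: float = 0.0,
    beta1_day_sd: float = 0.0,
    **day_kwargs,
) -> list[SyntheticDay]:
    """Generate a sequence of independent synthetic days.

    Dates advance daily from ``start_date``.  Optional day-level Gaussian
    perturbations of the intercept/slope (``beta0_day_sd``, ``beta1_day_sd``,
    both 0 by default) emulate the day-to-day variability a mixed-effects
    model targets; each day's effective truth is recorded on the day itself.
    """
    truth = truth or TruthParams()
    ss = np.random.SeedSequence(seed)
    day_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n_days)]
    rng_fx = np.random.default_rng(ss.spawn(1)[0]) if (beta0_day_sd or beta1_day_sd) else None
    dates = pd.date_range(start_date, periods=n_days, freq="D").strftime("%Y-%m-%d")
    days = []
    for t in range(n_days):
        tr = truth
        if rng_fx is not None:
            tr = replace(
                truth,
                beta0=truth.beta0 + beta0_day_sd * rng_fx.standard_normal(),
                beta1=truth.beta1 + beta1_day_sd * rng_fx.standard_normal(),
            )
        days.append(generate_day(grid, n_sites, tr, dates[t], day_seeds[t], **day_kwargs))
    return days
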