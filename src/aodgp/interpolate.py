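"""Grid assignment and variogram-constrained ordinary-kriging gap fill.

Cloud gaps in the daily gridded AOD are filled by ordinary kriging, but only
where the fill is defensible: a missing cell is filled only when at least
five observed cells lie within the effective range (1/phi) of the day's
fitted AOD variogram, mirroring the buffer-zone rule used to enlarge
PM2.5/AOD matchup datasets.  Interpolated cells are flagged and never used
as donors for other cells, and downstream prediction maps exclude them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist, pdist, squareform

from .grids import GridSpec
from .variogram import VariogramModel

__all__ = [
    "KrigingSolution",
    "GapFillReport",
    "SingularKrigingError",
    "assign_points_to_grid",
    "ordinary_kriging",
    "buffer_gapfill",
    "PROV_OBSERVED",
    "PROV_INTERPOLATED",
    "PROV_MISSING",
]

# provenance band values for filled fields
PROV_OBSERVED = 0
PROV_INTERPOLATED = 1
PROV_MISSING = 2


class SingularKrigingError(np.linalg.LinAlgError):
    """The ordinary-kriging system is singular (duplicate/degenerate donors)."""


@dataclass(frozen=True)
class KrigingSolution:
    """One ordinary-kriging prediction: weights, multiplier, value, variance."""

    weights: np.ndarray
    lagrange: float
    value: float
    variance: float

    def __post_init__(self) -> None:
        s = float(np.sum(self.weights))
        if abs(s - 1.0) > 1e-10:
            raise SingularKrigingError(
                f"ordinary-kriging weights sum to {s!r}, not 1; system ill-conditioned"
            )
        if self.variance < -1e-9:
            raise SingularKrigingError(f"negative kriging variance {self.variance}")
        if self.variance < 0:  # tiny negative round-off
            object.__setattr__(self, "variance", 0.0)


@dataclass
class GapFillReport:
    """Bookkeeping of one buffer-constrained gap fill."""

    n_observed: int
    n_filled: int
    n_missing: int
    neighbor_counts: dict[int, int] = field(default_factory=dict)  # per missing cell id

    @property
    def n_total(self) -> int:
        return self.n_observed + self.n_filled + self.n_missing


def assign_points_to_grid(
    points: pd.DataFrame, grid: GridSpec, value_col: str = "value"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign point records to grid cells; average multiple points per cell.

    ``points`` needs columns lon, lat and ``value_col``.  Cells are
    half-open ``[west, east) x [south, north)``; a point on a shared edge
    goes to the cell whose west/south edge it lies on.  Returns
    ``(cell_values, rejects)``: the first with columns cell_id, lon, lat
    (cell center), value (mean over points) and n_points; the second the
    out-of-bounds rows, reported rather than silently dropped.
    """
    for col in ("lon", "lat", value_col):
        if col not in points.columns:
            raise ValueError(f"points table lacks required column {col!r}")
    ids = grid.locate(points["lon"].to_numpy(), points["lat"].to_numpy())
    rejects = points.loc[ids < 0].copy()
    ok = points.loc[ids >= 0].copy()
    ok["cell_id"] = ids[ids >= 0]
    agg = ok.groupby("cell_id")[value_col].agg(["mean", "size"]).reset_index()
    centers = grid.cell_centers()[agg["cell_id"].to_numpy()]
    cell_values = pd.DataFrame(
        {
            "cell_id": agg["cell_id"],
            "lon": centers[:, 0],
            "lat": centers[:, 1],
            "value": agg["mean"],
            "n_points": agg["size"],
        }
    )
    return cell_values, rejects


def ordinary_kriging(
    obs_coords: np.ndarray,
    obs_values: np.ndarray,
    targets: np.ndarray,
    vg: VariogramModel,
) -> list[KrigingSolution]:
    """Solve the ordinary-kriging system for each target location.

    Uses the semivariance ``gamma(h) = tau2 + sigma2*(1 - rho(h))`` for
    h > 0 and ``gamma(0) = 0``, so with a zero nugget the predictor is an
    exact interpolator.  The unbiasedness constraint (weights sum to 1) is
    enforced through a Lagrange multiplier and verified on every solve.
    """
    obs_coords = np.atleast_2d(np.asarray(obs_coords, dtype=float))
    obs_values = np.asarray(obs_values, dtype=float)
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    n = len(obs_coords)
    if n < 2:
        raise ValueError(f"ordinary kriging needs >= 2 observations, got {n}")
    d = pdist(obs_coords)
    if d.min() == 0.0:
        dup = np.argwhere(squareform(d) + np.eye(n) == 0)
        raise SingularKrigingError(
            f"duplicate observation coordinates at index pairs {dup[: 3].tolist()}"
        )
    gamma_mat = np.zeros((n + 1, n + 1))
    gamma_mat[:n, :n] = squareform(vg.semivariance(d))
    gamma_mat[n, :n] = 1.0
    gamma_mat[:n, n] = 1.0
    try:
        from scipy.linalg import lu_factor, lu_solve

        lu = lu_factor(gamma_mat)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise SingularKrigingError(f"singular kriging system: {exc}") from exc

    g0 = vg.semivariance(cdist(obs_coords, targets))  # (n, m)
    rhs = np.vstack([g0, np.ones(targets.shape[0])])
    try:
        sol = lu_solve(lu, rhs)
    except (np.linalg.LinAlgError, ValueError) as exc:
        raise SingularKrigingError(f"singular kriging system: {exc}") from exc
    if not np.all(np.isfinite(sol)):
        raise SingularKrigingError("kriging solve produced non-finite weights "
                                   "(collinear or duplicate configuration)")
    out = []
    for j in range(targets.shape[0]):
        w = sol[:n, j]
        mu = float(sol[n, j])
        value = float(w @ obs_values)
        variance = float(w @ g0[:, j] + mu)
        out.append(KrigingSolution(w, mu, value, variance))
    return out


def buffer_gapfill(
    field: np.ndarray,
    grid: GridSpec,
    vg: VariogramModel,
    min_donors: int = 5,
    max_donors: int = 50,
) -> tuple[np.ndarray, np.ndarray, GapFillReport]:
    """Fill cloud gaps by ordinary kriging within range-based buffers.

    For each NaN cell, donors are the *observed* cells whose centers lie
    within the fitted variogram's effective range ``1/phi`` of the missing
    cell's center.  The cell is filled only when at least ``min_donors``
    (five, per the buffer rule) donors exist, kriging on at most
    ``max_donors`` nearest donors.  Interpolated cells never serve as
    donors.  Returns (filled field, provenance band, report); provenance is
    0 observed, 1 interpolated, 2 still missing.
    """
    field = np.asarray(field, dtype=float)
    if field.shape != grid.shape:
        raise ValueError(f"field shape {field.shape} does not match grid {grid.shape}")
    if not np.isfinite(vg.effective_range):
        raise ValueError("variogram must have a finite effective range")
    filled = field.copy()
    prov = np.where(np.isfinite(field), PROV_OBSERVED, PROV_MISSING).astype(np.int8)
    obs_flat = np.flatnonzero(np.isfinite(field).ravel())
    miss_flat = np.flatnonzero(~np.isfinite(field).ravel())
    report = GapFillReport(n_observed=len(obs_flat), n_filled=0, n_missing=len(miss_flat))
    if len(obs_flat) < min_donors or len(miss_flat) == 0:
        return filled, prov, report
    centers = grid.cell_centers()
    tree = cKDTree(centers[obs_flat])
    obs_vals = field.ravel()[obs_flat]
    rng_dist = vg.effective_range
    flat = filled.ravel()
    prov_flat = prov.ravel()
    n_filled = 0
    for cid in miss_flat:
        idx = tree.query_ball_point(centers[cid], rng_dist)
        report.neighbor_counts[int(cid)] = len(idx)
        if len(idx) < min_donors:
            continue
        if len(idx) > max_donors:
            dists = np.linalg.norm(centers[obs_flat[idx]] - centers[cid], axis=1)
            idx = [idx[k] for k in np.argsort(dists)[:max_donors]]
        sol = ordinary_kriging(centers[obs_flat[idx]], obs_vals[idx], centers[cid][None, :], vg)
        flat[cid] = sol[0].value
        prov_flat[cid] = PROV_INTERPOLATED
        n_filled += 1
    report.n_filled = n_filled
    report.n_missing = len(miss_flat) - n_filled
    return flat.reshape(grid.shape), prov_flat.reshape(grid.shape), report
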