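"""Plain-text readers/writers for the pipeline's tables and rasters.

Point tables are CSV (site_id, lon, lat, date, pm25, aod); gridded fields
are CSV long format (cell_id, lon, lat, value[, provenance]); chains,
variograms and metrics are CSV/JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import GridSpec

__all__ = [
    "write_matchups",
    "read_matchups",
    "write_field",
    "read_field",
    "write_field_netcdf",
    "write_json",
]

MATCHUP_COLUMNS = ["site_id", "lon", "lat", "date", "pm25", "aod"]


def write_matchups(matchups: pd.DataFrame, path) -> Path:
    path = Path(path)
    matchups[MATCHUP_COLUMNS].to_csv(path, index=False)
    return path


def read_matchups(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"site_id": str, "date": str})
    missing = [c for c in MATCHUP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def write_field(field: np.ndarray, grid: GridSpec, path, provenance: np.ndarray | None = None) -> Path:
    """Write a gridded field as long-format CSV in cell-id order."""
    path = Path(path)
    centers = grid.cell_centers()
    df = pd.DataFrame(
        {
            "cell_id": np.arange(grid.n_cells),
            "lon": centers[:, 0],
            "lat": centers[:, 1],
            "value": np.asarray(field, dtype=float).ravel(),
        }
    )
    if provenance is not None:
        df["provenance"] = np.asarray(provenance).ravel()
    df.to_csv(path, index=False)
    return path


def read_field(path, grid: GridSpec) -> np.ndarray:
    df = pd.read_csv(path)
    for col in ("cell_id", "value"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    out = np.full(grid.n_cells, np.nan)
    out[df["cell_id"].to_numpy(dtype=int)] = df["value"].to_numpy(dtype=float)
    return out.reshape(grid.shape)


def write_field_netcdf(
    field: np.ndarray, grid: GridSpec, path, name: str = "value",
    provenance: np.ndarray | None = None,
) -> Path:
    """Write a gridded field as a NetCDF raster with lon/lat coordinates.

    Uses xarray's scipy backend (NetCDF3), so no extra binary dependencies
    are needed.  The optional provenance band (0 observed, 1 interpolated,
    2 missing) is stored as a second variable.
    """
    import xarray as xr

    path = Path(path)
    data = {name: (("lat", "lon"), np.asarray(field, dtype=float))}
    if provenance is not None:
        data["provenance"] = (("lat", "lon"), np.asarray(provenance, dtype=np.int32))
    ds = xr.Dataset(
        data, coords={"lon": grid.lon_centers, "lat": grid.lat_centers}
    )
    ds.to_netcdf(path, engine="scipy")
    return path


def write_json(obj: dict, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable) + "\n")
    return path


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
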