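"""Regular longitude–latitude analysis grids.

The analysis is carried out on a regular 0.1° × 0.1° grid.  Cells are
half-open rectangles ``[west, east) × [south, north)`` so that every point
inside the grid bounds belongs to exactly one cell.  Cell ids are row-major
integers, latitude rows varying slowest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridSpec"]


@dataclass(frozen=True)
class GridSpec:
    """A regular lon/lat grid of square cells.

    Parameters
    ----------
    lon_min, lon_max, lat_min, lat_max
        Grid bounds in decimal degrees.  The extents must be (near-)integer
        multiples of ``cell_size``.
    cell_size
        Cell edge length in degrees (default 0.1°, the native resolution of
        the gridded AOD product emulated here).
    """

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    cell_size: float = 0.1

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        if self.lon_max <= self.lon_min or self.lat_max <= self.lat_min:
            raise ValueError("grid bounds must satisfy lon_min < lon_max and lat_min < lat_max")
        for name, lo, hi in (("lon", self.lon_min, self.lon_max), ("lat", self.lat_min, self.lat_max)):
            n = (hi - lo) / self.cell_size
            if abs(n - round(n)) > 1e-8 * max(1.0, abs(n)):
                raise ValueError(f"{name} extent {hi - lo} is not a multiple of cell_size {self.cell_size}")

    @property
    def n_lon(self) -> int:
        return int(round((self.lon_max - self.lon_min) / self.cell_size))

    @property
    def n_lat(self) -> int:
        return int(round((self.lat_max - self.lat_min) / self.cell_size))

    @property
    def n_cells(self) -> int:
        return self.n_lon * self.n_lat

    @property
    def shape(self) -> tuple[int, int]:
        """(n_lat, n_lon) — the shape of gridded field arrays."""
        return (self.n_lat, self.n_lon)

    @property
    def lon_centers(self) -> np.ndarray:
        return self.lon_min + (np.arange(self.n_lon) + 0.5) * self.cell_size

    @property
    def lat_centers(self) -> np.ndarray:
        return self.lat_min + (np.arange(self.n_lat) + 0.5) * self.cell_size

    def cell_centers(self) -> np.ndarray:
        """All cell centers as an (n_cells, 2) array of (lon, lat), id order."""
        lon, lat = np.meshgrid(self.lon_centers, self.lat_centers)
        return np.column_stack([lon.ravel(), lat.ravel()])

    def cell_id(self, ix: np.ndarray, iy: np.ndarray) -> np.ndarray:
        """Row-major id of the cell with lon index ``ix`` and lat index ``iy``."""
        return np.asarray(iy) * self.n_lon + np.asarray(ix)

    def locate(self, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
        """Map points to cell ids; -1 for points outside the half-open bounds.

        A point exactly on a shared edge belongs to the cell whose west/south
        edge it lies on; points at or beyond the east/north outer boundary
        are outside.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        tx = (lon - self.lon_min) / self.cell_size
        ty = (lat - self.lat_min) / self.cell_size
        ix = np.floor(tx).astype(int)
        iy = np.floor(ty).astype(int)
        # snap points a rounding error below a cell edge onto that edge
        ix = np.where(tx - ix > 1.0 - 1e-9, ix + 1, ix)
        iy = np.where(ty - iy > 1.0 - 1e-9, iy + 1, iy)
        ok = (ix >= 0) & (ix < self.n_lon) & (iy >= 0) & (iy < self.n_lat)
        out = np.where(ok, self.cell_id(np.clip(ix, 0, self.n_lon - 1), np.clip(iy, 0, self.n_lat - 1)), -1)
        return out

    def to_dict(self) -> dict:
        return {
            "lon_min": self.lon_min,
            "lon_max": self.lon_max,
            "lat_min": self.lat_min,
            "lat_max": self.lat_max,
            "cell_size": self.cell_size,
        }
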