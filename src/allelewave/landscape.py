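"""Discrete geographic domain: lat/lon grid, land mask, metric geometry.

The model operates on a plate-carrée grid of square (in degrees) cells.
Cells are indexed row-major from the south-west corner: row 0 is the
southernmost latitude band, column 0 the westernmost.  Cells are half-open
(a point on a shared edge belongs to the cell to its north-east).  All
metric quantities (cell extents, areas) are great-circle distances on a
sphere of radius ``EARTH_RADIUS_KM``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "EARTH_RADIUS_KM",
    "Raster",
    "Landscape",
    "haversine_km",
    "build_landscape",
    "cell_geometry",
    "locate",
]


def haversine_km(
    lat1: float, lon1: float, lat2: float, lon2: float, radius: float = EARTH_RADIUS_KM
) -> float:
    """Great-circle distance in km between two points given in degrees."""
    phi1, lam1, phi2, lam2 = np.radians([lat1, lon1, lat2, lon2])
    a = (
        np.sin((phi2 - phi1) / 2.0) ** 2
        + np.cos(phi1) * np.cos(phi2) * np.sin((lam2 - lam1) / 2.0) ** 2
    )
    return float(2.0 * radius * np.arcsin(np.sqrt(a)))


@dataclass
class Raster:
    """A north-up, regularly gridded elevation field (metres, negative = water).

    ``data[0, 0]`` is the south-west corner cell, matching Landscape
    orientation.  ESRI ASCII grids are flipped on read accordingly.
    """

    data: np.ndarray  # (n_rows, n_cols), row 0 = south
    lat_min: float
    lon_min: float
    cellsize: float
    nodata: float | None = None

    @property
    def lat_max(self) -> float:
        return self.lat_min + self.data.shape[0] * self.cellsize

    @property
    def lon_max(self) -> float:
        return self.lon_min + self.data.shape[1] * self.cellsize

    def covers(self, lat_min, lat_max, lon_min, lon_max, tol=1e-9) -> bool:
        return (
            self.lat_min <= lat_min + tol
            and self.lat_max >= lat_max - tol
            and self.lon_min <= lon_min + tol
            and self.lon_max >= lon_max - tol
        )


@dataclass
class Landscape:
    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float
    resolution: float
    n_rows: int
    n_cols: int
    land_mask: np.ndarray  # (n_rows, n_cols) bool
    dx_km: np.ndarray = field(repr=False, default=None)  # (n_rows, n_cols)
    dy_km: np.ndarray = field(repr=False, default=None)
    area_km2: np.ndarray = field(repr=False, default=None)
    earth_radius_km: float = EARTH_RADIUS_KM

    def __post_init__(self):
        self.land_mask = np.asarray(self.land_mask, dtype=bool)
        if self.land_mask.shape != (self.n_rows, self.n_cols):
            raise ValueError(
                f"land_mask shape {self.land_mask.shape} does not match grid "
                f"({self.n_rows}, {self.n_cols})"
            )
        if self.dx_km is None:
            self._compute_geometry()

    def _compute_geometry(self) -> None:
        R = self.earth_radius_km
        res = self.resolution
        lats = self.cell_center_lats
        # east-west extent at the cell-centre latitude; north-south extent
        # along a meridian (latitude independent on a sphere).
        dx = np.array([haversine_km(la, 0.0, la, res, R) for la in lats])
        dy = haversine_km(0.0, 0.0, res, 0.0, R)
        self.dx_km = np.broadcast_to(dx[:, None], (self.n_rows, self.n_cols)).copy()
        self.dy_km = np.full((self.n_rows, self.n_cols), dy)
        self.area_km2 = self.dx_km * self.dy_km

    @property
    def cell_center_lats(self) -> np.ndarray:
        return self.lat_min + (np.arange(self.n_rows) + 0.5) * self.resolution

    @property
    def cell_center_lons(self) -> np.ndarray:
        return self.lon_min + (np.arange(self.n_cols) + 0.5) * self.resolution

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        self._check_index(row, col)
        return (
            self.lat_min + (row + 0.5) * self.resolution,
            self.lon_min + (col + 0.5) * self.resolution,
        )

    def _check_index(self, row: int, col: int) -> None:
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(
                f"cell ({row}, {col}) outside grid {self.n_rows}x{self.n_cols}"
            )

    def is_land(self, row: int, col: int) -> bool:
        self._check_index(row, col)
        return bool(self.land_mask[row, col])

    @property
    def n_land(self) -> int:
        return int(self.land_mask.sum())

    @classmethod
    def from_mask(
        cls,
        land_mask: np.ndarray,
        lat_min: float = 30.0,
        lon_min: float = -10.0,
        resolution: float = 1.0,
    ) -> "Landscape":
        """Build a Landscape directly from a boolean mask (tests, simulations)."""
        mask = np.asarray(land_mask, dtype=bool)
        n_rows, n_cols = mask.shape
        return cls(
            lat_min=lat_min,
            lat_max=lat_min + n_rows * resolution,
            lon_min=lon_min,
            lon_max=lon_min + n_cols * resolution,
            resolution=resolution,
            n_rows=n_rows,
            n_cols=n_cols,
            land_mask=mask,
        )


def _integral_dim(span: float, resolution: float, axis: str) -> int:
    n = span / resolution
    n_round = round(n)
    if n_round < 1 or abs(n - n_round) > 1e-6:
        raise ValueError(
            f"bbox {axis} span {span} is not an integral multiple of "
            f"resolution {resolution}"
        )
    return int(n_round)


def build_landscape(
    bbox: tuple[float, float, float, float],
    resolution: float,
    topography: Raster,
    land_bridges: list[tuple[int, int]] | None = None,
) -> Landscape:
    """Construct the model grid from a bounding box and an elevation raster.

    Parameters
    ----------
    bbox
        (lat_min, lat_max, lon_min, lon_max) in degrees.
    resolution
        Cell size in degrees; both bbox spans must be integral multiples.
    topography
        Elevation raster covering the bbox.  A model cell is water when the
        majority of covering raster cells have negative elevation.
    land_bridges
        (row, col) model cells forced to land regardless of elevation.
    """
    lat_min, lat_max, lon_min, lon_max = bbox
    if lat_max <= lat_min or lon_max <= lon_min:
        raise ValueError("degenerate bbox: spans must be positive")
    n_rows = _integral_dim(lat_max - lat_min, resolution, "latitude")
    n_cols = _integral_dim(lon_max - lon_min, resolution, "longitude")
    if not topography.covers(lat_min, lat_max, lon_min, lon_max):
        raise ValueError(
            "topography raster does not cover the bounding box: raster spans "
            f"[{topography.lat_min}, {topography.lat_max}] x "
            f"[{topography.lon_min}, {topography.lon_max}]"
        )

    mask = np.zeros((n_rows, n_cols), dtype=bool)
    elev = topography.data
    if topography.nodata is not None:
        elev = np.where(elev == topography.nodata, -1.0, elev)
    cs = topography.cellsize
    for r in range(n_rows):
        i0 = int(np.floor((lat_min + r * resolution - topography.lat_min) / cs + 1e-9))
        i1 = int(np.ceil((lat_min + (r + 1) * resolution - topography.lat_min) / cs - 1e-9))
        i0, i1 = max(i0, 0), min(max(i1, i0 + 1), elev.shape[0])
        for c in range(n_cols):
            j0 = int(np.floor((lon_min + c * resolution - topography.lon_min) / cs + 1e-9))
            j1 = int(np.ceil((lon_min + (c + 1) * resolution - topography.lon_min) / cs - 1e-9))
            j0, j1 = max(j0, 0), min(max(j1, j0 + 1), elev.shape[1])
            block = elev[i0:i1, j0:j1]
            # majority vote: land only if non-negative cells strictly outnumber
            mask[r, c] = (block >= 0).sum() > (block < 0).sum()

    for row, col in land_bridges or []:
        if not (0 <= row < n_rows and 0 <= col < n_cols):
            raise ValueError(f"land bridge cell ({row}, {col}) outside grid")
        mask[row, col] = True

    return Landscape(
        lat_min=lat_min,
        lat_max=lat_max,
        lon_min=lon_min,
        lon_max=lon_max,
        resolution=resolution,
        n_rows=n_rows,
        n_cols=n_cols,
        land_mask=mask,
    )


def cell_geometry(landscape: Landscape, row: int, col: int) -> tuple[float, float, float]:
    """Return (dx_km, dy_km, area_km2) for one cell."""
    landscape._check_index(row, col)
    return (
        float(landscape.dx_km[row, col]),
        float(landscape.dy_km[row, col]),
        float(landscape.area_km2[row, col]),
    )


def locate(
    landscape: Landscape, lat: float, lon: float, snap_radius: int = 1
) -> tuple[int, int]:
    """Map a point to its containing cell, snapping off water if needed.

    If the containing cell is water, the nearest land cell (by great-circle
    distance between cell centres) within ``snap_radius`` cells (Chebyshev)
    is returned instead.
    """
    if not (
        landscape.lat_min <= lat < landscape.lat_max
        and landscape.lon_min <= lon < landscape.lon_max
    ):
        raise ValueError(
            f"point ({lat}, {lon}) outside bounding box "
            f"[{landscape.lat_min}, {landscape.lat_max}) x "
            f"[{landscape.lon_min}, {landscape.lon_max})"
        )
    row = int(np.floor((lat - landscape.lat_min) / landscape.resolution))
    col = int(np.floor((lon - landscape.lon_min) / landscape.resolution))
    row = min(row, landscape.n_rows - 1)
    col = min(col, landscape.n_cols - 1)
    if landscape.land_mask[row, col]:
        return row, col

    best = None
    best_d = np.inf
    for dr in range(-snap_radius, snap_radius + 1):
        for dc in range(-snap_radius, snap_radius + 1):
            r, c = row + dr, col + dc
            if not (0 <= r < landscape.n_rows and 0 <= c < landscape.n_cols):
                continue
            if not landscape.land_mask[r, c]:
                continue
            clat, clon = landscape.cell_center(r, c)
            d = haversine_km(lat, lon, clat, clon, landscape.earth_radius_km)
            if d < best_d:
                best, best_d = (r, c), d
    if best is None:
        raise ValueError(
            f"no land cell within {snap_radius} cells of point ({lat}, {lon})"
        )
    return best
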