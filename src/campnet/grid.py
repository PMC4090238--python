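"""Equal-area gridding of geographic points.

Trip origins and destinations are aggregated onto a continuous grid of
square map cells (default 15x15 km) defined in a Lambert azimuthal
equal-area (LAEA) projection centred on the data extent.  Cell ids are
row-major integers counted from the grid's lower-left corner, so a
(lon, lat) point maps to exactly one integer id and every id maps back
to a cell-center point.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_KM = 6371.0088  # mean Earth radius


def laea_forward(
    lon: np.ndarray,
    lat: np.ndarray,
    lon0: float,
    lat0: float,
    radius: float = EARTH_RADIUS_KM,
) -> tuple[np.ndarray, np.ndarray]:
    """Project lon/lat degrees to LAEA x/y in km (spherical form)."""
    lam = np.radians(np.asarray(lon, dtype=float))
    phi = np.radians(np.asarray(lat, dtype=float))
    lam0 = np.radians(lon0)
    phi0 = np.radians(lat0)
    dlam = lam - lam0
    cosc = np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(dlam)
    # antipode of the projection center is the only singular point
    denom = 1.0 + cosc
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.sqrt(2.0 / denom)
    x = radius * k * np.cos(phi) * np.sin(dlam)
    y = radius * k * (np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(dlam))
    return x, y


def laea_inverse(
    x: np.ndarray,
    y: np.ndarray,
    lon0: float,
    lat0: float,
    radius: float = EARTH_RADIUS_KM,
) -> tuple[np.ndarray, np.ndarray]:
    """Invert :func:`laea_forward`; returns lon/lat in degrees."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lam0 = np.radians(lon0)
    phi0 = np.radians(lat0)
    rho = np.hypot(x, y)
    c = 2.0 * np.arcsin(np.clip(rho / (2.0 * radius), -1.0, 1.0))
    sinc, cosc = np.sin(c), np.cos(c)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.arcsin(np.clip(cosc * np.sin(phi0) + y * sinc * np.cos(phi0) / rho, -1.0, 1.0))
        lam = lam0 + np.arctan2(x * sinc, rho * np.cos(phi0) * cosc - y * np.sin(phi0) * sinc)
    # rho == 0 is the projection center itself
    at_center = rho == 0.0
    phi = np.where(at_center, phi0, phi)
    lam = np.where(at_center, lam0, lam)
    return np.degrees(lam), np.degrees(phi)


def great_circle_km(
    lon1: np.ndarray, lat1: np.ndarray, lon2: np.ndarray, lat2: np.ndarray
) -> np.ndarray:
    """Haversine great-circle distance in km between lon/lat points."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass(frozen=True)
class GridSpec:
    """Deterministic mapping between geographic points and integer cell ids.

    Parameters
    ----------
    cell_size:
        Cell edge length in km (default 15, the aggregation resolution of
        the travel network).
    lon0, lat0:
        Center of the Lambert azimuthal equal-area projection.
    x_min, y_min, x_max, y_max:
        Projected bounding rectangle in km.  Points outside it raise.
    """

    cell_size: float = 15.0
    lon0: float = -98.0
    lat0: float = 39.5
    x_min: float = -3000.0
    y_min: float = -2000.0
    x_max: float = 3000.0
    y_max: float = 2000.0

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.x_max <= self.x_min or self.y_max <= self.y_min:
            raise ValueError("extent rectangle is empty")

    @property
    def n_cols(self) -> int:
        return int(np.ceil((self.x_max - self.x_min) / self.cell_size))

    @property
    def n_rows(self) -> int:
        return int(np.ceil((self.y_max - self.y_min) / self.cell_size))

    @classmethod
    def from_extent(
        cls,
        lon_min: float,
        lat_min: float,
        lon_max: float,
        lat_max: float,
        cell_size: float = 15.0,
        pad_km: float = 30.0,
    ) -> "GridSpec":
        """Build a grid covering a lon/lat rectangle, projection centred on it."""
        lon0 = 0.5 * (lon_min + lon_max)
        lat0 = 0.5 * (lat_min + lat_max)
        corners_lon = np.array([lon_min, lon_min, lon_max, lon_max, lon0, lon0])
        corners_lat = np.array([lat_min, lat_max, lat_min, lat_max, lat_min, lat_max])
        x, y = laea_forward(corners_lon, corners_lat, lon0, lat0)
        return cls(
            cell_size=cell_size,
            lon0=lon0,
            lat0=lat0,
            x_min=float(x.min() - pad_km),
            y_min=float(y.min() - pad_km),
            x_max=float(x.max() + pad_km),
            y_max=float(y.max() + pad_km),
        )

    def cell_id(self, lon, lat) -> np.ndarray:
        """Map lon/lat points to row-major integer cell ids.

        Raises ``ValueError`` naming the first offending index for points
        outside the grid extent.
        """
        x, y = laea_forward(np.atleast_1d(lon), np.atleast_1d(lat), self.lon0, self.lat0)
        col = np.floor((x - self.x_min) / self.cell_size).astype(np.int64)
        row = np.floor((y - self.y_min) / self.cell_size).astype(np.int64)
        bad = (col < 0) | (col >= self.n_cols) | (row < 0) | (row >= self.n_rows)
        if np.any(bad):
            i = int(np.argmax(bad))
            raise ValueError(f"point index {i} (lon={np.atleast_1d(lon)[i]}, lat={np.atleast_1d(lat)[i]}) is outside the grid extent")
        return row * self.n_cols + col

    def cell_center(self, cell_id) -> tuple[np.ndarray, np.ndarray]:
        """Lon/lat of the center of each cell id."""
        cid = np.atleast_1d(np.asarray(cell_id, dtype=np.int64))
        row, col = np.divmod(cid, self.n_cols)
        x = self.x_min + (col + 0.5) * self.cell_size
        y = self.y_min + (row + 0.5) * self.cell_size
        return laea_inverse(x, y, self.lon0, self.lat0)

    def cell_polygon(self, cell_id: int) -> list[tuple[float, float]]:
        """Lon/lat corner ring (closed, counter-clockwise) of one cell."""
        row, col = divmod(int(cell_id), self.n_cols)
        x0 = self.x_min + col * self.cell_size
        y0 = self.y_min + row * self.cell_size
        xs = np.array([x0, x0 + self.cell_size, x0 + self.cell_size, x0, x0])
        ys = np.array([y0, y0, y0 + self.cell_size, y0 + self.cell_size, y0])
        lon, lat = laea_inverse(xs, ys, self.lon0, self.lat0)
        return list(zip(lon.tolist(), lat.tolist()))

    def to_json(self) -> str:
        return json.dumps(
            {
                "cell_size": self.cell_size,
                "lon0": self.lon0,
                "lat0": self.lat0,
                "x_min": self.x_min,
                "y_min": self.y_min,
                "x_max": self.x_max,
                "y_max": self.y_max,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GridSpec":
        return cls(**json.loads(text))
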