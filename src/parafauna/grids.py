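"""Gridded range metrics on a regular longitude/latitude grid.

Host geographic ranges are represented as binary presence--absence rows over
a regular grid of cells (by convention 1 degree x 1 degree).  From these the
module derives the per-host quantities used downstream: range size in km^2
(spherical cell areas summed over occupied cells), range centroids, the
diversity field (mean number of co-occurring hosts over the range), and
pairwise haversine distances between centroids.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: IUGG mean Earth radius, km.  Fixed so that independent oracles can match
#: bit-for-bit.
EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class GridSpec:
    """A regular lon/lat grid.

    Cells are indexed 0-based, row-major from the northwest corner: cell
    ``(i, j)`` has center ``(lon_min + (j + 0.5) * res, lat_max - (i + 0.5) * res)``.
    """

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    resolution: float = 1.0

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat_min < self.lat_max <= 90.0):
            raise ValueError("latitude bounds must satisfy -90 <= lat_min < lat_max <= 90")
        if not (-180.0 <= self.lon_min < self.lon_max <= 180.0):
            raise ValueError("longitude bounds must satisfy -180 <= lon_min < lon_max <= 180")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        for extent in (self.lon_max - self.lon_min, self.lat_max - self.lat_min):
            n = extent / self.resolution
            if abs(n - round(n)) > 1e-9:
                raise ValueError("grid bounds must span an integer number of cells")

    @property
    def n_rows(self) -> int:
        return int(round((self.lat_max - self.lat_min) / self.resolution))

    @property
    def n_cols(self) -> int:
        return int(round((self.lon_max - self.lon_min) / self.resolution))

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def cell_center(self, i: int, j: int) -> tuple[float, float]:
        """(lon, lat) of the center of cell (i, j)."""
        return (
            self.lon_min + (j + 0.5) * self.resolution,
            self.lat_max - (i + 0.5) * self.resolution,
        )

    def cell_centers(self) -> np.ndarray:
        """(n_cells, 2) array of (lon, lat) centers in row-major cell order."""
        jj, ii = np.meshgrid(np.arange(self.n_cols), np.arange(self.n_rows))
        lon = self.lon_min + (jj + 0.5) * self.resolution
        lat = self.lat_max - (ii + 0.5) * self.resolution
        return np.column_stack([lon.ravel(), lat.ravel()])

    def cell_ids(self) -> list[str]:
        return [f"c{k}" for k in range(self.n_cells)]

    def to_dict(self) -> dict:
        return {
            "lon_min": self.lon_min,
            "lon_max": self.lon_max,
            "lat_min": self.lat_min,
            "lat_max": self.lat_max,
            "resolution": self.resolution,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(**{k: d[k] for k in ("lon_min", "lon_max", "lat_min", "lat_max", "resolution")})


@dataclass
class PresenceAbsenceMatrix:
    """Binary host x grid-cell occupancy."""

    host_ids: list[str]
    grid: GridSpec
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.host_ids), self.grid.n_cells):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.host_ids)} hosts x {self.grid.n_cells} cells"
            )
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("presence-absence values must be binary")
        self.values = self.values.astype(np.int8)

    @property
    def n_hosts(self) -> int:
        return len(self.host_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.host_ids, name="host_id"),
                            columns=self.grid.cell_ids())


def cell_area(grid: GridSpec, row_index: int) -> float:
    """Area in km^2 of one cell in latitude band ``row_index``.

    Spherical band formula R^2 * dlambda * (sin(phi_top) - sin(phi_bottom));
    constant within a row.
    """
    if not 0 <= row_index < grid.n_rows:
        raise IndexError(f"row_index {row_index} outside grid with {grid.n_rows} rows")
    lat_top = grid.lat_max - row_index * grid.resolution
    lat_bot = lat_top - grid.resolution
    dlon = np.deg2rad(grid.resolution)
    return float(
        EARTH_RADIUS_KM**2 * dlon * (np.sin(np.deg2rad(lat_top)) - np.sin(np.deg2rad(lat_bot)))
    )


def cell_areas(grid: GridSpec) -> np.ndarray:
    """Per-cell areas (km^2), row-major, one value repeated along each row."""
    per_row = np.array([cell_area(grid, i) for i in range(grid.n_rows)])
    return np.repeat(per_row, grid.n_cols)


def range_size(pam: PresenceAbsenceMatrix) -> pd.Series:
    """Per-host geographic range size (GR) in km^2: summed occupied-cell areas."""
    occ = pam.values
    if (occ.sum(axis=1) == 0).any():
        empty = [h for h, s in zip(pam.host_ids, occ.sum(axis=1)) if s == 0]
        raise ValueError(f"hosts with empty ranges: {empty}")
    areas = cell_areas(pam.grid)
    return pd.Series(occ @ areas, index=pd.Index(pam.host_ids, name="host_id"),
                     name="range_size_km2")


def range_centroid(pam: PresenceAbsenceMatrix) -> pd.DataFrame:
    """Per-host centroid: unweighted mean of occupied cell centers.

    Ranges spanning the antimeridian are handled by remapping longitudes to
    [0, 360) when the range's longitudinal extent is smaller in that frame,
    so the centroid cannot land in the range's complement.
    """
    centers = pam.grid.cell_centers()
    out = np.empty((pam.n_hosts, 2))
    for k in range(pam.n_hosts):
        occ = pam.values[k].astype(bool)
        if not occ.any():
            raise ValueError(f"host {pam.host_ids[k]} has an empty range")
        lon = centers[occ, 0]
        lat = centers[occ, 1]
        lon_alt = np.mod(lon, 360.0)
        if np.ptp(lon_alt) < np.ptp(lon):
            mean_lon = np.mean(lon_alt)
            if mean_lon >= 180.0:
                mean_lon -= 360.0
        else:
            mean_lon = np.mean(lon)
        out[k] = (mean_lon, np.mean(lat))
    return pd.DataFrame(out, index=pd.Index(pam.host_ids, name="host_id"),
                        columns=["centroid_lon", "centroid_lat"])


def diversity_field(pam: PresenceAbsenceMatrix) -> pd.Series:
    """Per-host diversity field (DF): mean number of other hosts co-occurring
    per occupied cell.

    ``DF_i = mean over cells c occupied by i of (S_c - 1)`` where ``S_c`` is
    the number of hosts present in cell c.  Every host in the matrix counts
    as a co-occurrer.
    """
    occ = pam.values
    n_per_host = occ.sum(axis=1)
    if (n_per_host == 0).any():
        empty = [h for h, s in zip(pam.host_ids, n_per_host) if s == 0]
        raise ValueError(f"hosts with empty ranges: {empty}")
    richness_per_cell = occ.sum(axis=0)  # S_c
    df = (occ @ (richness_per_cell - 1)) / n_per_host
    return pd.Series(df.astype(float), index=pd.Index(pam.host_ids, name="host_id"),
                     name="diversity_field")


def range_summaries(pam: PresenceAbsenceMatrix) -> pd.DataFrame:
    """RangeSummary table: range_size_km2, centroid_lon/lat, diversity_field."""
    return pd.concat([range_size(pam), range_centroid(pam), diversity_field(pam)], axis=1)


def haversine(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km between points given in degrees."""
    lam1, phi1, lam2, phi2 = map(np.deg2rad, (lon1, lat1, lon2, lat2))
    h = np.sin((phi2 - phi1) / 2) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin((lam2 - lam1) / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def haversine_matrix(centroids: pd.DataFrame) -> pd.DataFrame:
    """Pairwise haversine distances (km) between host centroids.

    ``centroids`` is the frame returned by :func:`range_centroid`.
    """
    lat = centroids["centroid_lat"].to_numpy(float)
    lon = centroids["centroid_lon"].to_numpy(float)
    if (np.abs(lat) > 90).any():
        raise ValueError("latitude outside [-90, 90]")
    if (np.abs(lon) > 360).any():
        raise ValueError("longitude outside sane bounds")
    d = haversine(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2  # enforce exact symmetry against rounding
    return pd.DataFrame(d, index=centroids.index, columns=centroids.index)
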