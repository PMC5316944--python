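"""Regular lon/lat grid for the geolocation filter."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

KM_PER_DEG = 2 * np.pi * 6371.0 / 360.0


@dataclass
class GridSpec:
    """Discrete spatial domain of the grid filter.

    Cell centroids sit at ``extent_min + resolution/2 + i*resolution`` on
    each axis.  ``bathymetry`` is metres positive-down; cells with zero
    bathymetry are land and excluded from the sea mask.
    """

    lons: np.ndarray        # (nlon,) cell-centre longitudes, ascending
    lats: np.ndarray        # (nlat,) cell-centre latitudes, ascending
    resolution: float       # degrees per cell, both axes
    bathymetry: np.ndarray  # (nlat, nlon) m
    sea: np.ndarray         # (nlat, nlon) bool

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.lats), len(self.lons))

    @property
    def n_cells(self) -> int:
        return self.shape[0] * self.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        r = self.resolution / 2
        return (float(self.lons[0] - r), float(self.lons[-1] + r),
                float(self.lats[0] - r), float(self.lats[-1] + r))

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(lat2d, lon2d) centroid meshgrids, shape (nlat, nlon)."""
        return np.meshgrid(self.lats, self.lons, indexing="ij")

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        """(row, col) of the cell containing a point; clipped to the grid."""
        i = int(np.clip(np.searchsorted(self.lats + self.resolution / 2, lat),
                        0, len(self.lats) - 1))
        j = int(np.clip(np.searchsorted(self.lons + self.resolution / 2, lon),
                        0, len(self.lons) - 1))
        return i, j

    def contains(self, lon: float, lat: float) -> bool:
        e = self.extent
        return e[0] <= lon <= e[1] and e[2] <= lat <= e[3]

    def cell_sizes_km(self) -> tuple[np.ndarray, float]:
        """(dx_km per latitude row, dy_km) physical cell sizes."""
        dx = KM_PER_DEG * self.resolution * np.cos(np.radians(self.lats))
        dy = KM_PER_DEG * self.resolution
        return dx, dy


def build_grid(extent, resolution: float, bathymetry) -> GridSpec:
    """Discretise an extent at the given resolution and attach bathymetry.

    Parameters
    ----------
    extent : (lon_min, lon_max, lat_min, lat_max)
        Must be an integer number of cells on each axis.
    resolution : float
        Cell size, degrees.
    bathymetry : EnvironmentFields or (lons, lats, values) triple
        Source field interpolated (bilinear) onto the cell centroids.
    """
    lon_min, lon_max, lat_min, lat_max = extent
    nx = (lon_max - lon_min) / resolution
    ny = (lat_max - lat_min) / resolution
    if abs(nx - round(nx)) > 1e-9 or abs(ny - round(ny)) > 1e-9:
        raise ValueError("resolution must divide the extent on both axes")
    nx, ny = int(round(nx)), int(round(ny))
    if nx < 1 or ny < 1:
        raise ValueError("degenerate extent")

    lons = lon_min + resolution / 2 + resolution * np.arange(nx)
    lats = lat_min + resolution / 2 + resolution * np.arange(ny)

    if hasattr(bathymetry, "bathymetry"):  # EnvironmentFields
        src = (bathymetry.lats, bathymetry.lons, bathymetry.bathymetry)
    else:
        blons, blats, vals = bathymetry
        src = (np.asarray(blats), np.asarray(blons), np.asarray(vals))
    f = RegularGridInterpolator((src[0], src[1]), src[2],
                                bounds_error=False, fill_value=None)
    glat, glon = np.meshgrid(lats, lons, indexing="ij")
    bathy = f(np.column_stack([glat.ravel(), glon.ravel()])).reshape(ny, nx)
    bathy = np.maximum(bathy, 0.0)
    sea = bathy > 0
    if not sea.any():
        raise ValueError("grid has no sea cells")
    return GridSpec(lons=lons, lats=lats, resolution=resolution,
                    bathymetry=bathy, sea=sea)
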