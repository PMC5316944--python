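"""Space-use aggregation: utilisation distributions, percentage volume
contours, hexagonal density grids and zone occupancy.

Daily posterior surfaces from the geolocation filter are averaged into a
per-animal utilisation distribution (UD); percentage volume contours (PVC)
extract the smallest set of cells holding a given share of that mass.
Density mapping follows the two-stage recipe used for multi-animal tag
studies: per animal, the proportion of tracking days falling in each
hexagonal cell (50-km apothem by default), then an unweighted mean across
animals.  Zone occupancy assigns each animal-day to a named polygon
(e.g. an EEZ) or to the High Seas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import Point, Polygon, shape

from .grid import GridSpec

EARTH_RADIUS_KM = 6371.0

POST_SUMMER_MONTH = 10  # "post-summer" = 1 October onwards


# ---------------------------------------------------------------------------
# utilisation distributions and percentage volume contours

def post_summer_filter(dates: pd.DatetimeIndex) -> np.ndarray:
    """Boolean mask selecting dates on/after the first 1 October in range."""
    dates = pd.DatetimeIndex(dates)
    oct1 = pd.Timestamp(dates[0].year, POST_SUMMER_MONTH, 1)
    return np.asarray(dates >= oct1)


def sum_uds(daily_posteriors: np.ndarray, dates: pd.DatetimeIndex,
            period_mask: np.ndarray | None = None) -> np.ndarray:
    """Average daily posteriors into one UD, renormalised.

    ``period_mask`` selects the days to include; by default, the
    post-summer period (1 October onwards).
    """
    dates = pd.DatetimeIndex(dates)
    if period_mask is None:
        period_mask = post_summer_filter(dates)
    period_mask = np.asarray(period_mask, dtype=bool)
    if period_mask.sum() == 0:
        raise ValueError("no days fall inside the requested period")
    ud = np.asarray(daily_posteriors)[period_mask].mean(axis=0)
    return ud / ud.sum()


def pvc(ud: np.ndarray, q_percent: float) -> np.ndarray:
    """Percentage volume contour: smallest cell set holding >= q% of mass.

    Cells are taken in descending probability order (ties broken by flat
    index, so the result is deterministic and of minimal cardinality).
    Returns a boolean mask with the shape of ``ud``.
    """
    if not 0 < q_percent <= 100:
        raise ValueError("q_percent must be in (0, 100]")
    flat = np.asarray(ud, dtype=float).ravel()
    order = np.argsort(-flat, kind="stable")
    csum = np.cumsum(flat[order])
    target = q_percent / 100.0 * flat.sum()
    k = int(np.searchsorted(csum, target - 1e-12)) + 1
    k = min(k, int((flat > 0).sum()))  # never include zero-mass cells
    mask = np.zeros(flat.shape, dtype=bool)
    mask[order[:k]] = True
    return mask.reshape(np.asarray(ud).shape)


# ---------------------------------------------------------------------------
# hexagonal density grid

def _aeq_forward(lon, lat, lon0, lat0):
    """Azimuthal equidistant projection about (lon0, lat0), km."""
    lon, lat = np.radians(lon), np.radians(lat)
    lon0, lat0 = np.radians(lon0), np.radians(lat0)
    dlon = lon - lon0
    cosc = np.sin(lat0) * np.sin(lat) + np.cos(lat0) * np.cos(lat) * np.cos(dlon)
    cosc = np.clip(cosc, -1.0, 1.0)
    c = np.arccos(cosc)
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(c > 1e-12, c / np.sin(c), 1.0)
    x = EARTH_RADIUS_KM * k * np.cos(lat) * np.sin(dlon)
    y = EARTH_RADIUS_KM * k * (np.cos(lat0) * np.sin(lat)
                               - np.sin(lat0) * np.cos(lat) * np.cos(dlon))
    return x, y


def _aeq_inverse(x, y, lon0, lat0):
    lon0, lat0 = np.radians(lon0), np.radians(lat0)
    x = np.asarray(x, dtype=float) / EARTH_RADIUS_KM
    y = np.asarray(y, dtype=float) / EARTH_RADIUS_KM
    c = np.hypot(x, y)
    with np.errstate(invalid="ignore", divide="ignore"):
        lat = np.where(
            c > 1e-12,
            np.arcsin(np.clip(np.cos(c) * np.sin(lat0)
                              + y * np.sin(c) * np.cos(lat0) / np.where(c > 1e-12, c, 1), -1, 1)),
            lat0)
        lon = lon0 + np.arctan2(
            x * np.sin(c),
            c * np.cos(lat0) * np.cos(c) - y * np.sin(lat0) * np.sin(c))
    return np.degrees(lon), np.degrees(lat)


@dataclass
class HexGrid:
    """Flat-topped hexagonal tessellation in a local equidistant projection.

    ``apothem_km`` is the centroid-to-edge distance; cell area is
    2*sqrt(3)*apothem^2 (8,660 km^2 for the default 50 km).  Because a
    hexagonal tiling is the Voronoi diagram of its centres, containment
    reduces to a nearest-centre query.
    """

    centers_km: np.ndarray  # (n, 2) projected centres
    apothem_km: float
    origin: tuple[float, float]  # (lon0, lat0) of the projection

    def __post_init__(self):
        self._tree = cKDTree(self.centers_km)

    @property
    def n_cells(self) -> int:
        return len(self.centers_km)

    @property
    def cell_area_km2(self) -> float:
        return 2.0 * np.sqrt(3.0) * self.apothem_km**2

    def cell_of(self, lon, lat) -> np.ndarray:
        """Index of the hexagon containing each (lon, lat) point."""
        x, y = _aeq_forward(np.asarray(lon, dtype=float),
                            np.asarray(lat, dtype=float), *self.origin)
        _, idx = self._tree.query(np.column_stack([np.atleast_1d(x),
                                                   np.atleast_1d(y)]))
        return idx

    def polygon(self, i: int) -> Polygon:
        """Shapely polygon of cell ``i`` in projected km coordinates."""
        cx, cy = self.centers_km[i]
        R = 2.0 * self.apothem_km / np.sqrt(3.0)  # circumradius
        ang = np.radians(np.arange(0, 360, 60))
        return Polygon(np.column_stack([cx + R * np.cos(ang),
                                        cy + R * np.sin(ang)]))

    def polygon_lonlat(self, i: int) -> list[tuple[float, float]]:
        verts = np.asarray(self.polygon(i).exterior.coords)
        lon, lat = _aeq_inverse(verts[:, 0], verts[:, 1], *self.origin)
        return list(zip(lon.tolist(), lat.tolist()))

    def centroids_lonlat(self) -> np.ndarray:
        lon, lat = _aeq_inverse(self.centers_km[:, 0], self.centers_km[:, 1],
                                *self.origin)
        return np.column_stack([lon, lat])


def build_hex_grid(extent, apothem_km: float = 50.0) -> HexGrid:
    """Tile an extent (lon_min, lon_max, lat_min, lat_max) with flat-topped
    hexagons of the given apothem, built in a local azimuthal-equidistant
    projection about the extent centre so the apothem is metric."""
    if apothem_km <= 0:
        raise ValueError("apothem must be > 0")
    lon_min, lon_max, lat_min, lat_max = extent
    lon0 = (lon_min + lon_max) / 2
    lat0 = (lat_min + lat_max) / 2

    # projected bounding box of the extent corners/edges
    edge_lon = np.concatenate([np.linspace(lon_min, lon_max, 25),
                               np.full(25, lon_min), np.full(25, lon_max),
                               np.linspace(lon_min, lon_max, 25)])
    edge_lat = np.concatenate([np.full(25, lat_min),
                               np.linspace(lat_min, lat_max, 25),
                               np.linspace(lat_min, lat_max, 25),
                               np.full(25, lat_max)])
    ex, ey = _aeq_forward(edge_lon, edge_lat, lon0, lat0)
    pad = 2 * apothem_km
    x0, x1 = ex.min() - pad, ex.max() + pad
    y0, y1 = ey.min() - pad, ey.max() + pad

    a = apothem_km
    R = 2 * a / np.sqrt(3)          # circumradius
    dx = 1.5 * R                    # column pitch
    dy = 2 * a                      # row pitch
    cols = np.arange(int(np.floor(x0 / dx)), int(np.ceil(x1 / dx)) + 1)
    rows = np.arange(int(np.floor(y0 / dy)) - 1, int(np.ceil(y1 / dy)) + 1)
    centers = []
    for c in cols:
        off = a if (c % 2) else 0.0
        xs = c * dx
        for r in rows:
            centers.append((xs, r * dy + off))
    return HexGrid(centers_km=np.asarray(centers), apothem_km=apothem_km,
                   origin=(lon0, lat0))


def hex_density(per_animal_data, hexgrid: HexGrid,
                grid: GridSpec | None = None) -> np.ndarray:
    """Mean per-cell occurrence of daily locations across animals.

    ``per_animal_data`` is a list with one entry per animal, either

    * a DataFrame of daily point locations (columns lon, lat) — Doppler
      tags — or
    * an ndarray of daily posterior rasters ``(ndays, nlat, nlon)`` on the
      shared ``grid`` — light tags; raster mass is apportioned to the hex
      containing each raster-cell centroid.

    Mixing the two kinds in one call is rejected: point-based and
    raster-based densities are mapped separately.
    """
    kinds = {("raster" if isinstance(d, np.ndarray) else "points")
             for d in per_animal_data}
    if len(kinds) > 1:
        raise ValueError("mixing point tracks and posterior rasters in one "
                         "density map is not supported; run separately")
    if not per_animal_data:
        raise ValueError("no animals given")

    dens = np.zeros((len(per_animal_data), hexgrid.n_cells))
    if kinds == {"points"}:
        for k, df in enumerate(per_animal_data):
            idx = hexgrid.cell_of(df["lon"].to_numpy(), df["lat"].to_numpy())
            counts = np.bincount(idx, minlength=hexgrid.n_cells)
            dens[k] = counts / counts.sum()
    else:
        if grid is None:
            raise ValueError("raster input needs the shared GridSpec")
        glat, glon = grid.mesh()
        cell_idx = hexgrid.cell_of(glon.ravel(), glat.ravel())
        for k, post in enumerate(per_animal_data):
            ud = np.asarray(post)
            if ud.ndim == 3:
                ud = ud.mean(axis=0)
            w = np.bincount(cell_idx, weights=ud.ravel(),
                            minlength=hexgrid.n_cells)
            dens[k] = w / w.sum()
    return dens.mean(axis=0)


def hex_density_table(density: np.ndarray, hexgrid: HexGrid,
                      keep_zero: bool = False) -> pd.DataFrame:
    """Tabulate a density vector as cell_id / centroid lon,lat / density."""
    cen = hexgrid.centroids_lonlat()
    df = pd.DataFrame({
        "cell_id": np.arange(hexgrid.n_cells),
        "centroid_lon": cen[:, 0],
        "centroid_lat": cen[:, 1],
        "mean_density": density,
    })
    return df if keep_zero else df[df["mean_density"] > 0].reset_index(drop=True)


# ---------------------------------------------------------------------------
# zone occupancy

HIGH_SEAS = "High Seas"


def load_zones(geojson: dict) -> list[tuple[str, object]]:
    """(name, shapely geometry) pairs from a GeoJSON FeatureCollection,
    preserving feature order."""
    out = []
    for feat in geojson.get("features", []):
        name = feat.get("properties", {}).get("name", f"zone{len(out)}")
        out.append((name, shape(feat["geometry"])))
    return out


def zone_occupancy(daily_locations: pd.DataFrame,
                   zones: list[tuple[str, object]]) -> pd.Series:
    """Percentage of animal-days in each named zone.

    Boundary points belong to the first zone (in input order) that covers
    them; points in no zone count as High Seas.  Percentages sum to 100.
    """
    names = [n for n, _ in zones]
    counts = dict.fromkeys(names + [HIGH_SEAS], 0)
    for lon, lat in zip(daily_locations["lon"], daily_locations["lat"]):
        pt = Point(float(lon), float(lat))
        for name, geom in zones:
            if geom.covers(pt):
                counts[name] += 1
                break
        else:
            counts[HIGH_SEAS] += 1
    total = len(daily_locations)
    if total == 0:
        raise ValueError("no locations given")
    return pd.Series({k: 100.0 * v / total for k, v in counts.items()},
                     name="percent")
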