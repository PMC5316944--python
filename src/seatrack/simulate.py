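"""Synthetic tag-data generator.

Produces gridded environment fields (SST and bathymetry), true migratory
tracks with three post-summer migration strategies of increasing amplitude,
and the noisy observations an archival or Argos satellite tag would record
along those tracks.  Everything downstream of this module (geolocation,
track metrics, space use, strategy classification) can then be exercised
end-to-end without any real tag download.

The spatial domain emulates the north-east Atlantic: a meridional coastline
and continental shelf on the eastern edge of the domain, a slope, and
abyssal open ocean to the west.  SST carries a monotone north-south
gradient, a seasonal cycle and small-scale spatial structure.

Observation noise matches the error model the geolocation filter assumes:
light-based position fixes with standard deviations of 1 deg longitude and
3.5 deg latitude, tag-recorded SST within 0.5 degC of the satellite field,
and daily maximum depths bounded by the bathymetry at the true position.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import gaussian_filter

KM_PER_DEG = 2 * np.pi * 6371.0 / 360.0  # 111.1949 km per degree of latitude

#: winter-target latitude offset (degrees south of deployment) per strategy
STRATEGY_AMPLITUDE_DEG = {"a": 3.0, "b": 10.0, "c": 20.0}

#: conventional Argos location-class error scales, km (classes 3..B)
ARGOS_CLASS_ERROR_KM = {"3": 0.25, "2": 0.5, "1": 1.0, "0": 2.0, "A": 5.0, "B": 10.0}
ARGOS_CLASS_PROBS = {"3": 0.08, "2": 0.12, "1": 0.18, "0": 0.22, "A": 0.22, "B": 0.18}


@dataclass(frozen=True)
class TagDeployment:
    """Identity and anchors of one tagged animal."""

    animal_id: str
    date: pd.Timestamp
    lon: float
    lat: float
    popoff_date: pd.Timestamp | None = None
    popoff_lon: float | None = None
    popoff_lat: float | None = None
    tag_class: str = "archival"  # "archival" (light/PAT) or "argos" (SPOT)
    sex: str | None = None
    length_m: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "date", pd.Timestamp(self.date))
        if self.popoff_date is not None:
            object.__setattr__(self, "popoff_date", pd.Timestamp(self.popoff_date))


@dataclass
class EnvironmentFields:
    """Gridded SST (date, lat, lon) and bathymetry (lat, lon) fields.

    Bathymetry is seafloor depth in metres, positive down; exactly 0 on land.
    Coordinates are cell centres on a regular lon/lat grid.
    """

    lons: np.ndarray            # (nlon,) ascending
    lats: np.ndarray            # (nlat,) ascending
    dates: pd.DatetimeIndex     # (ndates,) daily
    sst: np.ndarray             # (ndates, nlat, nlon), degC
    bathymetry: np.ndarray      # (nlat, nlon), m, >= 0, == 0 on land

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(lon_min, lon_max, lat_min, lat_max) of the outer cell edges."""
        dlon = self.lons[1] - self.lons[0]
        dlat = self.lats[1] - self.lats[0]
        return (
            float(self.lons[0] - dlon / 2),
            float(self.lons[-1] + dlon / 2),
            float(self.lats[0] - dlat / 2),
            float(self.lats[-1] + dlat / 2),
        )

    def date_index(self, date) -> int:
        date = pd.Timestamp(date).normalize()
        idx = self.dates.get_indexer([date], method="nearest")[0]
        return int(idx)

    def sst_on(self, date) -> np.ndarray:
        """SST field (nlat, nlon) for the calendar day nearest `date`."""
        return self.sst[self.date_index(date)]

    def sst_interp(self, date, lon, lat) -> np.ndarray:
        """Bilinear SST at arbitrary points for one date."""
        f = RegularGridInterpolator(
            (self.lats, self.lons), self.sst_on(date),
            bounds_error=False, fill_value=None,
        )
        return f(np.column_stack([np.atleast_1d(lat), np.atleast_1d(lon)]))

    def bathy_interp(self, lon, lat) -> np.ndarray:
        f = RegularGridInterpolator(
            (self.lats, self.lons), self.bathymetry,
            bounds_error=False, fill_value=None,
        )
        return f(np.column_stack([np.atleast_1d(lat), np.atleast_1d(lon)]))


@dataclass
class TrueTrack:
    """Ground-truth daily positions for one simulated animal."""

    animal_id: str
    strategy: str
    positions: pd.DataFrame  # columns: date, lon, lat; one row per day

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class ObservationSeries:
    """What the tag recorded: daily archival records plus Argos surface fixes.

    ``archival`` columns: date, light_lon, light_lat, sst_c, max_depth_m
    (light fixes may be NaN on days without a usable light curve).
    ``argos`` columns: timestamp, lon, lat, loc_class.
    """

    animal_id: str
    archival: pd.DataFrame
    argos: pd.DataFrame


@dataclass
class SimConfig:
    """Study-condition knobs for the simulated fleet.

    Defaults mirror the tag error model used by the geolocation filter
    (sigma_lon 1 deg, sigma_lat 3.5 deg, sigma_sst 0.5 degC) and a strategy
    mix of 6:5:1 across the three migration amplitudes.
    """

    seed: int = 0
    n_animals: int = 12
    strategy_mix: tuple[float, float, float] = (6 / 12, 5 / 12, 1 / 12)
    sigma_lon_deg: float = 1.0
    sigma_lat_deg: float = 3.5
    sigma_sst_c: float = 0.5
    surface_prob_winter: float = 0.3
    surface_prob_summer: float = 0.8
    light_missing_rate: float = 0.05
    n_days: int = 365

    def __post_init__(self):
        if abs(sum(self.strategy_mix) - 1.0) > 1e-9:
            raise ValueError("strategy_mix must sum to 1")
        for name in ("sigma_lon_deg", "sigma_lat_deg", "sigma_sst_c"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


DEFAULT_EXTENT = (-25.0, -1.0, 28.0, 62.0)


def _coast_lon(lat: np.ndarray, extent) -> np.ndarray:
    """Longitude of the synthetic coastline at each latitude (slight wiggle)."""
    lon_max = extent[1]
    lat_min = extent[2]
    return lon_max - 1.5 + 0.8 * np.sin(2 * np.pi * (np.asarray(lat) - lat_min) / 18.0)


def make_environment(
    extent: tuple[float, float, float, float] = DEFAULT_EXTENT,
    n_days: int = 365,
    seed: int = 0,
    start: str | pd.Timestamp = "2014-07-01",
    resolution: float = 0.5,
) -> EnvironmentFields:
    """Build synthetic SST and bathymetry fields on a regular lon/lat grid.

    The coastline is meridional on the eastern edge of the domain, fronted by
    a shelf shallower than 200 m, then a steep slope to abyssal (> 2,000 m)
    open ocean.  SST decreases monotonically northward, cycles seasonally
    (warmest in early September) and carries small-scale spatial noise.
    """
    lon_min, lon_max, lat_min, lat_max = extent
    if lon_max <= lon_min or lat_max <= lat_min:
        raise ValueError("degenerate extent: zero or negative area")
    if lat_max - lat_min < 20:
        raise ValueError("extent must span at least 20 degrees of latitude")

    rng = np.random.default_rng(seed)
    lons = np.arange(lon_min + resolution / 2, lon_max, resolution)
    lats = np.arange(lat_min + resolution / 2, lat_max, resolution)
    dates = pd.date_range(pd.Timestamp(start), periods=n_days, freq="D")
    glat, glon = np.meshgrid(lats, lons, indexing="ij")

    # bathymetry: shelf (0-180 m) out to 3 deg off the coast, slope to 4,000 m
    d_off = _coast_lon(glat, extent) - glon  # degrees west of the coastline
    bathy = np.zeros_like(glon)
    shelf = (d_off > 0) & (d_off <= 3.0)
    slope = (d_off > 3.0) & (d_off <= 6.0)
    abyss = d_off > 6.0
    bathy[shelf] = 180.0 * d_off[shelf] / 3.0
    bathy[slope] = 180.0 + (4000.0 - 180.0) * (d_off[slope] - 3.0) / 3.0
    bathy[abyss] = 4000.0 + 100.0 * np.sin(glat[abyss] / 3.0) ** 2
    sea = d_off > 0
    bathy[sea] = np.maximum(bathy[sea], 5.0)  # no zero-depth sea cells
    bathy[sea] += rng.normal(0, 10.0, size=sea.sum()).clip(-4, None)

    # SST: latitude gradient + seasonal cycle + static mesoscale structure
    # + small daily noise
    meso = gaussian_filter(rng.normal(0, 1.0, size=glat.shape), sigma=3.0) * 2.5
    doy = dates.dayofyear.to_numpy()
    seasonal = 4.0 * np.cos(2 * np.pi * (doy - 250) / 365.25)
    base = 24.0 - 0.33 * (glat - 30.0) + meso
    sst = base[None] + seasonal[:, None, None]
    sst = sst + rng.normal(0, 0.3, size=sst.shape)
    sst[:, ~sea] = np.nan  # undefined on land

    return EnvironmentFields(lons=lons, lats=lats, dates=dates,
                             sst=sst, bathymetry=bathy)


def _is_sea(env: EnvironmentFields, lon: float, lat: float) -> bool:
    ext = env.extent
    if not (ext[0] < lon < ext[1] and ext[2] < lat < ext[3]):
        return False
    return float(env.bathy_interp(lon, lat)[0]) > 1.0


def _target_latitude(day: pd.Timestamp, deploy_lat: float, amplitude: float) -> float:
    """Piecewise seasonal target: ramp south Oct 1 - Dec 1, hold over winter,
    ramp back north Mar 1 - May 15."""
    winter_lat = deploy_lat - amplitude
    y = day.year
    oct1 = pd.Timestamp(y, 10, 1)
    dec1 = pd.Timestamp(y, 12, 1)
    # season boundaries relative to the most recent Oct 1
    if day < pd.Timestamp(y, 10, 1):
        oct1 = pd.Timestamp(y - 1, 10, 1)
        dec1 = pd.Timestamp(y - 1, 12, 1)
    mar1 = pd.Timestamp(oct1.year + 1, 3, 1)
    may15 = pd.Timestamp(oct1.year + 1, 5, 15)
    if day < oct1 or day >= may15:
        return deploy_lat
    if day < dec1:
        frac = (day - oct1).days / (dec1 - oct1).days
        return deploy_lat + frac * (winter_lat - deploy_lat)
    if day < mar1:
        return winter_lat
    frac = (day - mar1).days / (may15 - mar1).days
    return winter_lat + frac * (deploy_lat - winter_lat)


def simulate_track(
    deployment: TagDeployment,
    strategy: str,
    env: EnvironmentFields,
    seed: int,
    n_days: int = 365,
    amplitudes: dict[str, float] | None = None,
    speed_km_day: float = 45.0,
    noise_km: float = 10.0,
    noise_rho: float = 0.6,
    max_step_km: float = 145.0,
) -> TrueTrack:
    """Biased correlated random walk with date-switched bias targets.

    From 1 October the walk is pulled toward a strategy-specific winter
    latitude (a: deployment - 3 deg, b: - 10 deg, c: - 20 deg), reversing
    on 1 March; the pull speed is capped at ``speed_km_day`` so the track
    lags the moving target by at most the daily noise scale.  Steps that
    would land ashore are deflected west of the coastline.
    """
    if strategy not in STRATEGY_AMPLITUDE_DEG:
        raise ValueError(f"unknown strategy {strategy!r}")
    amp = (amplitudes or STRATEGY_AMPLITUDE_DEG)[strategy]
    if not _is_sea(env, deployment.lon, deployment.lat):
        raise ValueError("deployment location is on land or outside the domain")

    rng = np.random.default_rng(seed)
    dates = pd.date_range(deployment.date, periods=n_days, freq="D")
    lon, lat = float(deployment.lon), float(deployment.lat)
    vx = vy = 0.0  # correlated (OU) velocity noise, km/day
    out_lon = np.empty(n_days)
    out_lat = np.empty(n_days)
    out_lon[0], out_lat[0] = lon, lat

    for i, day in enumerate(dates[1:], start=1):
        tgt_lat = _target_latitude(day, deployment.lat, amp)
        tgt_lon = deployment.lon
        coslat = np.cos(np.radians(lat))
        dx = (tgt_lon - lon) * KM_PER_DEG * coslat
        dy = (tgt_lat - lat) * KM_PER_DEG
        dist = np.hypot(dx, dy)
        if dist > 0:
            pull = min(speed_km_day, dist)
            dx, dy = dx / dist * pull, dy / dist * pull
        vx = noise_rho * vx + rng.normal(0, noise_km)
        vy = noise_rho * vy + rng.normal(0, noise_km)
        sx, sy = dx + vx, dy + vy
        step = np.hypot(sx, sy)
        if step > max_step_km:
            sx, sy = sx / step * max_step_km, sy / step * max_step_km
        new_lon = lon + sx / (KM_PER_DEG * coslat)
        new_lat = lat + sy / KM_PER_DEG
        if not _is_sea(env, new_lon, new_lat):
            # deflect: try pure southward/northward, then westward, else stay
            if _is_sea(env, lon, new_lat):
                new_lon = lon
            elif _is_sea(env, new_lon - abs(sx) / KM_PER_DEG, new_lat):
                new_lon = new_lon - abs(sx) / KM_PER_DEG
            else:
                new_lon, new_lat = lon, lat
        lon, lat = float(new_lon), float(new_lat)
        out_lon[i], out_lat[i] = lon, lat

    positions = pd.DataFrame({"date": dates, "lon": out_lon, "lat": out_lat})
    return TrueTrack(animal_id=deployment.animal_id, strategy=strategy,
                     positions=positions)


def simulate_observations(
    track: TrueTrack,
    env: EnvironmentFields,
    config: SimConfig,
    seed: int,
) -> ObservationSeries:
    """Corrupt a true track into what the tag would record.

    Light fixes: true position + independent zero-mean Gaussian noise
    (sigma_lon, sigma_lat), missing on a fraction of days.  SST: satellite
    field at the true position + Gaussian(0, sigma_sst).  Daily maximum
    depth: lognormal draw concentrated in the 50-200 m band, never exceeding
    the bathymetry at the true position (physiological cap 1,250 m).  Argos
    fixes on surfacing days with class-dependent noise.
    """
    pos = track.positions
    ext = env.extent
    inside = (
        (pos["lon"] > ext[0]).all() and (pos["lon"] < ext[1]).all()
        and (pos["lat"] > ext[2]).all() and (pos["lat"] < ext[3]).all()
    )
    t0, t1 = pos["date"].iloc[0], pos["date"].iloc[-1]
    if not inside or t0 < env.dates[0] or t1 > env.dates[-1]:
        raise ValueError("track does not overlap the environment in space/time")

    rng = np.random.default_rng(seed)
    n = len(pos)
    lons = pos["lon"].to_numpy()
    lats = pos["lat"].to_numpy()

    light_lon = lons + rng.normal(0, config.sigma_lon_deg, n)
    light_lat = lats + rng.normal(0, config.sigma_lat_deg, n)
    missing = rng.random(n) < config.light_missing_rate
    light_lon[missing] = np.nan
    light_lat[missing] = np.nan

    # vectorise SST lookup by date index
    didx = env.dates.get_indexer(pos["date"].dt.normalize(), method="nearest")
    sst_true = np.empty(n)
    for i in range(n):
        f = RegularGridInterpolator((env.lats, env.lons), env.sst[didx[i]],
                                    bounds_error=False, fill_value=None)
        sst_true[i] = f([[lats[i], lons[i]]])[0]
    sst_obs = sst_true + rng.normal(0, config.sigma_sst_c, n)

    bathy = env.bathy_interp(lons, lats)
    cap = np.minimum(bathy, 1250.0)
    draw = rng.lognormal(mean=np.log(110.0), sigma=0.55, size=n)
    max_depth = np.minimum(draw, cap)

    archival = pd.DataFrame({
        "date": pos["date"].to_numpy(),
        "light_lon": light_lon,
        "light_lat": light_lat,
        "sst_c": sst_obs,
        "max_depth_m": max_depth,
    })

    # Argos surfacing: seasonal daily probability, 1 fix per surfacing day
    month = pos["date"].dt.month.to_numpy()
    summer = (month >= 4) & (month <= 9)
    p_surface = np.where(summer, config.surface_prob_summer,
                         config.surface_prob_winter)
    surfaced = rng.random(n) < p_surface
    classes = list(ARGOS_CLASS_ERROR_KM)
    probs = np.array([ARGOS_CLASS_PROBS[c] for c in classes])
    rows = []
    for i in np.flatnonzero(surfaced):
        cls = rng.choice(classes, p=probs / probs.sum())
        scale = ARGOS_CLASS_ERROR_KM[cls]
        coslat = np.cos(np.radians(lats[i]))
        fix_lon = lons[i] + rng.normal(0, scale / (KM_PER_DEG * coslat))
        fix_lat = lats[i] + rng.normal(0, scale / KM_PER_DEG)
        hour = rng.integers(0, 24)
        rows.append((pos["date"].iloc[i] + pd.Timedelta(hours=int(hour)),
                     fix_lon, fix_lat, cls))
    argos = pd.DataFrame(rows, columns=["timestamp", "lon", "lat", "loc_class"])
    return ObservationSeries(animal_id=track.animal_id, archival=archival,
                             argos=argos)


def simulate_fleet(
    config: SimConfig,
    env: EnvironmentFields,
    deploy_lon: float = -9.0,
    deploy_lat: float = 56.0,
    deploy_date: str | pd.Timestamp = "2014-07-01",
    strategies: Sequence[str] | None = None,
) -> list[tuple[TagDeployment, TrueTrack, ObservationSeries]]:
    """Simulate a whole tagged fleet under one configuration.

    Strategies are drawn from ``config.strategy_mix`` unless given
    explicitly.  Deployment locations are jittered around a common tagging
    area (as for animals tagged at one coastal site in one season).
    Seeds for individual animals derive deterministically from config.seed.
    """
    rng = np.random.default_rng(config.seed)
    if strategies is None:
        strategies = rng.choice(["a", "b", "c"], size=config.n_animals,
                                p=np.asarray(config.strategy_mix))
    out = []
    for k, strat in enumerate(strategies):
        # jitter the tagging site; keep at sea
        for _ in range(100):
            lon = deploy_lon + rng.normal(0, 0.8)
            lat = deploy_lat + rng.normal(0, 0.8)
            if _is_sea(env, lon, lat):
                break
        dep = TagDeployment(animal_id=f"sim{k:03d}", date=deploy_date,
                            lon=lon, lat=lat, tag_class="archival")
        track = simulate_track(dep, str(strat), env,
                               seed=int(rng.integers(2**31)),
                               n_days=config.n_days)
        last = track.positions.iloc[-1]
        dep = dataclasses.replace(dep, popoff_date=last["date"],
                                  popoff_lon=float(last["lon"]),
                                  popoff_lat=float(last["lat"]))
        obs = simulate_observations(track, env, config,
                                    seed=int(rng.integers(2**31)))
        out.append((dep, track, obs))
    return out
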