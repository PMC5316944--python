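"""Hidden-Markov-model grid-filter geolocation.

The hidden state is the grid cell occupied by the animal on each day.  The
filter alternates two steps:

* **predict** — the daily probability surface evolves under an
  advection-diffusion equation, discretised with an explicit conservative
  finite-difference scheme (flux form, reflecting boundaries, sub-stepped
  to satisfy the stability bound ``D*dt/dx^2 <= 0.25`` per axis).  The
  default is pure diffusion with D = 1,000 km^2/day.
* **update** — the predicted surface is multiplied by observation
  likelihoods: a Gaussian around the raw light fix (sigma 1 deg longitude,
  3.5 deg latitude), a Gaussian match between tag-recorded and satellite
  SST (sigma 0.5 degC), and a bathymetric mask excluding cells shallower
  than the day's maximum recorded depth.

Day 0 is a point mass at the known deployment location.  When a pop-off
(end-of-track) position is known, a forward-backward smoothing pass
propagates that terminal constraint through the whole track.  Each daily
posterior is reduced to a best location as the probability-weighted mean
of the cell centroids.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .grid import GridSpec, build_grid, KM_PER_DEG

logger = logging.getLogger(__name__)

_NORM_TOL = 1e-6  # how closely an input field must sum to one


@dataclass
class FilterConfig:
    """Tunable parameters of the grid filter.

    D : diffusion coefficient, km^2/day.
    sigma_lon, sigma_lat : SD of raw light-based fixes, degrees.
    sigma_sst : SD of (tag SST - satellite SST), degC.
    advection : (u, v) velocity, km/day (default zero: pure diffusion).
    popoff_sigma_deg : SD of the terminal pop-off position constraint.
    """

    D: float = 1000.0
    sigma_lon: float = 1.0
    sigma_lat: float = 3.5
    sigma_sst: float = 0.5
    advection: tuple[float, float] = (0.0, 0.0)
    popoff_sigma_deg: float = 0.25

    def __post_init__(self):
        if self.D < 0:
            raise ValueError("D must be >= 0")
        for name in ("sigma_lon", "sigma_lat", "sigma_sst"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class DailyPosterior:
    date: pd.Timestamp
    p: np.ndarray  # (nlat, nlon), >= 0, sums to 1, zero on land


@dataclass
class FilterResult:
    """Output of the filter: one posterior and one best location per day."""

    grid: GridSpec
    dates: pd.DatetimeIndex
    posteriors: np.ndarray   # (ndays, nlat, nlon)
    track: pd.DataFrame      # date, lon, lat, source
    smoothed: bool = False

    def daily(self, i: int) -> DailyPosterior:
        return DailyPosterior(self.dates[i], self.posteriors[i])


def _check_normalised(p: np.ndarray) -> None:
    if abs(float(p.sum()) - 1.0) > _NORM_TOL or (p < 0).any():
        raise ValueError("input field is not a normalised probability surface")


def _diffuse(p: np.ndarray, grid: GridSpec, config: FilterConfig,
             dt_days: float, reverse_advection: bool = False) -> np.ndarray:
    """One application of the explicit advection-diffusion operator.

    Flux form between sea-cell neighbours only, so mass is conserved
    exactly and boundaries (domain edge and coastline) are reflecting.
    The pure-diffusion operator is symmetric, which the smoother exploits;
    the adjoint of the upwind advection term is the same term with the
    velocity negated (``reverse_advection``).
    """
    D = config.D
    u, v = config.advection
    if reverse_advection:
        u, v = -u, -v
    if (D == 0 and u == 0 and v == 0) or dt_days == 0:
        return p.copy()

    dx_row, dy = grid.cell_sizes_km()
    dx_min = dx_row.min()
    # sub-step so that D*dt/dx^2 <= 0.25 per axis and |u|*dt/dx <= 0.25
    limits = []
    if D > 0:
        limits.append(0.25 * dx_min**2 / D)
        limits.append(0.25 * dy**2 / D)
    if u != 0:
        limits.append(0.25 * dx_min / abs(u))
    if v != 0:
        limits.append(0.25 * dy / abs(v))
    n_sub = max(1, int(np.ceil(dt_days / min(limits))))
    ddt = dt_days / n_sub

    sea = grid.sea
    okx = sea[:, 1:] & sea[:, :-1]   # valid east-west edges
    oky = sea[1:, :] & sea[:-1, :]   # valid north-south edges
    ax = (D * ddt / dx_row**2)[:, None]
    ay = D * ddt / dy**2
    cx = (u * ddt / dx_row)[:, None]
    cy = v * ddt / dy

    p = p.copy()
    for _ in range(n_sub):
        dpx = np.where(okx, p[:, 1:] - p[:, :-1], 0.0)
        dpy = np.where(oky, p[1:, :] - p[:-1, :], 0.0)
        new = p.copy()
        # diffusive fluxes (into the lower-index cell when positive)
        fx = ax * dpx
        fy = ay * dpy
        new[:, :-1] += fx
        new[:, 1:] -= fx
        new[:-1, :] += fy
        new[1:, :] -= fy
        # first-order upwind advection across sea edges
        if u != 0:
            upw = np.where(cx > 0, p[:, :-1], p[:, 1:])  # donor cell
            fadv = np.where(okx, cx * upw, 0.0)
            new[:, 1:] += fadv
            new[:, :-1] -= fadv
        if v != 0:
            upw = np.where(cy > 0, p[:-1, :], p[1:, :])
            fadv = np.where(oky, cy * upw, 0.0)
            new[1:, :] += fadv
            new[:-1, :] -= fadv
        p = new
    return p


def predict_step(posterior: np.ndarray, grid: GridSpec, config: FilterConfig,
                 dt_days: float = 1.0) -> np.ndarray:
    """Advance a daily probability surface by ``dt_days`` of movement."""
    if dt_days <= 0:
        raise ValueError("dt_days must be > 0")
    _check_normalised(posterior)
    return _diffuse(posterior, grid, config, dt_days)


def light_likelihood(light_fix, grid: GridSpec,
                     config: FilterConfig) -> np.ndarray:
    """Gaussian likelihood of a raw light-based fix, independent per axis.

    ``light_fix`` is ``(lon, lat)``; a missing fix (None, or any NaN
    coordinate) yields a uniform (uninformative) field.
    """
    if light_fix is None:
        return np.ones(grid.shape)
    lon, lat = light_fix
    if not (np.isfinite(lon) and np.isfinite(lat)):
        return np.ones(grid.shape)
    glat, glon = grid.mesh()
    z = ((glon - lon) / config.sigma_lon) ** 2 \
        + ((glat - lat) / config.sigma_lat) ** 2
    return np.exp(-0.5 * z)


def sst_likelihood(sst_obs, env_sst_on_grid: np.ndarray,
                   config: FilterConfig) -> np.ndarray:
    """Gaussian match between the tag-recorded SST and the satellite field.

    ``env_sst_on_grid`` is the field for the day, interpolated onto the
    filter grid (NaN on land).  Missing observation -> uniform field.
    """
    if sst_obs is None or not np.isfinite(sst_obs):
        return np.ones(env_sst_on_grid.shape)
    L = np.exp(-0.5 * ((sst_obs - env_sst_on_grid) / config.sigma_sst) ** 2)
    return np.nan_to_num(L, nan=0.0)


def depth_mask(max_depth_obs, grid: GridSpec) -> np.ndarray:
    """Binary bathymetric constraint: the animal cannot have dived deeper
    than the seafloor, so cells shallower than the day's maximum depth are
    excluded.  Missing observation -> all sea cells allowed."""
    if max_depth_obs is None or not np.isfinite(max_depth_obs):
        return grid.sea.astype(float)
    if max_depth_obs < 0:
        raise ValueError("max depth must be >= 0")
    return (grid.sea & (grid.bathymetry >= max_depth_obs)).astype(float)


def update_step(prior: np.ndarray, likelihoods: dict[str, np.ndarray],
                date=None) -> np.ndarray:
    """Bayes update: posterior proportional to prior times all likelihoods.

    If the product has zero total mass, contradictory observations are
    dropped in a fixed order — depth first, then SST — with a warning;
    if the light fix itself contradicts the prior an error names the date.
    """
    _check_normalised(prior)
    drop_order = ["depth", "sst"]
    active = dict(likelihoods)
    while True:
        post = prior.copy()
        for L in active.values():
            post = post * L
        total = float(post.sum())
        if total > 0:
            return post / total
        dropped = None
        for name in drop_order:
            if name in active:
                dropped = name
                del active[name]
                break
        if dropped is None:
            raise ValueError(
                f"all observations contradict the prior on {date}")
        msg = (f"contradictory {dropped} observation dropped"
               + (f" on {date}" if date is not None else ""))
        logger.warning(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)


def _point_mass(grid: GridSpec, lon: float, lat: float) -> np.ndarray:
    p = np.zeros(grid.shape)
    i, j = grid.cell_of(lon, lat)
    if not grid.sea[i, j]:
        # snap to the nearest sea cell (deployments sit near the coast)
        ii, jj = np.nonzero(grid.sea)
        d = (grid.lats[ii] - lat) ** 2 + (grid.lons[jj] - lon) ** 2
        k = int(np.argmin(d))
        i, j = int(ii[k]), int(jj[k])
    p[i, j] = 1.0
    return p


def _gaussian_anchor(grid: GridSpec, lon: float, lat: float,
                     sigma_deg: float) -> np.ndarray:
    glat, glon = grid.mesh()
    z = ((glon - lon) ** 2 + (glat - lat) ** 2) / sigma_deg**2
    L = np.exp(-0.5 * z) * grid.sea
    if L.sum() == 0:
        L = _point_mass(grid, lon, lat)
    return L


def run_filter(observations: pd.DataFrame, grid: GridSpec,
               config: FilterConfig, deployment, env=None,
               smooth: bool | None = None) -> FilterResult:
    """Run the daily predict/update chain over one tag's observations.

    Parameters
    ----------
    observations : DataFrame
        Columns ``date`` plus any of ``light_lon``/``light_lat``,
        ``sst_c``, ``max_depth_m``.  Days absent from the table (between
        deployment and the last observation) become predict-only days.
    grid, config : the spatial domain and filter parameters.
    deployment : TagDeployment
        Supplies the day-0 anchor; its pop-off fields, when set, supply
        the terminal anchor.
    env : EnvironmentFields, optional
        Needed for the SST likelihood; without it SST is ignored.
    smooth : bool, optional
        Force smoothing on/off.  Default: smooth exactly when a pop-off
        position is known.
    """
    if not grid.contains(deployment.lon, deployment.lat):
        raise ValueError("deployment location outside the filter grid")
    obs = observations.copy()
    obs["date"] = pd.to_datetime(obs["date"]).dt.normalize()
    obs = obs.set_index("date").sort_index()
    start = pd.Timestamp(deployment.date).normalize()
    if len(obs) and obs.index[0] < start:
        raise ValueError("observations precede the deployment date")
    end = obs.index[-1] if len(obs) else start
    dates = pd.date_range(start, end, freq="D")

    has_popoff = (deployment.popoff_lon is not None
                  and deployment.popoff_lat is not None)
    if smooth is None:
        smooth = has_popoff

    # pre-interpolate SST onto the filter grid per date (cache by env day)
    sst_cache: dict[int, np.ndarray] = {}

    def sst_on_grid(date):
        k = env.date_index(date)
        if k not in sst_cache:
            from scipy.interpolate import RegularGridInterpolator
            f = RegularGridInterpolator((env.lats, env.lons), env.sst[k],
                                        bounds_error=False, fill_value=None)
            glat, glon = grid.mesh()
            vals = f(np.column_stack([glat.ravel(), glon.ravel()]))
            field_ = vals.reshape(grid.shape)
            field_[~grid.sea] = np.nan
            sst_cache[k] = field_
        return sst_cache[k]

    def day_likelihoods(date) -> dict[str, np.ndarray]:
        Ls: dict[str, np.ndarray] = {}
        if date not in obs.index:
            return Ls
        row = obs.loc[date]
        if isinstance(row, pd.DataFrame):  # duplicate dates: take the first
            row = row.iloc[0]
        if "light_lon" in row.index:
            Ls["light"] = light_likelihood(
                (row.get("light_lon"), row.get("light_lat")), grid, config)
        if env is not None and "sst_c" in row.index:
            Ls["sst"] = sst_likelihood(row.get("sst_c"),
                                       sst_on_grid(date), config)
        if "max_depth_m" in row.index:
            Ls["depth"] = depth_mask(row.get("max_depth_m"), grid)
        return Ls

    n = len(dates)
    filtered = np.empty((n,) + grid.shape)
    all_likelihoods: list[dict[str, np.ndarray]] = []

    p = _point_mass(grid, deployment.lon, deployment.lat)
    filtered[0] = p
    all_likelihoods.append({})
    for t in range(1, n):
        p = _diffuse(filtered[t - 1], grid, config, 1.0)
        Ls = day_likelihoods(dates[t])
        all_likelihoods.append(Ls)
        filtered[t] = update_step(p, Ls, date=dates[t]) if Ls else p

    posteriors = filtered
    if smooth and has_popoff:
        anchor = _gaussian_anchor(grid, deployment.popoff_lon,
                                  deployment.popoff_lat,
                                  config.popoff_sigma_deg)
        beta = anchor.copy()
        smoothed = np.empty_like(filtered)
        g = filtered[-1] * beta
        smoothed[-1] = g / g.sum()
        for t in range(n - 2, -1, -1):
            c = beta * _combined(all_likelihoods[t + 1], grid)
            c = c / c.sum()
            beta = _diffuse(c, grid, config, 1.0, reverse_advection=True)
            g = filtered[t] * beta
            smoothed[t] = g / g.sum()
        posteriors = smoothed

    track = pd.DataFrame(
        [best_daily_location(posteriors[t], grid) for t in range(n)],
        columns=["lon", "lat"])
    track.insert(0, "date", dates)
    track["source"] = "light-hmm"
    return FilterResult(grid=grid, dates=dates, posteriors=posteriors,
                        track=track, smoothed=bool(smooth and has_popoff))


def _combined(Ls: dict[str, np.ndarray], grid: GridSpec) -> np.ndarray:
    out = np.ones(grid.shape)
    for L in Ls.values():
        out = out * L
    if out.sum() == 0:  # mirror the forward pass's contradictory-obs policy
        out = np.ones(grid.shape)
        for name, L in Ls.items():
            if name != "depth":
                out = out * L
        if out.sum() == 0 and "light" in Ls:
            out = Ls["light"]
    return out


def best_daily_location(posterior: np.ndarray, grid: GridSpec):
    """Probability-weighted mean of the cell centroids (in degrees)."""
    _check_normalised(posterior)
    glat, glon = grid.mesh()
    return float((posterior * glon).sum()), float((posterior * glat).sum())


def transition_matrix(grid: GridSpec, config: FilterConfig,
                      dt_days: float = 1.0) -> np.ndarray:
    """Dense one-day transition matrix of the movement model (columns are
    the images of unit point masses).  Intended for small grids, e.g. to
    cross-check the filter against a dense forward algorithm."""
    n = grid.n_cells
    T = np.empty((n, n))
    for j in range(n):
        e = np.zeros(n)
        e[j] = 1.0
        T[:, j] = _diffuse(e.reshape(grid.shape), grid, config,
                           dt_days).ravel()
    return T


class HMMGeolocator(BaseEstimator):
    """Grid-filter HMM geolocation as a scikit-learn style estimator.

    Parameters mirror :class:`FilterConfig` plus the grid resolution.
    ``fit`` consumes one tag's observation table and stores the daily
    posteriors and the best-daily-location track as fitted attributes.

    Examples
    --------
    >>> geo = HMMGeolocator(resolution=1.0)
    >>> geo.fit(obs.archival, env=env, deployment=dep)   # doctest: +SKIP
    >>> geo.track_[["date", "lon", "lat"]].head()        # doctest: +SKIP
    """

    def __init__(self, D: float = 1000.0, sigma_lon: float = 1.0,
                 sigma_lat: float = 3.5, sigma_sst: float = 0.5,
                 advection: tuple[float, float] = (0.0, 0.0),
                 popoff_sigma_deg: float = 0.25,
                 resolution: float = 1.0, smooth: bool | None = None):
        self.D = D
        self.sigma_lon = sigma_lon
        self.sigma_lat = sigma_lat
        self.sigma_sst = sigma_sst
        self.advection = advection
        self.popoff_sigma_deg = popoff_sigma_deg
        self.resolution = resolution
        self.smooth = smooth

    def _config(self) -> FilterConfig:
        return FilterConfig(D=self.D, sigma_lon=self.sigma_lon,
                            sigma_lat=self.sigma_lat, sigma_sst=self.sigma_sst,
                            advection=tuple(self.advection),
                            popoff_sigma_deg=self.popoff_sigma_deg)

    def fit(self, X: pd.DataFrame, y=None, *, env, deployment,
            grid: GridSpec | None = None):
        """Reconstruct the track from one tag's observations.

        X : observation DataFrame (date, light_lon, light_lat, sst_c,
        max_depth_m).  ``env`` supplies SST and bathymetry; ``grid``
        overrides the default grid built from the environment extent at
        ``self.resolution``.
        """
        if grid is None:
            grid = build_grid(env.extent, self.resolution, env)
        self.grid_ = grid
        res = run_filter(X, grid, self._config(), deployment, env=env,
                         smooth=self.smooth)
        self.result_ = res
        self.posteriors_ = res.posteriors
        self.dates_ = res.dates
        self.track_ = res.track
        return self

    def predict(self, X=None) -> pd.DataFrame:
        """Best daily locations (the fitted track)."""
        if not hasattr(self, "track_"):
            raise AttributeError("HMMGeolocator is not fitted yet")
        return self.track_
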