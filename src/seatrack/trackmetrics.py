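"""Daily-track reduction and movement summaries.

Argos surface fixes are cleaned with a forward speed filter, reduced to one
location per UTC day (best location class wins), and summarised as
along-track distance, displacement from the tagging site and monthly
minimum latitudes — the quantities used to compare animals and to feed the
migration-strategy classification.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

#: Argos location-class quality ranking, best first; Z is invalid.
CLASS_ORDER = ["3", "2", "1", "0", "A", "B"]
_CLASS_RANK = {c: i for i, c in enumerate(CLASS_ORDER)}


def haversine_km(p1, p2) -> float:
    """Great-circle distance in km between (lon, lat) points, R = 6,371 km."""
    lon1, lat1 = np.radians(np.asarray(p1, dtype=float))
    lon2, lat2 = np.radians(np.asarray(p2, dtype=float))
    a = (np.sin((lat2 - lat1) / 2) ** 2
         + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2)
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def _haversine_pairwise(lons, lats) -> np.ndarray:
    """Distances between consecutive points of a track, vectorised."""
    lon = np.radians(np.asarray(lons, dtype=float))
    lat = np.radians(np.asarray(lats, dtype=float))
    a = (np.sin(np.diff(lat) / 2) ** 2
         + np.cos(lat[:-1]) * np.cos(lat[1:]) * np.sin(np.diff(lon) / 2) ** 2)
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def speed_filter(fixes: pd.DataFrame, vmax_kmh: float = 9.0) -> pd.DataFrame:
    """Remove implausibly fast Argos fixes.

    Forward pass: the first (non-Z) fix is always retained; each later fix
    is dropped if the speed from the last *retained* fix exceeds
    ``vmax_kmh``.  Class-Z fixes are always removed.  Input must be
    time-ordered (columns: timestamp, lon, lat, loc_class).
    """
    if len(fixes) == 0:
        return fixes.copy()
    f = fixes[fixes["loc_class"].astype(str) != "Z"].reset_index(drop=True)
    if len(f) == 0:
        return f
    keep = [0]
    for i in range(1, len(f)):
        j = keep[-1]
        dt_h = (pd.Timestamp(f["timestamp"].iloc[i])
                - pd.Timestamp(f["timestamp"].iloc[j])).total_seconds() / 3600.0
        d = haversine_km((f["lon"].iloc[j], f["lat"].iloc[j]),
                         (f["lon"].iloc[i], f["lat"].iloc[i]))
        if dt_h <= 0 or (np.isfinite(vmax_kmh) and d / dt_h > vmax_kmh):
            continue
        keep.append(i)
    return f.iloc[keep].reset_index(drop=True)


def daily_reduce(fixes: pd.DataFrame) -> pd.DataFrame:
    """One location per UTC day: best location class, ties broken by
    proximity to 12:00 UTC.  Returns columns date, lon, lat, source."""
    if len(fixes) == 0:
        return pd.DataFrame(columns=["date", "lon", "lat", "source"])
    f = fixes.copy()
    f["timestamp"] = pd.to_datetime(f["timestamp"])
    f["_day"] = f["timestamp"].dt.normalize()
    f["_rank"] = f["loc_class"].astype(str).map(_CLASS_RANK)
    noon = f["_day"] + pd.Timedelta(hours=12)
    f["_off"] = (f["timestamp"] - noon).abs()
    f = f.sort_values(["_day", "_rank", "_off"], kind="stable")
    best = f.groupby("_day", as_index=False).first()
    out = pd.DataFrame({"date": best["_day"], "lon": best["lon"],
                        "lat": best["lat"], "source": "argos"})
    return out.reset_index(drop=True)


def along_track_distance(track: pd.DataFrame) -> float:
    """Sum of great-circle distances over consecutive daily locations, km."""
    if len(track) < 2:
        warnings.warn("along-track distance of a <2-point track is 0",
                      RuntimeWarning, stacklevel=2)
        return 0.0
    return float(_haversine_pairwise(track["lon"], track["lat"]).sum())


def displacement_stats(track: pd.DataFrame, deployment
                       ) -> tuple[pd.Series, float]:
    """Per-day great-circle distance from the tagging location, and its
    maximum.  ``deployment`` needs ``lon``/``lat`` attributes."""
    lon0, lat0 = deployment.lon, deployment.lat
    lon = np.radians(track["lon"].to_numpy(dtype=float))
    lat = np.radians(track["lat"].to_numpy(dtype=float))
    a = (np.sin((lat - np.radians(lat0)) / 2) ** 2
         + np.cos(np.radians(lat0)) * np.cos(lat)
         * np.sin((lon - np.radians(lon0)) / 2) ** 2)
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
    series = pd.Series(d, index=pd.to_datetime(track["date"]).values,
                       name="displacement_km")
    return series, float(d.max()) if len(d) else 0.0


def min_monthly_latitude(track: pd.DataFrame) -> pd.Series:
    """Minimum latitude per calendar month present in the track."""
    t = track.copy()
    t["date"] = pd.to_datetime(t["date"])
    g = t.groupby(t["date"].dt.to_period("M"))["lat"].min()
    g.name = "min_lat"
    return g


def track_summary(track: pd.DataFrame, deployment) -> dict:
    """n_days, along-track distance, max displacement, southernmost latitude."""
    _, max_disp = displacement_stats(track, deployment)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        dist = along_track_distance(track)
    return {
        "animal_id": getattr(deployment, "animal_id", None),
        "n_days": int(len(track)),
        "along_track_km": dist,
        "max_displacement_km": max_disp,
        "southernmost_lat": float(track["lat"].min()),
    }


def cohort_summary(summaries: pd.DataFrame) -> pd.DataFrame:
    """Median, quartiles (linear interpolation), min and max per metric."""
    if len(summaries) == 0:
        raise ValueError("no summaries given")
    num = summaries.select_dtypes("number")
    rows = {}
    for col in num.columns:
        v = num[col].to_numpy(dtype=float)
        rows[col] = {
            "median": float(np.percentile(v, 50)),
            "q25": float(np.percentile(v, 25)),
            "q75": float(np.percentile(v, 75)),
            "min": float(v.min()),
            "max": float(v.max()),
        }
    return pd.DataFrame(rows).T
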