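"""File formats: observation/track CSVs, plain-text environment grids,
GeoJSON zones and YAML configs.

Every tabular file written here carries a ``# seatrack`` comment header
recording the config hash that produced it (readable back with pandas'
``comment='#'``).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import EnvironmentFields, TagDeployment


def _header(config_hash: str | None) -> str:
    return f"# seatrack config={config_hash or 'unknown'}\n"


def write_table(df: pd.DataFrame, path, config_hash: str | None = None):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(config_hash))
        df.to_csv(fh, index=False)


def read_table(path, parse_dates=None) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", parse_dates=parse_dates or [])


def write_observations(obs, path, config_hash=None):
    write_table(obs.archival, path, config_hash)


def read_observations(path) -> pd.DataFrame:
    return read_table(path, parse_dates=["date"])


def write_argos(obs, path, config_hash=None):
    write_table(obs.argos, path, config_hash)


def read_argos(path) -> pd.DataFrame:
    return read_table(path, parse_dates=["timestamp"])


def write_deployments(deployments: list[TagDeployment], path,
                      config_hash=None):
    rows = []
    for d in deployments:
        rows.append({
            "animal_id": d.animal_id, "date": d.date, "lon": d.lon,
            "lat": d.lat, "popoff_date": d.popoff_date,
            "popoff_lon": d.popoff_lon, "popoff_lat": d.popoff_lat,
            "tag_class": d.tag_class, "sex": d.sex, "length_m": d.length_m,
        })
    write_table(pd.DataFrame(rows), path, config_hash)


def read_deployments(path) -> list[TagDeployment]:
    df = read_table(path, parse_dates=["date", "popoff_date"])
    out = []
    for _, r in df.iterrows():
        out.append(TagDeployment(
            animal_id=str(r["animal_id"]), date=r["date"],
            lon=float(r["lon"]), lat=float(r["lat"]),
            popoff_date=None if pd.isna(r.get("popoff_date")) else r["popoff_date"],
            popoff_lon=None if pd.isna(r.get("popoff_lon")) else float(r["popoff_lon"]),
            popoff_lat=None if pd.isna(r.get("popoff_lat")) else float(r["popoff_lat"]),
            tag_class=str(r.get("tag_class", "archival")),
        ))
    return out


# ---------------------------------------------------------------------------
# plain-text environment grid: JSON header line + whitespace-separated blocks

def write_environment(env: EnvironmentFields, path, config_hash=None):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = {
        "format": "seatrack-environment-v1",
        "config": config_hash,
        "lons": env.lons.tolist(),
        "lats": env.lats.tolist(),
        "dates": [str(d.date()) for d in env.dates],
    }
    with open(path, "w") as fh:
        fh.write(json.dumps(header) + "\n")
        np.savetxt(fh, env.bathymetry, fmt="%.2f")
        for k in range(len(env.dates)):
            np.savetxt(fh, env.sst[k], fmt="%.3f")


def read_environment(path) -> EnvironmentFields:
    with open(path) as fh:
        header = json.loads(fh.readline())
        if header.get("format") != "seatrack-environment-v1":
            raise ValueError(f"{path} is not a seatrack environment file")
        lons = np.asarray(header["lons"])
        lats = np.asarray(header["lats"])
        dates = pd.DatetimeIndex([pd.Timestamp(d) for d in header["dates"]])
        nlat, nlon, nd = len(lats), len(lons), len(dates)
        data = np.loadtxt(fh)
    bathy = data[:nlat]
    sst = data[nlat:].reshape(nd, nlat, nlon)
    return EnvironmentFields(lons=lons, lats=lats, dates=dates, sst=sst,
                             bathymetry=bathy)


# ---------------------------------------------------------------------------
# posterior raster stacks: one text grid per day in a directory

def write_posteriors(result, outdir, config_hash=None):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {
        "format": "seatrack-posteriors-v1",
        "config": config_hash,
        "lons": result.grid.lons.tolist(),
        "lats": result.grid.lats.tolist(),
        "dates": [str(d.date()) for d in result.dates],
        "smoothed": result.smoothed,
    }
    (outdir / "meta.json").write_text(json.dumps(meta))
    for k, d in enumerate(result.dates):
        np.savetxt(outdir / f"{d.date()}.txt", result.posteriors[k],
                   fmt="%.6e")


def read_posteriors(indir):
    indir = Path(indir)
    meta = json.loads((indir / "meta.json").read_text())
    dates = pd.DatetimeIndex([pd.Timestamp(d) for d in meta["dates"]])
    stack = np.stack([np.loadtxt(indir / f"{d.date()}.txt") for d in dates])
    return stack, dates, meta


# ---------------------------------------------------------------------------
# zones + config

def read_zones_geojson(path):
    from .spaceuse import load_zones
    with open(path) as fh:
        return load_zones(json.load(fh))


def write_hex_geojson(density, hexgrid, path, config_hash=None):
    feats = []
    for i in np.flatnonzero(density > 0):
        feats.append({
            "type": "Feature",
            "properties": {"cell_id": int(i),
                           "mean_density": float(density[i])},
            "geometry": {"type": "Polygon",
                         "coordinates": [hexgrid.polygon_lonlat(int(i))]},
        })
    doc = {"type": "FeatureCollection", "features": feats,
           "properties": {"config": config_hash,
                          "apothem_km": hexgrid.apothem_km}}
    Path(path).write_text(json.dumps(doc))


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or not cfg:
        raise ValueError(f"config {path} is empty or not a mapping")
    return cfg
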