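# seatrack

Track reconstruction and space-use analysis for satellite-tagged marine
animals — built around a hidden-Markov-model **grid filter** for
light-based geolocation, with the downstream analyses a tagging study
needs: daily track metrics, utilisation distributions and percentage
volume contours, hexagonal density grids, zone (EEZ-style) occupancy,
k-means migration-strategy classification and depth-use profiles.

It is aimed at movement ecologists working with pop-up archival tags
(light, SST, depth) and Argos platform transmitters, and ships a
synthetic-data module that simulates seasonal shelf-edge migrations and
realistic tag noise, so the whole chain can be exercised and validated
without proprietary tag downloads.

## The model

The hidden state on day *t* is the grid cell **x**ₜ occupied by the
animal. The filter alternates:

**Predict** — the probability surface evolves under an
advection–diffusion equation, ∂p/∂t = ∇·(D∇p) − ∇·(**u**p), discretised
with an explicit conservative flux scheme (reflecting boundaries at the
coast and domain edge, sub-stepped so D·δt/Δx² ≤ 0.25 per axis).
Default: pure diffusion, D = 1,000 km² d⁻¹.

**Update** — Bayes' rule against the day's observations:

- light fix: independent Gaussians, σ_lon = 1°, σ_lat = 3.5°;
- SST: Gaussian match between tag-recorded and gridded SST, σ = 0.5 °C;
- depth: a bathymetric mask — cells shallower than the day's maximum
  recorded depth are excluded.

Day 0 is a point mass at the known deployment location; when a pop-off
position is known, a forward–backward smoothing pass propagates the
terminal constraint through the track. The best daily location is the
probability-weighted mean of the cell centroids. Per-animal utilisation
distributions are the normalised mean of the daily posteriors
(post-summer period: 1 October onwards), and percentage volume contours
take cells in descending probability until a fraction q of the mass is
covered. Density mapping uses regular hexagons with a 50-km apothem
(cell area 2√3·50² ≈ 8,660 km²): per animal, the proportion of tracking
days per cell; then the unweighted mean across animals.

## Worked example

```python
import numpy as np
from seatrack import (make_environment, simulate_fleet, SimConfig,
                      HMMGeolocator, haversine_km, kmeans_strategies,
                      epipelagic_fraction)

env = make_environment(seed=1, n_days=281)               # synthetic NE Atlantic
fleet = simulate_fleet(SimConfig(seed=1, n_animals=3, n_days=280), env,
                       strategies=["a", "b", "c"])

lats, ids = [], []
for dep, truth, obs in fleet:
    geo = HMMGeolocator(resolution=1.0).fit(obs.archival, env=env,
                                            deployment=dep)
    err = [haversine_km((a, b), (c, d)) for a, b, c, d in
           zip(geo.track_["lon"], geo.track_["lat"],
               truth.positions["lon"], truth.positions["lat"])]
    print(f"{dep.animal_id}: strategy {truth.strategy}, "
          f"RMSE {np.sqrt(np.mean(np.square(err))):.0f} km, "
          f"southernmost {geo.track_['lat'].min():.1f} deg N, "
          f"epipelagic {epipelagic_fraction(obs.archival['max_depth_m']):.0%}")
    ids.append(dep.animal_id)
    lats.append(geo.track_["lat"].min())

print(kmeans_strategies(lats, k=3, seed=7, animal_ids=ids))
```

prints

```
sim000: strategy a, RMSE 58 km, southernmost 53.0 deg N, epipelagic 87%
sim001: strategy b, RMSE 72 km, southernmost 46.1 deg N, epipelagic 84%
sim002: strategy c, RMSE 53 km, southernmost 36.0 deg N, epipelagic 89%
  animal_id  southernmost_lat strategy
0    sim000         53.000302        a
1    sim001         46.112576        b
2    sim002         35.975258        c
```

Each animal's smoothed track lands within ~50–70 km RMSE of the truth —
far below the ~390 km RMSE of the raw light fixes it was built from —
and the k-means step recovers the three migration amplitudes (a:
remaining near the tagging latitudes, b: mid-latitude winter grounds, c:
far-south migration) from the southernmost latitudes alone.

The same chain is available from the shell:

```bash
seatrack all --out runs/demo --seed 1
seatrack simulate --out runs/sim --seed 2 --n-animals 12
seatrack filter --out runs/sim --resolution 1.0
```

Every stage writes CSV/GeoJSON/plain-text-grid artifacts stamped with
the config hash that produced them, plus a `manifest.json` with
versions, seeds and timings.

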