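# Methods

## The grid-filter HMM

The movement model treats the animal's daily position as the hidden
state of an HMM whose state space is a regular longitude/latitude grid.
The prediction step solves the advection–diffusion equation for the
two-dimensional presence probability with an explicit finite-difference
scheme written in flux form: for each pair of adjacent sea cells a flux
`alpha * (p_j − p_i)` is exchanged, with `alpha = D·δt/Δ²` computed per
axis and per latitude row (the zonal cell width is scaled by cos φ of
the row, so the diffusion coefficient is isotropic in kilometres even
though the grid is kept in degrees). Because fluxes are antisymmetric
and only cross sea–sea edges, mass is conserved to machine precision
and the coastline and domain edge act as reflecting (no-flux)
boundaries. The scheme is sub-stepped so `D·δt/Δx² ≤ 0.25` per axis
(and `|u|·δt/Δx ≤ 0.25` for the optional upwind advection term), the
standard stability bound for the explicit scheme. On a uniform grid the
discrete second moment grows by exactly `2·D·δt` per axis per substep,
which is why the analytic-variance check passes at well under its 2%
tolerance rather than merely within it.

Defaults: `D = 1,000 km²/day`, advection `(0, 0)`. The advection field
is retained for generality but zero by default — the movement prior is
pure diffusion, with directionality entering only through the
observations.

The update step multiplies the predicted surface by per-observation
likelihoods: Gaussian in the raw light fix (σ_lon = 1°, σ_lat = 3.5° —
light-based latitudes are several times noisier than longitudes),
Gaussian in SST (σ = 0.5 °C between tag-recorded and gridded SST), and
a hard bathymetric mask (the day's maximum recorded depth cannot exceed
the seafloor depth). A missing observation contributes a uniform field.
If the likelihood product is identically zero, observations are dropped
in a fixed order — depth first (the most brittle constraint: a single
deep dive on a mis-gridded shelf edge zeroes the surface), then SST —
with a logged warning; if the light fix alone still contradicts the
prior, the filter raises an error naming the date. This drop policy is
a design choice of this package.

Day 0 is a point mass at the deployment location. Days missing from the
observation table become predict-only days, so gaps widen the posterior
rather than breaking the chain. When a pop-off position is known, a
forward–backward pass runs: the backward variable is initialised with a
tight Gaussian anchor at the pop-off point (σ = 0.25°, roughly the cell
scale at the default 1° resolution — the anchor should pin the terminal
cell without pretending to be more accurate than the grid) and
propagated with the adjoint of the transition operator. The diffusion
operator is symmetric by construction, so the adjoint is the operator
itself; the upwind advection term's adjoint is the same term with the
velocity negated. Without a pop-off anchor the filter returns plain
filtered posteriors.

The best daily location is the probability-weighted arithmetic mean of
cell centroids in degrees, not on the sphere: posteriors are unimodal
after an update and the domain spans < 40°, so the planar error is
negligible at the ~100-km scale of light geolocation.

Grid resolution is a free parameter (default 1°). Doubling the
resolution moves best daily locations by much less than half a coarse
cell on smooth cases (tested), so results are discretisation-stable at
the default.

## Synthetic data

The generator produces the conditions the analysis assumes, not a
behavioural model of any real animal.

**Environment.** A 24° × 34° domain (default 28–62° N, 25–1° W) with a
meridional coastline on the eastern edge: a shelf shallower than 200 m
out to ~3° off the coast, a slope to 4,000 m over the next 3°, then
abyssal ocean — the cross-shelf structure is what gives the depth mask
its discriminating power. SST is a monotone north–south gradient
(0.33 °C per degree of latitude) plus a ±4 °C seasonal cycle peaking in
early September, a static mesoscale anomaly field (Gaussian-filtered
noise, ~2.5 °C scale) and small daily noise; under the 0.5 °C
observation sigma this makes SST worth roughly ±1.5° of latitude, which
is the mechanism by which the filter beats the 3.5° raw light-fix
noise.

**Tracks.** A biased correlated random walk: each day the animal moves
up to 45 km toward a seasonal target (capped at the target distance),
plus AR(1) velocity noise (10 km/day innovations, persistence 0.6),
with steps capped at 145 km so daily displacement stays under a
plausible 150 km. The target latitude ramps from the deployment
latitude to a strategy-specific winter latitude between 1 October and
1 December, holds through winter, and ramps back between 1 March and
15 May; amplitudes are 3° (strategy a), 10° (b) and 20° (c) south of
deployment. The ramp speeds (≤ ~37 km/day) stay below the pull cap, so
tracks complete their return migration and are back within ~200 km of
the tagging site by late May. Steps that would land ashore are
deflected alongshore/offshore, never accepted.

**Observations.** Light fixes are truth plus independent N(0, 1°) /
N(0, 3.5°) noise, missing completely at random on 5% of days (per-day
light-fix availability is not a pinned-down quantity for real tags, so
the missingness rate is exposed as a parameter). SST is the gridded
field at the true position plus N(0, 0.5 °C). Daily maximum depth is a
lognormal draw (median 110 m, log-SD 0.55 — ~80% of days in the
50–200 m band) truncated at min(bathymetry, 1,250 m), so it never
contradicts the seafloor. Argos fixes occur with daily surfacing
probability 0.8 (April–September) or 0.3 (October–March), with class
drawn from a fixed distribution over {3, 2, 1, 0, A, B} and circular
Gaussian noise of scale 0.25/0.5/1/2/5/10 km respectively —
conventional Argos error magnitudes.

**What passing tests do not show.** The generator has no diel vertical
migration, no foraging behaviour, no spatially correlated light-fix
error (real light geolocation error is worse near equinoxes), and its
SST field is far smoother than a real frontal zone. Filter skill
measured here (raw-fix RMSE ~390 km reduced by ~85%) demonstrates the
machinery is correct and well-conditioned, not that real tracks reach
that accuracy; on real tags the paper-scale mean error of ~100 km is
the more realistic expectation.

## Space use

Per-animal UDs are the renormalised mean of daily posteriors over the
analysis period; "post-summer" is fixed at 1 October onwards. PVCs take
cells in descending probability order until cumulative mass reaches
q/100; ties are broken by flat cell index, so the mask is deterministic
and of provably minimal cardinality (verified by exhaustive subset
enumeration on small instances). Note this means exact ties at the cut
are *not* all included — minimality wins over tie symmetry.

The hexagonal grid is built in a local azimuthal-equidistant projection
about the extent centre, so the 50-km apothem is metric; flat-topped
hexagons with circumradius 2a/√3 tile the plane (column pitch 1.5R, row
pitch 2a, odd columns offset by a), giving cell area 2√3·a² =
8,660.25 km² at a = 50 km. Containment uses the fact that a hexagonal
tiling is the Voronoi diagram of its centres: a nearest-centre KD-tree
query. Posterior rasters are apportioned to hexes by raster-cell
centroid containment rather than areal weighting — the apportionment
error is far below the ~100-km geolocation error that motivates 50-km
cells in the first place.

Zone occupancy is point-in-polygon per animal-day, with boundary points
assigned to the first covering zone in input order and uncovered days
to the High Seas; percentages sum to 100 by construction.

## Track metrics

Great-circle distances use the haversine formula with R = 6,371 km.
The Argos speed filter is a forward pass: the first non-Z fix is
retained, and each later fix is dropped if the implied speed from the
last *retained* fix exceeds vmax (default 9 km/h — generous for a
sustained basking-shark swim; exposed as a flag since the original
filtering settings are not recoverable). Daily reduction keeps the best
location class per UTC day, ties broken by proximity to 12:00 UTC.
Cohort quartiles use linear interpolation between order statistics.

## Strategy classification

K-means (k = 3 by default) on the 1-D southernmost latitude of each
track, via Lloyd's algorithm with k-means++ initialisation and 25
restarts, best within-cluster sum of squares kept. Clusters are
relabelled a/b/c by descending mean latitude; ties in the mean are
broken by cluster size, larger first. Standardisation is a non-issue
for 1-D input. k = 3 reflects the three observed migration amplitudes
and is exposed as a parameter. Depth bins are right-closed ([0, 25],
(25, 50], …, (1000, ∞)), consistent with integer-metre bin labels like
"26–50 m"; the epipelagic fraction (≤ 200 m) equals the sum of the
first four bin proportions by construction.

## Problem sizes and determinism

Validation runs use a 0.5° environment grid, a 1° filter grid
(816 sea-dominated cells over the default domain), 280–365-day tracks
and fleets of 3–20 animals; the dense-oracle cross-checks use ≤ 100
cells, where the brute-force forward algorithm is exact. All
stochastic stages consume `numpy.random.default_rng` seeds derived
deterministically from a single configured seed, so every simulated
dataset and every pipeline artifact is bit-reproducible.
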