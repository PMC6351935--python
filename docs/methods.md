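# Methods

This note documents the models, the numerical choices, and what the
synthetic data does and does not show. It is the design record of the
package; empirical numbers quoted here are ones the test suite or
`scripts/acceptance.py` computes.

## Travel-time networks

A network is an undirected graph whose nodes are planar points (metres)
and whose edges carry minutes, `t = L / (v · 1000/60)`. Segments connect
only at endpoints; endpoints closer than `snap_tol_m` (default 0.5 m, a
safety net — generated layers emit exactly coincident endpoints) are
merged. Undirectedness is a deliberate modelling choice: one-way streets,
turn restrictions, signal delays and elevation effects are out of scope,
and symmetry (t_kj = t_jk) is what lets one shortest-path sweep per
facility serve both steps of the catchment computation and is the basis
of the supply-conservation identity below. Shortest paths are Dijkstra
(label-setting) on minute weights; the 30-min cutoff is inclusive, with a
1e-9 min slack absorbing float round-off.

Mode specifics:

- **Driving** — road classes map to speed limits (Collector 50, Major 65,
  Expressway 80, Alley 15 km/h). A descriptive vocabulary (primary
  highway, secondary highway, major road, local road) is aliased onto
  those classes via config.
- **Walking** — constant 4.8 km/h on sidewalks, trails, pathways and
  crosswalks. The constant-speed assumption is standard for city-scale
  walkability work; it ignores slope, crowding and ability differences.
- **Transit** — bus routes at their road-class speed when labelled, else
  40 km/h; trains at 45 km/h (no published value; configurable). Routes
  are split at stops; each stop links to its nearest walking node
  (≤ 100 m) at walking speed plus an optional boarding penalty (default
  0 min — no timetables, headways or waiting times are modelled). Transit
  edges join only stop nodes, so vehicles cannot be boarded mid-segment.
  Because the walking graph is a subgraph, multimodal travel times never
  exceed walking times.

### Crosswalk generation

Municipal sidewalk layers are often digitized per block and are therefore
disconnected at every street crossing. Crossing links are derived
geometrically: around each road intersection, take the circle of radius
18 m (the buffer boundary), split it at its crossing points with sidewalk
segments, and keep only the arcs that cross a road segment — those arcs
are the crosswalks. The implementation computes line–circle intersections
analytically and emits arcs whose vertices lie exactly on the circle
(5° discretization, ~1.6 m chords), rather than approximating the buffer
with a polygon; this keeps the on-circle invariant testable at 1e-6 m.
Crosswalk endpoints fall mid-segment on sidewalk sides, so the walking
builder splits sidewalks at those points before graph construction —
otherwise endpoint-only connectivity would leave the crosswalks dangling.

## E2SFCA and SPAR

Catchments are 30 min with three zones [0–10], (10–20], (20–30] min and
stepwise decay weights 1.00 / 0.42 / 0.09 — the sharp urban decay profile
appropriate where facilities are plentiful and people rarely travel far
by choice. Zone intervals are closed on the right.

- Step 1: R_j = S_j / Σ_k P_k·W(t_kj). A facility whose catchment holds
  no population gets R_j = 0 and is flagged rather than erroring.
- Step 2: A_i = Σ_j R_j·W(t_ij); zero when nothing is reachable.
- SPAR_i = A_i / mean(A), the mean unweighted over **all** population
  locations including zeros. Including zeros scales all SPAR values by a
  common factor, so ranks, quantile classes and the shortage set are
  unaffected by that convention. An all-zero access field (no facilities)
  raises an error instead of dividing by zero.

Facilities and population centroids are snapped to the nearest network
node (≤ 500 m); the off-network gap contributes no time, mirroring
service-area practice. On the default city the worst gap is ~280 m
(≈ 3.5 min of walking), a known bias shared by all modes.

**Supply conservation.** Substituting Step 1 into Step 2 and exchanging
summation order gives Σ_i P_i·A_i = Σ_j S_j over facilities with
non-empty catchments, exactly, whenever the same symmetric times feed
both steps. The suite asserts this at 1e-9 relative tolerance on the full
city for all three modes; it is the sharpest end-to-end correctness check
the method admits.

Quantile classification is cartographic only: zeros are isolated as
"no access", positive values split into five equal-count rank classes
with ties broken by location id for determinism.

## Spatial statistics

- **Weights** — symmetrized (union) k-nearest-neighbour (k = 8),
  row-standardized; chosen as the default because it is robust to
  irregular centroid spacing. Queen contiguity over the census polygons
  is available as a config alternative. Row-standardization of a
  symmetric adjacency yields real eigenvalues (the matrix is similar to a
  symmetric one), which the lag model's log-determinant relies on.
- **Collinearity screen** — greedy scan in column order, dropping any
  covariate with |Pearson r| ≥ 0.70 against an already-retained one.
- **Moran's I** — I = (n/S0)·z'Wz / z'z; significance by 999 random
  permutations (seeded, two-sided around the permutation mean) rather
  than the normal approximation, which is unreliable at the few-hundred
  observation sizes the synthetic cities produce. Null expectation
  −1/(n−1).
- **Spatial lag** — ML estimation of y = ρWy + Xβ + ε by concentrating
  the likelihood in ρ; the Jacobian term is Σ log(1 − ρλ_i) over the
  eigenvalues of W (Ord's method), and the search is a bounded scalar
  optimization over (1/λ_min, 1/λ_max) with tolerance 1e-8. Standard
  errors come from the analytic asymptotic information matrix of
  (β, ρ, σ²). The LR statistic is 2(ℓ_lag − ℓ_OLS) on 1 df;
  AIC = −2ℓ + 2k with k = #β + 2 (ρ and σ²). A weights matrix with no
  links degenerates exactly to OLS with ρ = 0. OLS itself is delegated to
  statsmodels.

Calibration (recomputed by the suite and the acceptance script): at
n = 400, k = 8, ρ = 0.5, the mean ρ̂ over 100 seeded replicates is within
±0.05 of the truth, and at ρ = 0 the LR test rejects at the 0.05 level in
2–8 % of 200 replicates.

## Synthetic city

The generator emulates the layer inventory of a municipal study on a
square grid, with every draw taken from one seeded generator so identical
(config, seed) reproduce byte-identical GeoJSON.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| blocks_per_side, block_m | 20, 400 m | 8 km × 8 km city: a 30-min walk (2.4 km) covers only part of it, so mode differences are visible |
| population per DA | DiscreteUniform(400, 700) | the census definition of a dissemination area |
| DA geometry | one block each, jittered centroid | smallest census unit; centroid stays inside its polygon |
| road classes | every 5th line Major, rest Collector | arterial spacing typical of gridded cities |
| sidewalks | per-block rings inset 6 m, disconnected | reproduces the per-block digitization that makes crosswalk generation necessary; ring corners sit 8.5 m from intersections, inside the 18-m circle |
| bus corridors | interior rows every 8th line; stops every 400 m | sparse enough that far-from-corridor periphery stays transit-poor |
| train | one central line, stations every 800 m | a single rapid-transit spine |
| clinics | 30, placed at interior intersections with probability ∝ exp(−8·d/d_max); S_j ~ 1 + Poisson(2) | the core-vs-periphery facility gradient of real cities |
| covariates | six deprivation-index variables, centre-distance trend + SAR(ρ = 0.5) noise; proportions clipped to [0, 1] | gives the regression stage recoverable spatial signal; an optional collinear pair (|r| ≥ 0.9) exercises the screen |

This geometry was designed so the default city reproduces the qualitative
structure the method is meant to detect — shortage population strictly
ordered walking > multimodal > driving (on seed 42: 31.9 % > 8.2 % > 0 %);
the corridor spacing and clinic concentration were chosen during
generator design to realize that ordering and then frozen.

What the synthetic city does **not** emulate: irregular street topology,
rivers/parks/zero-population areas, one-way systems, transit schedules,
heterogeneous DA sizes, and realistic covariate marginals. Passing tests
therefore demonstrate correctness of the computations and the qualitative
mode structure, not calibration of any real city's access levels.

## Numerical conventions and degenerate inputs

- Node snapping ties break by smallest node id; quantile ties by location
  id; both make outputs order-independent and reproducible.
- Floating-point time comparisons use 1e-9 absolute slack (cutoffs and
  zone edges inclusive).
- CSV reports round to 6 significant digits for stable golden files; the
  JSON report keeps full precision. GeoJSON floats use shortest
  round-trip representation, so write→read is lossless.
- Degenerate cases: empty intersection layer → no crosswalks (not an
  error); facility with empty catchment → flagged, R_j = 0; no facilities
  at all → hard error at the SPAR stage; constant SPAR field (every DA in
  the same decay zone of every clinic, typical of very small test cities
  under driving) → Moran's I and the regression are undefined and raise.
- Geographic (degree) coordinates are detected per layer by bounding box
  and rejected with a reprojection hint.

## Problem sizes

The test suite runs the full pipeline on the 20×20-block city (400 DAs,
~6 500-edge walking network) and the lag-model calibration at n = 400
with 100 + 200 replicates; `scripts/acceptance.py` uses 50 + 100
replicates. These sizes were chosen as the smallest at which the
statistical assertions are stable.

## Known limitations

- Access/egress to the network is snapped, not timed; intra-DA
  heterogeneity is collapsed to one centroid.
- Bus travel times use static per-route speeds; an alternative convention
  (deriving speed from end-to-end trip time) exists in the literature and
  is not implemented.
- The stepwise decay is discontinuous at zone edges; locations straddling
  a boundary can differ sharply in access.
- The spatial-lag standard errors are asymptotic; no small-sample or
  heteroskedasticity-robust variants are provided.
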