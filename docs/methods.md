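# Methods

This note documents the models, conventions and design choices behind
`roadproxy`, in the order the pipeline runs them.

## Synthetic data generator

The generator emulates a rural/peri-urban personal-monitoring campaign
in a metric planar frame (no geodetic coordinates; real data are
expected to be projected, e.g. to the UTM zone of the study-area
centroid, before entering the pipeline).

**Landscape** (`generate_landscape`). Roads are edge-to-edge polylines
with mild interior jitter, classed `highway` / `main` / `other`; the
default study area is 10 × 10 km with 2 highways and 3 main roads.
Village centroids are drawn near roads with probability 0.7 (a random
point along a random road plus a lateral Normal(0, 350 m) offset) and
uniformly otherwise — settlements cluster along roads, and the mix
gives the road-density proxy genuine between-village variance.
Boundaries are irregular 12-gon stars with radius 200–400 m. Population
is a sum of per-village isotropic Gaussian bumps (total 500–3000 people
per village, σ = half the equivalent-circle radius) discretised to a
100 m raster, matching the resolution of gridded population products.
Buildings are 8–14 m rectangles scattered inside each boundary.
Identical seeds give bit-identical landscapes.

**Exposure model.** Outdoor concentration at point *p* is

    C(p) = [B + A·exp(−d_road(p)/L) + Σ_h A_h·exp(−d_h(p)/L_h)] · exp(ε)

with background B = 15 µg/m³, kerbside traffic increment A = 40 µg/m³,
decay length L = 250 m, optional hotspot terms, and multiplicative
lognormal noise ε ~ N(0, 0.3²); indoor readings are further multiplied
by an attenuation factor 0.6. `d_road` is the distance to the nearest
road segment of any class. The form and defaults are chosen so that
both a traffic-dominated regime (concentration falls with distance from
roads) and a hotspot-dominated regime (a strong non-traffic source such
as crop burning away from the road network) are reachable; they are not
fitted to any measured campaign. With noise off the model is exactly
reproducible from the logged positions, which the tests exploit as an
oracle.

**Mobility.** Each participant is assigned a home building by
round-robin over villages (participant *i* → village *i* mod
n_villages; `participant_villages` exposes the rule) and alternates
episodes with geometric lengths (means: 30 min indoor, 20 min outdoor).
Indoor positions jitter < 2 m inside the footprint; outdoor steps are
uniform 60–110 m/min (typical adult walking pace) in random directions,
reflected at the landscape boundary, biased homeward beyond a 1200 m
roam radius, and re-drawn if they would land inside a footprint — so
building containment is exactly equivalent to the indoor truth label.
RH and temperature are diurnal sinusoids plus noise; they are carried in
the trace schema but unused downstream.

What the generator does **not** emulate: GPS positional error,
meteorology-driven dispersion, traffic-volume variation, realistic
activity schedules, or the marginal distributions of any real campaign.
Passing tests therefore demonstrate the correctness and statistical
behaviour of the pipeline under a known data-generating process, not
field performance on real traces.

`sample_village_exposure` provides village-level PM2.5 directly by
evaluating the (noisy, outdoor) exposure model at points sampled inside
each village boundary — the village-aggregation analogue of filtering
and averaging full traces, used where minute-level simulation would add
cost but no information (correlation and model studies at 60 villages).

## Indoor/outdoor classification

Speeds are per-minute displacements (first reading carries back the
second's speed; speed is missing across gaps > 5 min — the gap cutoff
avoids spurious low speeds across recording breaks). The speed rule
labels a reading outdoor at speed ≥ 100 m/min, boundary inclusive;
missing speeds are conservatively not-outdoor. Note 100 m/min is
1.667 m/s, though it is often glossed as ≈1.5 m/s; the canonical
parameter here is 100 m/min and it is configurable.

Building validation labels a reading indoor iff it lies inside or on
the boundary of any footprint. A **coverage region** distinguishes "no
building here" from "no building data here": outside coverage the
building label is `uncovered` and the speed label decides (not-outdoor
falling back to indoor). Within coverage the building label is treated
as ground truth: all covered readings are re-labelled from it, and the
confusion matrix of speed vs building labels (positive class outdoor)
is reported before correction. Invalid footprint polygons are repaired
with a validity-restoring rebuild and rejected, by index, if
unrepairable.

## Proxies

Fishnet cells are exactly the population-raster cells, so alignment is
by construction. A cell belongs to a village iff its intersection with
the boundary has positive area (edge-touching cells are excluded). Road
length per cell is computed on the boundary-clipped network, so edge
cells contribute only in-boundary length; per-cell density uses the
full cell area (cell_size/1000)². Cell population is the full raster
count (no area weighting of partial edge cells). WRND is the
population-weighted mean density; when a village's total population is
zero the unweighted mean is returned with an explicit flag, since the
weighted form is undefined there. EM/EH use exact point-to-polyline
distance with interior projection; a missing road class yields NaN plus
a flag rather than an error, because real study regions may simply lack
highways. Zero-length segments are dropped with a warning.

## Hexagonal tessellation

"5 km" hexagons are interpreted as flat-to-flat width, flat-top
orientation (both configurable; edge-length and spacing readings of the
figure are equally defensible). Villages join the hexagon containing
their centroid, boundary ties resolved to the lowest hexagon id;
aggregation is the arithmetic mean; empty hexagons are omitted. Display
classes: WRND fixed breakpoints 10 and 20 km/km²; EM fixed breakpoints
2 and 4 km (the published caption's "0–2, 2–4, >3" overlaps and is read
as a typo for >4); EH has no published scheme, so data-driven terciles
are used; PM2.5 uses quintile indices standing in for a sequential
colour gradient. All intervals are left-closed, right-open, last class
closed above; constant distributions collapse to class 1. Rendering is
out of scope — the package emits class codes.

## Spearman correlation

rho is the Pearson correlation of mid-ranks (ties averaged). Two-sided
p-values use the t approximation t = rho·√((n−2)/(1−rho²)) for n ≥ 10
and the exact permutation distribution of rho for n < 10; constant
inputs return rho = 0, p = 1 with a flag. The unit of analysis is the
village (one PM2.5 mean paired with its proxies); pairs with missing
values are dropped case-wise, and strata with fewer than 3 complete
pairs are flagged undefined rather than erroring. No multiple-testing
correction is applied; significance stars at 0.05/0.01/0.001.

## Random-forest land-use regression

Per stratum and pooled, four models are fitted: WRND-only, EM-only,
EH-only, Combined. Forests use 50 trees, mtry = max(1, ⌊√p⌋) features
per split (p = 3 → 1), bootstrap sampling, unlimited depth, mean
aggregation (scikit-learn's regressor behind the module surface).
Observations are shuffled with the run seed into 3 near-equal folds;
metrics (R², RMSE, MAE, MBE) are computed on the pooled out-of-fold
predictions — a single pooled estimate is less noisy at village-scale n
than averaging per-fold metrics, which are nevertheless retained.
Feature importances (mean impurity decrease, averaged over trees and
folds, normalised to 1) are reported for combined models only. The
observation unit is the village mean by default; a per-reading mode
(each outdoor reading inheriting its village's proxies) is available in
the pipeline config. Bias profiles bin observations by observed PM2.5
(default 20 µg/m³ bins from 0) and report per-bin mean/median bias with
a seeded nonparametric bootstrap 95% CI of the mean (1000 resamples);
bins with fewer than 3 observations are flagged.

## Pipeline and reproducibility

`run_pipeline` executes generate/load → classify → proxies → hexagons →
correlations → models → report from one validated YAML-able config,
writing CSV/GeoJSON/JSON outputs plus a manifest of per-stage counts
and timings. All randomness flows from the single config seed, and
re-running a config reproduces byte-identical tables. A
`use_building_validation` switch lets the speed rule alone decide the
outdoor filter (useful where footprints are unavailable); with building
validation on and full coverage, the building labels dominate and the
filter recovers the generator's truth labels essentially exactly.

## Problem sizes in the shipped studies

The test-suite and acceptance studies run at deliberately modest
scales: classification recovery uses 5 participants × 600 min over 20
seeds; the correlation-regime and model studies use 60 villages per
seed (a single-highway 20 × 20 km corridor landscape for the regime
study, sampled at 15 points per village) with 20-seed sweeps; oracle
comparisons use 100 random fixtures. These sizes give stable Monte
Carlo behaviour for the properties being checked while keeping a full
run inexpensive.

## Known limitations

- No geodetic handling: all inputs must already share a metric planar
  frame; reprojection is the caller's responsibility.
- The population raster is text-based (ESRI ASCII grid); very large
  rasters would warrant a binary format and windowed reads.
- Hexagon assignment is point-in-polygon per village (fine at hundreds
  of villages; a spatial index would be needed at much larger scale).
- The exact-permutation Spearman branch enumerates n! permutations and
  is intentionally capped at n < 10.
- Speed-only classification degrades when walking speeds straddle the
  threshold, as the shipped confusion matrices show; the building
  reconciliation is what makes the outdoor filter reliable.
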