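# Methods

This note documents the models, the numerical choices, and what the
synthetic-data tests do and do not establish about real collar data.

## Projection

Tracks are projected from WGS84 geographic coordinates to UTM
(default zone 36N, configurable) with a transverse Mercator implemented
from the Krueger series in conformal-latitude form, carried to sixth
order in the third flattening. Within a zone this agrees with the
defining equations to well below a millimetre; the test suite checks
forward/inverse round trips to 1e−6° and planar distances against a
numeric meridian-arc integral. Inter-fix distances change by <0.1%
between adjacent zone choices for tracks spanning a few kilometres, so
the zone is a convention, not a tuning parameter. Timestamps without an
explicit zone are interpreted as East Africa Time (UTC+3, configurable).

## Cleaning

Two rules, both exposed in `CleaningParams`:

- **Speed filter (20 km/h).** The average speed of each step is the
  planar distance over the elapsed time. While any step exceeds the
  threshold, the *later* fix of the first offending step is removed and
  speeds recomputed. Treating the jump as the error is the deterministic
  reading of "exclude fixes above the threshold"; the procedure
  terminates (every pass removes a fix) and is idempotent. Zero-duration
  steps are flagged invalid rather than infinite; they cannot occur
  after ingestion, which collapses duplicate timestamps to the first
  occurrence.
- **Short recordings (24 h).** "Hours of data" is read as the elapsed
  span between first and last fix — the simplest reading, consistent
  with reporting recording *periods*. The rule is strictly `< 24 h`:
  a 24.0 h span is kept.

No DOP/horizontal-error filtering is attempted; collar exports carry no
such fields here, and speed screening is the method being reproduced.

## Movement metrics

- **Distance** is the sum of planar step lengths of the cleaned track;
  daily distance is `total × 24 / recording_hours`, robust to partial
  first/last days (a per-calendar-day variant exists for sensitivity
  analysis). Summing raw steps is upward-biased by GPS noise by
  ≈ 2σ²/L per step of length L with per-axis noise σ; at σ ≈ 2.5 m and
  typical minute-steps of 10–60 m this amounts to 1–3% — worth
  remembering when comparing absolute distances between devices.
- **Household occupancy** uses last-observation-carried-forward time
  attribution: each inter-fix interval belongs to the location of its
  earlier fix. Under motion-triggered logging a gap means the dog
  stopped at the last seen location, so LOCF is the faithful choice and
  gaps are deliberately not capped (a cap is available for sensitivity
  analysis). A fix-count-weighted variant is provided; time weighting is
  the default. The household area is a 20 m-radius disc around the
  recorded household point.

## Biased-random-bridge utilization distribution

The UD is built on a raster (default 10 m cells) covering the track's
bounding box plus a 200 m pad. For each step with duration T ≤ T_max
and length ≥ L_min, Gaussian mass is deposited at `n_substeps` (default
10) midpoints p of the straight segment with isotropic variance
σ²(p) = h_min² + 4 D T p (1 − p) and weight T/n_substeps. The variance
law is Brownian-bridge scaling — the animal is known to be at the fixes,
uncertainty is maximal mid-step — floored by h_min for GPS error. Steps
with T > T_max are un-bridgeable gaps (rest under motion-triggered
logging) and deposit T/2 at each endpoint with variance h_min²; steps
shorter than L_min are treated the same (no real movement to
interpolate). Total mass is normalised to 1.

Parameter defaults, all recorded in the output metadata:

| parameter | default | rationale |
|---|---|---|
| D | plug-in estimate | mean of L²/(4T) over qualifying steps |
| h_min | 25 m | GPS error scale of consumer collars |
| T_max | 3 × median fix interval | longer gaps are rest, not movement |
| L_min | 5 m | below GPS noise: not movement |
| cell | 10 m | ≤ h_min/2: discretisation error ≪ smoothing |
| pad | 200 m | > 8 kernel sd beyond the data |

The plug-in D is exact for pure diffusion, biased for drift-dominated
or mean-reverting motion (mean reversion shrinks, commuting inflates
it); a factor-2 agreement is all the tests claim, and D can be fixed
explicitly. Kernels are evaluated exactly at cell centres within 9σ (the
discarded tail is below 1e−17 of a deposit, keeping the grid equal to an
untruncated brute-force summation to 1e−10); cell probability is density
× cell area, adequate for cells no larger than about half of h_min.

**Isopleths** follow the standard volume-contour rule: cells ranked by
mass descending (row-major tie-break for determinism), the smallest
prefix reaching the level's cumulative mass is selected; level 100
means the whole grid. Nesting of levels is structural (a larger prefix
contains a smaller one). Selected cells are merged into polygons by
4-connectivity — diagonal contact does not merge, which is conservative
for centroid counts — and the area is the cell count × cell area
(hectares; 1 ha = 10⁴ m²). For an isotropic Gaussian UD the selected
area at level p is 2πσ² ln(1/(1−p)); the suite checks the 95%/50% ratio
ln 20 / ln 2 ≈ 4.32 to 5% at cell = h_min/5, and that halving the cell
changes smooth-UD areas by <5%.

**Centroids** are the unweighted arithmetic mean of member-cell centres,
one per polygon (not a mass-weighted or geometric centroid — the
convention matches how the ground-truthing field protocol defined them),
reported in both planar and geographic coordinates. The 95% level is an
analysis product only; centroid inventories cover 10/50/90%.

## Mixed models

Outcomes are transformed before modelling (√ for core HR, log for
extended HR; the other two untransformed), after a collinearity screen
that flags outcome pairs with |Pearson r| ≥ 0.7. Models are linear with
a random intercept per site, fit by REML through statsmodels `MixedLM`.
Categorical terms are tested jointly by Wald tests across their levels;
fixed terms without variation are dropped with a warning (the same
lack-of-variation rule used in covariate screening); a single-site
table falls back to OLS. Variance components at the boundary
(σ²_b → 0) are reported as zero, in which case the fixed effects
coincide with OLS. ICC = σ²_b/(σ²_b + σ²_w). Significance is declared
at p ≤ 0.1 — a deliberate small-sample convention to limit type-II
error — and no multiple-testing correction is applied. Influence
diagnostics are leave-one-site-out refits (coefficient sign stability)
plus standardized-residual flags at |z| > 3.

Calibration at the study's design size (73 dogs, 8 sites): over 200
replicates the mean recovered coefficient at a true β = 3 is within
10% (measured bias ≈ 0.03%), the mean recovered ICC at a true 0.2 is
within 0.08 (measured +0.014), and 95% Wald intervals cover a null
effect in ≥90 of 100 replicates (measured 94).

## Synthetic trajectory generator

The generator emulates the deployment context: a collar recording once
per minute *only while the dog moves*, worn ~5 days by a home-anchored
dog. It is a two-state process switching by exponential clocks:

- **rest** (mean 1400 s): stationary wherever the dog stopped;
- **travel** (mean 700 s): a speed-clipped Ornstein–Uhlenbeck pull
  toward a target — the household (weight 3) or an attraction site
  (weight 1 each) — with drift `min(β·d, v_cruise)` (β = 0.01 s⁻¹,
  v_cruise = 2 m/s) plus diffusion D = 0.4 m²/s. Far from the target
  this is a steady trot; near it, OU jitter around the site. An
  infinite β pins the dog to its target.

A raw OU drift was rejected because its speed grows linearly with
distance (a dog 1 km from home would "travel" at 36 km/h); the clip
keeps OU behaviour near sites and realistic cruise speeds between them.
The rest/travel bout means are tuning choices (no quantitative bout
data exist for this system), set so that the *consequences* match the
deployment: a median near 20 recorded fixes/hour, daily distances of
order 12–15 km, and roughly a third to a half of time within 20 m of
the household. Fixes are emitted on the minute grid when the
displacement over the preceding minute exceeds the motion gate
(0.05 m/s), then perturbed by isotropic Gaussian GPS noise (default
σ = 2.5 m); spurious jumps can be injected at a configurable rate.

Ground truth comes from the dense noise-free path (5 s resolution):
time fractions within 20 m of the household and of each site, and the
path length *sampled at the nominal fix interval*. The latter choice
matters: a diffusive path has no resolution-free length, so truth and
fix-based estimates are compared at matched temporal resolution.
Recovery tests run at σ = 1.5 m GPS noise, where the step-inflation
bias derived above is ≪1%; at the default 2.5 m the per-dog distance
error reaches ~2.5%, which is a property of raw step-summing, not of
the simulator.

The cohort generator lays out 8 sites of 8–10 dogs (73 total, matching
the analysed study layout), each site with three communal attraction
sites shared by its dogs (so cross-dog overlap flags are meaningful),
households scattered ~300 m around the site centre, log-normal per-dog
variation in speed, diffusion and bout lengths, deployment lengths
drawn from 25–152 h (86% ≥ 96 h), and metadata categories drawn with
the study cohort's frequencies. `simulate_analysis_table` generates
covariate tables with a known site random effect directly, for
mixed-model calibration.

**What passing tests do not show.** The generator has no diel cycle, no
social interaction, no habitat structure, no satellite-visibility
dropouts, and its categorical covariates are independent of behaviour
(null effects by construction). Truth-recovery results therefore
validate the *estimators* under the stated movement model, not the
field accuracy of any particular collar; and cohort medians from the
generator are indicative of scale, not reproductions of field values —
in particular the core-HR scale is bounded below by the h_min smoothing
floor (a single point of mass already occupies ~0.27 ha at the 50%
level with h_min = 25 m).

## Problem sizes

Default test and reproduction runs use 5-day deployments at 5 s
simulation steps, 10 m UD cells, cohorts of 73 dogs, and 200-replicate
calibration loops; these sizes keep a full reproduction run to a couple
of minutes on one CPU while leaving every estimator in its intended
regime.

## Known limitations

- The speed filter drops the later fix of an over-speed pair; if the
  *earlier* fix were the outlier, one good fix is lost (the next pass
  recovers the geometry, at the cost of one fix).
- Bridged mass is laid along straight segments; true paths curve, so
  the UD slightly understates off-segment use at long fix intervals.
- The plug-in diffusion estimate conflates drift with diffusion;
  studies needing an unbiased D should fix it from external knowledge.
- Isopleth areas are cell-count areas; at the default 10 m cell the
  discretisation of a core-HR-sized region is ~1–3%.
- REML variance components from 8 clusters are noisy; ICC values carry
  wide implicit intervals at this design size.
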