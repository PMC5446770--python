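# Methods

This note documents the models, conventions and design choices behind
`relicttrack`, in the order the pipeline runs them.

## Coordinates, distances and dates

Coordinates are decimal-degree WGS84, longitude east-positive; no
projection is applied outside the home-range stage.  Distances are
haversine great circles on a sphere of radius 6371.0 km (sub-0.5%
error at the ≤ 1000 km scales involved).  Timestamps are UTC; no
timezone inference is attempted.

All date statistics use a **non-leap day-of-year** coding: every year
is treated as 365 days and Feb 29 collapses onto day 59.  Cross-year
durations (e.g. wintering residence) are `(365 − doy_start) +
doy_end`.  This coding is what makes the reference journey table
reproduce its published F statistics exactly; with true calendar
arithmetic the leap years 2008 and 2012 shift several values by one
day and the F values drift.  Because all journeys of one season fall
inside a three-month window, linear (non-circular) means of
day-of-year values are safe.

## Plausibility filter

The filter re-implements the distance / movement-rate / turning-angle
logic of classic Argos track filters at the contract level; exact
parity with any particular released tool is a non-goal, and every
threshold is exposed in `FilterConfig`.

Rules, evaluated iteratively until a fixpoint (≤ `max_iterations`):

1. LC Z fixes are always removed; fixes at or above
   `keep_lc_at_or_above` (default LC 1) are always kept.
2. An auxiliary fix within `redundant_dist_km` (3 km) of a surviving
   temporal neighbour is kept (near-duplicate consistency).
3. Otherwise it is removed if the implied speed to **both** surviving
   neighbours exceeds `max_sustained_rate_kmh` (90 km/h — observed
   sustained flight in this system is ~30–45 km/h, so genuine flight
   is never flagged), or if it forms an out-and-back spike: internal
   angle < `spike_angle_deg` (15°) with both legs longer than
   `spike_dist_km` (50 km).
4. When two adjacent fixes mutually imply an excess rate, the one with
   the worse location class is removed (the later one on ties).

The spike-leg scale is deliberately separate from the redundancy
scale: auxiliary-class positional error reaches tens of km (LC B RMS
~6 km, tails beyond 15 km), and an error-sized wobble flanked by two
accurate fixes is geometrically a miniature spike.  Tying the angle
test to a 50-km leg scale restricts it to gross excursions — which sit
≥ 100 km off path and, unlike rate violations, remain detectable when
they bracket a long transmitter-off gap (implied speeds across a 15-h
gap can look sustainable).  With the default configuration on
simulated data the filter removes ~99% of injected outliers while
losing ~0.01% of genuine fixes.

## Stopovers and journeys

A stopover operationalises "moved less than 20 km during at least
24 h": a greedy left-to-right window grows while every member fix lies
within `radius_km` (20 km) of the running centroid (arithmetic mean of
member coordinates — robust to slow within-site drift, unlike a
first-fix anchor).  Windows spanning ≥ `min_hours` (24 h) with ≥ 2
fixes emit a stopover (a single fix cannot demonstrate residence).
Consecutive stopovers are merged when their centroids are within the
radius, the gap is ≤ 24 h, **and** the merged cluster still satisfies
the radius invariant; merged stopovers track their member fix ranges
explicitly, so a stray fix between merged clusters is not a member.
The radius/duration invariants are re-checked on output in the test
suite.

Departure and arrival events use the median-date rule: the calendar
date of the midpoint instant between the last fix at the previous
location and the first fix at the new one.  A midpoint falling exactly
at midnight takes the earlier date.  Events bridging a gap of more
than ten days are left undated.  Under an 8 h on / 15 h off duty cycle
the maximum bracketing gap is ~16 h, so the rule recovers event dates
to within a day (mean absolute error ~0.1 d on simulation).

Journeys are delineated between residence regions: the breeding colony
is a 20-km disc around the published capture site (39.138° N,
109.870° E) and the wintering areas are the supplied coastal polygons
(no explicit departure/arrival geometry is published, so the geometry
is configuration).  Region occupancy must persist ≥ 24 h to count as
residence, which suppresses duty-cycle flicker at boundaries.
Stopovers strictly between the departure and arrival events belong to
the journey; segment lengths are great-circle distances origin →
stopover centroids → destination, rounded to the nearest 10 km for
comparability with the reference table (which prints multiples of 10).

Route metrics report |Δlon| and |Δlat| between the journey endpoints
and the latitude at which 114° E (the route midline) is first crossed,
linearly interpolated between the bracketing fixes.  The published
"inverted-V versus direct route" dichotomy has no stated threshold, so
route-type labelling is left to the user (the latitude at 114° E is
the natural discriminant).

## Dispersal

Winter dispersal is a change of occupied named region persisting
≥ 24 h, dated by the median-date rule on the bracketing fixes.
Pre-breeding dispersal is an excursion after spring arrival whose
maximum displacement from the colony reaches `min_km` (default 100 km,
the minimum of the observed excursion range) and lasts ≥ 24 h; its
duration runs from the last fix inside the colony disc to the first
fix back inside (open-ended if the bird never returns).  Wintering
residence is the non-leap day count from autumn arrival to the next
spring departure.  Note one known coding ambiguity: the maximum
residence computed from the reference table is 256 d where 255 d was
printed; only the minimum (206) and mean (234) are used as checks.

## Fixed-kernel home range

Pooled locations are projected with a Lambert azimuthal equal-area
projection about their centroid (areas preserved to first order, so
grid cells are km² on the ground).  The estimator is the classic
fixed bivariate Gaussian kernel of home-range practice: coordinates
are standardized by their marginal SDs, a single scalar bandwidth `h`
is chosen on the standardized points, and the per-axis bandwidths
`h·σx, h·σy` are used on the original scale.

Bandwidth selection minimises the least-squares cross-validation score
`CV(h) = ∫ f̂² − (2/n) Σᵢ f̂₋ᵢ(xᵢ)`, computed in closed form from
pairwise squared distances (the Gaussian convolution identities; the
closed form agrees with brute-force numeric integration to ~1e-11).
The search evaluates 50 log-spaced candidates in `[h_ref/10, 2·h_ref]`
around the bivariate-normal reference bandwidth `h_ref = n^(−1/6)`
(standardized scale) and refines the best bracket by bounded
golden-section search.  If the score is monotone over the bracket —
common for large, tightly clustered telemetry samples, a
well-documented failure mode of LSCV — the reference bandwidth is
returned with `converged=False` and a warning.

The UD is the equal-weight Gaussian mixture on a regular grid (default
cell `h/4`, margin `3h`, both exposed), normalized to integrate to
exactly 1 (checked to 1e-6 on every run).  Isopleths are
percent-volume contours: cells ranked by density, smallest prefix
reaching the target mass, area = cell count × cell area.  On 2000
points from a standard bivariate normal the 50% isopleth area lands
within ~10% of the analytic highest-density region `2π ln 2`; the
residual excess is the known kernel-smoothing inflation (a factor
≈ 1 + h² for the normal), not an implementation artefact.

The published 1,380 km² winter core range cannot be recomputed because
the raw winter coordinates are unpublished; the stack is validated
analytically instead, and produces core areas of the same magnitude on
synthetic wintering data.

## Phenology statistics

One-way ANOVA uses the standard decomposition (groups = individuals;
singleton groups permitted); p-values come from the F distribution.
Repeatability is the Lessells–Boag intraclass correlation from the
ANOVA mean squares with effective group size
`n₀ = (N − Σnᵢ²/N)/(a−1)`; `r` may be negative and is returned
unclamped.  Two-sample comparisons use the **pooled-variance** Student
t-test — stated explicitly because pooled (not Welch) is what
reproduces the reference t values (16.13, 4.136).  Paired comparisons
of autumn versus spring distance use per-individual means across
repeated seasons.  p-values are formatted to three decimals with
"<0.001" below that, for display only.

Two reference values are reported but not asserted against print,
because no simple data coding recovers them exactly: the
nine-individual winter-arrival F (computed 11.56 vs printed 11.76) and
the repeatability coefficients (computed 0.83/0.80 vs printed
0.80/0.76 — the source's exact n₀ or software convention is unknown;
the corresponding F values, which *are* exactly recovered, serve as
the acceptance surface).  The paired distance t computes to 1.20
against a printed 1.08 under every coding tried; it is reported only.

## Synthetic annual cycles

The generator emulates the tracked system so each pipeline stage can
be scored against ground truth.  Defaults are the study conditions:

| parameter | default | basis |
|---|---|---|
| colony | 39.138° N, 109.870° E | published capture site |
| wintering sites | Bohai coast (39.05, 118.30); Laizhou (37.30, 119.00) | published bays |
| autumn departure | DOY ~ N(212, 8) | ≈ 31 Jul mean, mid-Jul–Sep spread |
| spring departure | DOY ~ N(95, 3) | ≈ 5 Apr, range Mar 31–Apr 10 |
| stopovers (autumn) | P(0..5) = .30,.25,.30,.10,0,.05 | empirical counts, mean 1.4 |
| stopover duration | 1.5 d + Gamma(1.3, 5.0), cap 20 d | accumulated-days table, mean ≈ 8 d |
| flight speed | 40 km/h | observed > 30 km/h sustained |
| duty cycle | 8 h on / 15 h off | the 2008 deployment schedule |
| LC mix | 41% LC 1–3 | reported high-quality share |
| LC error (RMS, m) | 150/250/600/1200 for 3/2/1/0; 3000/6000 for A/B | nominal 1-σ radii; A/B extrapolated (no published accuracy) |
| outliers | 2% of fixes, displaced U(100, 1000) km | auxiliary classes only |
| winter dispersal | p = 12/13, ~28 Dec out, ~13 Mar back (p = .75) | published dispersal dates |
| pre-breeding excursion | p = 9/13, N(204, 146) km clipped to [100, 540], away 17 ± 6 d | published excursion summaries |

Within-site movement is a stationary Ornstein–Uhlenbeck walk (SD =
`residence_radius_km`/2 per axis, relaxation 12 h): positions an hour
apart are strongly correlated, as in real telemetry.  Flights are
great-circle (spherical linear) interpolation through stopover
waypoints; autumn routes arch north through the plateau-lake belt
("inverted V", p = 13/20) or run direct.  Position error is isotropic
Gaussian with per-axis SD σ/√2 so that the RMS planar displacement
equals the configured class σ (verified to 10% over ≥ 10⁴ fixes).
Outliers are drawn only among auxiliary classes: standard-class error
is bounded by construction, and Douglas-style filtering targets
auxiliary locations.  Sampling occurs at 1-h intervals inside duty-on
windows with a random phase.  A single `numpy` Generator keyed by the
config seed drives everything, so identical configs are bitwise
reproducible.

What the simulator does **not** model: satellite-pass geometry and the
resulting anisotropic, heavy-tailed Argos error; weather-driven route
and timing covariance; foraging commutes structured by the tidal
cycle; transmitter failure and data dropouts.  Passing recovery tests
therefore show that the algorithms are correct under duty-cycled
sampling with class-dependent isotropic noise — not that they are
robust to every pathology of real Argos data.

## Problem sizes

The recovery study in the test suite uses 100 simulated annual tracks
(~2,500 fixes each) at the 8/15 duty cycle; the acceptance script runs
the same study at 30 tracks and reports the size alongside each
number.  The home-range validation uses 2,000 points (and n = 50 for
the LSCV closed-form cross-check).  These sizes give Monte-Carlo
standard errors well inside the tolerances they are checked against.

## Known limitations

* The filter is a contract-level re-implementation; it will not match
  any specific released Argos filter fix-for-fix.
* Journey delineation assumes the supplied residence geometry; birds
  summering or wintering outside the configured regions yield no
  journeys (logged, not an error).
* LSCV instability on large clustered samples is handled by the
  reference-bandwidth fallback rather than by alternative selectors
  (plug-in, biased CV), which are out of scope.
* The statistics layer implements the ANOVA/ICC framework only — no
  mixed-effects or Bayesian repeatability.
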