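# Methods

This note documents the models, algorithms, numerical choices and known
limitations behind the package, in the order data flow through the
pipeline.

## Preprocessing

Raw fixes carry a timestamp (UTC), projected planar coordinates (meters),
elevation (m) and the device-reported estimated horizontal position error
(EHPE, raw device units). Four removal rules are applied per cat:

1. elevation outside the closed interval [0, 300] m (boundary values are
   retained — "outside the range" is read strictly);
2. fixes from the first 2 calendar days of deployment (collar-habituation
   and handling artefacts);
3. fixes from days on which the unit was retrieved for data download;
4. fixes with EHPE ≥ 5000. EHPE units are passed through numerically;
   the cutoff's physical meaning depends on the device firmware and no
   unit conversion is assumed.

Rules 1, 3 and 4 are row-local, hence idempotent and order-independent;
rule 2 depends only on the deployment start date, which no other rule
alters, so the whole chain commutes. Calendar days are computed in a
configurable local time zone expressed as a fixed UTC offset
(`tz_offset_hours`, default +2, the study region's May offset): day
boundaries move the first-days and download-day cuts, so the offset is an
explicit, serialised parameter rather than an assumption. Exact duplicate
(cat, timestamp) rows collapse to the first occurrence, preserving the
strict time-ordering invariant against device re-logging.

Thinning is a greedy scan: keep the first fix, then every fix at least
`min_interval` (default 120 s) after the last kept one. The output never
contains a sub-threshold interval and re-thinning is a no-op.

**Daily outdoor coverage.** How "hours tracked outdoors per day" should be
computed from fixes is genuinely open; the package sums consecutive
same-day inter-fix gaps capped at 30 min (`gap_cap`). The cap prevents a
stray pair of fixes hours apart from claiming the whole gap as coverage;
at the nominal 30-s interval the sum is essentially the true switched-on
duration. Days with a single fix count as days with data at 0 h. The
per-cat aggregation weight is w = mean over days-with-data of
(outdoor hours)/24, in [0, 1].

## Indoor-cluster excision

Units left powered on indoors log long stationary bouts. These are
detected as sequential position clusters with a single time-ordered scan:
a cluster opens when a fix falls within `radius` (default 10 m, the scale
of the reported GPS error) of an earlier unclustered fix within `window`
(default 24 h); members must lie within `radius` of the running centroid
(recomputed after each addition) and within `window` of the last member;
clusters close after `window` of silence; clusters smaller than
`min_points` (default 2) are dropped; no fix joins two clusters. When a
fix could join several open clusters the most recently active one wins —
the natural reading of a stationary bout — and when several earlier fixes
could seed a cluster the most recent partner is chosen. The defaults are
set so stationary indoor bouts cluster while single transit fixes do not;
all three are configurable.

A cluster whose centroid lies inside *or on the boundary of* the owner's
residence footprint is treated as indoor and all its member fixes are
removed. The resulting time gap is left as a genuine gap: nothing is
interpolated across an excised bout, and the bridge max-lag rule (below)
prevents the movement model from bridging it.

## Brownian bridge movement model

Conditional on consecutive fixes z_i, z_{i+1} separated by T seconds, the
position at fraction a of the gap is bivariate normal with mean
z_i + a (z_{i+1} - z_i) and per-axis variance

    s2(a) = T a (1-a) sigma_m^2 + (1-a)^2 delta^2 + a^2 delta^2,

with sigma_m^2 the Brownian motion variance (m^2/s internally; reported
also per minute) and delta the isotropic GPS error SD. The UD is the
Delta-t-weighted average of bridge densities over all pairs with gap at
most `max_lag` (default 60 min, so bridges never span excised indoor
bouts or overnight gaps), discretised by the midpoint rule with `n_alpha`
(default 50) nodes. Density is evaluated on a separable local window
truncated at 8 SD (truncation error < 1e-9 per cell), multiplied by cell
area and renormalised to sum to exactly 1. The 50-node default tracks the
exact alpha-integral to ~1e-5 per cell on a representative bridge and
converges as n_alpha grows (verified against adaptive quadrature); raise
`n_alpha` when per-cell accuracy beyond that matters.

**Motion-variance estimation.** Every other interior fix is withheld and
scored against the bridge implied by its two observed neighbours
(leave-one-out on alternating fixes; triplets whose legs exceed `max_lag`
are skipped). A withheld *observation* differs from the latent mid-bridge
position by its own measurement error, so the default likelihood variance
is

    T a (1-a) sigma_m^2 + ((1-a)^2 + a^2 + 1) delta^2,

i.e. the bridge variance plus the withheld fix's delta^2. The classical
bridge-literature formulation omits that last term; with delta^2
comparable to the bridge variance (2-min fixes, 5-m error) the omission
inflates sigma_m^2 estimates by roughly delta^2 / (T a (1-a)) — about
+100% at those settings — because the estimator absorbs the unmodelled
error. `error_model="classic"` reproduces the classical formula exactly
for comparison with the original implementations; the default
`error_model="full"` recovers simulated truth with a median relative
error of a few percent. Optimisation is 1-D bounded scalar minimisation
of the negative log-likelihood on [0, sigma2_max] with
sigma2_max = (largest observed squared displacement)/(smallest fix
interval) — a deliberately generous bracket — at absolute tolerance 1e-8,
with the boundary value 0 snapped when it is as good as the interior
optimum (all-stationary tracks return exactly 0).

**Grids and rasters.** All cats share one global grid (cell size 10 m by
default, of the order of the device error): the bounding box of all
outdoor fixes buffered by three times the 95% radius of a `max_lag`
bridge at the largest fitted variance, capped at 500 m. A shared grid
makes the aggregation's "resample to align" step an exact identity;
the conservative area-weighted resampler remains available for rasters
from other sources. Rasters store probability mass per cell, row 0
northernmost; on disk they are ESRI ASCII grids (plain text, exact
round-trip at float precision).

**Volume contours.** Cells are ranked by mass and the smallest prefix
reaching the level is selected, ties at the cut included in full; the
area is cell count x cell area, and the polygon is the union of the
selected cell squares (row-wise run-length merged before union). On a
discretised isotropic Gaussian the 95% area matches the closed form
2 pi sigma^2 ln 20 to well under 1%.

## Population aggregation

Three steps: (1) align UDs on the template grid (identity here, by
construction); (2) multiply each UD by its cat's outdoor weight w; (3)
sum cell-wise. The total is deliberately left at Sigma w_i rather than
renormalised to 1 so that surfaces are comparable between populations and
time slices in magnitude as well as shape. Aggregation is linear,
order-invariant, homogeneous of degree 1 in the weights, and monotone in
population membership; total mass is conserved to 1e-6 at any grid
resolution.

Summary statistics and their conventions:

* **Intensity fold range** — max/min over positive cells inside the 99%
  volume contour of the normalised surface; a flat surface gives 1.
* **Near-home intensity ratio** — mean cell intensity within 50 m of any
  home over mean cell intensity at 50-100 m of the nearest home. Means
  (not totals) are compared because the zones have different areas;
  distances are cell-center to nearest home. Distances are to the
  *nearest* home of any cat, one defensible reading of "a cat owner's
  home" when homes are interleaved.
* **Distance statistics** — mean/max Euclidean fix-to-home distance and
  the fraction of fixes within 50 m. Fixes stand in for time: at a
  near-constant fix interval they sample tracked time uniformly, and no
  additional time-weighting is applied.
* **Land-cover partition** — cells are classed by cell-center
  point-in-polygon against the "developed" classes (boundary counts as
  developed); this is a deterministic +-1-cell-edge approximation to
  area-weighted overlay. Reported are the fraction of 99%-contour cells
  outside developed land and those cells' share of total intensity.

`run_pipeline` wires everything together, excludes cats with fewer than
`min_tracking_days` (default 5) days of outdoor data or too few fixes to
fit (every exclusion is logged with its reason), and serialises the full
configuration — every default included — into `manifest.yaml`. The
pipeline contains no randomness: identical inputs give byte-identical
summary CSVs and rasters.

## Synthetic populations

The generator emulates a month-long neighbourhood campaign: 28 study days
of 30-s fixes, homes on a jittered grid (spacing 120 m, square 10-m
footprints) inside a rectangular urban polygon surrounded by "other"
cover, ~18% of households with two cats. Outdoor excursions (one per day,
4-12 h, within 06:00-22:00 local) follow an Ornstein-Uhlenbeck walk
anchored at the home with per-cat sigma_m^2 drawn from 5-30 m^2/min and
reversion rate 0.005/min — stationary SD around 40 m, i.e. few-hectare
home ranges with most time spent within tens of meters of home, the
regime reported for suburban pet cats. Observation error is isotropic
Gaussian (SD 5 m). The generator plants everything preprocessing must
handle: fixes on the first two days and on a mid-study download day,
EHPE outliers (rate 0.02, values >= 5000), elevation outliers (rate
0.005, values outside [0, 300]), whole missing days (probability 0.1),
and indoor bouts (30-120 min, probability 0.3 per day) logged as 1-m
jitter inside the footprint. Ground truth (per-cat variance, scheduled
outdoor hours, fraction of true positions within 50 m, indoor fix
indices, and the analytic stationary intensity surface) is returned
alongside the data.

Randomness is split with `SeedSequence([seed, cat_index])` per cat and a
separate stream per household, so adding a cat never perturbs existing
cats' data and every output is byte-reproducible under a fixed seed.

Mean reversion makes the movement model deliberately misspecified for the
bridge estimator — real cats are not Brownian either — but at the default
(weak) reversion the process is locally Brownian over a 4-min triplet and
estimates land within ~10% of truth. A `pure_brownian` switch, and the
`simulate_brownian_track` helper, generate exactly the assumed model for
clean parameter-recovery tests. Two deterministic fixtures
(`make_filter_fixture`, `make_indoor_fixture`) plant violations in
disjoint time blocks so that exact removal counts and exact indoor-fix
excision are determined by construction.

**What passing tests on synthetic data do not show:** the generator has
no cat-cat interaction, no habitat selection or barriers, a single
excursion block per day, and honest GPS noise — so agreement on synthetic
data validates the computational chain, not the behavioural realism of
any particular field dataset. Statistics that depend on behaviour
(near-home ratio, fold range) will differ from field values whenever the
simulated home-anchoring differs from real cats'.

## Problem sizes and defaults used in checks

The standard test population is 12 cats over 28 days (~300k raw fixes,
~25k per cat), chosen as a faithful small-neighbourhood configuration
that exercises two-cat households, all filters, and multi-cat
aggregation; the full pipeline on it runs in seconds. Parameter-recovery
checks use 1000 fixes at 2-min spacing over 10 seeds. The acceptance
script (`scripts/acceptance.py`) runs the pipeline with the generator's
known 5-m GPS error supplied as the BBMM location error; analyses of
field data, where the true error is unknown, fall back to the 10-m
default (or per-fix EHPE-derived values where trustworthy).

## Other limitations

* No dynamic (behaviour-switching) bridge variance, no autocorrelated
  KDE or MCP estimators — the bridge model is the single estimator.
* The lon/lat reader projects with a local azimuthal-equidistant
  approximation about the data centroid (sub-meter over a few km);
  analyses at regional scale should supply already-projected coordinates.
* No temporal (day/night) slicing of the population surface.
* EHPE is filtered on the raw device scale; it is not converted to meters
  and not (by default) propagated into per-fix location errors.
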