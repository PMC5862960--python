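# Methods

This note documents the models, conventions and numerical choices behind
`sharkmove`, in the order data flow through the pipeline.

## Synthetic seascape

Oceanic high islands are modelled as radially symmetric profiles: a land
core (negative depth = elevation, linear to a configurable peak), an
insular shelf ramping linearly from 0 m at the coastline to 200 m over a
configurable shelf width, then a steep slope (default 200 m/km) capped at
5,000 m. The seafloor at any point is the shallowest of the per-island
profiles, so two islands can share a saddle of shelf. The 200-m shelf-break
depth matches the upper end of the 100–200 m range typical of such islands;
the slope default puts the 4,000-m isobath ~19 km beyond the break, giving
the offshore-loop exclusion rule something to bite on. Grids are regular in
degrees, row 0 southernmost, origin at the south-west cell center, stored
as ESRI ASCII grid (single band, nodata tagged) — a plain-text raster that
any GIS reads.

Depth convention everywhere: positive = water depth (m), negative = land;
"at sea" means depth > 0. Harvested depths are always the seafloor below a
surface position, never an animal's swimming depth; the API names
(`seafloor_m`, `DepthProfile`) keep the two from being conflated.

## Movement model

A biased correlated random walk in a local planar frame (km east/north of
the attraction center; equirectangular conversion, adequate below ~200 km):

- drift: −k·Δt·x (Ornstein–Uhlenbeck pull, k = `attraction_per_h`,
  default 0.5 h⁻¹);
- noise: first-order autocorrelated Gaussian steps
  (`noise_km` = 0.5 km/step, autocorrelation 0.5);
- hard speed cap: realized steps are rescaled to at most
  `max_speed_kmh`·Δt (default 4.0 km/h, deliberately below the 4.2 km/h
  filter threshold so a correctly filtered track loses almost nothing);
- land avoidance by redraw: a proposed step onto land or off the grid is
  re-drawn (up to 25 times, then the shark holds position) — reflection
  rather than absorption, because sharks do not beach;
- surfacing: i.i.d. Bernoulli per step (default 0.15, inside the 10–20%
  surface-time range reported for large surface-oriented sharks);
- offshore excursions: a Poisson process (default 0.01/day) during which
  the central pull is replaced by outward drift at the mean speed for an
  Exponential(72 h) duration.

The default time step is 1 min — finer than needed for desk-scale tests
(the shortest duty-cycle silence is 20 s, but transmissions are placed in
continuous time within steps and positions interpolated linearly).

With the default cap, most proposed steps exceed the cap and are rescaled;
the walk behaves as constant-speed motion whose direction is the noisy
drift. The consequence — visible in tests — is that the realized core of a
finite track wanders around the programmed center by a few km; the
parameter-recovery checks therefore fix seeds, and the 0.25-isopleth
centroid criterion (within 2 km) is a seeded regression, not a universal
bound.

Reproducibility: every component draws from its own named stream
(`movement:<id>`, `surfacing:<id>`, `duty:<id>`, `argos:<id>`) spawned from
the single user seed, so adding a receiver or transmitter never perturbs a
path.

## Telemetry simulation

Acoustic: the transmitter alternates a pulse train (uniform 3–5 s) with a
randomized silence (uniform 20–230 s, the slowest duty cycle in multi-year
shark deployments), giving a mean start-to-start interval of 129 s
(≈ 27.9 transmissions/h). Every receiver deployed and within range
(default 900 m, the empirical maximum from range testing) logs the
transmission as one detection. Transmissions stop at nominal battery end.

Argos: one satellite-coverage window per clock hour (duration uniform
6–12 min, placed uniformly in the hour); every 1-min step at which the
shark is at the surface inside a window yields one fix. Location classes
are drawn from a configurable mix (default 3/2/1/0/A/B =
0.10/0.15/0.15/0.20/0.20/0.20); positional error is isotropic Gaussian
with radial RMS 150/300/1000 m for LC 3/2/1 (published upper bounds) and
2/4/8 km for LC 0/A/B (no published error; chosen so the speed filter has
realistic work). LC Z carries no position (NaN, removed first in the
pipeline). Generating a fix per surfaced in-window step intentionally
produces temporal clusters for the thinning step to resolve.

## Argos filtering

Pipeline order: drop Z → outlier radius → speed/land filter → cluster
thinning. Choices the source description left open:

- "Previous higher-quality location" = the most recent LC 1/2/3/G fix in
  time, whether or not intervening 0/A/B fixes were retained; retained
  0/A/B fixes never become anchors. A fix before the first anchor is
  tested against the first subsequent anchor rather than discarded.
- Manual removal of obviously spurious distant fixes is automated as a
  radius from the tagging site, default 2,500 km — beyond the longest
  plausible offshore excursion (~1,500 km), so real movements survive.
- The speed buffer is straight-line great-circle (sphere, R = 6371 km)
  plus an at-sea check, not an around-land path.
- Zero elapsed time between fix and anchor is treated as infinite speed
  unless the positions coincide (a 1e-9-h floor in the divisor).
- Cluster thinning: maximal runs with successive gaps strictly below the
  threshold (default: median inter-fix interval of the retained track)
  collapse to the highest-quality member, earliest on ties. Strict
  comparison leaves evenly sampled tracks untouched. Note the threshold is
  data-dependent: a burst embedded in a sparsely sampled track can absorb
  the immediately following fix (its lead gap is one burst-width short of
  the sampling interval).

The filter is idempotent, and anchors are never removed by the speed rule,
so reapplication is safe.

## UTM projection

Sixth-order Krüger series in the third flattening on WGS84 (k₀ = 0.9996,
zone 4 central meridian 159°W). Truncation error is sub-millimetre within
a zone; round-trips test below 1 m. Latitudes beyond ±84° raise;
longitudes > 10° from the central meridian warn.

## LoCoH

Neighbor rules: k (root + k−1 nearest), r (all within r), adaptive a
(nearest points in increasing distance while the running distance sum
stays ≤ a; a-sets grow monotonically with a). Hulls are convex hulls over
root + neighbors; degenerate (collinear/duplicate) sets give zero-area
hulls that participate in sorting rather than erroring. Enclosure counts
all points on or inside a hull (STRtree-accelerated).

Isopleths: hulls sorted by (enclosed count desc, area asc) — the standard
density ordering, chosen here since no ordering was prescribed — and
accumulated until the enclosed fraction reaches each level. Level
geometries are prefix unions, so nesting (containment and area
monotonicity) holds by construction; the achieved fraction can exceed the
level (it jumps hull-by-hull). Areas are reported in km² after planar
projection. Time weighting (`s`) is reserved in the API but rejected for
any value other than 0.

a-value selection scores each candidate's 95% isopleth for interior holes
and for fractional overlap with terrestrial habitat (default tolerance 1%
of isopleth area); the smallest candidate passing both wins, and the full
diagnostics table is always returned. Offshore-loop exclusion is purely
depth-thresholded (runs of consecutive fixes with harvested depth beyond
the 4,000-m isobath are removed in full) — a reproducible rule in place of
visual loop judgment; a single fix over a deep pocket is removed too.

Both the 0.10 and 0.25 isopleths are produced as "core" candidates;
neither is hard-coded as the core.

## Residency metrics

Days are local calendar days at a configurable UTC offset (default −10,
the study region's zone; detection-day metrics are day-boundary
sensitive). All intervals are half-open [start, end); a monitoring window
is (receiver deployment) ∩ (transmitter activation → nominal battery end)
∩ (analysis period), and its day count is the number of distinct local
dates the intersection touches. Nominal battery life is used exactly
(zero-failure assumption).

Visit segmentation closes the open visit at the last detection at the old
receiver the moment a detection appears elsewhere (even within 30 min) or
when the gap reaches 30 min; exact timestamp ties are broken by receiver
id and logged through deterministic ordering. The 7.7-min single-detection
convention (3.6 s + 2 × 230 s = 463.6 s, rounded to one decimal) applies
to all transmitters regardless of duty cycle, to avoid biasing visit
durations for faster tags. Mean-excluding-zeros applies to SFI and
visits/day only; visit-duration means include all visits.

SFI detections falling outside their pair's monitoring window are warned
about and not counted; detections at a pair with zero monitored days raise
(data inconsistency).

## Temporal patterns

Distinct-shark counting is per pooled bin: a shark detected at hour 9 on
fifty days counts once toward hour 9 ("number of individuals detected");
`per_day=True` switches to shark-days. The KS test treats the n observed
bin counts and n copies of their mean as two samples; D is the maximum
absolute ECDF difference (computed directly and oracle-tested), the
p-value comes from `scipy.stats.ks_2samp` (exact for n ≤ 12, asymptotic
above). Two caveats are inherent to this construction and documented
rather than patched: (1) the null sample is all ties, so exact p-values
are approximate; (2) integer counts compared against a fractional mean
can push all observations to one side of the mean, yielding large D for
nearly flat patterns. The implementation is a faithful rendering of the
described procedure, not an endorsement; an all-zero observed vector
short-circuits to D = 0 with a degenerate flag.

## Hurdle tables and model selection

Predictors per shark × receiver pair: great-circle tagging-site distance
(km), receiver depth (m), sex, total length (cm), tagging island;
continuous predictors mean-centered and scaled to unit SD (constants kept
in `attrs`). The binary table carries detected 0/1 and an offset of log
monitored days — emitted as specified even though an offset is unusual
under a logit link; the proportional table keeps non-zero pairs as
(days detected, days not detected) successes/failures. The split is
exactly invertible (`reconstruct_sfi`).

VIF_j = 1/(1−R²_j) from OLS of predictor j on the others (intercept
included); designs with R² ≥ 1−10⁻¹² report infinite VIF with a flag.
AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1), Akaike weights normalized over the
candidate set, substantial support flagged at Δ < 2. Mixed-model and
smooth fitting is deliberately not reimplemented: `ModelSpec` records
response, family/link, fixed terms, marginality-checked interactions,
random effects (transmitter, receiver) and the smooth-basis bound (k = 5)
for any standard engine to consume.

## What the simulator does and does not emulate

It reproduces the statistical structure the downstream analyses assume:
duty-cycle detection rates, class-dependent Argos error, surfacing-gated
fix opportunities, monitoring-window truncation, core-structured space
use, and zero-inflated shark × receiver detection matrices. It does not
emulate oceanography (currents, temperature, productivity), tides,
acoustic propagation variability (range is a hard 900-m disc), behavioural
diel cycles, inter-individual interactions, or tag failure. Passing tests
therefore validate the analysis machinery, not ecological conclusions
about any real system; seasonal/diel null results in the synthetic study
reflect time-homogeneous simulation, and the KS power check uses a
binomial stand-in at a stated 3× winter/summer contrast.

## Problem sizes and tolerances

Test and acceptance runs use desk-scale sizes chosen to exercise every
code path with stable statistics: 120×120–140×160 grid cells (~1.3–1.7 km),
5,000–20,000 movement steps, ~100–150 simulated listening hours for
rate convergence (3σ renewal-count tolerance), ≥1,000 Argos fixes for RMS
checks (±10%), 200 random point sets for isopleth invariants (union areas
to 10⁻⁶ relative), 1,000 random logs for visit-partition equality (exact),
and 200–300 Monte-Carlo replicates for the seasonal KS power regression
(power ≥ 0.8 at α = 0.05). Interpolation matches its oracle to 10⁻⁹;
exact cell-center queries snap within 10⁻⁹ cell units.
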