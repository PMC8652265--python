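# Methods

This note documents the models, parameter choices and numerical
conventions of `greencool`, and what its synthetic test bed does and does
not establish about real cities.

## Pipeline overview

The pipeline runs in five stages, each a module:

1. `synthetic_city` — generate a coarse LULC raster, fine tree/building
   masks, a gridded population and a station temperature series;
2. `refine` — reclassify LULC pixels by binned tree/building cover and
   derive per-class biophysical coefficients;
3. `scenario` — select and transform candidate pixels under a
   proportion/strategy configuration;
4. `cooling` → `metrics` → `exposure` — simulate air temperature,
   quantify canopy pattern, count exposed population;
5. `experiment` — orchestrate the full design and aggregate runs.

## Refinement conventions

* Cover fractions are exact block means of the 1 m masks over each 10 m
  pixel (aggregation factor 10).
* Bins are half-open `[a, b)` with the last bin closed at 1.0, so a
  fraction of exactly 0.25 falls in bin 1 and 0.75 in bin 3. The
  high-canopy rule ("cover of 75% or more") therefore coincides exactly
  with membership in the top bin; one threshold, no off-by-one classes.
* Refined code = `base*100 + tree_bin*10 + building_bin` — lossless for
  up to 10 bins and readable in printouts.
* Shade of a refined class is its tree-bin midpoint; albedo is
  `(1−m)·albedo_base + m·albedo_roof` with `m` the building-bin midpoint
  and `albedo_roof` the albedo of the 'building' class. The crop
  coefficient `k_c` and the green-area flag follow the base class
  unchanged: greening a pixel therefore acts through shade only, which
  keeps the effect of canopy addition interpretable and pixel-wise
  monotone.
* The base-class values (albedo, k_c, green flag) ship as a packaged CSV
  (`data/biophysical_defaults.csv`) and are configuration, not code.
  They are role-consistent defaults (asphalt dark, concrete bright,
  vegetation with high k_c, forest/garden flagged green); any
  application to real data should substitute locally calibrated values.

## Scenario sampling

* Candidate rules: base class in {building; road, path; sidewalk;
  traffic island; other impervious; garden}, building bin 0 (< 25%
  cover), tree bin < 3, and for roads at least one of the 8 Moore
  neighbours of a different base class (in-bounds neighbours only — no
  wraparound or padding).
* `cluster`/`scatter` are greedy: each step transforms the remaining
  candidate with the maximal/minimal count of high-canopy Moore
  neighbours. Counts are *dynamic* — pixels transformed during the run
  count as high canopy immediately — because the stated intent of the
  strategies is to grow (or avoid) contiguous canopy; a `static`
  toggle disables the updates. Ties are broken uniformly at random from
  the run RNG.
* All three strategies are implemented as one seeded ordering per
  (strategy, seed); the scenario at proportion p is its first
  `round_half_up(p·N)` elements. Consequences: pixel sets are nested
  across proportions for a fixed (strategy, run), the 100% scenario is
  identical for every strategy and seed, and any scenario is
  reproducible in isolation from (master seed, strategy, run).
* Half-up rounding of p·N makes scenario sizes exactly reproducible
  across platforms.

## Cooling model

Cooling capacity is the weighted form `CC = w_s·shade + w_a·albedo +
w_e·ETI`, defaults (0.6, 0.2, 0.2); `ETI = k_c·ET0/ET_max` clipped to
[0, 1]. ET0 uses the temperature-based Hargreaves formula with the
extraterrestrial radiation `R_a` expressed in mm/day water equivalent
(default 16.7, a clear mid-latitude summer day). Scalar ET0 inputs are
broadcast; rasters of other shapes are bilinearly resampled.

The park effect operates through 8-connected patches of green-flagged
classes of area ≥ 2 ha: every pixel within `d_cool` (default 100 m) of
such a patch receives `HM = max(CC, Σ w·CC_green / Σ w)` with
`w = exp(−d/d_cool)` over the qualifying green pixels within `d_cool`;
beyond that distance HM = CC. The influence is gated at `d_cool` because
the weighted *mean* does not decay with distance on its own.

Temperature: `T_nomix = T_ref + (1−HM)·UHI_max`, then a Gaussian moving
average with σ = `r_mix`/3 (default r_mix 500 m), truncated at 3σ and
renormalized at the raster border (filtered numerator divided by the
filtered indicator). Blending is therefore a convex combination and the
bounds `T_ref ≤ T ≤ T_ref + UHI_max` hold pixel-wise by construction.

The weights, `d_cool`, `r_mix` and the 2 ha park threshold are model
configuration with conventional defaults, not calibrated values; any
real-world use should calibrate them against station data. Known
limitations inherited from this model family: air mixing is spatially
uniform, building shade is ignored, and the cooling of large green
spaces is only represented through the exponential park kernel.

`T_ref`/`UHI_max` selection: among days whose minimum 21.00 station
reading exceeds 20 °C, the day with the largest max–min spread is the
reference day; `T_ref` is its minimum, `UHI_max` its spread.

## Landscape metrics

High-canopy patches are 8-connected (consistent with the Moore
neighbourhood used in sampling); a 4-connected option exists. Perimeter
is exposed cell-edge length, and edges on the raster boundary *count* by
default (a toggle implements the opposite convention, since reference
tools differ). The shape index is the raster approximation
`0.25·P/√A` (1.0 for a single square cell); the integer-cell
minimum-perimeter variant is available as `variant="min_perimeter"`.
With zero patches the means are reported as NaN (missing), not 0.

## Exposure

The 10 m temperature field is averaged (option: max) over each 100 m
population cell; a cell's whole population is exposed when its
temperature strictly exceeds the threshold ("higher than"), because the
census is only resolved at the cell level. Thresholds default to
21–26 °C.

## Experiment orchestration

Per-run seeds derive from `SeedSequence([master_seed, strategy_index,
run])`, independent of the proportion, so proportions share one ordering
per run (see above). Per-configuration aggregates are means over runs;
aggregate maps use the mean for temperature/heat mitigation and the
pixel-wise mode for LULC codes. Confidence intervals are Student-t
(mean ± t₀.₉₇₅,ₙ₋₁·SE); with n < 2 they are reported missing. Strategy
contrasts (reference − other) pair runs by run index. Failed scenarios
are logged and excluded from aggregates rather than aborting the batch.

## The synthetic city

The generator emulates a compact European agglomeration at reduced
scale: a water strip on one edge, a forested periphery, a garden-rich
residential ring and an artificial core, with a grid of connected road
corridors plus one three-cell-wide highway (so road pixels without a
different-class neighbour exist). Default extent is 2 400 m —
240×240 cells at 10 m, 24×24 population cells at 100 m — chosen as the
smallest scale that keeps whole 100 m census cells, thousands of
candidate pixels and non-trivial patch statistics while the full
211-scenario experiment runs in well under a minute. Default class mix:
13% building, 8% road, 4% sidewalk, 1% traffic island, 6% other
impervious, 28% garden, 33% forest, 7% water.

Fine masks are placed block by block: buildings as rectangles, trees as
pseudo-disk crowns of radius 5 cells (a 5 m crown on the 1 m grid), with
per-pixel target densities drawn from class-conditional clipped normals
(e.g. tree cover 0.88±0.07 under forest, 0.45±0.12 under garden,
0.05±0.04 under roads) and realized exactly up to whole cells; tree and
building cells never overlap. The 'building' class uses a bimodal
building-cover mixture (90% ≈ 0.88, 10% uniform 0.03–0.22) to emulate
polygon-edge pixels, so a small share of building-class pixels remains
eligible for greening, as observed in cadastre-based candidate maps.
The population (default 20 000) is multinomial over 100 m cells weighted
by building-pixel counts (plus a small garden weight), concentrating it
in the core. The station series (default 11 stations, 31 days) has a
rural anchor station and progressively warmer urban stations; the
warmest day is nudged above the 20 °C admissibility floor so a reference
day always exists.

What the synthetic city does **not** emulate: real street geometry,
terrain and lake breezes, vertical urban form, within-class biophysical
heterogeneity, or empirically calibrated cooling parameters. Passing
tests therefore establish the internal correctness and qualitative
behaviour of the pipeline (bounds, monotonicity, strategy orderings,
near-linear temperature response), not quantitative predictions for any
real city.

## Numerical notes and degenerate inputs

* All stages are pure functions of their inputs and seeds; experiments
  are bit-reproducible from the master seed.
* Greedy sampling keeps a float priority array updated in place; ties
  are exact integer comparisons on float-held counts.
* A proportion that rounds to zero pixels warns and returns an empty
  scenario; an all-identical station network yields UHI_max = 0 and a
  spatially uniform 21.00 temperature field; a landscape without
  candidates raises.
* The park-effect convolution and its brute-force all-pairs double loop
  agree to 1e-9 on small grids (tested), as do the landscape metrics
  against naive flood-fill/edge counting.
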