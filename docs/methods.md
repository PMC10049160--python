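# Methods

## Data model

Land use is a single integer-coded raster per date with seven classes
(1 farmland, 2 forests, 3 grassland, 4 wetland, 5 waters, 6 construction
land, 7 unused land), square cells in an equal-area projection, and a
frozen nodata boundary. Cell area is `(cell_size/100)²` ha; all area
bookkeeping is cell counting, which makes conservation checks exact.
Coordinates follow the raster convention: origin at the upper-left
corner, cell centers at `(col+0.5, row+0.5) × cell_size`, all distances
cell-center based. Equal-area projection is assumed, not verified — the
package never reprojects.

I/O: ESRI ASCII grids are the primary format (plain text, bit-exact
round-trip for integer rasters); single-band GeoTIFF is read and written
through `tifffile` with ModelPixelScale/ModelTiepoint tags and a
GDAL-style nodata tag.

## Demand projection

The transition cross-tabulation between two dated maps is row-normalized
into a Markov chain (empty source classes get identity rows); demand at
the horizon is `areas · Pⁿ`, which conserves total area exactly because
the rows are stochastic. An OLS line per class over three or more dates
is available as a cross-check and can be blended in with a configurable
weight; the default weight is 1.0 on the Markov chain, because how the
two should be combined is genuinely open and the chain is the one that
respects the transition structure. Negative linear extrapolations are
clamped to zero with the shortfall redistributed proportionally, keeping
the total conserved. Demand in hectares is converted to whole cells by
largest-remainder rounding, so the cell total always matches the map.

## Development probabilities (LEAS)

One binary random forest per class — expansion cells (converted to the
class between the two dates) against an equal-sized uniform sample of
unconverted cells — predicted over the whole driver stack. Defaults:
100 trees, 1:1 class balance, both configurable; the forest seed is
explicit, so surfaces are deterministic. Feature importances are
reported but never used for selection. A class with zero observed
expansion yields an all-zero surface rather than an error, since the
allocator treats "no evidence of expansion" as "no score".

Fitting one model per class (rather than one multiclass model) means
each class's expansion is explained by its own drivers and the surfaces
are directly comparable to per-class transition propensities.

## Patch allocation (CARS)

Each sweep scores every admissible conversion of cell *x* (current class
*f*) to target class *i*:

    score = P_i(x) × Ω_i(x) × inertia_i × m(f, i) [× spatial(x, i)]

* `Ω_i` — fraction of class-*i* cells in the (2r+1)² Moore window
  (center excluded), times a per-class weight in [0,1]. Default r = 1,
  weights 1.0.
* `inertia_i` — self-adaptive coefficient: multiplied by (1+ε) while the
  class is under demand, divided while over; ε = 0.1 by default,
  updated every sweep.
* `m(f, i)` — scenario multiplier matrix (policy pressure), with
  optional per-target spatial layers for planned-development zones.
* Patch seeding: a cell with Ω = 0 can still be offered with probability
  μ (default 0.02 per class) provided its development probability beats
  a threshold that starts at 1 and shrinks by δ = 0.9 each sweep — so
  new patches nucleate first where probabilities are highest, and
  seeding loosens only as allocation stalls.

Candidate cells draw their target class by roulette over class scores,
are ordered by an exponential-keys weighted draw (weighted sampling
without replacement), and convert greedily — but only from classes above
their demand to classes below it, and never on restricted or nodata
cells. This source-surplus/target-deficit rule is what guarantees the
audit invariants: total cell count conserved, per-class demand gaps
non-increasing every sweep, and exact reproducibility from the seed.
Demand tolerance defaults to max(1 cell, 0.1% of class demand); exact
equality can be unattainable under transition constraints. Infeasible
demand (all scores structurally zero while gaps remain) terminates with
a partial allocation and a diagnostic naming the unmet classes.

Per-class conversion caps (development-intensity ceilings) are enforced
as a hard budget on converted cells per source class.

## Scenarios

Scenarios are declarative YAML compiled against a base map and named
mask layers. Relative policy phrases act multiplicatively on scores
("improve by 60%" → ×1.6, "reduce by 80%" → ×0.2): this keeps scores in
a valid cone and matches the relative phrasing; additive probability
shifts would not. The same multiplier matrix also re-weights the Markov
rows (renormalized) before demand projection, so policy pressure reaches
both the demand totals and the spatial pattern; either path can be
disabled per scenario (`apply_to_demand`, `apply_to_allocation`).

Shipped rule sets: **nes** — identity; **eps** — restoration boosted,
farmland/unused→construction cut, ecological classes frozen in barrier
zones except inside a 10-km buffer of existing construction; **eds** —
everything except waters converts more readily to farmland/construction,
existing waters frozen, planned zones favored; **pds** — barriers freeze
forests/wetland/waters, agricultural zones freeze farmland, and each
class may convert at most 6.9% of its unrestricted area. The 6.9%
ceiling is interpreted per class (the flag-switchable total-area reading
is also implemented); the barrier/agricultural/planned masks are user
inputs — digitizing real planning polygons is out of scope, and the test
fixtures build toy masks programmatically.

## Carbon accounting

Storage is strictly linear: per class, area (ha) × summed four-pool
density (Mg ha⁻¹); totals in Tg (10⁶ Mg), transition flows in 10⁴ Mg to
match the two reporting conventions in use. Densities are class-uniform
by construction — the model carries no within-class spatial variation,
which is the standard (and acknowledged) simplification of this kind of
bookkeeping. Waters carries all-zero pools and the table constructor
enforces it.

Transition flows price entry (i→j) as `area(i→j) × (d(j) − d(i))`. By
default both classes use the horizon-year density table, isolating the
land-change effect from density drift; a flag prices the origin class at
the start-year table instead. The per-hectare term is antisymmetric, so
a round trip i→j→i nets to zero at fixed densities.

### GM(1,1) density forecasting

Standard construction: 1-AGO accumulation, background values
`z(k) = (x¹(k)+x¹(k−1))/2`, least squares on `x⁰(k) = −a·z(k) + b`,
restored forecast `x̂⁰(k) = (x⁰(1) − b/a)(1 − eᵃ)e^(−a(k−1))` with the
a→0 limit handled as the constant b. Requires strictly positive series
of length ≥ 4. For an exact geometric series `c·r^(k−1)` the normal
equations are solved exactly by `a = −2(r−1)/(r+1), b = 2c/(r+1)`
(substitute the series into the gray difference equation; residuals
vanish) — this closed form is the test oracle. Note the restored
forecast of a fitted geometric series is near- but not exactly
geometric (the `e^a` discretization), which is inherent to the model,
not an implementation artifact.

## Validation metrics

Overall accuracy (trace/total) and Cohen's κ on the cellwise confusion
matrix; κ raises explicitly when expected agreement is 1. The figure of
merit uses the four-component change-space definition — hits /
(misses + hits + wrong-class + false alarms) — computed over cells with
either observed or simulated change; it raises when that set is empty.
Nodata cells are excluded from every component.

## Coordination analysis

Land-use intensity per aggregation block is the level-weighted area sum
(levels: unused 1; forests/grassland/wetland/waters 2; farmland 3;
construction 4). Growth rates are simple annualized relative changes
(compound growth is available by flag; the index is scale-invariant so
the choice mainly moves near-zero sub-labels). Blocks default to 3 km.
A zero-base block with growth has an undefined rate: it is labelled
"no-change", logged, and excluded from ellipse summaries, as is the
both-rates-zero case.

The index `O = |(ALUI+ACS)/2| / √(ALUI²+ACS²)` is scale-invariant, zero
at exactly opposed rates, and attains its maximum √2/2 ≈ 0.707 only when
the rates are equal. Consequently the upper classification band
[0.8, 1] of the conventional three-way table (uncoordinated < 0.5 ≤
adapted < 0.8 ≤ coordinated) is unreachable under this normalization;
`rms=True` divides by the root-mean-square instead (a √2 rescale that
reaches 1 at equal rates) and makes the full table usable. The default
stays with the plain formula because that is the form the index is
stated in; the boundary 0.8 itself is assigned to "coordinated" and
exact rate ties to the "ahead" sub-label (both measure-zero
conventions, logged). Sub-labels: "ahead" when carbon growth outpaces
intensity growth (ALUI < ACS), else "lagging".

Standard deviational ellipses use the classical angle equation
(clockwise from north) with semiaxes equal to the weighted standard
deviations along the rotated axes — the 1σ convention; a scale flag
multiplies both axes for the √2 variant, since published ellipse
"oblateness" figures are not always self-consistent about the
convention. Weighted points behave exactly like replicated unit-weight
points; collinear input degenerates to a zero minor axis with a flag.

## Synthetic landscapes

The generator emulates what the pipeline needs from real multi-date
land-use data, with exact ground truth:

* drivers: standardized Gaussian-filtered noise fields (default 4,
  correlation length 8 cells) plus a standardized distance-to-city
  layer — the spatially autocorrelated covariates that make development
  probabilities learnable;
* an initial map carved from quantiles of an independent smooth field
  (default proportions of a forested river basin: 53% forests, 28%
  farmland, the rest minor classes) with a compact construction core at
  the city seed;
* transitions: per (from, to) rule, logistic in the drivers. Default
  rules encode urbanization pulled toward the city and
  afforestation/wetland restoration following terrain fields, with
  intercepts placing baseline conversion rates at a few percent per
  step — the magnitude of decadal change in fast-developing basins.
  The exact per-cell probabilities are returned alongside the maps, so
  fitted surfaces can be scored against truth rather than realizations;
* demand-constrained steps convert exactly the k highest-probability
  eligible cells (ranked draw without replacement), making the
  generator demand-exact by construction.

One seeded RNG stream per invocation; identical seeds give
byte-identical outputs. What the generator does **not** emulate: real
driver semantics (climate, soil, GDP), class-imbalance extremes,
registration error, or the sheer size of real 30 m basin rasters —
passing tests demonstrate the algorithms' correctness and mutual
consistency, not predictive skill on any real landscape.

## Problem sizes and numerical choices

Tests and the shipped pipeline run on 100×100 to 200×200 landscapes —
large enough for patch structure and stable recovery statistics, small
enough that the full suite runs in well under a minute per property.
Recovery of known transition rules is checked over 20 seeded replicates
(mean AUC ≈ 0.97, mean Spearman ρ ≈ 0.84 against the true probability
among convertible cells); allocation beats a random-allocation null on
figure of merit in ≥19 of 20 replicates. Rank correlation is evaluated
over cells whose class can convert into the target: cells with no rule
have structurally zero truth that drivers cannot encode, so including
them would measure class membership rather than recovery.

Tolerances: Markov row sums to 1e−9; the two carbon computation paths
(area table vs per-cell map) agree to 1e−6 relative; gray-model closed
forms to 1e−9; published-table reproduction to ±0.05 Tg (the rounding
of printed inputs — e.g. unused land computes to 0.0903 Tg where the
printed table rounds to 0.10).

## Known limitations

* Class-uniform carbon densities; no within-class or within-cell
  variation, no flux dynamics — this is stock bookkeeping.
* The allocator is a faithful member of the patch-generating CA family,
  not a bit-compatible reimplementation of any released tool; its free
  parameters (μ, δ, ε, window, tolerance) are exposed defaults, not
  calibrated values.
* Scenario masks are inputs; the package does not digitize planning
  boundaries.
* No reprojection or resampling; inputs must be co-registered in an
  equal-area grid.
* Memory strategy for full-size (≈ 22,000² cells) rasters is out of
  scope; the implementation is dense in-memory NumPy.
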