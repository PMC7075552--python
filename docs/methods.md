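# Methods

## Dispersal model

Spread between locations is governed by a negative-exponential
distance-decay kernel

    P(x) = min(1, exp(A − B·x)),    B > 0,

with *x* the centroid-to-centroid distance in meters.  *A* and *B* are
not fitted to data; they are pinned exactly by two (distance, probability)
constraints solved as a 2×2 linear system in log space:

    B = ln(p₁/p₂) / (d₂ − d₁),    A = ln(p₁) + B·d₁.

The closed form avoids any optimizer tolerance questions.  The default
constraints — a 90% chance of spreading 30 m (conservative vegetative
spread by adult plants) and a 0.05% chance of spreading 1,610 m (rare
long-range seed dispersal) — give A ≈ 0.03696 and B ≈ 0.0047440 m⁻¹.
With these values exp(A) slightly exceeds 1, so evaluated probabilities
are capped at 1; the cap only affects distances below A/B ≈ 7.8 m, two
orders of magnitude below the 500 m cell spacing, and exists purely to
keep the model a probability.

The kernel is treated as a **per-annual-step** pairwise colonization
probability.  The source formulation is ambiguous about whether the
calibrated probabilities refer to one year or to the whole five-year
frame; the annual reading is the one consistent with reporting yearly
acreage growth, and it is the package's documented choice rather than a
settled fact.  Users who prefer the five-year reading can recalibrate the
constraints accordingly.

## Grid and rasterization

Cells are 500 m squares (61.7763 acres each) indexed 0-based, row-major
from the north-west corner, on planar projected coordinates (no geodesy —
the synthetic study system has no datum, and state-scale applications are
expected to supply already-projected coordinates).  A cell's extent is
the half-open square [x₀, x₀+s) × (y₀−s, y₀], so every point maps to
exactly one cell and points on shared edges are assigned deterministically
(to the cell whose west or north edge carries them).  Points outside the
grid or on non-timberland cells are counted and reported, never silently
dropped, so users can audit how many occurrence records fed the model.
The timberland mask is consumed as a precomputed binary grid; whatever
fractional-cover threshold produced it (25% in the motivating study)
belongs to data preparation and should be recorded in the run config.

## Spread simulation

Each year, every unoccupied masked cell draws colonization as a Bernoulli
trial with probability

    p_cell = 1 − Π_i (1 − P(d_i))

over all occupied cells *i* within the kernel's effective radius.
Assumptions, each a deliberate design choice:

* **Independence** of colonization attempts from multiple sources
  (complement-product combination) — the standard assumption for pairwise
  spread models; nothing in the motivating analysis specifies otherwise.
* **Synchronous annual update**: cells colonized in year *t* become
  sources in year *t+1*.  This removes any dependence on within-year
  update order.
* **No reversion** (no eradication) and no habitat weighting beyond the
  binary mask.
* **Kernel truncation**: pairs farther apart than the distance where the
  kernel falls to `p_floor` (default 10⁻⁶, radius ≈ 2,920 m) are ignored.
  The test suite verifies that halving `p_floor` changes the year-5 mean
  infested area by far less than 0.1%.

Implementation: each source cell adds its log(1−P(d)) neighbourhood
"stamp" to a running per-cell log-miss field once, when it first becomes
a source.  This is algebraically identical to re-scanning all
source–target pairs every year but costs O(new sources × stamp size) per
year, which is what makes 6,000 replicates of a 120×120 grid cheap.
One uniform variate is drawn per grid cell per year regardless of
candidacy, so paired runs with the same seed stay on common random
numbers even when settings such as `p_floor` differ.

Randomness: a single master seed; replicate *i* uses the *i*-th spawned
child of `numpy.random.SeedSequence(seed)`, making results independent of
execution order and bit-reproducible.  The "iterations" count is
interpreted as full independent replicates of the whole multi-year run.
Occurrence probability for a cell-year is the fraction of replicates in
which the cell was occupied by the end of that year; the infested-area
trajectory reports the mean and the 2.5–97.5 percentile band across
replicates (the printed acreages in the motivating study are not
identified as means or single draws; means with intervals are strictly
more informative).

## Scenarios

Occurrence probabilities map onto dispersal-mode scenarios: A = [0.01,
0.25) (seed dispersal plus vegetative spread), B = [0.25, 1.0] (vegetative
spread via adults and saplings; closed at 1 so A and B partition
[0.01, 1]), and C = 10% of scenario B's area (adult-only vegetative
spread).  The description of scenario A as "most aggressive" can also be
read as subsuming the high-probability cells; the flag
`scenario_a_includes_b` (default off, following the literal band
definition) switches A to the union [0.01, 1.0].  Band membership is
evaluated on masked cells only.

## Economics

Direct impacts are a linear proration of a regional economic base:
metric × (infested acres / base-area acres).  Total impacts are direct
impacts times per-metric SAM multipliers.  For users with a technical
coefficient matrix, `leontief_output` solves X = (I − A)⁻¹Y directly
(dense `numpy.linalg.solve`; productivity is enforced by requiring every
column sum of A below 1, which bounds the spectral radius).

The default base and multipliers come from the published Oklahoma
forest-sector figures bundled in `vinespread.datasets`:

* base area 2.7M ha (6,671,845 acres) — the figure printed alongside the
  study's results; a 2.9M ha figure also circulates and is configurable;
* direct output $3.3B/yr and payroll (labor income) $1.0B/yr —
  published directly;
* multipliers = full-precision total/direct ratios of the year-5
  aggressive-scenario table row (output 1.59728, employment 1.98980,
  labor income 2.31741, value added 1.92829).  These ratios are constant
  across the published years to within 0.6%, which the tests verify;
* direct employment and direct value added are **not** published at the
  statewide level, so the default base derives them: employment =
  19,000 total jobs ÷ employment multiplier; value added = $3.3B × the
  table's direct value-added:output ratio (35.14/105.11).  Both are
  package choices, fully overridable in config.

The published impact tables cannot be reconciled exactly with any single
(base, area) proration choice, so the package documents its defaults
rather than asserting they replicate the original workflow; the bundled
tables are what anchor the parts that *are* exactly checkable (multiplier
constancy, the 10%-of-B relation, the sensitivity scalings).

Report rounding is decimal half-up — two decimals for $M, integers for
jobs — because that convention reproduces the published sensitivity rows
from the published year-1/year-5 rows to within a final-digit rounding
(±0.01 $M / ±1 job).  Unrounded values are kept internally so scaling
never compounds rounding error.

## Sensitivity analysis

Reduced-area cases scale every unrounded impact entry by an exact
`fractions.Fraction` — "66%" means 2/3 (105.11 × 2/3 → 70.07, matching
the published row; 105.11 × 0.66 → 69.37 does not).  By linearity,
scaling impacts and scaling areas are indistinguishable; the module
scales impacts.

## Synthetic study system

The generator emulates the *structure* of the study inputs, not
Oklahoma's geometry: a contiguous timberland block anchored at the
south-east corner covering `mask_fraction` of the grid (deterministic
row-major fill — exact cell count, 4-connected), and `n_points` (default
76) presence points from a cluster process (centres uniform over masked
cells, isotropic Gaussian scatter with sd 1 km, resampled onto the mask).
Defaults: 120×120 grid of 500 m cells, 40% masked, 8 clusters.  The grid
is large enough for five years of spread (radius ≈ 6 cells/year) without
boundary saturation, small enough for desk-scale runs.

What passing tests on this system do **not** show: real landscapes have
fragmented, irregular timberland, anisotropic spread corridors (rivers,
roads), observation bias in occurrence records, and long-distance
anthropogenic jumps — none of which the generator produces.  Results on
synthetic data validate the machinery (calibration, simulation
invariants, accounting identities), not any real region's forecast.

## Numerical choices

* Complement-products are accumulated as sums of `log1p(−p)` with p
  clipped to 1 − 10⁻¹⁵, avoiding underflow for many weak sources.
* Kernel calibration and evaluation is in double precision; the
  constraint round-trip is exact to ~10⁻¹² relative.
* Degenerate inputs: equal calibration distances raise; empty point sets
  rasterize to a valid all-zero grid with a warning; an all-occupied grid
  is absorbing; a zero-occupancy grid yields identically zero maps.
* Areas use the international acre (4,046.8564224 m²); hectare conversion
  at 2.4710538 acres/ha.

## Problem sizes

The standard verification configuration runs the full pipeline on the
120×120 synthetic landscape with 500 Monte Carlo replicates, and checks
simulator calibration against exact enumeration on 2- and 3-cell systems
at the full 6,000 replicates.  Larger replicate counts change only the
Monte Carlo standard error (∝ 1/√n) and scale linearly in run time.

## Known limitations

* Single-sector, static input-output accounting: constant returns,
  fixed multipliers, no structural change — which is why projections are
  confined to a five-year horizon.
* Isotropic, thin-tailed kernel; no separate anthropogenic jump process.
* Scenario areas are banded snapshots of a cumulative probability map;
  a cell can migrate from band A to band B between years, so band-A
  acreage (unlike total infested acreage) is not guaranteed monotone.
* The run log records wall-clock timings, so it is the one output file
  excluded from the byte-for-byte reproducibility guarantee.
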