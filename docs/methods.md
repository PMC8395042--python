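# Methods

## Carbon model

The carbon model is the static pool-bookkeeping scheme used by
InVEST-style carbon assessments. Each LULC class *i* has four pools
(above-ground, below-ground, soil, dead organic matter, Mg/ha) whose sum is
the class density C_i; total storage of a map is C_tot = Σᵢ C_i·S_i with
S_i the class area in hectares. Carbon is assumed to track land cover
immediately: converting a cell re-labels its stock at the new class density
in the same step, with no multi-decade relaxation toward a new equilibrium.
Sequestration over a period is therefore exactly the storage difference,
and period sequestration telescopes: the per-period values over a series
sum to the first-to-last value identically.

The packaged density table covers the ten coastal classes. Three of its
rows (coastal marsh, paddy field, rainfed cropland) have a printed total
that does not equal their four-pool sum. The printed total column is what
the aggregate formula consumes, so it drives all storage computations by
default; the contradiction is surfaced by the input validator and by
`CarbonDensityTable.inconsistent_rows()` rather than silently repaired.
`strict=True` switches every computation to the pool sums for users who
prefer the internally consistent convention. No result in this repository
depends on which convention the original assessment used — that is not
recoverable from the published numbers.

## Transition matrices

Matrices are exact underneath: integer cell counts scaled by the cell area,
with rounding to 0.01 km² only at serialization. Nodata cells (sentinel 0)
are excluded everywhere and the nodata mask must be identical across dates,
so the matrix total equals the fixed study area for every period. The CSV
layout is the published one — rows are start classes, columns end classes,
a trailing transfer-out column and a final transfer-in row — but with one
canonical column order (codes 1..10), since the published blocks are not
consistent about it; columns are always labelled explicitly.

`materialize_from_matrix` inverts the tabulation: it lays out a grid pair
(row-major fill, arbitrary geometry) whose recomputed matrix equals a given
area matrix exactly, provided every entry is an integer multiple of the
cell area. 100 m cells make any 0.01-km²-precision table integral, which
turns published matrices into exact raster fixtures. The published blocks
only report changes (zero diagonal), so fixture pairs built from them have
every mapped cell change class; that affects nothing downstream, as all
marginals exclude the diagonal.

One marginal cell of the packaged 2000–2009 block (grassland transfer-in,
printed 5.97 km²) contradicts its own column, which sums to 5.89 km². The
body is treated as authoritative; the check scripts report the cell as a
known mismatch instead of patching either number.

## Driving-process taxonomy

The six processes are defined purely on ordered class pairs: A
{1→2, 1→3, 5→2, 5→3}, S {2→3, 2→4, 3→4}, Rs {3→2}, E {2→1, 3→1, 4→1}, R
{1–5}→{6–10}, Re {6–10}→{1–5}; same-class pairs are Stable. That covers 71
of the 100 ordered pairs. The remaining 29 (e.g. 9→6, 2→5) get an explicit
Unclassified step: the taxonomy does not name them, and guessing a label
would fabricate attribution, so chains containing them are reported
separately and excluded from the per-chain carbon table and the clustering
matrix by default (`include_unclassified=True` opts in; `extra_steps` lets
a user extend the mapping instead).

A pixel's chain drops Stable intervals and collapses consecutive duplicate
steps, so "Mono" means one *distinct* process rather than one interval —
with four dates a chain has at most three steps. The per-chain category
sign comes from the chain's aggregate carbon change; the per-pixel category
map signs each cell by its own change, since one chain can gain carbon in
aggregate while individual pixels lose it. An aggregate change of exactly
zero is reported as "Neutral" rather than forced into ±; it can occur in
synthetic data even though the published analysis never meets it.

## Natural-breaks levels

Carbon-level maps classify the ten class densities into k=4 ordered levels
with Fisher–Jenks natural breaks: the contiguous partition of the sorted
values minimizing total within-class sum of squared deviations, computed by
the O(k·n²) dynamic program with prefix sums. Ten values is a trivial
problem size, but ties are handled deterministically anyway: among
equal-cost partitions the lexicographically smallest (leftmost) break
indices win, implemented by a suffix DP with greedy forward reconstruction.
The test oracle is independent exhaustive search over all contiguous
partitions.

## Clustering

The chains × dates matrix holds, for each chain, the summed storage of its
pixels at each date. Each date column is z-scored across chains before
clustering. The plain (X − μ)/σ formula names no correction, so σ is the
population standard deviation (divide by n) by default, with a sample-sd
switch for parity with heatmap tools that default to n−1. A constant
column maps to all zeros. Rows are clustered agglomeratively under
Euclidean distance; complete linkage is the default (the common clustered-
heatmap default), with average and single available. The agglomeration is
implemented directly — row counts here are tens — so tie-breaking is fully
specified (lowest active node-id pair merges first) and the leaf order is a
deterministic depth-first traversal, lower node id first. scipy's linkage
is the independent cross-check in the tests, not the implementation. Date
columns stay in chronological order; a years-clustering flag exists but is
off by default because the analysis is about similarity of process rows.

## Synthetic coastal generator

The generator emulates the statistical structure the analysis assumes, not
the hydrodynamics of a real estuary. Date 0 is a land–sea gradient (an
inshore strip of paddy/construction/cropland, then marsh, tidal flat, and
offshore water); each interval applies the six processes in a fixed order —
accretion, succession, regressive succession, erosion, reclamation,
restoration — as per-cell Bernoulli draws, with 4-adjacency defining the
accretion/erosion fronts and reclamation confined within a configurable
column distance of the initial land edge. A cell changes at most once per
interval, mirroring one process step per mapped period. All randomness
comes from one generator seeded by the scenario, with full-grid draws
consumed in row-major order per process, so runs are bit-reproducible.

No field rates exist for the real processes, so the defaults are chosen
once as a plausible prograding-shore regime: accretion 0.35, succession
0.25, regressive succession 0.03, erosion 0.05, reclamation 0.08,
restoration 0.02 per interval, with reclamation targets weighted toward
aquaculture ponds (0.30) and paddies (0.25) over cropland (0.20),
construction (0.15) and reservoirs (0.10). Default geometry is 60 × 80
cells of 100 m over four dates. What passing tests on synthetic data show
is that the machinery is correct — chains recovered, rates recovered,
bookkeeping exact; they cannot show that any particular real coast has the
published chain composition, which depends on the unreleased classified
maps.

## Problem sizes and tolerances

The shipped analyses and checks run on 60 × 80 synthetic grids (4,800
cells, four dates) and on fixture grids of up to ~88,000 mapped cells
materialized from the published matrices — comfortable sizes for exact
assertions. Area identities and telescoping are asserted to 1e-9 absolute;
marginal reproductions to 0.005 km² (half the published precision);
rate-recovery to three binomial standard errors at 10⁴ cells. Storage uses
float64 throughout; equality of grids is code-level exact.

## Known limitations

The published headline totals (storage 1659.44→1789.78 × 10⁴ Mg and the
three period sequestration values) require the original classified rasters,
which were never deposited, and cannot be recomputed from the published
change matrices alone — the matrices lack the unchanged diagonal, and the
density table's internal contradiction leaves the density convention
ambiguous. The package therefore anchors to what is exactly reproducible:
the change-matrix marginals, the pool arithmetic, and the method's
invariants. Raster support is deliberately minimal (single-band integer,
no reprojection or resampling); inputs must already be co-registered on a
common grid.
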