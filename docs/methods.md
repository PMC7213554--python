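# Methods notes

## Data model and assumptions

The package treats biodiversity data as three linked node classes —
taxa, occurrence records, and lattice cells — with typed relations:
IS_PARENT_OF (taxon hierarchy), IS_IN / IS_CONTAINED_IN (occurrence →
containing cell, plus the derived species → cell "recorded here" edge),
and IS_NEIGHBOUR_OF (lattice adjacency). Everything runs in-process; the
graph-database semantics (constant-cost edge traversal, lazy evaluation)
are preserved as dictionary indices and generator-based traversals that
expand no edges until iterated and iterate deterministically (sorted
ids).

Assumptions baked into the model:

* **Fixed eight-rank taxonomy.** Root (depth 0) through species
  (depth 7), no rank skipping in the stored backbone. Occurrence files
  that imply an unknown lineage may create new backbone nodes; a missing
  intermediate rank is filled with a placeholder named
  `incertae:<child-name>` (logged) so that lineage lengths stay
  rank-aligned — the alternative, dropping such records, would silently
  bias counts.
* **Presence-only records.** No absences, no effort correction. An
  occurrence's identity is its integer id: two records at the same
  coordinates are distinct observations, and all set algebra
  (merge/intersect/trim) operates on id sets. This makes the
  intersection of trees from disjoint cells provably empty.
* **Half-open cells.** A cell owns `[west, west+res) × [south,
  south+res)`; the grid's outermost top/right edge is closed so the
  extent is exactly partitioned. Interior points on shared edges belong
  to the greater-index cell.
* **Queen adjacency.** Neighbourhoods are Moore neighbourhoods (Chebyshev
  distance ≤ k, (2k+1)² cells in the interior, clipped at borders); the
  order-k neighbourhood equals the k-fold closure of order-1, which the
  tests assert. Rook (4-neighbour) adjacency is not offered because every
  downstream consumer here (neighbourhood co-occurrence) is defined on
  the queen halo.

## Parameters that matter

| parameter | default | units | notes |
| --- | --- | --- | --- |
| grid resolution | caller-set (0.05° typical) | degrees/cell | drives cell area ≈ 30.91·cos φ km² at 0.05° |
| neighbourhood order k | 4 in the pipeline | cells | k=1 for quick looks; cost grows as (2k+1)² |
| Albers lat_1, lat_2, lat_0, lon_0 | none (caller supplies, e.g. 14.5/32.5/24/−105) | degrees | standard parallels should bracket the latitude span |
| earth radius | 6 371 007.2 | m | authalic sphere; see numerical choices |
| red-list categories | CR, EN, VU | — | the "threatened" filter set |
| match mode | substring | — | `binomial` closes nesting false-positives |
| sun azimuth/altitude | 315°/45° | degrees | hillshade defaults |
| nodata | −9999.0 | — | raster sentinel |

## Appearance frequency and ranking

`count_node_frequencies_on_list` sets, for every node of a target tree,
AF = (number of reference trees containing that node's taxon) / (number
of reference trees). Reference lists include empty cell trees (an empty
tree still contains the root, so the root's AF counts those); pipeline
callers therefore see AF denominators equal to the number of
neighbourhood cells. Ranking sorts each rank's accessor list by (AF
descending, name ascending); the alphabetical tie-break makes runs
reproducible. Printed summaries show AF only after it has been computed
— there is no default display value beforehand.

The published per-rank percentages that motivated this design mix two
readings of "most abundant"; the pipeline's rank tables therefore carry
both numbers per node — its AF and its occurrence share within its rank
— so neither has to be inferred from the other.

## The co-occurrence pipeline

`run_cooccurrence` composes: cells with ≥1 focal occurrence → union of
their order-k neighbourhoods (deduplicated by default; a
`deduplicate_neighbourhoods=False` flag preserves the duplicates a plain
list-flatten would produce — duplicates cannot change the merged tree,
because the algebra is set-based, but they do inflate AF denominators,
which is why deduplication is the default) → one tree per cell → a
single-shot merge from the union of occurrence ids (result-identical to
folding `+`, asserted by tests) → AF against the per-cell trees → rank →
red-list filter → coverage percentage (100 × matched species / listed
species in the selected categories) → per-cell equal-area statistics
(mean, population SD, total, optionally the percentage of a supplied
region polygon's area).

Red-list matching is lowercased substring containment of the listed name
in the species name, so a listed binomial matches a full scientific name
with authorship. This is deliberately permissive; `mode="binomial"`
compares only the first two name tokens for a strict alternative.

## Numerical choices

* **Projection.** Albers equal-area conic on the authalic sphere
  (R = 6371.0072 km), parsed from proj-style strings. On a regional
  latitude span the area error against the ellipsoidal projection is
  well below the 0.5 % tolerance the tests impose via an independent
  spherical-excess (L'Huilier) oracle; an ellipsoidal backend can be
  substituted through `ProjectionSpec.radius` plus a custom forward
  function if sub-0.1 % areas are ever needed. Polygon areas are planar
  shoelace areas of the projected rings (shapely), ÷10⁶ for km².
* **Raster sampling** is containing-pixel (no interpolation): correct
  for categorical layers and reproducible for continuous ones. Pixel
  membership in a clip polygon is decided by the pixel centre.
* **Terrain derivatives** use Horn's 3×3 finite differences; the x pixel
  size is scaled by cos(latitude) per row to convert degrees to metres,
  the y size by the constant meridian arc. Slope is in degrees, aspect
  in degrees clockwise from north (flat pixels: aspect nodata, hillshade
  computed with aspect 0), hillshade scaled 0–255 and clamped at 0.
  Border pixels are nodata.
* **Degenerate inputs.** Grids must contain ≥1 cell; neighbourhood order
  <1, adjacency depth outside 0–7, empty reference lists, empty red
  lists, zero coverage denominators, and clip polygons that miss every
  pixel centre all raise typed errors rather than returning silent
  defaults. Trees built from zero occurrences are valid values (they
  print "No record available") and act as the identity of merge.

## Synthetic data: what it does and does not emulate

`fixtures` generates complete backbones with configurable fan-out
(deterministic names), occurrence landscapes (uniform or
cluster-centred placement, integer-grid draws from a seeded
`numpy.random.default_rng` so results are platform-stable), analytic
rasters (constant / plane / cone / sinusoid / seeded noise), and seeded
red lists drawn from backbone species.

The exact-count mode deals records round-robin over each class's species
until requested class totals are met, confined to designated cells. The
`tutorial_landscape` preset fixes those totals to the printed class
listings of two reference trees — t1 (nine classes, 1062 records, one
cell) and t2 (five classes, 151 records, a disjoint cell) — because the
class-level counts, not the coordinates, determine every tree-algebra
result checked against the published listings. Counts below class level
in that preset are synthetic (one order/family/genus per class, three
species), as the listings print nothing below class.

None of the generators emulate real spatial sampling bias, taxonomic
misidentification, coordinate error, or niche structure. Passing tests
therefore demonstrate the correctness of the graph/tree/raster
machinery under the stated models, not robustness to the messiness of
real aggregated occurrence data.

Problem sizes used by the test suite and acceptance script — grids of
10×10 to 100×100 cells, tens to ~1200 occurrences per fixture, 100
random oracle replicates, 20–25 Monte-Carlo seeds — were chosen as the
smallest sizes at which the checked quantities are statistically
meaningful; everything scales linearly in occurrences and cells except
the brute-force oracles themselves.

## Known limitations

* No synonym or fuzzy name reconciliation; name matching is exact
  (taxonomy) or substring/binomial (red list).
* Only the forward Albers mapping is provided — no general CRS engine,
  no datum shifts, no raster reprojection or resampling.
* The knowledge graph is not persistent beyond GraphML export; there is
  no query language.
* Occurrence dates are carried but unused by the analyses (no temporal
  filtering).
* Very large grids are cheap (cells materialize on demand) but the
  brute-force test oracles are quadratic and cap the fixture sizes used
  in the suite.
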