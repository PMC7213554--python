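# occutree

Knowledge-graph toolkit for species occurrence records: build local
taxonomic trees ("trees of life") over a regular longitude–latitude
lattice, operate on them with a set algebra, rank co-occurring taxa by how
frequently they appear across grid-cell neighbourhoods, and extract raster
covariates for the result.

It is aimed at biodiversity informatics and spatial ecology work with
presence-only data (GBIF-style records): questions such as *which
threatened species co-occur within a k-cell neighbourhood of a focal
taxon, how often, and over what area?* — answerable without a database
server, entirely in-process.

## The model

An **occurrence** is a presence-only record: a species name, a WGS84 point
and a date. Occurrences are classified against a fixed eight-rank
**taxonomic backbone** (root "LUCA" at depth 0 down to species at depth
7, the parent relation IS_PARENT_OF) and located in the cells of a
regular lattice (the relation IS_IN, assigned by point-in-cell test;
cells are related by IS_NEIGHBOUR_OF, 8-neighbour queen adjacency).

A **local taxonomic tree** T(O) over an occurrence set O is the union of
the root-to-species lineages of the records in O; every node v carries

    n.count(v) = |{o ∈ O : v lies on o's lineage}|,

so n.count is conserved: each internal node's count is the sum of its
children's. The tree algebra is set algebra on occurrence identities:

* **addition**  T(O₁) + T(O₂) = T(O₁ ∪ O₂)  (commutative, associative,
  idempotent; a fold over a list equals one build from the union),
* **intersection**  T(O₁) & T(O₂) = T(O₁ ∩ O₂)  — empty whenever the two
  sets come from disjoint grid cells,
* **trimming**  planting a node rebuilds a full tree from exactly the
  occurrences below it.

Given a reference list of trees T₁…Tₙ (one per grid cell), the
**appearance frequency** of a node v is

    AF(v) = #{i : taxon(v) ∈ Tᵢ} / n ∈ [0, 1],

and ranking a tree orders each taxonomic level by AF descending. The
co-occurrence pipeline composes these: cells of a focal taxon → order-k
Chebyshev neighbourhood → one tree per cell → merged tree → AF ranking →
red-list filtering (substring name match) → coverage percentage and
equal-area (spherical Albers) cell-area statistics in km².

## Worked example

```python
from occutree.fixtures import tutorial_landscape
from occutree.tree import Tree

grid, backbone, t1_occs, t2_occs = tutorial_landscape(seed=0)
t1, t2 = Tree(t1_occs, backbone), Tree(t2_occs, backbone)

print(t1)                   # <LocalTree Of Life | Root: LUCA - n.count: 1062- >
print(t1.to_Animalia)       # <LocalTree | Kingdom: Animalia - n.count: 742- >

t3 = t1 + t2
for node in sorted(t3.classes, key=lambda n: n.taxon.name)[:3]:
    print(node)
# <LocalTree | Class: Agaricomycetes - n.count: 4- >
# <LocalTree | Class: Amphibia - n.count: 1- >
# <LocalTree | Class: Aves - n.count: 667- >

print(t1 & t2)              # <LocalTree Of Life | No record available: - n.count: 0- >
```

The two generated occurrence sets sit in disjoint grid cells, with
class-level totals fixed by the exact-count generator (t1: nine classes
summing to 1062 records; t2: five classes summing to 151). Addition
merges the class counts (e.g. Myxomycetes 46 + 112 = 158, and Aves 667
passes through unchanged since it occurs only in t1); intersection of
disjoint-cell trees is the empty tree.

The same flows are scriptable from the shell:

```bash
occutree fixtures --preset tutorial-t1t2 --outdir fx
occutree tree --backbone fx/backbone.csv \
  --occurrences fx/occurrences_t1.csv --occurrences fx/occurrences_t2.csv \
  --op merge --classes
occutree cooccur --backbone fx/backbone.csv --occurrences fx/occurrences_t1.csv \
  --bbox 0,0,1,1 --res 0.25 --focal-rank class --focal-name Mammalia \
  --order 1 --proj "+proj=aea +lat_1=14.5 +lat_2=32.5 +lat_0=24 +lon_0=-105" \
  --out report.json
```

## Layout

| module | contents |
| --- | --- |
| `occutree.taxonomy` | backbone, ranks, lineage resolution, occurrence parsing |
| `occutree.grid` | lattice cells, point-to-cell assignment, order-k neighbourhoods |
| `occutree.projection` | spherical Albers equal-area forward mapping, areas in km² |
| `occutree.graph` | in-process knowledge graph (typed edges, lazy traversals) |
| `occutree.tree` | local trees, the set algebra, AF ranking, graph exports |
| `occutree.raster` | multiband rasters: tiling, sampling, clipping, DEM products |
| `occutree.pipeline` | neighbourhood co-occurrence analysis with red-list filtering |
| `occutree.fixtures` | deterministic synthetic backbones, landscapes, rasters |
| `occutree.cli` | `occutree` command-line interface |

See `docs/methods.md` for the methods notes (assumptions, parameter
choices, numerical conventions, limitations).
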