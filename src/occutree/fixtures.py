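"""Deterministic synthetic data: backbones, occurrence landscapes, rasters.

Everything here is seeded and reproducible across platforms (placement
decisions are made with integer draws from ``numpy.random.default_rng``).
Two generator families exist:

* parametric generators (``make_backbone``, ``make_landscape``,
  ``make_raster``) for property and oracle tests, and
* the exact-count worked-example preset (:func:`tutorial_backbone`,
  :func:`tutorial_landscape`) whose per-class occurrence totals reproduce
  the printed class listings of two local trees (t1 and t2) in disjoint
  grid cells, so the tree-algebra results on them are checkable against
  the published listings.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ParameterError
from .grid import Cell, Grid, GridSpec, build_grid
from .raster import RasterGrid
from .taxonomy import Occurrence, TaxonRank, TaxonomyBackbone

#: printed class-level occurrence counts of the worked example's tree t1
T1_CLASS_COUNTS: dict[str, int] = {
    "Myxomycetes": 46,
    "Bryopsida": 99,
    "Amphibia": 1,
    "Aves": 667,
    "Reptilia": 2,
    "Mammalia": 70,
    "Liliopsida": 36,
    "Magnoliopsida": 139,
    "Insecta": 2,
}

#: printed class-level occurrence counts of the worked example's tree t2
T2_CLASS_COUNTS: dict[str, int] = {
    "Protosteliomycetes": 2,
    "Myxomycetes": 112,
    "Agaricomycetes": 4,
    "Liliopsida": 8,
    "Magnoliopsida": 25,
}

#: kingdom > phylum > class spine of the worked example's taxa
TUTORIAL_CLASSIFICATION: dict[str, dict[str, list[str]]] = {
    "Animalia": {
        "Chordata": ["Amphibia", "Aves", "Reptilia", "Mammalia"],
        "Arthropoda": ["Insecta"],
    },
    "Plantae": {
        "Bryophyta": ["Bryopsida"],
        "Magnoliophyta": ["Liliopsida", "Magnoliopsida"],
    },
    "Fungi": {
        "Basidiomycota": ["Agaricomycetes"],
    },
    "Protozoa": {
        "Mycetozoa": ["Myxomycetes", "Protosteliomycetes"],
    },
}


@dataclass
class FixtureSpec:
    """Parameters of a synthetic landscape.

    ``fanout`` gives children per node for ranks kingdom..species (7
    entries).  ``class_counts`` switches on exact-count mode: occurrences
    are dealt round-robin to the species of each named class until the
    requested class totals are hit, all inside ``target_cells`` (cell ids).
    Otherwise ``n_occurrences`` records are placed by the intensity model
    (``uniform``, or ``cluster`` around ``cluster_centres`` with normal
    ``dispersion`` in degrees).
    """

    seed: int = 0
    fanout: Sequence[int] = (2, 2, 2, 2, 2, 2, 2)
    grid: GridSpec = field(default_factory=lambda: GridSpec(0.0, 0.0, 1.0, 1.0, 0.1))
    n_occurrences: int = 100
    intensity: str = "uniform"
    cluster_centres: Sequence[tuple[float, float]] = ()
    dispersion: float = 0.05
    class_counts: Mapping[str, int] | None = None
    target_cells: Sequence[int] = ()

    def to_json(self) -> str:
        d = {k: (dict(v) if isinstance(v, Mapping) else (list(v) if isinstance(v, (tuple, list)) else v))
             for k, v in self.__dict__.items() if k != "grid"}
        d["grid"] = self.grid.__dict__.copy()
        return json.dumps(d, sort_keys=True)


# -- backbones ----------------------------------------------------------------

def make_backbone(fanout: Sequence[int] = (2, 2, 2, 2, 2, 2, 2)) -> TaxonomyBackbone:
    """Complete 8-rank tree with the given children-per-node counts.

    Names are deterministic: ``<rank-letter><path>`` such as ``c1.2`` for
    the second class under the first branch chain.
    """
    if len(fanout) != 7 or any(f < 1 for f in fanout):
        raise ParameterError("fanout needs 7 entries (kingdom..species), each >= 1")
    letters = "kpcofgs"
    backbone = TaxonomyBackbone()
    root = backbone.add_node("LUCA", TaxonRank.ROOT, None)
    frontier = [(root, "")]
    for depth, width in enumerate(fanout):
        rank = TaxonRank(depth + 1)
        nxt = []
        for parent, path in frontier:
            for i in range(1, width + 1):
                sub = f"{path}.{i}" if path else str(i)
                node = backbone.add_node(f"{letters[depth]}{sub}", rank, parent.id)
                nxt.append((node, sub))
        frontier = nxt
    return backbone


def tutorial_backbone(species_per_class: int = 3) -> TaxonomyBackbone:
    """Backbone holding the worked example's kingdoms/phyla/classes.

    Below class level the lineages are synthetic (one order, family, and
    genus per class; ``species_per_class`` species per genus) because the
    published listings only print counts down to class level.
    """
    backbone = TaxonomyBackbone()
    root = backbone.add_node("LUCA", TaxonRank.ROOT, None)
    for kingdom, phyla in TUTORIAL_CLASSIFICATION.items():
        knode = backbone.add_node(kingdom, TaxonRank.KINGDOM, root.id)
        for phylum, classes in phyla.items():
            pnode = backbone.add_node(phylum, TaxonRank.PHYLUM, knode.id)
            for cls in classes:
                cnode = backbone.add_node(cls, TaxonRank.CLASS, pnode.id)
                onode = backbone.add_node(f"{cls} order", TaxonRank.ORDER, cnode.id)
                fnode = backbone.add_node(f"{cls} family", TaxonRank.FAMILY, onode.id)
                gnode = backbone.add_node(f"{cls} genus", TaxonRank.GENUS, fnode.id)
                for i in range(1, species_per_class + 1):
                    backbone.add_node(f"{cls} species {i}", TaxonRank.SPECIES, gnode.id)
    return backbone


# -- landscapes ----------------------------------------------------------------

def _points_in_cell(cell: Cell, n: int, rng: np.random.Generator) -> list[tuple[float, float]]:
    w, s, e, nrth = cell.bounds
    lons = w + (e - w) * rng.integers(1, 1000, n) / 1000.0
    lats = s + (nrth - s) * rng.integers(1, 1000, n) / 1000.0
    return list(zip(lons.tolist(), lats.tolist()))


def exact_count_occurrences(
    backbone: TaxonomyBackbone,
    grid: Grid,
    class_counts: Mapping[str, int],
    target_cells: Sequence[int],
    seed: int = 0,
    start_id: int = 0,
) -> list[Occurrence]:
    """Occurrences whose per-class totals equal ``class_counts`` exactly.

    Records of each class are dealt round-robin over the class's species
    and placed at seeded positions inside ``target_cells`` (cycled).
    """
    if not target_cells:
        raise ParameterError("exact-count mode needs at least one target cell")
    rng = np.random.default_rng(seed)
    occurrences: list[Occurrence] = []
    next_id = start_id
    cells = [grid.cell(cid) for cid in target_cells]
    for ci, (cls_name, count) in enumerate(class_counts.items()):
        cls = backbone.pick_node(TaxonRank.CLASS, cls_name)
        species = backbone.species_under(cls.id)
        cell = cells[ci % len(cells)]
        for k, (lon, lat) in enumerate(_points_in_cell(cell, count, rng)):
            occurrences.append(
                Occurrence(next_id, species[k % len(species)].id, lon, lat)
            )
            next_id += 1
    return occurrences


def make_landscape(spec: FixtureSpec, backbone: TaxonomyBackbone | None = None
                   ) -> tuple[Grid, list[Occurrence], TaxonomyBackbone]:
    """Grid + occurrence set for ``spec`` (and the backbone used)."""
    grid = build_grid(spec.grid)
    if backbone is None:
        backbone = (tutorial_backbone() if spec.class_counts
                    else make_backbone(spec.fanout))
    if spec.class_counts is not None:
        occs = exact_count_occurrences(
            backbone, grid, spec.class_counts, spec.target_cells, spec.seed
        )
        return grid, occs, backbone

    rng = np.random.default_rng(spec.seed)
    species = [n for n in backbone if n.rank == TaxonRank.SPECIES]
    g = spec.grid
    occs = []
    for i in range(spec.n_occurrences):
        sp = species[int(rng.integers(0, len(species)))]
        if spec.intensity == "cluster" and spec.cluster_centres:
            cx, cy = spec.cluster_centres[int(rng.integers(0, len(spec.cluster_centres)))]
            lon = float(np.clip(cx + rng.normal(0, spec.dispersion), g.min_lon, g.max_lon))
            lat = float(np.clip(cy + rng.normal(0, spec.dispersion), g.min_lat, g.max_lat))
        else:
            lon = g.min_lon + (g.max_lon - g.min_lon) * int(rng.integers(0, 10000)) / 10000.0
            lat = g.min_lat + (g.max_lat - g.min_lat) * int(rng.integers(0, 10000)) / 10000.0
        occs.append(Occurrence(i, sp.id, lon, lat))
    return grid, occs, backbone


def tutorial_landscape(
    grid_spec: GridSpec | None = None,
    t1_cell: int = 0,
    t2_cell: int | None = None,
    seed: int = 0,
) -> tuple[Grid, TaxonomyBackbone, list[Occurrence], list[Occurrence]]:
    """The worked-example preset: t1 and t2 occurrence sets in disjoint cells.

    Returns (grid, backbone, t1_occurrences, t2_occurrences); the class
    totals of each set equal the printed listings, so a tree over t1 has
    root n.count 1062 and the merged tree reproduces the printed sums.
    """
    grid = build_grid(grid_spec or GridSpec(0.0, 0.0, 1.0, 1.0, 0.25))
    if t2_cell is None:
        t2_cell = len(grid) - 1
    if t1_cell == t2_cell:
        raise ParameterError("t1 and t2 must occupy disjoint cells")
    backbone = tutorial_backbone()
    t1 = exact_count_occurrences(backbone, grid, T1_CLASS_COUNTS, [t1_cell], seed)
    t2 = exact_count_occurrences(backbone, grid, T2_CLASS_COUNTS, [t2_cell],
                                 seed + 1, start_id=len(t1))
    return grid, backbone, t1, t2


# -- rasters -------------------------------------------------------------------

def make_raster(
    shape: tuple[int, int] = (20, 20),
    surface: str = "constant",
    *,
    west: float = 0.0,
    north: float = 10.0,
    resolution: float = 0.1,
    value: float = 1.0,
    gradient: tuple[float, float] = (1.0, 0.0),
    nbands: int = 1,
    seed: int = 0,
    name: str = "synthetic",
) -> RasterGrid:
    """Analytic or seeded-noise raster for derivative and aggregation tests.

    Surfaces: ``constant`` (= value), ``plane`` (value + gradient . (x_m,
    y_m) with metre offsets from the top-left pixel centre), ``cone``
    (value - distance from centre * |gradient|), ``sinusoid``, ``noise``.
    """
    from .raster import METRES_PER_DEGREE

    nr, nc = shape
    rows, cols = np.mgrid[0:nr, 0:nc]
    # metre offsets of pixel centres from the top-left pixel centre
    lat0 = north - 0.5 * resolution
    x = cols * resolution * METRES_PER_DEGREE * np.cos(np.radians(lat0))
    y = -rows * resolution * METRES_PER_DEGREE  # northward positive
    gx, gy = gradient
    if surface == "constant":
        data = np.full(shape, float(value))
    elif surface == "plane":
        data = value + gx * x + gy * y
    elif surface == "cone":
        cx, cy = x.mean(), y.mean()
        data = value - np.hypot(x - cx, y - cy) * float(np.hypot(gx, gy))
    elif surface == "sinusoid":
        data = value * np.sin(2 * np.pi * cols / nc) * np.cos(2 * np.pi * rows / nr)
    elif surface == "noise":
        rng = np.random.default_rng(seed)
        stack = rng.integers(0, 1000, size=(nbands, nr, nc)) / 10.0
        return RasterGrid(stack, west, north, resolution, name=name)
    else:
        raise ParameterError(f"unknown surface {surface!r}")
    stack = np.broadcast_to(data, (nbands, nr, nc)).copy()
    return RasterGrid(stack, west, north, resolution, name=name)


def make_redlist(
    backbone: TaxonomyBackbone,
    n_listed: int,
    seed: int = 0,
    categories: Sequence[str] = ("Critically Endangered", "Endangered", "Vulnerable"),
):
    """Red-list entries drawn from the backbone's species (seeded, no repeats)."""
    from .pipeline import RedListEntry

    species = sorted(
        (n for n in backbone if n.rank == TaxonRank.SPECIES), key=lambda n: n.id
    )
    if n_listed > len(species):
        raise ParameterError("more listed species requested than exist")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(species), size=n_listed, replace=False)
    return [
        RedListEntry(species[int(i)].name, categories[int(i) % len(categories)])
        for i in sorted(chosen)
    ]
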