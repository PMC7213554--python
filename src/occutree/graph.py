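"""In-process knowledge graph joining taxa, occurrences, and grid cells.

Node classes are taxa (linked by IS_PARENT_OF), occurrence records, and
lattice cells; relations are IS_IN / IS_CONTAINED_IN (occurrence -> its
containing cell, and the derived species -> cell "recorded here" edge) and
IS_NEIGHBOUR_OF (lattice adjacency).  Traversal primitives are lazy:
constructing one performs no edge expansion until iterated, and iteration
order is deterministic (sorted ids).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import networkx as nx

from .grid import Cell, Grid
from .taxonomy import Occurrence, TaxonNode, TaxonomyBackbone

logger = logging.getLogger(__name__)


@dataclass
class IngestReport:
    """Tally of an ingest pass."""

    total: int = 0
    in_grid: int = 0
    out_of_grid: int = 0
    per_cell: dict[int, int] = field(default_factory=dict)


class KnowledgeGraph:
    """Typed multigraph over one backbone, one grid, and ingested occurrences."""

    def __init__(self, backbone: TaxonomyBackbone, grid: Grid) -> None:
        self.backbone = backbone
        self.grid = grid
        self.occurrences: dict[int, Occurrence] = {}
        self._occ_cell: dict[int, int] = {}          # IS_IN: occurrence -> cell id
        self._cell_occs: dict[int, list[int]] = {}    # reverse index
        self._species_cells: dict[int, set[int]] = {} # derived species -> cells
        self._out_of_grid: set[int] = set()
        self.report = IngestReport()

    # -- ingest -------------------------------------------------------------

    def ingest(self, occurrences: Iterable[Occurrence]) -> IngestReport:
        """Materialize IS_IN edges (and derived species->cell edges).

        Out-of-extent records are flagged, counted, and kept queryable; they
        never raise.
        """
        for occ in occurrences:
            self.occurrences[occ.id] = occ
            self.report.total += 1
            cell = self.grid.cell_for_point(occ.longitude, occ.latitude)
            if cell is None:
                self._out_of_grid.add(occ.id)
                self.report.out_of_grid += 1
                logger.info("occurrence %s outside grid extent", occ.id)
                continue
            self._occ_cell[occ.id] = cell.id
            self._cell_occs.setdefault(cell.id, []).append(occ.id)
            self._species_cells.setdefault(occ.species_id, set()).add(cell.id)
            self.report.in_grid += 1
            self.report.per_cell[cell.id] = self.report.per_cell.get(cell.id, 0) + 1
        return self.report

    # -- traversals (lazy) ---------------------------------------------------

    def cell_of(self, occurrence_id: int) -> Cell | None:
        cid = self._occ_cell.get(occurrence_id)
        return None if cid is None else self.grid.cell(cid)

    def occurrences_in_cell(self, cell: Cell | int) -> Iterator[Occurrence]:
        """All occurrences with an IS_IN edge to ``cell``, ordered by id."""
        cid = cell.id if isinstance(cell, Cell) else cell

        def gen() -> Iterator[Occurrence]:
            for oid in sorted(self._cell_occs.get(cid, ())):
                yield self.occurrences[oid]

        return gen()

    def _species_ids_under(self, taxon: TaxonNode) -> list[int]:
        return [s.id for s in self.backbone.species_under(taxon.id)]

    def cells_with_taxon(self, taxon: TaxonNode) -> Iterator[Cell]:
        """Distinct cells holding >= 1 occurrence whose lineage passes
        through ``taxon``, ordered by cell id (lazy)."""

        def gen() -> Iterator[Cell]:
            cell_ids: set[int] = set()
            for sid in self._species_ids_under(taxon):
                cell_ids |= self._species_cells.get(sid, set())
            for cid in sorted(cell_ids):
                yield self.grid.cell(cid)

        return gen()

    def taxon_occurrence_filter(
        self, cells: Iterable[Cell | int], taxon: TaxonNode | None = None
    ) -> list[Occurrence]:
        """Occurrences inside any of ``cells`` whose lineage passes through
        ``taxon`` (all occurrences when ``taxon`` is None); distinct, by id."""
        species: set[int] | None = (
            None if taxon is None else set(self._species_ids_under(taxon))
        )
        ids: set[int] = set()
        for cell in cells:
            cid = cell.id if isinstance(cell, Cell) else cell
            for oid in self._cell_occs.get(cid, ()):
                if species is None or self.occurrences[oid].species_id in species:
                    ids.add(oid)
        return [self.occurrences[i] for i in sorted(ids)]

    def neighbour_cells(
        self, cells: Iterable[Cell], order: int = 1, with_center: bool = True,
        deduplicate: bool = True,
    ) -> list[Cell]:
        """Union (or concatenation) of order-k neighbourhoods of ``cells``.

        ``deduplicate=False`` reproduces a plain flatten of the per-cell
        neighbour lists (overlaps repeated), for compatibility with
        list-reduce workflows; duplicates never change merged trees because
        the algebra is set-based.
        """
        if deduplicate:
            ids: set[int] = set()
            for cell in cells:
                ids.update(c.id for c in self.grid.neighbourhood(cell, order, with_center))
            return [self.grid.cell(cid) for cid in sorted(ids)]
        out: list[Cell] = []
        for cell in cells:
            out.extend(self.grid.neighbourhood(cell, order, with_center))
        return out

    # -- export ---------------------------------------------------------------

    def to_networkx(self, neighbour_edges: bool = False) -> nx.MultiDiGraph:
        """Typed multigraph export (GraphML-ready).

        ``neighbour_edges`` adds symmetric IS_NEIGHBOUR_OF edges between the
        occupied cells (the full lattice would be quadratic and is implicit
        in the grid indices).
        """
        g = nx.MultiDiGraph()
        used_cells = sorted(self._cell_occs)
        for cid in used_cells:
            cell = self.grid.cell(cid)
            g.add_node(f"cell:{cid}", kind="Cell", row=cell.row, col=cell.col)
        taxa_seen: set[int] = set()
        for occ in self.occurrences.values():
            g.add_node(f"occ:{occ.id}", kind="Occurrence",
                       longitude=occ.longitude, latitude=occ.latitude)
            for node in self.backbone.lineage_of(occ.species_id):
                if node.id not in taxa_seen:
                    g.add_node(f"taxon:{node.id}", kind="Taxon",
                               name=node.name, rank=node.rank.label)
                    taxa_seen.add(node.id)
                    if node.parent_id is not None:
                        g.add_edge(f"taxon:{node.parent_id}", f"taxon:{node.id}",
                                   label="IS_PARENT_OF")
            cid = self._occ_cell.get(occ.id)
            if cid is not None:
                g.add_edge(f"occ:{occ.id}", f"cell:{cid}", label="IS_IN")
                g.add_edge(f"occ:{occ.id}", f"cell:{cid}", label="IS_CONTAINED_IN")
        for sid, cids in sorted(self._species_cells.items()):
            for cid in sorted(cids):
                g.add_edge(f"taxon:{sid}", f"cell:{cid}", label="IS_IN")
        if neighbour_edges:
            used = set(used_cells)
            for cid in used_cells:
                for nb in self.grid.neighbourhood(self.grid.cell(cid), 1, with_center=False):
                    if nb.id in used:
                        g.add_edge(f"cell:{cid}", f"cell:{nb.id}",
                                   label="IS_NEIGHBOUR_OF")
        return g

    def write_graphml(self, path, **kwargs) -> None:
        nx.write_graphml(self.to_networkx(**kwargs), path)


def ingest(
    backbone: TaxonomyBackbone, occurrences: Iterable[Occurrence], grid: Grid
) -> KnowledgeGraph:
    """Build a knowledge graph and ingest ``occurrences`` in one call."""
    kg = KnowledgeGraph(backbone, grid)
    kg.ingest(occurrences)
    return kg
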