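"""Taxonomic backbone: the IS_PARENT_OF hierarchy and occurrence records.

The backbone is a fixed eight-rank rooted tree (root "LUCA" at depth 0 down
to species at depth 7), the classification against which presence-only
occurrence records are aggregated.  Lineage resolution (species -> root) is
the primitive every tree construction builds on.
"""
from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

from .errors import (
    AmbiguousTaxonError,
    BackboneStructureError,
    UnknownTaxonError,
)

logger = logging.getLogger(__name__)

ROOT_NAME = "LUCA"


class TaxonRank(IntEnum):
    """Depth level in the backbone: 0 for root, 7 for species."""

    ROOT = 0
    KINGDOM = 1
    PHYLUM = 2
    CLASS = 3
    ORDER = 4
    FAMILY = 5
    GENUS = 6
    SPECIES = 7

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "TaxonRank":
        try:
            return cls[label.strip().upper()]
        except KeyError:
            raise ValueError(f"unknown taxonomic rank {label!r}") from None


#: rank labels ordered root -> species
RANK_LABELS: tuple[str, ...] = tuple(r.label for r in TaxonRank)

#: occurrence-file lineage columns ordered species -> kingdom
LINEAGE_COLUMNS: tuple[str, ...] = (
    "species", "genus", "family", "order", "class", "phylum", "kingdom",
)

DEFAULT_COLUMN_MAP: dict[str, str] = {
    **{c: c for c in LINEAGE_COLUMNS},
    "longitude": "decimalLongitude",
    "latitude": "decimalLatitude",
    "event_date": "eventDate",
}


@dataclass(frozen=True)
class TaxonNode:
    """One node of the backbone; ``parent_id`` is ``None`` only for the root."""

    id: int
    name: str
    rank: TaxonRank
    parent_id: int | None

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.rank.label.capitalize()}: {self.name}"


@dataclass(frozen=True)
class Occurrence:
    """A presence-only record: species identity + WGS84 point + date.

    Identity for set algebra is the record id: two records at the same
    point are distinct observations.
    """

    id: int
    species_id: int
    longitude: float
    latitude: float
    event_date: str | None = None
    attributes: Mapping[str, str] = field(default_factory=dict, compare=False, hash=False)


@dataclass
class ParseReport:
    """Outcome of parsing an occurrence file."""

    total_rows: int = 0
    accepted: int = 0
    rejected_bounds: int = 0
    rejected_unresolved: int = 0
    placeholders_created: int = 0

    @property
    def rejected(self) -> int:
        return self.rejected_bounds + self.rejected_unresolved


class TaxonomyBackbone:
    """Rooted eight-rank taxonomy with a (rank, lowercased name) index.

    Every non-root node's parent sits exactly one rank above it, so
    ``lineage_of`` always returns ``rank.ordinal + 1`` nodes.
    """

    def __init__(self) -> None:
        self._nodes: dict[int, TaxonNode] = {}
        self._children: dict[int, list[int]] = {}
        self._by_name: dict[tuple[TaxonRank, str], list[int]] = {}
        self._root_id: int | None = None
        self._next_id = 0

    # -- construction -----------------------------------------------------

    def _register(self, node: TaxonNode) -> TaxonNode:
        if node.id in self._nodes:
            raise BackboneStructureError(f"duplicate taxon id {node.id}")
        self._nodes[node.id] = node
        self._children.setdefault(node.id, [])
        if node.parent_id is None:
            if self._root_id is not None:
                raise BackboneStructureError("more than one root node")
            self._root_id = node.id
        else:
            self._children.setdefault(node.parent_id, []).append(node.id)
        self._by_name.setdefault((node.rank, node.name.lower()), []).append(node.id)
        self._next_id = max(self._next_id, node.id + 1)
        return node

    def add_node(
        self, name: str, rank: TaxonRank, parent_id: int | None, id: int | None = None
    ) -> TaxonNode:
        """Append a node (used by loaders and the occurrence parser)."""
        if parent_id is not None:
            parent = self.node(parent_id)
            if parent.rank != rank - 1:
                raise BackboneStructureError(
                    f"rank step violation: {name!r} ({rank.label}) under "
                    f"{parent.name!r} ({parent.rank.label})"
                )
        node = TaxonNode(self._next_id if id is None else id, name, rank, parent_id)
        return self._register(node)

    def _validate(self) -> None:
        if self._root_id is None:
            raise BackboneStructureError("no root node (node without parent)")
        root = self._nodes[self._root_id]
        if root.rank != TaxonRank.ROOT:
            raise BackboneStructureError("root node must have rank 'root'")
        # referential integrity + rank steps
        for node in self._nodes.values():
            if node.parent_id is None:
                continue
            if node.parent_id not in self._nodes:
                raise BackboneStructureError(
                    f"node {node.id} references missing parent {node.parent_id}"
                )
            parent = self._nodes[node.parent_id]
            if parent.rank != node.rank - 1:
                raise BackboneStructureError(
                    f"rank step violation at node {node.id} ({node.rank.label} "
                    f"under {parent.rank.label})"
                )
        # reachability (also detects cycles: unreachable components)
        seen: set[int] = set()
        stack = [self._root_id]
        while stack:
            nid = stack.pop()
            seen.add(nid)
            stack.extend(self._children.get(nid, ()))
        if len(seen) != len(self._nodes):
            raise BackboneStructureError(
                f"{len(self._nodes) - len(seen)} node(s) unreachable from root "
                "(cycle or disconnected component)"
            )

    # -- queries ----------------------------------------------------------

    @property
    def root(self) -> TaxonNode:
        assert self._root_id is not None
        return self._nodes[self._root_id]

    def __len__(self) -> int:
        return len(self._nodes)

    def __contains__(self, node_id: int) -> bool:
        return node_id in self._nodes

    def __iter__(self) -> Iterator[TaxonNode]:
        return iter(self._nodes.values())

    def node(self, node_id: int) -> TaxonNode:
        try:
            return self._nodes[node_id]
        except KeyError:
            raise UnknownTaxonError(f"unknown taxon id {node_id}") from None

    def children_of(self, node_id: int) -> list[TaxonNode]:
        return [self._nodes[c] for c in self._children.get(node_id, ())]

    def lineage_of(self, node_id: int) -> list[TaxonNode]:
        """Path of nodes from the root down to ``node_id`` (inclusive)."""
        node = self.node(node_id)
        path = [node]
        while node.parent_id is not None:
            node = self.node(node.parent_id)
            path.append(node)
        path.reverse()
        return path

    def pick_node(self, rank: TaxonRank | str, name: str) -> TaxonNode:
        """The unique node of ``rank`` whose name equals ``name`` (case-insensitive)."""
        if isinstance(rank, str):
            rank = TaxonRank.from_label(rank)
        ids = self._by_name.get((rank, name.lower()), [])
        if not ids:
            raise UnknownTaxonError(f"no {rank.label} named {name!r}")
        if len(ids) > 1:
            cands = ", ".join(
                f"{i} (under {self.node(self.node(i).parent_id).name})" for i in ids
            )
            raise AmbiguousTaxonError(
                f"{len(ids)} nodes of rank {rank.label} named {name!r}: {cands}"
            )
        return self._nodes[ids[0]]

    def find_nodes(self, rank: TaxonRank, name: str) -> list[TaxonNode]:
        return [self._nodes[i] for i in self._by_name.get((rank, name.lower()), [])]

    def descendants(self, node_id: int) -> Iterator[TaxonNode]:
        """All strict descendants of a node, preorder."""
        stack = list(reversed(self._children.get(node_id, [])))
        while stack:
            nid = stack.pop()
            yield self._nodes[nid]
            stack.extend(reversed(self._children.get(nid, [])))

    def species_under(self, node_id: int) -> list[TaxonNode]:
        node = self.node(node_id)
        if node.rank == TaxonRank.SPECIES:
            return [node]
        return [d for d in self.descendants(node_id) if d.rank == TaxonRank.SPECIES]

    def count_by_rank(self) -> dict[str, int]:
        counts = {r.label: 0 for r in TaxonRank}
        for node in self._nodes.values():
            counts[node.rank.label] += 1
        return counts


# -- loaders ---------------------------------------------------------------

def load_backbone(rows: Iterable[Sequence] | pd.DataFrame) -> TaxonomyBackbone:
    """Build a backbone from ``(id, name, rank, parent_id)`` rows.

    The rows must form a single rooted tree with no rank skipping; the root
    row has an empty/null parent_id and rank ``root``.
    """
    if isinstance(rows, pd.DataFrame):
        rows = rows[["id", "name", "rank", "parent_id"]].itertuples(index=False)
    backbone = TaxonomyBackbone()
    for raw in rows:
        nid, name, rank, parent = raw
        parent_id: int | None
        if parent is None or parent == "" or (isinstance(parent, float) and pd.isna(parent)):
            parent_id = None
        else:
            parent_id = int(parent)
        backbone._register(
            TaxonNode(int(nid), str(name), TaxonRank.from_label(str(rank)), parent_id)
        )
    backbone._validate()
    return backbone


def read_backbone_csv(path_or_buf) -> TaxonomyBackbone:
    """Read a backbone from CSV with columns ``id,name,rank,parent_id``."""
    df = pd.read_csv(path_or_buf, dtype={"id": int, "name": str, "rank": str})
    return load_backbone(df)


def write_backbone_csv(backbone: TaxonomyBackbone, path_or_buf) -> None:
    rows = [
        {"id": n.id, "name": n.name, "rank": n.rank.label,
         "parent_id": "" if n.parent_id is None else n.parent_id}
        for n in sorted(backbone, key=lambda n: n.id)
    ]
    pd.DataFrame(rows, columns=["id", "name", "rank", "parent_id"]).to_csv(
        path_or_buf, index=False
    )


# -- occurrence parsing ----------------------------------------------------

def _resolve_species(
    backbone: TaxonomyBackbone,
    lineage_names: dict[str, str],
    report: ParseReport,
) -> TaxonNode | None:
    """Resolve (or create) the species node for one occurrence row.

    If the species name is unknown but the row carries lineage columns, the
    missing chain is created top-down; gaps in the supplied lineage are
    filled with placeholder nodes named ``incertae:<child-name>`` so the
    one-rank-per-step invariant holds.
    """
    species_name = lineage_names.get("species", "").strip()
    if not species_name:
        return None
    matches = backbone.find_nodes(TaxonRank.SPECIES, species_name)
    if len(matches) == 1:
        return matches[0]
    if len(matches) > 1:
        # disambiguate through the supplied genus, if any
        genus = lineage_names.get("genus", "").strip().lower()
        if genus:
            for m in matches:
                if backbone.node(m.parent_id).name.lower() == genus:
                    return m
        return matches[0]
    # create the lineage top-down from the deepest resolvable ancestor
    if not any(lineage_names.get(c, "").strip() for c in LINEAGE_COLUMNS[1:]):
        return None
    parent = backbone.root
    for rank in list(TaxonRank)[1:]:  # kingdom .. species
        name = lineage_names.get(rank.label, "").strip()
        if not name:
            # find the next named level to synthesize a placeholder for
            deeper = next(
                (lineage_names[r.label].strip() for r in list(TaxonRank)[rank:]
                 if lineage_names.get(r.label, "").strip()),
                species_name,
            )
            name = f"incertae:{deeper}"
            report.placeholders_created += 1
            logger.info("placeholder %s created at rank %s", name, rank.label)
        existing = [
            n for n in backbone.find_nodes(rank, name) if n.parent_id == parent.id
        ]
        parent = existing[0] if existing else backbone.add_node(name, rank, parent.id)
    return parent


def parse_occurrences(
    stream,
    backbone: TaxonomyBackbone,
    column_map: Mapping[str, str] | None = None,
    start_id: int = 0,
) -> tuple[list[Occurrence], ParseReport]:
    """Parse a delimited occurrence file against a backbone.

    ``stream`` is a path or open text buffer of UTF-8 CSV with a header
    row.  Rows with coordinates outside WGS84 bounds, or whose species
    cannot be resolved (and that carry no lineage columns), are rejected
    and counted in the report rather than raising.  Ids are assigned
    sequentially from ``start_id`` (occurrence identity for the tree
    algebra), so pass disjoint ranges when loading several files.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(stream, dtype=str, keep_default_na=False)
    for key in ("longitude", "latitude"):
        if cmap[key] not in df.columns:
            raise KeyError(f"mapped column {cmap[key]!r} not in file header")

    report = ParseReport(total_rows=len(df))
    occurrences: list[Occurrence] = []
    next_id = start_id
    for row in df.itertuples(index=False):
        rowd = dict(zip(df.columns, row))
        try:
            lon = float(rowd[cmap["longitude"]])
            lat = float(rowd[cmap["latitude"]])
        except (TypeError, ValueError):
            report.rejected_bounds += 1
            continue
        if not (-180.0 <= lon <= 180.0 and -90.0 <= lat <= 90.0):
            report.rejected_bounds += 1
            continue
        lineage_names = {
            c: rowd.get(cmap.get(c, c), "") for c in LINEAGE_COLUMNS
        }
        species = _resolve_species(backbone, lineage_names, report)
        if species is None:
            report.rejected_unresolved += 1
            logger.warning("rejected row with unresolvable species %r",
                           lineage_names.get("species"))
            continue
        date = rowd.get(cmap["event_date"], "") or None
        occurrences.append(Occurrence(next_id, species.id, lon, lat, date))
        next_id += 1
        report.accepted += 1
    return occurrences, report


def write_occurrences_csv(
    occurrences: Iterable[Occurrence],
    backbone: TaxonomyBackbone,
    path_or_buf,
) -> None:
    """Write occurrences with full lineage columns (round-trips through the parser)."""
    own = isinstance(path_or_buf, (str, bytes)) or hasattr(path_or_buf, "__fspath__")
    handle = open(path_or_buf, "w", newline="") if own else path_or_buf
    try:
        writer = csv.writer(handle)
        writer.writerow(list(DEFAULT_COLUMN_MAP.values()))
        for occ in occurrences:
            lineage = {n.rank.label: n.name for n in backbone.lineage_of(occ.species_id)}
            writer.writerow(
                [lineage.get(c, "") for c in LINEAGE_COLUMNS]
                + [repr(occ.longitude), repr(occ.latitude), occ.event_date or ""]
            )
    finally:
        if own:
            handle.close()
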