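"""Local taxonomic trees (trees of life) and their set algebra.

A :class:`Tree` aggregates a set of occurrence records by taxonomy: the
root is always LUCA, internal nodes are the taxa on the records' lineages,
and each node carries ``n_count``, the number of occurrence records in its
subtree.  The algebra is set algebra on the underlying occurrence ids:

* ``a + b`` (merge) builds the tree over the union of occurrence sets,
* ``a & b`` (intersect) over the intersection — empty whenever the
  operands come from disjoint grid cells,
* planting a node rebuilds a full tree from exactly the occurrences below
  it (trimming).

Appearance frequency (AF) of a node against a reference list of trees
(typically one per grid cell) is the fraction of reference trees that
contain the node's taxon; ``rank_levels`` orders each rank's accessor list
by AF descending.
"""
from __future__ import annotations

import logging
import re
from typing import Iterable, Iterator, Sequence

import networkx as nx
import numpy as np
from shapely.ops import unary_union

from .errors import (
    AlgebraError,
    AmbiguousTaxonError,
    ParameterError,
    StateError,
    UnknownTaxonError,
)
from .grid import Cell, Grid
from .taxonomy import Occurrence, TaxonNode, TaxonRank, TaxonomyBackbone

logger = logging.getLogger(__name__)

_SANITIZE = re.compile(r"\W+")


def _sanitize(name: str) -> str:
    return _SANITIZE.sub("_", name).strip("_")


class LocalTree:
    """One node of a local taxonomic tree with its subtree.

    Children keep first-seen occurrence order; ``to_<TaxonName>`` attribute
    access navigates to the child of that (sanitized) name, mirroring the
    accessor style used for interactive exploration.
    """

    __slots__ = ("taxon", "children", "_species_ids", "n_count", "af", "_nav")

    def __init__(self, taxon: TaxonNode) -> None:
        self.taxon = taxon
        self.children: list[LocalTree] = []
        self._species_ids: set[int] = set()  # occurrence ids, species nodes only
        self.n_count: int = 0
        self.af: float | None = None
        self._nav: dict[str, list[LocalTree]] = {}

    # -- structure ---------------------------------------------------------

    def _child_for(self, taxon: TaxonNode) -> "LocalTree":
        key = _sanitize(taxon.name)
        for child in self._nav.get(key, ()):
            if child.taxon.id == taxon.id:
                return child
        child = LocalTree(taxon)
        self.children.append(child)
        self._nav.setdefault(key, []).append(child)
        return child

    def walk(self) -> Iterator["LocalTree"]:
        """Preorder traversal of the subtree (self first)."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    @property
    def occurrence_ids(self) -> set[int]:
        """Ids of all occurrence records reachable below this node."""
        if self.taxon.rank == TaxonRank.SPECIES:
            return set(self._species_ids)
        out: set[int] = set()
        for node in self.walk():
            out |= node._species_ids
        return out

    def _refresh_counts(self) -> int:
        if self.taxon.rank == TaxonRank.SPECIES:
            self.n_count = len(self._species_ids)
        else:
            self.n_count = sum(c._refresh_counts() for c in self.children)
        return self.n_count

    # -- navigation ---------------------------------------------------------

    def __getattr__(self, name: str):
        if name.startswith("to_"):
            key = name[3:]
            matches = self._nav.get(key, [])
            if len(matches) == 1:
                return matches[0]
            if len(matches) > 1:
                raise AmbiguousTaxonError(
                    f"{len(matches)} children sanitize to {key!r} under "
                    f"{self.taxon.name!r}"
                )
            raise UnknownTaxonError(
                f"no child named {key!r} under {self.taxon.name!r}"
            )
        raise AttributeError(name)

    def __repr__(self) -> str:
        af = "" if self.af is None else f" | AF: {self.af:g}"
        if self.taxon.rank == TaxonRank.ROOT:
            if self.n_count == 0:
                return "<LocalTree Of Life | No record available: - n.count: 0- >"
            return f"<LocalTree Of Life | Root: {self.taxon.name} - n.count: {self.n_count}-{af} >"
        rank = self.taxon.rank.label.capitalize()
        return f"<LocalTree | {rank}: {self.taxon.name} - n.count: {self.n_count}-{af} >"


class Tree:
    """Handle over a local taxonomic tree built from a set of occurrences.

    Exposes rank accessors (``kingdoms`` … ``species``), the set algebra
    (``+``, ``&``), trimming (:meth:`plant`), appearance-frequency ranking,
    and graph exports.
    """

    def __init__(
        self,
        occurrences: Iterable[Occurrence],
        backbone: TaxonomyBackbone,
    ) -> None:
        self.backbone = backbone
        self.root = LocalTree(backbone.root)
        self._occurrences: dict[int, Occurrence] = {}
        self._rank_lists: dict[TaxonRank, list[LocalTree]] | None = None
        self._taxa: frozenset[int] | None = None
        self._af_set = False
        rejected = 0
        for occ in occurrences:
            if occ.id in self._occurrences:
                continue  # set semantics: ids are identity
            try:
                species = backbone.node(occ.species_id)
            except UnknownTaxonError:
                rejected += 1
                logger.warning("occurrence %s: unknown species id %s", occ.id, occ.species_id)
                continue
            if species.rank != TaxonRank.SPECIES:
                rejected += 1
                logger.warning("occurrence %s: taxon %s is not species rank", occ.id, species.name)
                continue
            node = self.root
            for taxon in backbone.lineage_of(species.id)[1:]:
                node = node._child_for(taxon)
            node._species_ids.add(occ.id)
            self._occurrences[occ.id] = occ
        self.rejected = rejected
        self.root._refresh_counts()

    # -- basic queries ------------------------------------------------------

    @property
    def n_count(self) -> int:
        return self.root.n_count

    @property
    def is_empty(self) -> bool:
        return self.root.n_count == 0

    @property
    def occurrences(self) -> list[Occurrence]:
        return [self._occurrences[i] for i in sorted(self._occurrences)]

    @property
    def occurrence_ids(self) -> set[int]:
        return set(self._occurrences)

    def taxa(self) -> frozenset[int]:
        """Ids of all taxa present in this tree (cached; trees are immutable)."""
        if self._taxa is None:
            self._taxa = frozenset(n.taxon.id for n in self.root.walk())
        return self._taxa

    def nodes_at(self, rank: TaxonRank) -> list[LocalTree]:
        if self._rank_lists is None:
            lists: dict[TaxonRank, list[LocalTree]] = {r: [] for r in TaxonRank}
            for node in self.root.walk():
                lists[node.taxon.rank].append(node)
            self._rank_lists = lists
        return self._rank_lists[rank]

    kingdoms = property(lambda self: self.nodes_at(TaxonRank.KINGDOM))
    phyla = property(lambda self: self.nodes_at(TaxonRank.PHYLUM))
    classes = property(lambda self: self.nodes_at(TaxonRank.CLASS))
    orders = property(lambda self: self.nodes_at(TaxonRank.ORDER))
    families = property(lambda self: self.nodes_at(TaxonRank.FAMILY))
    genera = property(lambda self: self.nodes_at(TaxonRank.GENUS))
    species = property(lambda self: self.nodes_at(TaxonRank.SPECIES))

    def __getattr__(self, name: str):
        if name.startswith("to_"):
            return getattr(self.root, name)
        raise AttributeError(name)

    def __repr__(self) -> str:
        return repr(self.root)

    def __len__(self) -> int:
        return self.n_count

    # -- geometry -----------------------------------------------------------

    def cells_of(self, grid: Grid) -> list[Cell]:
        """Distinct grid cells containing this tree's occurrences, by id."""
        ids = {
            cell.id
            for occ in self._occurrences.values()
            if (cell := grid.cell_for_point(occ.longitude, occ.latitude)) is not None
        }
        return [grid.cell(cid) for cid in sorted(ids)]

    def geometry(self, grid: Grid):
        """Union polygon of the containing cells (the tree's geometric feature)."""
        return unary_union([c.polygon for c in self.cells_of(grid)])

    # -- algebra ------------------------------------------------------------

    def __add__(self, other: "Tree") -> "Tree":
        return merge(self, other)

    def __and__(self, other: "Tree") -> "Tree":
        return intersect(self, other)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Tree):
            return NotImplemented
        return (
            self.backbone is other.backbone
            and self.occurrence_ids == other.occurrence_ids
        )

    def __hash__(self) -> int:  # identity by occurrence set
        return hash(frozenset(self._occurrences))

    def plant(self, node: LocalTree) -> "Tree":
        """Rebuild a full tree from exactly the occurrences under ``node``
        (the trimming operation); the new root is again LUCA with the single
        surviving lineage spine.
        """
        ids = node.occurrence_ids
        return Tree((self._occurrences[i] for i in sorted(ids)), self.backbone)

    def plant_at(self, *path: str) -> "Tree":
        """Navigate ``path`` of taxon names from the root and plant there."""
        node = self.root
        for name in path:
            node = getattr(node, f"to_{_sanitize(name)}")
        return self.plant(node)

    # -- appearance frequency ------------------------------------------------

    def count_node_frequencies_on_list(self, reference: Sequence["Tree"]) -> "Tree":
        """Set every node's appearance frequency against ``reference`` trees.

        ``af(v)`` = (number of reference trees whose node set contains v's
        taxon) / len(reference).  Returns self (mutated).
        """
        if not reference:
            raise ParameterError("reference tree list must be non-empty")
        n = len(reference)
        taxa_sets = [t.taxa() for t in reference]
        for node in self.root.walk():
            node.af = sum(node.taxon.id in s for s in taxa_sets) / n
        self._af_set = True
        return self

    def rank_levels(self) -> "Tree":
        """Sort each rank accessor list by (AF descending, name ascending)."""
        if not self._af_set:
            raise StateError(
                "appearance frequencies unset; call count_node_frequencies_on_list first"
            )
        for rank in TaxonRank:
            self.nodes_at(rank).sort(key=lambda nd: (-(nd.af or 0.0), nd.taxon.name))
        return self

    # -- exports ------------------------------------------------------------

    def to_networkx(self, depth_level: int = 7, directed: bool = False) -> nx.Graph:
        """Graph of the tree down to ``depth_level`` (0 root … 7 species)."""
        if not 0 <= depth_level <= 7:
            raise ParameterError(f"depth_level must be in 0..7, got {depth_level}")
        g: nx.Graph = nx.DiGraph() if directed else nx.Graph()
        for node in self.root.walk():
            if node.taxon.rank > depth_level:
                continue
            g.add_node(
                node.taxon.id,
                name=node.taxon.name,
                rank=node.taxon.rank.label,
                n_count=node.n_count,
                af=float("nan") if node.af is None else node.af,
            )
            for child in node.children:
                if child.taxon.rank <= depth_level:
                    g.add_edge(node.taxon.id, child.taxon.id)
        return g

    def to_adjacency(
        self, depth_level: int = 7, undirected: bool = True
    ) -> tuple[np.ndarray, list[LocalTree]]:
        """0/1 adjacency matrix over the tree nodes with rank <= depth_level.

        Returns the matrix and the node ordering (preorder).  ``undirected``
        symmetricizes parent-child entries.
        """
        if not 0 <= depth_level <= 7:
            raise ParameterError(f"depth_level must be in 0..7, got {depth_level}")
        nodes = [n for n in self.root.walk() if n.taxon.rank <= depth_level]
        index = {n.taxon.id: i for i, n in enumerate(nodes)}
        mat = np.zeros((len(nodes), len(nodes)), dtype=np.int8)
        for node in nodes:
            for child in node.children:
                if child.taxon.rank <= depth_level:
                    mat[index[node.taxon.id], index[child.taxon.id]] = 1
                    if undirected:
                        mat[index[child.taxon.id], index[node.taxon.id]] = 1
        return mat, nodes

    def write_graphml(self, path, depth_level: int = 7) -> None:
        g = self.to_networkx(depth_level=depth_level, directed=True)
        # GraphML cannot carry NaN portably; drop unset AF attributes
        for _, data in g.nodes(data=True):
            if data.get("af") != data.get("af"):
                del data["af"]
        nx.write_graphml(g, path)


# -- module-level operation wrappers ---------------------------------------

def build_tree(occurrences: Iterable[Occurrence], backbone: TaxonomyBackbone) -> Tree:
    """Aggregate occurrences into a local taxonomic tree rooted at LUCA."""
    return Tree(occurrences, backbone)


def _check_shared_backbone(trees: Sequence[Tree]) -> TaxonomyBackbone:
    backbone = trees[0].backbone
    for t in trees[1:]:
        if t.backbone is not backbone:
            raise AlgebraError("tree operands must share the same backbone")
    return backbone


def merge(*trees: Tree) -> Tree:
    """Tree over the union of the operands' occurrence sets (the ``+`` operation).

    Variadic: ``merge(*list_of_trees)`` is the efficient single-shot form,
    result-identical to folding ``+`` over the list.
    """
    if not trees:
        raise ParameterError("merge needs at least one operand")
    backbone = _check_shared_backbone(trees)
    combined: dict[int, Occurrence] = {}
    for t in trees:
        combined.update(t._occurrences)
    return Tree((combined[i] for i in sorted(combined)), backbone)


def intersect(a: Tree, b: Tree) -> Tree:
    """Tree over the intersection of occurrence-id sets (the ``&`` operation)."""
    backbone = _check_shared_backbone([a, b])
    ids = a.occurrence_ids & b.occurrence_ids
    return Tree((a._occurrences[i] for i in sorted(ids)), backbone)


def plant_tree_node(tree: Tree, *path: str) -> Tree:
    """Trim: plant a new tree from the node reached by ``path`` of names."""
    return tree.plant_at(*path)


def count_node_frequencies_on_list(tree: Tree, reference: Sequence[Tree]) -> Tree:
    return tree.count_node_frequencies_on_list(reference)


def rank_levels(tree: Tree) -> Tree:
    return tree.rank_levels()
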