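"""Focal-taxon neighbourhood co-occurrence analysis with red-list filtering.

The procedure: find the grid cells holding the focal taxon, take the
order-k neighbourhood around them, build one local taxonomic tree per
cell, merge them (set union of occurrences), score every merged-tree node
with its appearance frequency over the per-cell trees, rank each
taxonomic level by that frequency, filter the species against a red list
of threatened names, and report coverage and equal-area cell statistics.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry.base import BaseGeometry

from .errors import ParameterError
from .graph import KnowledgeGraph
from .projection import ProjectionSpec, polygon_area_km2
from .taxonomy import TaxonNode, TaxonRank
from .tree import Tree, merge

logger = logging.getLogger(__name__)

#: red-list categories counted as threatened by default
THREATENED_CATEGORIES: tuple[str, ...] = (
    "Critically Endangered", "Endangered", "Vulnerable",
)


@dataclass(frozen=True)
class RedListEntry:
    """One catalogue row: a scientific name and its threat category."""

    scientific_name: str
    category: str

    def __post_init__(self) -> None:
        if not self.scientific_name.strip():
            raise ParameterError("red-list entry needs a non-empty name")


def read_redlist_csv(path_or_buf) -> list[RedListEntry]:
    """Read ``scientificName,redlistCategory`` CSV rows."""
    df = pd.read_csv(path_or_buf, dtype=str, keep_default_na=False)
    return [
        RedListEntry(r["scientificName"], r["redlistCategory"])
        for _, r in df.iterrows()
    ]


def _selected_names(
    redlist: Sequence[RedListEntry], categories: Sequence[str]
) -> list[str]:
    cats = set(categories)
    return [e.scientific_name.lower() for e in redlist if e.category in cats]


def match_threatened_species(
    tree: Tree,
    redlist: Sequence[RedListEntry],
    categories: Sequence[str] = THREATENED_CATEGORIES,
    mode: str = "substring",
) -> list:
    """Species nodes of ``tree`` matching the selected red-list names.

    ``substring`` (default) matches a lowercased listed name contained
    anywhere in the species name — a listed binomial therefore matches the
    full scientific name with authorship.  ``binomial`` requires the first
    two whitespace-separated words to match exactly, closing the
    name-nesting false-positive of substring matching.
    """
    if not redlist:
        raise ParameterError("red list must be non-empty")
    if mode not in ("substring", "binomial"):
        raise ParameterError(f"unknown match mode {mode!r}")
    names = _selected_names(redlist, categories)
    matched = []
    for node in tree.species:
        sp = node.taxon.name.lower()
        if mode == "substring":
            hit = any(listed in sp for listed in names)
        else:
            binom = " ".join(sp.split()[:2])
            hit = any(" ".join(listed.split()[:2]) == binom for listed in names)
        if hit:
            matched.append(node)
    return matched


def filter_threatened(
    tree: Tree,
    redlist: Sequence[RedListEntry],
    categories: Sequence[str] = THREATENED_CATEGORIES,
    mode: str = "substring",
) -> Tree:
    """New tree over the occurrences of the red-listed species in ``tree``."""
    matched = match_threatened_species(tree, redlist, categories, mode)
    ids: set[int] = set()
    for node in matched:
        ids |= node.occurrence_ids
    return Tree((tree._occurrences[i] for i in sorted(ids)), tree.backbone)


def coverage_percentage(
    threatened_tree: Tree,
    redlist: Sequence[RedListEntry],
    categories: Sequence[str] = THREATENED_CATEGORIES,
) -> float:
    """100 x (distinct species in the threatened tree) / (listed species)."""
    n_listed = len(_selected_names(redlist, categories))
    if n_listed == 0:
        raise ParameterError("no red-list species in the selected categories")
    return 100.0 * len(threatened_tree.species) / n_listed


@dataclass
class CooccurrenceReport:
    """Everything the neighbourhood co-occurrence pipeline computes."""

    focal_name: str
    order: int
    focal_cell_ids: list[int]
    neighbourhood_cell_ids: list[int]
    merged_tree: Tree
    threatened_tree: Tree | None
    coverage_percent: float | None
    mean_cell_area_km2: float | None
    sd_cell_area_km2: float | None
    total_area_km2: float | None
    region_fraction_percent: float | None
    ranked: dict[str, list[dict]] = field(default_factory=dict)

    def rank_table(self, rank: str) -> pd.DataFrame:
        return pd.DataFrame(self.ranked.get(rank, []))

    def to_dict(self) -> dict:
        return {
            "focal": self.focal_name,
            "order": self.order,
            "n_focal_cells": len(self.focal_cell_ids),
            "n_neighbourhood_cells": len(self.neighbourhood_cell_ids),
            "focal_cell_ids": self.focal_cell_ids,
            "neighbourhood_cell_ids": self.neighbourhood_cell_ids,
            "merged_n_count": self.merged_tree.n_count,
            "threatened_n_count": (
                None if self.threatened_tree is None else self.threatened_tree.n_count
            ),
            "threatened_n_species": (
                None if self.threatened_tree is None
                else len(self.threatened_tree.species)
            ),
            "coverage_percent": self.coverage_percent,
            "mean_cell_area_km2": self.mean_cell_area_km2,
            "sd_cell_area_km2": self.sd_cell_area_km2,
            "total_area_km2": self.total_area_km2,
            "region_fraction_percent": self.region_fraction_percent,
            "ranked": self.ranked,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _ranked_tables(merged: Tree) -> dict[str, list[dict]]:
    """Per-rank listings sorted by AF; each row carries both the appearance
    frequency and the occurrence share within its rank (the two different
    'most abundant' readings)."""
    out: dict[str, list[dict]] = {}
    for rank in list(TaxonRank)[1:]:
        nodes = merged.nodes_at(rank)
        total = sum(n.n_count for n in nodes) or 1
        out[rank.label] = [
            {
                "name": n.taxon.name,
                "n_count": n.n_count,
                "af": n.af,
                "occurrence_share_percent": 100.0 * n.n_count / total,
            }
            for n in nodes
        ]
    return out


def run_cooccurrence(
    graph: KnowledgeGraph,
    focal: TaxonNode,
    order: int = 4,
    redlist: Sequence[RedListEntry] | None = None,
    categories: Sequence[str] = THREATENED_CATEGORIES,
    projection: ProjectionSpec | None = None,
    region_polygon: BaseGeometry | None = None,
    match_mode: str = "substring",
    deduplicate_neighbourhoods: bool = True,
) -> CooccurrenceReport:
    """Run the full neighbourhood co-occurrence analysis around ``focal``.

    Requires the focal taxon to have at least one in-grid occurrence.
    ``projection`` enables the equal-area cell statistics;
    ``region_polygon`` (lon/lat degrees) additionally reports the
    neighbourhood's share of that region's area.
    """
    if order < 1:
        raise ParameterError(f"neighbourhood order must be >= 1, got {order}")
    focal_cells = list(graph.cells_with_taxon(focal))
    if not focal_cells:
        raise ParameterError(f"focal taxon {focal.name!r} has no in-grid occurrence")

    neighbours = graph.neighbour_cells(
        focal_cells, order=order, with_center=True,
        deduplicate=deduplicate_neighbourhoods,
    )
    cell_trees = [
        Tree(graph.occurrences_in_cell(c), graph.backbone) for c in neighbours
    ]
    # single-shot union build: result-identical to folding + over cell_trees
    merged = merge(*cell_trees) if cell_trees else Tree([], graph.backbone)
    merged.count_node_frequencies_on_list(cell_trees)
    merged.rank_levels()

    threatened = None
    coverage = None
    if redlist:
        threatened = filter_threatened(merged, redlist, categories, match_mode)
        if threatened.n_count:
            threatened.count_node_frequencies_on_list(cell_trees)
            threatened.rank_levels()
        coverage = coverage_percentage(threatened, redlist, categories)

    mean_a = sd_a = total_a = fraction = None
    if projection is not None:
        areas = np.array(
            [polygon_area_km2(c.polygon, projection) for c in neighbours]
        )
        mean_a = float(areas.mean())
        sd_a = float(areas.std())
        total_a = float(areas.sum())
        if region_polygon is not None:
            region_area = polygon_area_km2(region_polygon, projection)
            fraction = 100.0 * total_a / region_area

    return CooccurrenceReport(
        focal_name=focal.name,
        order=order,
        focal_cell_ids=[c.id for c in focal_cells],
        neighbourhood_cell_ids=[c.id for c in neighbours],
        merged_tree=merged,
        threatened_tree=threatened,
        coverage_percent=coverage,
        mean_cell_area_km2=mean_a,
        sd_cell_area_km2=sd_a,
        total_area_km2=total_a,
        region_fraction_percent=fraction,
        ranked=_ranked_tables(merged),
    )
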