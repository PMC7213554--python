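"""Regular longitude-latitude lattice: cells, point assignment, neighbourhoods.

Cells partition the grid extent with half-open intervals
``[west + col*res, west + (col+1)*res)`` (likewise for rows); the global
top/right boundary is closed so points on the outer edge are not lost.
Cell ids are row-major (``id = row*ncols + col``).  Neighbourhoods are
order-k Moore (queen) neighbourhoods: all cells within Chebyshev distance
k, clipped at the grid border.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterator

from shapely.geometry import box

from .errors import GridError, ParameterError


@dataclass(frozen=True)
class GridSpec:
    """Bounding box (WGS84 degrees) plus resolution in degrees per cell side."""

    min_lon: float
    min_lat: float
    max_lon: float
    max_lat: float
    resolution: float
    name: str = "grid"

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise GridError(f"resolution must be positive, got {self.resolution}")
        if self.max_lon <= self.min_lon or self.max_lat <= self.min_lat:
            raise GridError("empty bounding box")

    @property
    def ncols(self) -> int:
        return math.ceil(round((self.max_lon - self.min_lon) / self.resolution, 9))

    @property
    def nrows(self) -> int:
        return math.ceil(round((self.max_lat - self.min_lat) / self.resolution, 9))


@dataclass(frozen=True)
class Cell:
    """One lattice rectangle; identity is the row-major integer id."""

    id: int
    row: int
    col: int
    grid: GridSpec

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(min_lon, min_lat, max_lon, max_lat) of the cell rectangle."""
        res = self.grid.resolution
        w = self.grid.min_lon + self.col * res
        s = self.grid.min_lat + self.row * res
        return (w, s, w + res, s + res)

    @property
    def polygon(self):
        return box(*self.bounds)

    @property
    def centre(self) -> tuple[float, float]:
        w, s, e, n = self.bounds
        return ((w + e) / 2.0, (s + n) / 2.0)

    def __repr__(self) -> str:
        return f"<Cell-{self.grid.name} id = {self.id} >"


class Grid:
    """Indexed collection of cells over a :class:`GridSpec`.

    Cells are materialized on demand, so very large lattices (hundreds of
    thousands of cells) cost nothing to build.
    """

    def __init__(self, spec: GridSpec) -> None:
        if spec.ncols < 1 or spec.nrows < 1:
            raise GridError("grid has no cells")
        self.spec = spec

    @property
    def ncols(self) -> int:
        return self.spec.ncols

    @property
    def nrows(self) -> int:
        return self.spec.nrows

    def __len__(self) -> int:
        return self.ncols * self.nrows

    def __iter__(self) -> Iterator[Cell]:
        for cid in range(len(self)):
            yield self.cell(cid)

    def cell(self, cell_id: int) -> Cell:
        if not 0 <= cell_id < len(self):
            raise ParameterError(f"cell id {cell_id} outside 0..{len(self) - 1}")
        return Cell(cell_id, cell_id // self.ncols, cell_id % self.ncols, self.spec)

    def cell_at(self, row: int, col: int) -> Cell:
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            raise ParameterError(f"cell index ({row}, {col}) outside grid")
        return Cell(row * self.ncols + col, row, col, self.spec)

    def cell_for_point(self, lon: float, lat: float) -> Cell | None:
        """The unique cell containing the point, or ``None`` outside the extent.

        Interior shared edges belong to the greater-index cell (half-open
        rule); the exact top/right grid boundary folds into the last
        row/column so the extent is fully covered.
        """
        s = self.spec
        if not (s.min_lon <= lon <= s.max_lon and s.min_lat <= lat <= s.max_lat):
            return None
        col = min(int((lon - s.min_lon) / s.resolution), s.ncols - 1)
        row = min(int((lat - s.min_lat) / s.resolution), s.nrows - 1)
        return self.cell_at(row, col)

    def neighbourhood(self, cell: Cell, order: int = 1, with_center: bool = True) -> list[Cell]:
        """Cells at Chebyshev distance <= ``order`` from ``cell``, row-major.

        ``with_center=False`` drops the centre cell itself.  Border cells
        get clipped neighbourhoods.
        """
        if cell.grid != self.spec:
            raise ParameterError("cell does not belong to this grid")
        if order < 1:
            raise ParameterError(f"neighbourhood order must be >= 1, got {order}")
        out: list[Cell] = []
        for row in range(max(0, cell.row - order), min(self.nrows, cell.row + order + 1)):
            for col in range(max(0, cell.col - order), min(self.ncols, cell.col + order + 1)):
                if not with_center and row == cell.row and col == cell.col:
                    continue
                out.append(self.cell_at(row, col))
        return out

    def to_geojson(self, cells: list[Cell] | None = None) -> dict:
        """GeoJSON FeatureCollection of cell polygons with id/row/col properties."""
        features = []
        for cell in (cells if cells is not None else self):
            w, s, e, n = cell.bounds
            features.append({
                "type": "Feature",
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [[[w, s], [e, s], [e, n], [w, n], [w, s]]],
                },
                "properties": {"id": cell.id, "row": cell.row, "col": cell.col},
            })
        return {"type": "FeatureCollection", "features": features}

    def write_geojson(self, path, cells: list[Cell] | None = None) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_geojson(cells), fh)


def build_grid(spec: GridSpec) -> Grid:
    """Build the lattice for ``spec`` (degenerate specs raise :class:`GridError`)."""
    return Grid(spec)
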