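"""Albers equal-area conic projection (spherical) and polygon areas in km².

The forward mapping uses the spherical Albers formulas on the authalic
radius R = 6371.0072 km.  For area work over a regional latitude span the
difference from the ellipsoidal projection is well under one part in a
thousand, which is why the sphere is the default earth model here; the
:class:`ProjectionSpec` keeps the ellipsoid parameters so another backend
can be plugged in.

With standard parallels phi1, phi2 and origin (phi0, lam0):

    n    = (sin phi1 + sin phi2) / 2
    C    = cos^2 phi1 + 2 n sin phi1
    rho  = R sqrt(C - 2 n sin phi) / n
    rho0 = R sqrt(C - 2 n sin phi0) / n
    x    = rho sin(n (lam - lam0)) + FE
    y    = rho0 - rho cos(n (lam - lam0)) + FN
"""
from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from shapely.geometry import Polygon
from shapely.geometry.base import BaseGeometry
from shapely.ops import transform as shapely_transform

from .errors import GeometryError, ParameterError

#: authalic earth radius in metres (sphere of equal surface area)
AUTHALIC_RADIUS_M = 6_371_007.2


@dataclass(frozen=True)
class ProjectionSpec:
    """Albers equal-area conic parameters (angles in degrees, offsets in metres)."""

    lat_1: float
    lat_2: float
    lat_0: float = 0.0
    lon_0: float = 0.0
    false_easting: float = 0.0
    false_northing: float = 0.0
    radius: float = AUTHALIC_RADIUS_M

    def __post_init__(self) -> None:
        if math.isclose(self.lat_1, -self.lat_2):
            raise ParameterError(
                "degenerate Albers cone: lat_1 == -lat_2 (n = 0)"
            )

    @classmethod
    def from_proj4(cls, text: str) -> "ProjectionSpec":
        """Parse a proj-style parameter string, e.g.
        ``"+proj=aea +lat_1=14.5 +lat_2=32.5 +lat_0=24 +lon_0=-105"``.
        """
        params = dict(re.findall(r"\+(\w+)=([^\s;]+)", text))
        if params.get("proj") not in ("aea", None):
            raise ParameterError(f"unsupported projection {params.get('proj')!r}")
        if "lat_1" not in params or "lat_2" not in params:
            raise ParameterError("proj string must define lat_1 and lat_2")
        return cls(
            lat_1=float(params["lat_1"]),
            lat_2=float(params["lat_2"]),
            lat_0=float(params.get("lat_0", 0.0)),
            lon_0=float(params.get("lon_0", 0.0)),
            false_easting=float(params.get("x_0", 0.0)),
            false_northing=float(params.get("y_0", 0.0)),
        )

    # derived cone constants
    @property
    def _n(self) -> float:
        return 0.5 * (math.sin(math.radians(self.lat_1)) + math.sin(math.radians(self.lat_2)))

    @property
    def _C(self) -> float:
        phi1 = math.radians(self.lat_1)
        return math.cos(phi1) ** 2 + 2.0 * self._n * math.sin(phi1)

    def _rho(self, lat_deg: float) -> float:
        n = self._n
        return self.radius * math.sqrt(self._C - 2.0 * n * math.sin(math.radians(lat_deg))) / n

    def __call__(self, lon: float, lat: float) -> tuple[float, float]:
        return project_point(lon, lat, self)


def project_point(lon: float, lat: float, proj: ProjectionSpec) -> tuple[float, float]:
    """Forward Albers mapping of a WGS84 point to (x, y) in metres."""
    if abs(lat) >= 90.0:
        raise GeometryError(f"latitude {lat} out of the projection domain")
    n = proj._n
    rho = proj._rho(lat)
    rho0 = proj._rho(proj.lat_0)
    theta = n * math.radians(lon - proj.lon_0)
    x = rho * math.sin(theta) + proj.false_easting
    y = rho0 - rho * math.cos(theta) + proj.false_northing
    return (x, y)


def project_geometry(geom: BaseGeometry, proj: ProjectionSpec) -> BaseGeometry:
    """Project any shapely geometry coordinate-wise."""
    return shapely_transform(lambda x, y, z=None: proj(x, y), geom)


def polygon_area_km2(
    polygon: BaseGeometry | Sequence[tuple[float, float]],
    proj: ProjectionSpec,
) -> float:
    """Planar (shoelace) area of the projected polygon, in km².

    ``polygon`` is a shapely geometry in lon/lat degrees or a sequence of
    (lon, lat) vertices.  Because the projection is equal-area, this equals
    the geodetic area to within the spherical-model error.
    """
    if not isinstance(polygon, BaseGeometry):
        coords = list(polygon)
        if len(coords) < 3:
            raise GeometryError("polygon needs at least 3 vertices")
        polygon = Polygon(coords)
    elif polygon.is_empty:
        raise GeometryError("empty polygon")
    return project_geometry(polygon, proj).area / 1.0e6


def spherical_polygon_area_km2(
    coords: Iterable[tuple[float, float]], radius_m: float = AUTHALIC_RADIUS_M
) -> float:
    """Exact spherical area of a lon/lat ring via L'Huilier spherical excess.

    Independent of the projection path; used as the equal-area oracle.
    """
    pts = [tuple(p) for p in coords]
    if pts[0] == pts[-1]:
        pts = pts[:-1]
    if len(pts) < 3:
        raise GeometryError("polygon needs at least 3 vertices")

    def to_xyz(lon: float, lat: float) -> tuple[float, float, float]:
        lam, phi = math.radians(lon), math.radians(lat)
        return (math.cos(phi) * math.cos(lam), math.cos(phi) * math.sin(lam), math.sin(phi))

    def tri_excess(a, b, c) -> float:
        # spherical excess of the triangle with vertices a,b,c (unit vectors)
        num = abs(
            a[0] * (b[1] * c[2] - b[2] * c[1])
            - a[1] * (b[0] * c[2] - b[2] * c[0])
            + a[2] * (b[0] * c[1] - b[1] * c[0])
        )
        dot_ab = sum(x * y for x, y in zip(a, b))
        dot_bc = sum(x * y for x, y in zip(b, c))
        dot_ca = sum(x * y for x, y in zip(c, a))
        den = 1.0 + dot_ab + dot_bc + dot_ca
        return 2.0 * math.atan2(num, den)

    xyz = [to_xyz(lon, lat) for lon, lat in pts]
    total = 0.0
    for i in range(1, len(xyz) - 1):
        total += tri_excess(xyz[0], xyz[i], xyz[i + 1])
    return total * radius_m**2 / 1.0e6
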