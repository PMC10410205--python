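"""Planar polygon primitives shared by every analysis stage.

All coordinates are metres in a projected CRS. Distances are planar
Euclidean; haul-out sites are well under a kilometre across, so geodesic
corrections are negligible at the scales analysed.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely import affinity
from shapely.geometry import Point, Polygon

#: Interior intersections at or below this area (m^2) count as grazing
#: contact, not overlap; keeps overlap resolution robust to floating-point
#: contacts between polygons pushed exactly flank to flank.
OVERLAP_AREA_TOL = 1e-9


class GeometryError(ValueError):
    """Raised for polygons that violate the annotation contract."""


def validate_polygon(poly: Polygon, what: str = "polygon") -> Polygon:
    """Check that *poly* is a simple ring with >= 3 distinct vertices,
    finite coordinates and strictly positive area. Returns it unchanged."""
    if not isinstance(poly, Polygon) or poly.is_empty:
        raise GeometryError(f"{what}: expected a non-empty Polygon")
    coords = np.asarray(poly.exterior.coords)
    if not np.isfinite(coords).all():
        raise GeometryError(f"{what}: non-finite coordinates")
    if len(np.unique(coords[:-1], axis=0)) < 3:
        raise GeometryError(f"{what}: fewer than 3 distinct vertices")
    if not poly.is_valid:
        raise GeometryError(f"{what}: ring is not simple (self-intersection)")
    if poly.area <= 0.0:
        raise GeometryError(f"{what}: zero area")
    return poly


def edge_distance(a: Polygon, b: Polygon) -> float:
    """Minimum edge-to-edge distance between two polygons, in metres.

    Exactly 0.0 when the polygons touch or intersect: two animals lying
    flank to flank are at distance zero.
    """
    validate_polygon(a, "a")
    validate_polygon(b, "b")
    return float(shapely.distance(a, b))


def centre_point(a: Polygon) -> Point:
    """Area centroid of a polygon — the "centre point" around which the
    density circles are drawn and about which overlap-resolution rotation
    pivots."""
    validate_polygon(a)
    return a.centroid


def overlaps(a: Polygon, b: Polygon, tol: float = OVERLAP_AREA_TOL) -> bool:
    """True iff the interiors intersect with positive area.

    Boundary contact alone is not overlap (animals may touch), so the
    predicate is ``intersection area > tol`` rather than ``intersects``.
    """
    if not a.intersects(b):
        return False
    return a.intersection(b).area > tol


@dataclass(frozen=True)
class RigidMotion:
    """Rotation (degrees, about the polygon's area centroid) followed by a
    translation (dx, dy) in metres. Preserves area and perimeter."""

    rotation_deg: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)


def apply_motion(a: Polygon, m: RigidMotion) -> Polygon:
    """Rotate *a* by ``m.rotation_deg`` about its centroid, then translate
    by ``m.translation``. Shape-preserving by construction."""
    validate_polygon(a)
    out = a
    if m.rotation_deg != 0.0:
        out = affinity.rotate(out, m.rotation_deg, origin="centroid")
    dx, dy = m.translation
    if dx != 0.0 or dy != 0.0:
        out = affinity.translate(out, xoff=dx, yoff=dy)
    return out


def diameter(a: Polygon) -> float:
    """Largest vertex-to-vertex distance of a polygon. The diameter of a
    polygon is attained at convex-hull vertices, which are a subset of the
    ring vertices."""
    hull = a.convex_hull
    if hull.geom_type != "Polygon":  # degenerate (collinear) input
        pts = np.asarray(a.exterior.coords[:-1]) if isinstance(a, Polygon) else np.asarray(hull.coords)
    else:
        pts = np.asarray(hull.exterior.coords[:-1])
    diff = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((diff ** 2).sum(-1)).max())
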