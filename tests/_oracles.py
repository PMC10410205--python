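"""Independent brute-force oracles used by the test suite.

Deliberately implemented from first principles (pure numpy, no shapely) so
they constitute an independent check of the geometric primitives.
"""
from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree


def _orient(a, b, c):
    return np.sign((b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0]))


def _on_segment(a, b, p):
    return (min(a[0], b[0]) - 1e-12 <= p[0] <= max(a[0], b[0]) + 1e-12 and
            min(a[1], b[1]) - 1e-12 <= p[1] <= max(a[1], b[1]) + 1e-12)


def segments_intersect(a, b, c, d) -> bool:
    o1, o2 = _orient(a, b, c), _orient(a, b, d)
    o3, o4 = _orient(c, d, a), _orient(c, d, b)
    if o1 != o2 and o3 != o4:
        return True
    for (p, q, r) in ((a, b, c), (a, b, d), (c, d, a), (c, d, b)):
        if _orient(p, q, r) == 0 and _on_segment(p, q, r):
            return True
    return False


def point_segment_distance(p, a, b) -> float:
    p, a, b = map(np.asarray, (p, a, b))
    ab = b - a
    denom = float(ab @ ab)
    t = 0.0 if denom == 0.0 else float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
    return float(np.linalg.norm(a + t * ab - p))


def segment_segment_distance(a, b, c, d) -> float:
    if segments_intersect(a, b, c, d):
        return 0.0
    return min(point_segment_distance(a, c, d),
               point_segment_distance(b, c, d),
               point_segment_distance(c, a, b),
               point_segment_distance(d, a, b))


def _ring(coords) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if not np.allclose(coords[0], coords[-1]):
        coords = np.vstack([coords, coords[0]])
    return coords


def polygon_min_distance(coords_a, coords_b) -> float:
    """Minimum boundary-to-boundary distance: brute force over every pair of
    boundary segments. Equals the region distance for disjoint polygons."""
    A, B = _ring(coords_a), _ring(coords_b)
    best = np.inf
    for i in range(len(A) - 1):
        for j in range(len(B) - 1):
            best = min(best, segment_segment_distance(A[i], A[i + 1],
                                                      B[j], B[j + 1]))
    return best


def boundary_sample_distance(coords_a, coords_b, spacing: float = 0.001) -> float:
    """Minimum distance between the two boundaries, estimated by dense
    sampling at *spacing* metres and a KD-tree query. Overestimates the
    true boundary distance by at most ~spacing."""

    def sample(coords):
        ring = _ring(coords)
        pts = []
        for p, q in zip(ring[:-1], ring[1:]):
            length = np.linalg.norm(q - p)
            k = max(int(np.ceil(length / spacing)), 1)
            t = np.linspace(0.0, 1.0, k + 1)[:-1]
            pts.append(p + t[:, None] * (q - p))
        return np.vstack(pts)

    pa, pb = sample(coords_a), sample(coords_b)
    d, _ = cKDTree(pb).query(pa)
    return float(d.min())


def shoelace_area_centroid(coords) -> tuple[float, tuple[float, float]]:
    """Signed area and area centroid of a simple polygon by the shoelace
    formula."""
    ring = _ring(coords)
    x, y = ring[:-1, 0], ring[:-1, 1]
    xn, yn = ring[1:, 0], ring[1:, 1]
    cross = x * yn - xn * y
    area = 0.5 * cross.sum()
    cx = ((x + xn) * cross).sum() / (6.0 * area)
    cy = ((y + yn) * cross).sum() / (6.0 * area)
    return float(area), (float(cx), float(cy))


def rect_intersection_area(r1, r2) -> float:
    """Closed-form intersection area of two axis-aligned rectangles given as
    (minx, miny, maxx, maxy)."""
    w = min(r1[2], r2[2]) - max(r1[0], r2[0])
    h = min(r1[3], r2[3]) - max(r1[1], r2[1])
    return max(w, 0.0) * max(h, 0.0)


def random_star_polygon(rng, n_vertices: int = 8, radius: float = 1.0,
                        centre=(0.0, 0.0)) -> np.ndarray:
    """A random simple (star-shaped) polygon: sorted angles, random radii."""
    # angles strictly increasing and covering the full circle, so the
    # polygon is genuinely star-shaped about *centre* (hence simple)
    gaps = rng.uniform(0.5, 1.5, n_vertices)
    angles = 2.0 * np.pi * np.cumsum(gaps) / gaps.sum()
    radii = rng.uniform(0.3 * radius, radius, n_vertices)
    return np.column_stack([centre[0] + radii * np.cos(angles),
                            centre[1] + radii * np.sin(angles)])
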