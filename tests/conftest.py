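import numpy as np
import pytest
from shapely.geometry import Polygon, box

from sealspacing.annotations import HaulOutSite, SealAnnotation, default_window


def square(x0: float, y0: float, side: float = 1.0) -> Polygon:
    return box(x0, y0, x0 + side, y0 + side)


def make_site(polygons, species="grey", site_id="s1", crs="EPSG:28992",
              window=None, pupping=False) -> HaulOutSite:
    """Build a HaulOutSite from bare polygons (single species)."""
    # a "mixed" site holds alternating grey/harbour animals
    sp = (lambda i: species) if species != "mixed" else \
        (lambda i: "grey" if i % 2 == 0 else "harbour")
    anns = [SealAnnotation(id=f"a{i}", site_id=site_id, species=sp(i),
                           polygon=p) for i, p in enumerate(polygons)]
    if window is None:
        window = default_window([p for p in polygons])
    return HaulOutSite(site_id=site_id, species=species, annotations=anns,
                       window=window, crs=crs, pupping=pupping)


@pytest.fixture
def rng():
    return np.random.default_rng(20230809)


def random_triangle(rng, offset=(0.0, 0.0), scale: float = 1.0) -> np.ndarray:
    """Random non-degenerate triangle inside a unit box at *offset*."""
    while True:
        pts = rng.uniform(0.0, scale, size=(3, 2)) + np.asarray(offset)
        u, v = pts[1] - pts[0], pts[2] - pts[0]
        area = 0.5 * abs(u[0] * v[1] - u[1] * v[0])
        if area > 0.05 * scale ** 2:
            return pts
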