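"""The spatial-perturbation ("shuffling") null model for social distancing.

The idea: if animals placed themselves according to the colony's coarse
spatial density alone — with no short-range avoidance — how often would
very small nearest-neighbour distances occur? Each animal's outline is
displaced around its observed position at the spatial scale given by a
cross-validated kernel bandwidth, keeping its orientation, so the
heterogeneous density of the colony is preserved while any fine-scale
spacing is erased. Polygons that land on top of one another are separated
by incremental rotation and, failing that, incremental translation in a
random direction — animals rarely lie on top of each other, so the null
configuration must be overlap-free too. A deficit of very small NNDs in
the observed pattern relative to the shuffled one is the social-distancing
signal.

Every stage is driven by a single seed; per-site substreams are derived
from (seed, site_id) so adding a site never perturbs another site's draws.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import shapely
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import pdist
from shapely.geometry import Polygon

from .annotations import HaulOutSite, SealAnnotation
from .geometry import RigidMotion, apply_motion, centre_point, diameter, overlaps
from .nnd import NNDRecord, nearest_neighbour_distances

MIN_CENTRES_FOR_CV = 10
BANDWIDTH_FLOOR_M = 0.1


# --------------------------------------------------------------------------
# bandwidth selection
# --------------------------------------------------------------------------

def _mse_cv_criterion(sq_dists: np.ndarray, n: int, sigma: np.ndarray) -> np.ndarray:
    """Leave-one-out least-squares (mean integrated squared error) CV score
    for a Gaussian kernel intensity, evaluated at each sigma.

    With lambda_s(u) = sum_j phi_s(u - x_j) (isotropic Gaussian, no edge
    correction) the criterion is

        M(s) = int lambda_s(u)^2 du - 2 sum_i lambda_s^{(-i)}(x_i)

    where the squared integral reduces, via the Gaussian convolution
    identity, to a sum of Gaussians of bandwidth s*sqrt(2) over all pairs.
    ``sq_dists`` is the condensed vector of squared pairwise distances.
    """
    s2 = np.atleast_1d(np.asarray(sigma, dtype=float)) ** 2
    d2 = sq_dists[:, None]
    cross = np.exp(-d2 / (4.0 * s2)).sum(axis=0)      # pairs i<j
    loo = np.exp(-d2 / (2.0 * s2)).sum(axis=0)
    term_sq = (n + 2.0 * cross) / (4.0 * np.pi * s2)
    term_loo = 4.0 * loo / (2.0 * np.pi * s2)         # 2 * sum_{i != j}
    out = term_sq - term_loo
    return out if np.ndim(sigma) else float(out[0])


def cv_bandwidth(centres: np.ndarray, window: Polygon,
                 n_grid: int = 80) -> float:
    """Cross-validated Gaussian bandwidth (m) for a site's centre points.

    Minimises the mean-square-error cross-validation criterion over
    [0.1 m, diameter(window)/2]: a log-spaced grid locates the basin, then
    golden-section search refines between the best grid point's
    neighbours. Deterministic for fixed input.
    """
    centres = np.asarray(centres, dtype=float)
    if len(centres) < MIN_CENTRES_FOR_CV:
        raise ValueError(
            f"cross-validated bandwidth needs >= {MIN_CENTRES_FOR_CV} centre "
            f"points, got {len(centres)}; supply bandwidth_override instead"
        )
    sq = pdist(centres) ** 2
    if sq.max() == 0.0:
        raise ValueError("all centre points identical; bandwidth undefined")
    lo, hi = BANDWIDTH_FLOOR_M, diameter(window) / 2.0
    if hi <= lo:
        raise ValueError("window too small for bandwidth search")
    grid = np.geomspace(lo, hi, n_grid)
    scores = _mse_cv_criterion(sq, len(centres), grid)
    k = int(np.argmin(scores))
    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, n_grid - 1)]
    if a == b:
        return float(grid[k])
    res = minimize_scalar(lambda s: _mse_cv_criterion(sq, len(centres), s),
                          bounds=(a, b), method="bounded",
                          options={"xatol": 1e-4})
    best = float(res.x) if res.fun <= scores[k] else float(grid[k])
    return best


def species_averaged_bandwidths(sites: Sequence[HaulOutSite]) -> dict[str, float]:
    """Per-site CV bandwidths averaged within species.

    Returns {species: mean bandwidth over that species' sites}. The common
    per-species value is what the shuffle uses for every site of that
    species, so single busy sites do not dominate their own null.
    """
    per_species: dict[str, list[float]] = {}
    for site in sites:
        centres = np.array([[centre_point(a.polygon).x,
                             centre_point(a.polygon).y]
                            for a in site.annotations])
        per_species.setdefault(site.species, []).append(
            cv_bandwidth(centres, site.window))
    return {sp: float(np.mean(v)) for sp, v in per_species.items()}


# --------------------------------------------------------------------------
# kernel intensity
# --------------------------------------------------------------------------

@dataclass
class KernelModel:
    """Gaussian kernel intensity over a site's centre points, clipped to the
    analysis window and normalised so it integrates to the number of
    animals over the window."""

    sigma: float
    centres: np.ndarray          # (n, 2)
    window: Polygon
    norm: float = field(default=1.0)

    def raw(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        dx = x[..., None] - self.centres[:, 0]
        dy = y[..., None] - self.centres[:, 1]
        s2 = self.sigma ** 2
        return np.exp(-(dx * dx + dy * dy) / (2.0 * s2)).sum(axis=-1) / (
            2.0 * np.pi * s2)

    def intensity(self, x, y):
        """Animals per m^2 at (x, y); only meaningful inside the window."""
        return self.norm * self.raw(x, y)

    def integral(self, n_cells: int = 200) -> float:
        """Quadrature of the intensity over the window (midpoint rule on an
        n_cells x n_cells grid masked to the window)."""
        xs, ys, inside, cell = _window_grid(self.window, n_cells)
        return float(self.intensity(xs[inside], ys[inside]).sum() * cell)


def _window_grid(window: Polygon, n_cells: int):
    minx, miny, maxx, maxy = window.bounds
    ex = np.linspace(minx, maxx, n_cells + 1)
    ey = np.linspace(miny, maxy, n_cells + 1)
    cx = (ex[:-1] + ex[1:]) / 2.0
    cy = (ey[:-1] + ey[1:]) / 2.0
    xs, ys = np.meshgrid(cx, cy)
    xs, ys = xs.ravel(), ys.ravel()
    inside = shapely.contains_xy(window, xs, ys)
    cell = (ex[1] - ex[0]) * (ey[1] - ey[0])
    return xs, ys, inside, cell


def fit_kernel(site: HaulOutSite, sigma: float, n_cells: int = 200) -> KernelModel:
    """Fit the Gaussian kernel intensity to a site's centre points.

    Edge-uncorrected; the normalisation constant (computed by quadrature
    over the window) restores total mass n inside the window, so boundary
    leakage does not deflate the surface.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    centres = np.array([[centre_point(a.polygon).x, centre_point(a.polygon).y]
                        for a in site.annotations])
    model = KernelModel(sigma=float(sigma), centres=centres, window=site.window)
    minx, miny, maxx, maxy = site.window.bounds
    cell_side = max(maxx - minx, maxy - miny) / n_cells
    if sigma < 2.0 * cell_side:
        # kernels far narrower than the window (and than the quadrature
        # cells): boundary leakage is negligible, mass is already ~n
        model.norm = 1.0
        return model
    xs, ys, inside, cell = _window_grid(site.window, n_cells)
    raw_mass = float(model.raw(xs[inside], ys[inside]).sum() * cell)
    if raw_mass <= 0:
        raise ValueError("kernel mass vanishes inside the window")
    model.norm = len(centres) / raw_mass
    return model


# --------------------------------------------------------------------------
# shuffling
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ShuffleConfig:
    """Knobs of the perturbation null model.

    rotation_increment_deg and translation_increment_m are the overlap
    resolution step sizes (1 degree / 10 cm); mode selects how new centres
    are drawn: "jitter" displaces each animal by an isotropic Gaussian of
    sd = bandwidth around its own position (preserves local density),
    "intensity" draws fresh centres from the fitted colony-wide surface.
    """

    seed: int = 0
    rotation_increment_deg: float = 1.0
    translation_increment_m: float = 0.10
    mode: str = "jitter"  # "jitter" | "intensity"
    max_translation_steps: int = 1000
    bandwidth_override: float | None = None
    max_window_tries: int = 10_000

    def __post_init__(self):
        if self.rotation_increment_deg <= 0 or self.translation_increment_m <= 0:
            raise ValueError("increments must be positive")
        if self.mode not in ("jitter", "intensity"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class ResolutionEntry:
    id: str
    initially_overlapping: bool
    degrees_rotated: float
    metres_translated: float


@dataclass
class ShuffleResult:
    placed: list[SealAnnotation]
    resolution_log: list[ResolutionEntry]
    initial_overlap_fraction: float
    nnd_records: list[NNDRecord]
    sigma: float
    seed: int


def site_rng(seed: int, site_id: str) -> np.random.Generator:
    """Independent, reproducible substream for one site: derived from the
    pipeline seed and a stable hash of the site id, so adding or removing a
    site never changes another site's draws."""
    tag = zlib.crc32(site_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))


def propose_positions(site: HaulOutSite, model: KernelModel,
                      cfg: ShuffleConfig,
                      rng: np.random.Generator) -> np.ndarray:
    """New centre point for every animal, all inside the window.

    jitter mode: centre + N(0, sigma^2 I), rejection-resampled until the
    point falls inside the window. intensity mode: rejection sampling from
    the fitted intensity surface over the window. Orientation is untouched
    (positions only)."""
    out = np.empty((site.n, 2))
    if cfg.mode == "jitter":
        for i, ann in enumerate(site.annotations):
            c = centre_point(ann.polygon)
            for _ in range(cfg.max_window_tries):
                p = np.array([c.x, c.y]) + model.sigma * rng.standard_normal(2)
                if shapely.contains_xy(site.window, p[0], p[1]):
                    out[i] = p
                    break
            else:
                raise RuntimeError(
                    f"window rejection exceeded {cfg.max_window_tries} tries "
                    f"for annotation {ann.id!r}"
                )
    else:
        minx, miny, maxx, maxy = site.window.bounds
        # envelope: the Gaussian mixture cannot exceed n / (2 pi sigma^2)
        lam_max = model.norm * len(model.centres) / (2 * np.pi * model.sigma ** 2)
        for i, ann in enumerate(site.annotations):
            for _ in range(cfg.max_window_tries):
                p = np.array([rng.uniform(minx, maxx), rng.uniform(miny, maxy)])
                if not shapely.contains_xy(site.window, p[0], p[1]):
                    continue
                if rng.uniform(0.0, lam_max) <= float(model.intensity(p[0], p[1])):
                    out[i] = p
                    break
            else:
                raise RuntimeError(
                    f"intensity rejection exceeded {cfg.max_window_tries} "
                    f"tries for annotation {ann.id!r}"
                )
    return out


def _overlaps_any(poly: Polygon, finalized: list[Polygon],
                  bounds: np.ndarray | None = None) -> bool:
    if not finalized:
        return False
    minx, miny, maxx, maxy = poly.bounds
    if bounds is None:
        cand = finalized
    else:
        hit = ~((bounds[:, 2] < minx) | (bounds[:, 0] > maxx) |
                (bounds[:, 3] < miny) | (bounds[:, 1] > maxy))
        cand = [finalized[j] for j in np.nonzero(hit)[0]]
    return any(overlaps(poly, f) for f in cand)


def initial_overlap_fraction(polys: Sequence[Polygon]) -> float:
    """Fraction of polygons that overlap at least one other polygon."""
    n = len(polys)
    if n < 2:
        return 0.0
    tree = shapely.STRtree(list(polys))
    flag = np.zeros(n, dtype=bool)
    for i, p in enumerate(polys):
        for j in tree.query(p):
            if j != i and overlaps(p, polys[j]):
                flag[i] = True
                break
    return float(flag.mean())


def resolve_overlaps(annotations: Sequence[SealAnnotation],
                     proposed: Sequence[Polygon],
                     cfg: ShuffleConfig,
                     rng: np.random.Generator,
                     window: Polygon | None = None,
                     ) -> tuple[list[SealAnnotation], list[ResolutionEntry], float]:
    """Separate overlapping polygons by rotation, then translation.

    Polygons are finalized one by one in a seeded random order, each tested
    only against already-finalized polygons. An overlapping polygon is
    first rotated about its centroid in +1 degree increments through 359;
    if no rotation frees it, the rotation is discarded and the polygon is
    stepped 10 cm at a time along a random unit direction (redrawn, seeded,
    if a step would carry the centre outside the window) until free.
    Orientation therefore changes only for polygons the rotation pass
    actually freed — the resolution log proves it.
    """
    n = len(annotations)
    frac = initial_overlap_fraction(list(proposed))
    order = rng.permutation(n)
    placed: list[SealAnnotation | None] = [None] * n
    log: list[ResolutionEntry | None] = [None] * n
    finalized: list[Polygon] = []
    bounds_list: list[tuple] = []

    for idx in order:
        ann = annotations[idx]
        poly = proposed[idx]
        bounds = np.array(bounds_list) if bounds_list else None
        was_overlapping = _overlaps_any(poly, finalized, bounds)
        deg_rot = 0.0
        metres = 0.0
        final = poly
        if was_overlapping:
            final = None
            # rotation pass: +increment steps up to (but excluding) 360
            k = 1
            ang = cfg.rotation_increment_deg
            while ang < 360.0 - 1e-9:
                cand = apply_motion(poly, RigidMotion(rotation_deg=ang))
                if not _overlaps_any(cand, finalized, bounds):
                    final = cand
                    deg_rot = ang
                    break
                k += 1
                ang = k * cfg.rotation_increment_deg
            if final is None:
                # translation pass from the unrotated proposed pose
                theta = rng.uniform(0.0, 2.0 * np.pi)
                direction = np.array([np.cos(theta), np.sin(theta)])
                cur = poly
                cx, cy = centre_point(poly).x, centre_point(poly).y
                pos = np.array([cx, cy])
                step = cfg.translation_increment_m
                for s in range(1, cfg.max_translation_steps + 1):
                    nxt = pos + direction * step
                    if window is not None and not shapely.contains_xy(
                            window, nxt[0], nxt[1]):
                        # blocked by the window edge: redraw the direction
                        theta = rng.uniform(0.0, 2.0 * np.pi)
                        direction = np.array([np.cos(theta), np.sin(theta)])
                        nxt = pos + direction * step
                        if not shapely.contains_xy(window, nxt[0], nxt[1]):
                            continue  # keep the step budget ticking
                    cur = apply_motion(
                        cur, RigidMotion(translation=tuple(nxt - pos)))
                    pos = nxt
                    metres += step
                    if not _overlaps_any(cur, finalized, None if bounds is None
                                         else bounds):
                        final = cur
                        break
                if final is None:
                    raise RuntimeError(
                        f"could not resolve overlap for annotation "
                        f"{ann.id!r} after {cfg.max_translation_steps} "
                        f"translation steps (seed {cfg.seed})"
                    )
        placed[idx] = SealAnnotation(id=ann.id, site_id=ann.site_id,
                                     species=ann.species, polygon=final)
        log[idx] = ResolutionEntry(id=ann.id,
                                   initially_overlapping=bool(was_overlapping),
                                   degrees_rotated=deg_rot,
                                   metres_translated=metres)
        finalized.append(final)
        bounds_list.append(final.bounds)
    return list(placed), list(log), frac


def shuffle_site(site: HaulOutSite, cfg: ShuffleConfig,
                 rng: np.random.Generator | None = None) -> ShuffleResult:
    """Run the full perturbation null for one site.

    Bandwidth (override or per-site CV) -> kernel fit -> position proposals
    -> overlap resolution -> NNDs of the placed polygons. Fully
    reproducible for a fixed seed.
    """
    if site.n < 2:
        raise ValueError(f"site {site.site_id!r} has fewer than 2 animals")
    if rng is None:
        rng = site_rng(cfg.seed, site.site_id)
    if cfg.bandwidth_override is not None:
        sigma = float(cfg.bandwidth_override)
        if sigma <= 0:
            raise ValueError("bandwidth_override must be positive")
    else:
        centres = np.array([[centre_point(a.polygon).x,
                             centre_point(a.polygon).y]
                            for a in site.annotations])
        sigma = cv_bandwidth(centres, site.window)
    model = fit_kernel(site, sigma)
    new_centres = propose_positions(site, model, cfg, rng)
    proposed = []
    for ann, c in zip(site.annotations, new_centres):
        old = centre_point(ann.polygon)
        proposed.append(apply_motion(
            ann.polygon, RigidMotion(translation=(c[0] - old.x, c[1] - old.y))))
    placed, log, frac = resolve_overlaps(site.annotations, proposed, cfg, rng,
                                         window=site.window)
    # centres are confined to the window but a body can straddle its edge;
    # pad the bookkeeping window so the placed site is self-consistent
    pad = max(diameter(p.polygon) for p in placed)
    shuffled_site = HaulOutSite(site_id=site.site_id, species=site.species,
                                annotations=placed,
                                window=site.window.buffer(pad),
                                crs=site.crs)
    records = nearest_neighbour_distances(shuffled_site)
    return ShuffleResult(placed=placed, resolution_log=log,
                         initial_overlap_fraction=frac, nnd_records=records,
                         sigma=sigma, seed=cfg.seed)
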