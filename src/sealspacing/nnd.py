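"""Nearest-neighbour distances within a haul-out site.

Every animal contributes one NND — the minimum edge-to-edge distance from
its outline polygon to any other polygon on the same site. The statistic is
directed (each animal is a focal individual making an independent spatial
decision), so mutual nearest neighbours are counted twice by design. NNDs
are never computed across sites.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely

from .annotations import HaulOutSite


@dataclass(frozen=True)
class NNDRecord:
    id: str
    site_id: str
    species: str
    nnd: float  # metres, >= 0


@dataclass(frozen=True)
class NNDSummary:
    group: str
    n: int
    mean: float
    median: float
    q25: float
    q75: float


def distance_matrix(site: HaulOutSite) -> np.ndarray:
    """Symmetric n x n matrix of pairwise edge-to-edge distances (m).

    The diagonal is 0 by convention and must be excluded from any minimum.
    Raises for sites with fewer than two animals ("site has no neighbours").
    """
    if site.n < 2:
        raise ValueError(f"site {site.site_id!r} has no neighbours (n={site.n})")
    geoms = np.array([a.polygon for a in site.annotations], dtype=object)
    d = shapely.distance(geoms[:, None], geoms[None, :])
    # enforce exact symmetry against any floating asymmetry in the backend
    return np.minimum(d, d.T)


def nearest_neighbour_distances(site: HaulOutSite) -> list[NNDRecord]:
    """One NND record per animal: the row minimum of the distance matrix
    with the diagonal masked. Touching or overlapping neighbours give 0."""
    d = distance_matrix(site).copy()
    np.fill_diagonal(d, np.inf)
    mins = d.min(axis=1)
    return [
        NNDRecord(id=a.id, site_id=site.site_id, species=a.species,
                  nnd=float(m))
        for a, m in zip(site.annotations, mins)
    ]


def records_frame(records: Iterable[NNDRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.id, r.site_id, r.species, r.nnd) for r in records],
        columns=["id", "site_id", "species", "nnd_m"],
    )


def summarize_nnd(records: Sequence[NNDRecord],
                  group_by: str = "species") -> list[NNDSummary]:
    """Per-group n, mean, median and quartiles of the NNDs.

    ``group_by`` is "species" or "site". Quantiles use linear interpolation
    between order statistics (quantile type 7), pinned so summaries are
    reproducible bit-for-bit.
    """
    if not records:
        raise ValueError("no NND records to summarize")
    if group_by not in ("species", "site"):
        raise ValueError(f"group_by must be 'species' or 'site', got {group_by!r}")
    key = (lambda r: r.species) if group_by == "species" else (lambda r: r.site_id)
    groups: dict[str, list[float]] = {}
    for r in records:
        groups.setdefault(key(r), []).append(r.nnd)
    out = []
    for g in sorted(groups):
        x = np.asarray(groups[g], dtype=float)
        q25, med, q75 = np.quantile(x, [0.25, 0.5, 0.75])  # type-7 default
        out.append(NNDSummary(group=g, n=len(x), mean=float(x.mean()),
                              median=float(med), q25=float(q25),
                              q75=float(q75)))
    return out


def bin_nnd(records, bin_width: float = 0.25) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of NNDs in left-closed, right-open bins [0, w), [w, 2w), ...

    ``records`` may be NNDRecords or raw distances. Returns (edges, counts);
    counts always sum to the number of inputs (the last bin is whichever
    bin contains the largest value).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    values = np.asarray(
        [r.nnd if isinstance(r, NNDRecord) else float(r) for r in records],
        dtype=float,
    )
    if values.size == 0:
        return np.array([0.0, bin_width]), np.zeros(1, dtype=int)
    idx = np.floor(values / bin_width).astype(int)  # exact [k*w, (k+1)*w)
    nbins = int(idx.max()) + 1
    counts = np.bincount(idx, minlength=nbins)
    edges = np.arange(nbins + 1) * bin_width
    return edges, counts
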