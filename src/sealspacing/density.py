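"""Neighbourhood density: neighbour counts within fixed radii.

For each focal animal, circles of increasing radius are drawn around its
centre point (area centroid) and the centre points of all other animals on
the same site falling within each circle are counted. No edge correction is
applied, so counts near the colony boundary are biased low; the same bias
affects both species equally in a comparison.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .annotations import HaulOutSite
from .geometry import centre_point

DEFAULT_RADII = (1.0, 3.0, 5.0, 10.0)


@dataclass(frozen=True)
class DensityRecord:
    id: str
    site_id: str
    species: str
    radius: float  # metres
    count: int  # neighbours with centre point within <= radius


@dataclass(frozen=True)
class DensitySummary:
    species: str
    radius: float
    n: int
    mean: float
    median: float
    ci_low: float   # normal-approximation 95% CI of the mean
    ci_high: float
    q2_5: float     # distributional 2.5% / 97.5% quantiles, for reference
    q97_5: float


def neighbour_counts(site: HaulOutSite,
                     radii: Sequence[float] = DEFAULT_RADII,
                     ) -> list[DensityRecord]:
    """Neighbour counts for every animal at every radius.

    A neighbour is another animal whose centre point lies at Euclidean
    distance <= radius from the focal centre point (ties on the circle count
    as inside; measure-zero on real data but pinned for determinism).
    A single-animal site yields zero counts.
    """
    radii = [float(r) for r in radii]
    if any(r <= 0 for r in radii) or any(
            b <= a for a, b in zip(radii, radii[1:])):
        raise ValueError("radii must be positive and strictly increasing")
    centres = np.array(
        [[centre_point(a.polygon).x, centre_point(a.polygon).y]
         for a in site.annotations]
    )
    d = cdist(centres, centres)
    np.fill_diagonal(d, np.inf)
    out = []
    for a, row in zip(site.annotations, d):
        for r in radii:
            out.append(DensityRecord(id=a.id, site_id=site.site_id,
                                     species=a.species, radius=r,
                                     count=int((row <= r).sum())))
    return out


def records_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.id, r.site_id, r.species, r.radius, r.count) for r in records],
        columns=["id", "site_id", "species", "radius_m", "count"],
    )


def summarize_density(records: Sequence[DensityRecord]) -> list[DensitySummary]:
    """Mean, median and 95% CI of the neighbour count per species x radius.

    The CI on the mean is the normal approximation (mean +/- 1.96 * se);
    distributional 2.5/97.5% quantiles are also reported since either
    reading of a "95% CI" can be wanted for a density table.
    """
    if not records:
        raise ValueError("no density records to summarize")
    groups: dict[tuple[str, float], list[int]] = {}
    for r in records:
        groups.setdefault((r.species, r.radius), []).append(r.count)
    out = []
    for (species, radius) in sorted(groups):
        x = np.asarray(groups[(species, radius)], dtype=float)
        se = x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0
        q025, med, q975 = np.quantile(x, [0.025, 0.5, 0.975])
        out.append(DensitySummary(
            species=species, radius=radius, n=len(x), mean=float(x.mean()),
            median=float(med),
            ci_low=float(x.mean() - 1.96 * se),
            ci_high=float(x.mean() + 1.96 * se),
            q2_5=float(q025), q97_5=float(q975),
        ))
    return out
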