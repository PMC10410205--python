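"""Reading, validating and writing georeferenced seal annotations.

One annotation = one animal = one simple polygon in a projected metric CRS,
grouped into haul-out sites. Input and output are GeoJSON FeatureCollections;
tabular results are plain CSV. The CRS contract is enforced at read time:
annotations digitised in a geographic (degree-unit) CRS make every distance
in the pipeline meaningless, so they are rejected outright.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from shapely.geometry import MultiPolygon, Polygon, mapping, shape
from shapely.ops import unary_union

from .geometry import GeometryError, validate_polygon

logger = logging.getLogger(__name__)

SPECIES_VALUES = ("grey", "harbour")
SITE_SPECIES_VALUES = ("grey", "harbour", "mixed")

#: EPSG codes of common geographic (degree-unit) CRSs. Anything here, or a
#: missing CRS, is a hard error; other codes are taken to be projected with
#: metre units (the study contract; reprojection is the caller's job).
GEOGRAPHIC_EPSG = {4326, 4258, 4269, 4283, 4326, 4617, 4759, 4019}

#: Buffer (m) applied to the convex hull of a site's polygons when no
#: explicit analysis window is supplied.
DEFAULT_WINDOW_BUFFER_M = 10.0


class AnnotationError(ValueError):
    """Raised when an input file violates the annotation contract."""


@dataclass(frozen=True)
class SealAnnotation:
    """A single animal: a simple polygon outline plus its labels."""

    id: str
    site_id: str
    species: str  # "grey" | "harbour"
    polygon: Polygon

    def __post_init__(self):
        if self.species not in SPECIES_VALUES:
            raise AnnotationError(
                f"annotation {self.id!r}: unknown species {self.species!r} "
                f"(expected one of {SPECIES_VALUES})"
            )
        try:
            validate_polygon(self.polygon, what=f"annotation {self.id!r}")
        except GeometryError as exc:
            raise AnnotationError(str(exc)) from exc


@dataclass
class HaulOutSite:
    """All annotations of one haul-out site plus its analysis window.

    ``species`` is the site-level label ("mixed" when the member annotations
    disagree); mixed sites are representable but excluded from species
    comparisons by :func:`filter_sites`.
    """

    site_id: str
    species: str  # "grey" | "harbour" | "mixed"
    annotations: list[SealAnnotation]
    window: Polygon
    crs: str
    date: str | None = None
    resolution_cm: float | None = None
    pupping: bool = False

    def __post_init__(self):
        if self.species not in SITE_SPECIES_VALUES:
            raise AnnotationError(
                f"site {self.site_id!r}: unknown species {self.species!r}"
            )
        for ann in self.annotations:
            if ann.site_id != self.site_id:
                raise AnnotationError(
                    f"annotation {ann.id!r} carries site_id {ann.site_id!r} "
                    f"inside site {self.site_id!r}"
                )
            if not self.window.covers(ann.polygon):
                raise AnnotationError(
                    f"site {self.site_id!r}: window does not contain "
                    f"annotation {ann.id!r}"
                )

    @property
    def n(self) -> int:
        return len(self.annotations)


def _parse_epsg(crs_obj) -> tuple[str, int | None]:
    """Normalise the GeoJSON ``crs`` member to a display string and an EPSG
    code (None when the code cannot be extracted)."""
    if isinstance(crs_obj, str):
        name = crs_obj
    elif isinstance(crs_obj, Mapping):
        name = str(crs_obj.get("properties", {}).get("name", ""))
    else:
        name = ""
    if not name:
        return "", None
    if "CRS84" in name.upper():
        return name, 4326
    m = re.search(r"EPSG[:]{1,2}(\d+)", name, flags=re.IGNORECASE)
    return name, (int(m.group(1)) if m else None)


def _check_crs(crs_obj, path) -> str:
    name, code = _parse_epsg(crs_obj)
    if not name:
        raise AnnotationError(
            f"{path}: no CRS metadata; a projected metric CRS "
            "(e.g. EPSG:28992) is required"
        )
    if code in GEOGRAPHIC_EPSG:
        raise AnnotationError(
            f"{path}: CRS {name!r} uses degrees; projected metric CRS required"
        )
    return name


def default_window(polygons: Sequence[Polygon],
                   buffer_m: float = DEFAULT_WINDOW_BUFFER_M) -> Polygon:
    """Convex hull of all polygons, buffered. Used when no explicit analysis
    window is supplied: bounded, contains every animal, reproducible."""
    return unary_union(list(polygons)).convex_hull.buffer(buffer_m)


def _normalise_species(value, feature_id) -> str:
    v = str(value).strip().lower()
    aliases = {"grey": "grey", "gray": "grey", "halichoerus grypus": "grey",
               "hg": "grey", "harbour": "harbour", "harbor": "harbour",
               "phoca vitulina": "harbour", "pv": "harbour"}
    if v not in aliases:
        raise AnnotationError(
            f"feature {feature_id!r}: unknown species value {value!r}"
        )
    return aliases[v]


def read_annotations(path,
                     species_field: str = "species",
                     site_field: str = "site",
                     split_multipolygons: bool = False,
                     window_buffer_m: float = DEFAULT_WINDOW_BUFFER_M,
                     windows: Mapping[str, Polygon] | None = None,
                     ) -> list[HaulOutSite]:
    """Read a GeoJSON FeatureCollection of seal outlines into sites.

    Each polygon feature becomes one :class:`SealAnnotation`; features are
    grouped by ``site_field``. A site whose features carry more than one
    species value is labelled "mixed". Multipolygon features are rejected
    unless ``split_multipolygons`` is set, in which case the largest part is
    kept (annotation artefacts should be surfaced, not silently absorbed).

    ``windows`` may supply an explicit analysis window per site; otherwise
    the window defaults to the convex hull of the site's polygons buffered
    by ``window_buffer_m`` metres.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise AnnotationError(f"{path}: expected a GeoJSON FeatureCollection")
    crs = _check_crs(doc.get("crs"), path)

    per_site: dict[str, list[SealAnnotation]] = {}
    site_meta: dict[str, dict] = {}
    bad: list[str] = []
    for i, feat in enumerate(doc.get("features", [])):
        props = feat.get("properties") or {}
        fid = str(feat.get("id", props.get("id", i)))
        geom = shape(feat["geometry"])
        if isinstance(geom, MultiPolygon):
            if not split_multipolygons:
                raise AnnotationError(
                    f"{path}: feature {fid!r} is a MultiPolygon; one animal "
                    "must be one polygon (use split_multipolygons to keep "
                    "the largest part)"
                )
            geom = max(geom.geoms, key=lambda g: g.area)
        if not isinstance(geom, Polygon):
            raise AnnotationError(
                f"{path}: feature {fid!r} has geometry type "
                f"{geom.geom_type!r}; Polygon required"
            )
        if site_field not in props:
            raise AnnotationError(
                f"{path}: feature {fid!r} lacks site attribute {site_field!r}"
            )
        site_id = str(props[site_field])
        species = _normalise_species(props.get(species_field), fid)
        try:
            ann = SealAnnotation(id=fid, site_id=site_id, species=species,
                                 polygon=geom)
        except AnnotationError:
            bad.append(fid)
            continue
        per_site.setdefault(site_id, []).append(ann)
        meta = site_meta.setdefault(site_id, {"pupping": False, "date": None,
                                              "resolution_cm": None})
        meta["pupping"] = meta["pupping"] or bool(props.get("pupping", False))
        meta["date"] = meta["date"] or props.get("date")
        if props.get("resolution_cm") is not None:
            meta["resolution_cm"] = float(props["resolution_cm"])
    if bad:
        raise AnnotationError(
            f"{path}: invalid polygon geometry in features {bad!r}"
        )
    if not per_site:
        raise AnnotationError(f"{path}: no polygon features found")

    sites = []
    for site_id in sorted(per_site):
        anns = sorted(per_site[site_id], key=lambda a: a.id)
        species_set = {a.species for a in anns}
        site_species = species_set.pop() if len(species_set) == 1 else "mixed"
        if windows is not None and site_id in windows:
            window = windows[site_id]
        else:
            window = default_window([a.polygon for a in anns], window_buffer_m)
        meta = site_meta[site_id]
        sites.append(HaulOutSite(site_id=site_id, species=site_species,
                                 annotations=anns, window=window, crs=crs,
                                 date=meta["date"],
                                 resolution_cm=meta["resolution_cm"],
                                 pupping=meta["pupping"]))
    return sites


def write_annotations(sites: Iterable[HaulOutSite], path) -> None:
    """Write sites back to a single GeoJSON FeatureCollection (with a legacy
    ``crs`` member so the round trip preserves the CRS contract)."""
    sites = list(sites)
    if not sites:
        raise AnnotationError("no sites to write")
    features = []
    for site in sites:
        for ann in site.annotations:
            features.append({
                "type": "Feature",
                "id": ann.id,
                "properties": {"id": ann.id, "site": ann.site_id,
                               "species": ann.species,
                               "pupping": site.pupping},
                "geometry": mapping(ann.polygon),
            })
    doc = {
        "type": "FeatureCollection",
        "crs": {"type": "name", "properties": {"name": sites[0].crs}},
        "features": features,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


def filter_sites(sites: Sequence[HaulOutSite],
                 exclude_mixed: bool = True,
                 exclude_pupping: bool = True,
                 pupping_site_ids: Sequence[str] = (),
                 ) -> list[HaulOutSite]:
    """Drop sites that cannot enter the species comparison.

    Mixed-species sites and sites photographed during the pupping season
    (flagged on the site or listed in ``pupping_site_ids``) are removed;
    every exclusion is logged with its reason.
    """
    kept = []
    for site in sites:
        if exclude_mixed and site.species == "mixed":
            logger.info("excluding site %s: mixed-species colony", site.site_id)
            continue
        if exclude_pupping and (site.pupping or site.site_id in set(pupping_site_ids)):
            logger.info("excluding site %s: pupping season", site.site_id)
            continue
        kept.append(site)
    return kept


def write_table(records, path) -> None:
    """Write tabular records (dataclasses, dicts or a DataFrame) as CSV.

    UTF-8, '.' decimal separator, deterministic row order (sorted by
    site_id then id where those columns exist). Floats are written at full
    repr precision so a re-read reproduces values exactly.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        records = list(records)
        if not records:
            raise ValueError("no records to write")
        if dataclasses.is_dataclass(records[0]):
            df = pd.DataFrame([dataclasses.asdict(r) for r in records])
        else:
            df = pd.DataFrame(records)
    if df.empty:
        raise ValueError("no records to write")
    sort_cols = [c for c in ("site_id", "id") if c in df.columns]
    if sort_cols:
        df = df.sort_values(sort_cols, kind="mergesort")
    df.to_csv(path, index=False, encoding="utf-8")
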