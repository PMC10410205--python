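"""Annotation I/O contract: GeoJSON round trips, CRS and species
validation, site filtering, CSV writing."""
import json

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon, mapping

from sealspacing.annotations import (AnnotationError, SealAnnotation,
                                     filter_sites, read_annotations,
                                     write_annotations, write_table)

from conftest import make_site, square


def _feature(fid, site, species, poly, **extra):
    return {"type": "Feature", "id": fid,
            "properties": {"site": site, "species": species, **extra},
            "geometry": mapping(poly)}


def _collection(features, crs="EPSG:28992"):
    doc = {"type": "FeatureCollection", "features": features}
    if crs is not None:
        doc["crs"] = {"type": "name",
                      "properties": {"name": f"urn:ogc:def:crs:{crs.replace(':', '::')}"}}
    return doc


def _write(tmp_path, doc, name="ann.geojson"):
    p = tmp_path / name
    p.write_text(json.dumps(doc))
    return p


class TestRead:
    def test_three_features_one_site(self, tmp_path):
        feats = [_feature(f"f{i}", "A", "grey", square(3 * i, 0))
                 for i in range(3)]
        sites = read_annotations(_write(tmp_path, _collection(feats)))
        assert len(sites) == 1
        (site,) = sites
        assert site.site_id == "A" and site.species == "grey" and site.n == 3

    def test_geographic_crs_rejected(self, tmp_path):
        feats = [_feature("f0", "A", "grey", square(0, 0))]
        path = _write(tmp_path, _collection(feats, crs="EPSG:4326"))
        with pytest.raises(AnnotationError, match="projected metric CRS"):
            read_annotations(path)

    def test_missing_crs_rejected(self, tmp_path):
        feats = [_feature("f0", "A", "grey", square(0, 0))]
        path = _write(tmp_path, _collection(feats, crs=None))
        with pytest.raises(AnnotationError, match="CRS"):
            read_annotations(path)

    def test_unknown_species_rejected(self, tmp_path):
        feats = [_feature("f0", "A", "walrus", square(0, 0))]
        with pytest.raises(AnnotationError, match="species"):
            read_annotations(_write(tmp_path, _collection(feats)))

    def test_invalid_geometry_names_feature(self, tmp_path):
        bowtie = {"type": "Polygon",
                  "coordinates": [[(0, 0), (1, 1), (1, 0), (0, 1), (0, 0)]]}
        feats = [_feature("f0", "A", "grey", square(0, 0))]
        feats.append({"type": "Feature", "id": "bad",
                      "properties": {"site": "A", "species": "grey"},
                      "geometry": bowtie})
        with pytest.raises(AnnotationError, match="bad"):
            read_annotations(_write(tmp_path, _collection(feats)))

    def test_multipolygon_rejected_by_default_split_on_request(self, tmp_path):
        mp = {"type": "MultiPolygon",
              "coordinates": [
                  [[(0, 0), (2, 0), (2, 1), (0, 1), (0, 0)]],
                  [[(5, 5), (5.1, 5), (5.1, 5.1), (5, 5.1), (5, 5)]]]}
        feats = [{"type": "Feature", "id": "m0",
                  "properties": {"site": "A", "species": "grey"},
                  "geometry": mp}]
        path = _write(tmp_path, _collection(feats))
        with pytest.raises(AnnotationError, match="MultiPolygon"):
            read_annotations(path)
        (site,) = read_annotations(path, split_multipolygons=True)
        assert site.n == 1
        assert site.annotations[0].polygon.area == pytest.approx(2.0)

    def test_mixed_species_site_labelled_mixed(self, tmp_path):
        feats = [_feature("f0", "A", "grey", square(0, 0)),
                 _feature("f1", "A", "harbour", square(3, 0))]
        (site,) = read_annotations(_write(tmp_path, _collection(feats)))
        assert site.species == "mixed"

    def test_default_window_contains_everything(self, tmp_path):
        feats = [_feature(f"f{i}", "A", "grey", square(7 * i, 0))
                 for i in range(4)]
        (site,) = read_annotations(_write(tmp_path, _collection(feats)))
        for ann in site.annotations:
            assert site.window.covers(ann.polygon)
            # buffered by 10 m: strictly larger than the bare hull
            assert site.window.exterior.distance(ann.polygon) > 1.0


class TestRoundTrip:
    def test_read_write_read_preserves_vertices_and_attributes(self, tmp_path):
        rng = np.random.default_rng(5)
        feats = []
        for i in range(6):
            poly = Polygon(np.asarray(square(4 * i, 0).exterior.coords)
                           + rng.uniform(0, 1e-3, (5, 2)))
            feats.append(_feature(f"f{i}", "A" if i < 3 else "B",
                                  "grey" if i < 3 else "harbour", poly))
        sites1 = read_annotations(_write(tmp_path, _collection(feats)))
        out = tmp_path / "round.geojson"
        write_annotations(sites1, out)
        sites2 = read_annotations(out)
        assert [s.site_id for s in sites2] == [s.site_id for s in sites1]
        for s1, s2 in zip(sites1, sites2):
            assert s2.species == s1.species and s2.crs == s1.crs
            for a1, a2 in zip(s1.annotations, s2.annotations):
                assert a1.id == a2.id and a1.species == a2.species
                assert np.allclose(np.asarray(a1.polygon.exterior.coords),
                                   np.asarray(a2.polygon.exterior.coords),
                                   atol=1e-9)


class TestFilterSites:
    def test_mixed_removed(self):
        sites = [make_site([square(0, 0), square(2, 0)], "grey", "g1"),
                 make_site([square(0, 0), square(2, 0)], "mixed", "m1"),
                 make_site([square(0, 0), square(2, 0)], "harbour", "h1")]
        kept = filter_sites(sites)
        assert [s.site_id for s in kept] == ["g1", "h1"]

    def test_empty_input(self):
        assert filter_sites([]) == []

    def test_study_design_counts(self):
        # 11 sites: 2 grey + 6 harbour (1 pupping) + 3 mixed -> 7 retained
        sites = (
            [make_site([square(0, 0), square(2, 0)], "grey", f"g{i}")
             for i in range(2)]
            + [make_site([square(0, 0), square(2, 0)], "harbour", f"h{i}",
                         pupping=(i == 0)) for i in range(6)]
            + [make_site([square(0, 0), square(2, 0)], "mixed", f"m{i}")
               for i in range(3)]
        )
        kept = filter_sites(sites)
        assert len(kept) == 7
        assert sum(s.species == "grey" for s in kept) == 2
        assert sum(s.species == "harbour" for s in kept) == 5

    def test_pupping_by_id_list(self):
        sites = [make_site([square(0, 0), square(2, 0)], "harbour", "h1")]
        assert filter_sites(sites, pupping_site_ids=["h1"]) == []


class TestWriteTable:
    def test_roundtrip_full_precision_and_sorted(self, tmp_path):
        rows = [{"site_id": "B", "id": "x", "value": 1 / 3},
                {"site_id": "A", "id": "y", "value": np.pi * 1e-7}]
        out = tmp_path / "t.csv"
        write_table(rows, out)
        back = pd.read_csv(out)
        assert list(back["site_id"]) == ["A", "B"]  # deterministic order
        assert back["value"].tolist() == [np.pi * 1e-7, 1 / 3]  # exact

    def test_empty_errors(self, tmp_path):
        with pytest.raises(ValueError):
            write_table([], tmp_path / "t.csv")

    def test_annotation_invariants_enforced_on_construction(self):
        with pytest.raises(AnnotationError):
            SealAnnotation(id="a", site_id="s", species="grey",
                           polygon=Polygon([(0, 0), (1, 1), (1, 0), (0, 1)]))
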