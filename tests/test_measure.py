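"""Measurement engine: primitives, mesh sections, catalog evaluation."""

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings
from hypothesis import strategies as st

import acroface as af
from acroface.landmarks import ReferencePlane, ValidationError
from acroface.measure import (
    _chain_segments,
    extract_profile_curves,
    mesh_plane_section,
    semi_perimeter,
)

from conftest import random_rotation

coord = st.floats(-100, 100, allow_nan=False)
point = st.tuples(coord, coord, coord).map(np.array)


class TestPrimitives:
    def test_linear_distance_examples(self):
        assert af.linear_distance((0, 0, 0), (3, 4, 0)) == pytest.approx(5.0)
        assert af.linear_distance((1, 2, 3), (1, 2, 3)) == 0.0
        with pytest.raises(ValidationError):
            af.linear_distance((np.nan, 0, 0), (0, 0, 0))

    @given(p=point, q=point)
    @settings(max_examples=50, deadline=None)
    def test_linear_distance_matches_coordinatewise_formula(self, p, q):
        expect = np.sqrt(sum((a - b) ** 2 for a, b in zip(p, q)))
        assert af.linear_distance(p, q) == pytest.approx(expect, abs=1e-12)

    def test_polyline_length(self):
        assert af.polyline_length([(0, 0, 0), (1, 0, 0), (1, 1, 0)]) == pytest.approx(2.0)
        p, q = np.array([1.0, 2, 3]), np.array([4.0, 6, 3])
        assert af.polyline_length([p, q]) == af.linear_distance(p, q)
        with pytest.raises(ValidationError):
            af.polyline_length([(0, 0, 0)])

    def test_polyline_semicircle_closed_form(self):
        theta = np.linspace(0, np.pi, 100)
        pts = np.column_stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)])
        assert af.polyline_length(pts) == pytest.approx(np.pi, abs=1e-3)

    def test_angle_examples(self):
        assert af.angle_at((1, 0, 0), (0, 0, 0), (0, 1, 0)) == pytest.approx(90.0)
        assert af.angle_at((2, 0, 0), (0, 0, 0), (5, 0, 0)) == pytest.approx(0.0)
        assert af.angle_at((-1, 0, 0), (0, 0, 0), (5, 0, 0)) == pytest.approx(180.0)
        with pytest.raises(ValidationError):
            af.angle_at((0, 0, 0), (0, 0, 0), (1, 0, 0))

    @given(p=point, v=point, q=point)
    @settings(max_examples=50, deadline=None)
    def test_angle_matches_arccos_oracle(self, p, v, q):
        u, w = p - v, q - v
        if np.linalg.norm(u) < 1e-6 or np.linalg.norm(w) < 1e-6:
            return
        c = np.clip(np.dot(u, w) / (np.linalg.norm(u) * np.linalg.norm(w)), -1, 1)
        assert af.angle_at(p, v, q) == pytest.approx(np.degrees(np.arccos(c)), abs=1e-5)

    def test_signed_plane_distance(self):
        pl = ReferencePlane("TVL", np.array([1.0, 2, 3]), np.array([0.0, 0, 1]), "anterior")
        assert af.signed_plane_distance(pl.point, pl) == 0.0
        assert af.signed_plane_distance(pl.point + 2 * pl.normal, pl) == pytest.approx(2.0)

    def test_index_value_table_op(self):
        import pandas as pd

        values = pd.DataFrame({"ICW": [41.56, 10.0, 5.0], "BnW": [93.60, 10.0, 0.0]},
                              index=["a", "b", "c"])
        design = pd.DataFrame({"sex": ["male"] * 3, "group": ["control"] * 3},
                              index=values.index)
        table = af.FeatureTable(values, design, {"ICW": "mm", "BnW": "mm"})
        out = af.index_value("ICW", "BnW", table)
        assert out["a"] == pytest.approx(44.40, abs=0.005)
        assert out["b"] == pytest.approx(100.0)
        assert np.isnan(out["c"])  # zero denominator -> missing
        doubled = af.FeatureTable(values * 2, design, table.units)
        np.testing.assert_allclose(
            af.index_value("ICW", "BnW", doubled)[:2], out[:2])


class TestMeshSection:
    def test_unit_cube_midheight_is_square(self):
        box = trimesh.creation.box(extents=(1, 1, 1))
        pl = ReferencePlane("FH", np.zeros(3), np.array([0.0, 1, 0]), "superior")
        polys = mesh_plane_section(np.asarray(box.vertices), np.asarray(box.faces), pl)
        assert len(polys) == 1
        loop = polys[0]
        np.testing.assert_allclose(loop[0], loop[-1], atol=1e-9)  # closed
        assert af.polyline_length(loop) == pytest.approx(4.0, abs=1e-9)

    def test_icosphere_great_circle_within_one_percent(self):
        s = trimesh.creation.icosphere(subdivisions=4)
        pl = ReferencePlane("FH", np.zeros(3), np.array([0.0, 1, 0]), "superior")
        polys = mesh_plane_section(np.asarray(s.vertices) * 10, np.asarray(s.faces), pl)
        total = sum(af.polyline_length(p) for p in polys)
        assert total == pytest.approx(2 * np.pi * 10, rel=0.01)

    def test_plane_missing_mesh_gives_empty(self):
        box = trimesh.creation.box(extents=(1, 1, 1))
        pl = ReferencePlane("FH", np.array([0.0, 10, 0]), np.array([0.0, 1, 0]), "superior")
        assert mesh_plane_section(np.asarray(box.vertices), np.asarray(box.faces), pl) == []

    def test_chaining_merges_shuffled_segments(self):
        # a square broken into 8 half-edges, shuffled
        corners = np.array([[0, 0, 0], [1, 0, 0], [1, 0, 1], [0, 0, 1]], float)
        segs = []
        for i in range(4):
            a, b = corners[i], corners[(i + 1) % 4]
            mid = (a + b) / 2
            segs += [[a, mid], [mid, b]]
        rng = np.random.default_rng(0)
        segs = np.array(segs)[rng.permutation(8)]
        polys = _chain_segments(segs, 1e-9)
        assert len(polys) == 1
        assert af.polyline_length(polys[0]) == pytest.approx(4.0)


class TestSemiPerimeter:
    @staticmethod
    def _vertical_cylinder(radius=5.0, height=20.0):
        c = trimesh.creation.cylinder(radius=radius, height=height, sections=256)
        c.apply_transform(trimesh.transformations.rotation_matrix(np.pi / 2, [1, 0, 0]))
        return np.asarray(c.vertices), np.asarray(c.faces)

    @staticmethod
    def _plumbs(z):
        n = np.array([0.0, 0, 1])
        return [
            ReferencePlane("plumb_left", np.array([5.0, 0, z]), n, "anterior"),
            ReferencePlane("plumb_right", np.array([-5.0, 0, z]), n, "anterior"),
        ]

    def test_half_cylinder_closed_form(self):
        v, f = self._vertical_cylinder()
        level = ReferencePlane("FH", np.zeros(3), np.array([0.0, 1, 0]), "superior")
        sp = semi_perimeter(v, f, level, self._plumbs(0.0))
        assert sp == pytest.approx(np.pi * 5, rel=1e-3)

    def test_noop_clip_returns_full_section(self):
        v, f = self._vertical_cylinder()
        level = ReferencePlane("FH", np.zeros(3), np.array([0.0, 1, 0]), "superior")
        sp = semi_perimeter(v, f, level, self._plumbs(-100.0))
        assert sp == pytest.approx(2 * np.pi * 5, rel=1e-3)

    def test_empty_section_is_missing(self):
        v, f = self._vertical_cylinder()
        level = ReferencePlane("FH", np.array([0.0, 100, 0]), np.array([0.0, 1, 0]), "superior")
        assert np.isnan(semi_perimeter(v, f, level, self._plumbs(0.0)))

    def test_semi_perimeters_rigid_invariant(self, template_scan_mesh):
        base = af.measure_all(template_scan_mesh)
        rng = np.random.default_rng(11)
        moved = template_scan_mesh.transformed(random_rotation(rng), rng.standard_normal(3) * 30)
        after = af.measure_all(moved)
        for mid in ("PTGP", "PMFP", "PTNP"):
            assert after.values[mid] == pytest.approx(base.values[mid], abs=1e-6)


class TestProfileCurves:
    def test_lip_curve_passes_near_lip_landmarks(self, template_scan_mesh):
        aligned, _ = af.align_frankfort(template_scan_mesh)
        planes = af.build_reference_planes(aligned)
        curves = extract_profile_curves(aligned, planes)
        lip = curves["lip"]

        def seg_dist(p):
            a, b = lip[:-1], lip[1:]
            ab = b - a
            t = np.clip(np.einsum("ij,ij->i", p - a, ab) / np.einsum("ij,ij->i", ab, ab), 0, 1)
            return np.linalg.norm(a + t[:, None] * ab - p, axis=1).min()

        for code in ("ls", "sto", "li"):
            d = seg_dist(aligned.coords[code])
            assert d < 1.0, f"{code} is {d:.2f} mm from the lip profile"

    def test_inverted_window_raises(self, template_scan_mesh):
        aligned, _ = af.align_frankfort(template_scan_mesh)
        coords = dict(aligned.coords)
        coords["sn"], coords["sm"] = coords["sm"], coords["sn"]  # invert lip window
        bad = af.FaceScan("s", "male", "control", coords,
                          aligned.mesh_vertices, aligned.mesh_faces)
        planes = af.build_reference_planes(aligned)
        with pytest.raises(ValidationError, match="inverted"):
            extract_profile_curves(bad, planes)

    def test_profile_shape_rigid_invariant(self, template_scan_mesh):
        aligned, _ = af.align_frankfort(template_scan_mesh)
        planes = af.build_reference_planes(aligned)
        lip0 = extract_profile_curves(aligned, planes)["lip"]
        rng = np.random.default_rng(3)
        moved = template_scan_mesh.transformed(random_rotation(rng), rng.standard_normal(3))
        re_aligned, _ = af.align_frankfort(moved)
        lip1 = extract_profile_curves(re_aligned, af.build_reference_planes(re_aligned))["lip"]
        assert af.polyline_length(lip1) == pytest.approx(af.polyline_length(lip0), abs=1e-6)


class TestMeasureAll:
    def test_full_catalog_complete_with_mesh(self, template_scan_mesh):
        fv = af.measure_all(template_scan_mesh)
        assert len(fv.values) == 58
        assert fv.n_missing() == 0

    def test_without_mesh_sections_missing_curves_fall_back(self, template_scan):
        fv = af.measure_all(template_scan)
        missing = sorted(k for k, v in fv.values.items() if not np.isfinite(v))
        assert missing == ["PMFP", "PTGP", "PTNP"]
        assert fv.provenance["MCL"] == "landmark_chain"
        fv2 = af.measure_all(template_scan, curve_fallback=False)
        also = sorted(k for k, v in fv2.values.items() if not np.isfinite(v))
        assert also == ["LVCL", "PMFP", "PTGP", "PTNP", "UVCL"]

    def test_missing_landmark_yields_diagnostic_not_crash(self, template_scan):
        coords = dict(template_scan.coords)
        del coords["al_l"]
        fv = af.measure_all(af.FaceScan("s", "male", "control", coords))
        assert np.isnan(fv.values["NW"])
        assert "al_l" in fv.diagnostics["NW"]
        assert np.isfinite(fv.values["MFH"])

    def test_homogeneity_under_uniform_scaling(self, template_scan):
        base = af.measure_all(template_scan)
        scaled_scan = af.FaceScan(
            "s2", "male", "control", {k: 2.0 * p for k, p in template_scan.coords.items()}
        )
        scaled = af.measure_all(scaled_scan)
        units = af.default_catalog().units()
        for mid, v in base.values.items():
            if not np.isfinite(v):
                continue
            factor = 2.0 if units[mid] == "mm" else 1.0
            assert scaled.values[mid] == pytest.approx(factor * v, abs=1e-6), mid

    def test_rigid_invariance_of_all_values(self, template_scan):
        base = af.measure_all(template_scan)
        rng = np.random.default_rng(21)
        moved = template_scan.transformed(random_rotation(rng), rng.standard_normal(3) * 40)
        after = af.measure_all(moved)
        for mid, v in base.values.items():
            if np.isfinite(v):
                assert after.values[mid] == pytest.approx(v, abs=1e-6), mid

    def test_mirror_symmetry_leaves_catalog_unchanged(self, template_scan):
        base = af.measure_all(template_scan)
        mirror = {}
        for k, p in template_scan.coords.items():
            mk = k
            if k.endswith("_l"):
                mk = k[:-2] + "_r"
            elif k.endswith("_r"):
                mk = k[:-2] + "_l"
            mirror[mk] = p * np.array([-1.0, 1.0, 1.0])
        fv = af.measure_all(af.FaceScan("m", "male", "control", mirror))
        for mid, v in base.values.items():
            if np.isfinite(v):
                assert fv.values[mid] == pytest.approx(v, abs=1e-6), mid

    def test_catalog_has_58_unique_ids_and_topological_order(self):
        cat = af.default_catalog()
        assert len(cat) == 58
        order = cat.evaluation_order()
        seen = set()
        for mid in order:
            assert cat[mid].dependencies() <= seen
            seen.add(mid)

    def test_feature_table_csv_roundtrip(self, template_scan, tmp_path):
        table = af.measure_cohort([template_scan])
        path = tmp_path / "features.csv"
        table.to_csv(path)
        back = af.FeatureTable.from_csv(path)
        np.testing.assert_allclose(
            back.values.to_numpy(float), table.values.to_numpy(float), rtol=1e-12)
        assert back.units["MFH"] == "mm"
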