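"""3D mesh morphometry: STL parsing, volume/area, principal frames,
dimensionless descriptors, convexity, dihedral census."""

import io
import math

import numpy as np
import pytest
import trimesh as _trimesh
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from fbmorph import mesh as M
from fbmorph.errors import (
    DegenerateGeometryError,
    EmptyInputError,
    MeshParseError,
)
from fbmorph.fixtures import make_mesh


def _cube_ascii_stl(path):
    box = _trimesh.creation.box(extents=(1, 1, 1))
    tri = box.vertices[box.faces]
    with open(path, "w") as fh:
        fh.write("solid cube\n")
        for t in tri:
            n = np.cross(t[1] - t[0], t[2] - t[0])
            n = n / np.linalg.norm(n)
            fh.write(f"facet normal {n[0]} {n[1]} {n[2]}\n outer loop\n")
            for v in t:
                fh.write(f"  vertex {v[0]} {v[1]} {v[2]}\n")
            fh.write(" endloop\nendfacet\n")
        fh.write("endsolid cube\n")


class TestLoadStl:
    def test_ascii_cube_dedup_and_watertight(self, tmp_path):
        p = tmp_path / "cube.stl"
        _cube_ascii_stl(p)
        m = M.load_stl(p)
        assert len(m.vertices) == 8
        assert len(m.faces) == 12
        assert m.watertight

    def test_binary_matches_ascii(self, tmp_path):
        pa = tmp_path / "cube.stl"
        _cube_ascii_stl(pa)
        pb = tmp_path / "cube_bin.stl"
        _trimesh.creation.box(extents=(1, 1, 1)).export(str(pb))
        ma, mb = M.load_stl(pa), M.load_stl(pb)
        assert mb.watertight
        assert len(mb.vertices) == len(ma.vertices) == 8
        assert M.signed_volume(ma) == pytest.approx(M.signed_volume(mb), rel=1e-12)

    def test_truncated_file_raises_parse_error(self, tmp_path):
        p = tmp_path / "bad.stl"
        p.write_bytes(b"\x00" * 90)  # shorter than a binary STL header
        with pytest.raises((MeshParseError, EmptyInputError)):
            M.load_stl(p)

    def test_missing_face_breaks_watertightness(self):
        box = _trimesh.creation.box(extents=(1, 1, 1))
        m = M.TriMesh.from_arrays(box.vertices, box.faces[:-1])
        assert not m.watertight
        assert m.boundary_edge_count == 3


class TestVolumeArea:
    def test_unit_cube(self):
        m, _ = make_mesh("box", {"extents": (1.0, 1.0, 1.0)})
        assert M.signed_volume(m) == pytest.approx(1.0, rel=1e-12)
        assert M.surface_area(m) == pytest.approx(6.0, rel=1e-12)

    def test_icosphere_converges_to_analytic(self):
        m, _ = make_mesh("icosphere", {"radius": 5.0, "subdivisions": 4})
        assert M.signed_volume(m) == pytest.approx(4 / 3 * math.pi * 125, rel=5e-3)
        assert M.surface_area(m) == pytest.approx(4 * math.pi * 25, rel=5e-3)

    def test_translation_invariance(self):
        m, _ = make_mesh("box", {"extents": (2.0, 3.0, 4.0)})
        v0 = M.signed_volume(m)
        shifted = M.TriMesh.from_arrays(
            m.vertices + np.array([100.0, -50.0, 3.0]), m.faces
        )
        assert M.signed_volume(shifted) == pytest.approx(v0, rel=1e-9)

    def test_area_scales_quadratically(self):
        m, _ = make_mesh("capsule", {})
        a0 = M.surface_area(m)
        scaled = M.TriMesh.from_arrays(m.vertices * 3.0, m.faces)
        assert M.surface_area(scaled) == pytest.approx(9.0 * a0, rel=1e-12)

    def test_nonwatertight_warns_but_returns(self):
        box = _trimesh.creation.box(extents=(1, 1, 1))
        m = M.TriMesh.from_arrays(box.vertices, box.faces[:-1])
        with pytest.warns(UserWarning, match="not watertight"):
            v = M.signed_volume(m)
        assert 0 < v <= 1.0

    def test_divergence_oracle_agrees(self, mesh_suite):
        """Signed-tetrahedron volume vs divergence-theorem flux, < 0.1%."""
        for m, _ in mesh_suite:
            v1, v2 = M.signed_volume(m), M.divergence_volume(m)
            assert abs(v1 / v2 - 1) < 1e-3, m.name

    def test_refinement_monotone(self):
        errs_v, errs_a = [], []
        for sub in (1, 2, 3, 4):
            m, _ = make_mesh("icosphere", {"radius": 5.0, "subdivisions": sub})
            errs_v.append(abs(M.signed_volume(m) - 4 / 3 * math.pi * 125))
            errs_a.append(abs(M.surface_area(m) - 4 * math.pi * 25))
        assert errs_v == sorted(errs_v, reverse=True)
        assert errs_a == sorted(errs_a, reverse=True)


class TestPrincipalFrame:
    def test_axis_aligned_box_extents(self):
        m, _ = make_mesh("box", {"extents": (8.0, 6.0, 4.0)})
        fr = M.principal_frame(m)
        assert np.allclose(fr.extents, [8.0, 6.0, 4.0], atol=1e-9)

    def test_rotation_leaves_extents(self):
        m, _ = make_mesh("box", {"extents": (8.0, 6.0, 4.0)})
        R = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        rot = M.TriMesh.from_arrays(m.vertices @ R.T, m.faces)
        fr = M.principal_frame(rot)
        assert np.allclose(fr.extents, [8.0, 6.0, 4.0], atol=1e-9)

    def test_rank_deficient_raises(self):
        # all vertices coplanar
        verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.0]])
        faces = np.array([[0, 1, 2], [1, 3, 2]])
        m = M.TriMesh.from_arrays(verts, faces)
        with pytest.raises(DegenerateGeometryError, match="rank"):
            M.principal_frame(m)

    def test_inertia_frame_agreement(self, mesh_suite):
        """PCA-frame extents vs uniform-density inertia-frame extents < 2%."""
        for m, gt in mesh_suite:
            if gt.generator_params["kind"] not in ("box", "ellipsoid", "capsule"):
                continue
            e_pca = M.principal_frame(m).extents
            e_in = M.inertia_frame(m).extents
            assert np.max(np.abs(e_pca / e_in - 1)) < 0.02, m.name

    def test_inertia_frame_matches_trimesh_axes(self):
        m, _ = make_mesh("box", {"extents": (10.0, 4.0, 2.0), "rotate": True}, seed=3)
        tm = _trimesh.Trimesh(m.vertices, m.faces, process=False)
        ours = M.inertia_frame(m).axes
        theirs = tm.principal_inertia_vectors
        # same axes up to sign/order: absolute dot products ~ permutation
        dots = np.abs(ours @ np.asarray(theirs).T)
        assert np.allclose(np.sort(dots.max(axis=1)), [1, 1, 1], atol=1e-4)


class TestDimensionlessShape:
    def test_sphere_limit(self):
        m, _ = make_mesh("icosphere", {"radius": 5.0, "subdivisions": 4})
        fr = M.principal_frame(m)
        e, f, psi = M.dimensionless_shape(
            fr, 4 / 3 * math.pi * 125, 4 * math.pi * 25
        )
        assert e == pytest.approx(0.0, abs=2e-3)
        assert f == pytest.approx(0.0, abs=2e-3)
        assert psi == pytest.approx(1.0, abs=1e-9)

    def test_case_sphericity_from_printed_v_and_a(self):
        assert round(M.sphericity(73.3, 106.3), 2) == 0.80

    def test_elongation_formula_on_case_extents(self):
        """The quadratic elongation formula evaluated literally on the case
        extents gives 0.70 (the sqrt variant 0.84 is diagnostic-only)."""
        fr = M.PrincipalFrame(
            centroid=np.zeros(3), axes=np.eye(3),
            extents=np.array([8.24, 5.72, 4.51]),
            eigenvalues=np.array([3.0, 2.0, 1.0]),
        )
        e, f, _ = M.dimensionless_shape(fr, 73.3, 106.3)
        assert round(e, 2) == 0.70
        assert round(f, 2) == 0.52
        diag = M.shape_diagnostics(fr)
        assert round(diag["elongation_sqrt"], 2) == 0.84
        assert round(diag["flatness_sqrt"], 2) == 0.72


class TestConvexity:
    @pytest.mark.parametrize("kind,params", [
        ("box", {"extents": (2.0, 3.0, 4.0)}),
        ("icosphere", {"radius": 3.0, "subdivisions": 2}),
    ])
    def test_convex_bodies_equal_their_hull(self, kind, params):
        m, _ = make_mesh(kind, params)
        assert M.convexity_ratio(m) == pytest.approx(1.0, abs=1e-6)

    def test_notched_box_analytic(self):
        m, gt = make_mesh("notched_box", {})
        assert M.convexity_ratio(m) == pytest.approx(
            gt.analytic["convexity_ratio"], rel=1e-6
        )

    def test_rigid_motion_invariance(self):
        p = {"extents": (10.0, 8.0, 6.0), "notch_width_frac": 0.3,
             "notch_depth_frac": 0.6}
        m0, _ = make_mesh("notched_box", p)
        m1, _ = make_mesh("notched_box", {**p, "rotate": True}, seed=11)
        assert M.convexity_ratio(m1) == pytest.approx(
            M.convexity_ratio(m0), rel=1e-9
        )


class TestDihedral:
    def test_cube_has_no_strictly_sharp_edges(self):
        m, _ = make_mesh("box", {"extents": (1.0, 1.0, 1.0)})
        count, min_deg = M.dihedral_sharpness(m)
        assert count == 0
        assert min_deg == pytest.approx(90.0, abs=1e-9)

    def test_regular_tetrahedron_closed_form(self):
        verts = np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
        )
        faces = np.array([[0, 1, 2], [0, 3, 1], [0, 2, 3], [1, 3, 2]])
        m = M.TriMesh.from_arrays(verts, faces)
        count, min_deg = M.dihedral_sharpness(m)
        assert count == 6
        assert min_deg == pytest.approx(math.degrees(math.acos(1 / 3)), abs=1e-9)

    def test_fine_sphere_is_nowhere_sharp(self):
        m, _ = make_mesh("icosphere", {"radius": 5.0, "subdivisions": 4})
        count, min_deg = M.dihedral_sharpness(m)
        assert count == 0
        assert min_deg > 160.0  # near-flat adjacent faces

    def test_star_prism_apex_angle(self):
        m, gt = make_mesh("spiked_star", {})
        count, min_deg = M.dihedral_sharpness(m)
        assert count == gt.analytic["sharp_edge_count"]
        assert min_deg == pytest.approx(gt.analytic["min_dihedral_deg"], abs=1e-6)

    def test_threshold_is_strict(self):
        m, _ = make_mesh("box", {"extents": (1.0, 1.0, 1.0)})
        assert M.dihedral_sharpness(m, sharp_threshold_deg=90.0)[0] == 0
        assert M.dihedral_sharpness(m, sharp_threshold_deg=90.001)[0] == 12


class TestDescribe3D:
    def test_surface_to_volume_of_case_values(self):
        assert round(106.3 / 73.3, 2) == 1.45

    def test_sphere_av_is_3_over_r(self):
        m, _ = make_mesh("icosphere", {"radius": 5.0, "subdivisions": 4})
        d = M.describe_3d(m)
        assert d.surface_to_volume_per_mm == pytest.approx(3 / 5, rel=0.01)
        assert d.sphericity <= 1 + 1e-6

    def test_rigid_motion_leaves_descriptors(self):
        p = {"extents": (12.0, 5.0, 4.0), "notch_width_frac": 0.5,
             "notch_depth_frac": 0.5}
        d0 = M.describe_3d(make_mesh("notched_box", p)[0])
        d1 = M.describe_3d(make_mesh("notched_box", {**p, "rotate": True}, seed=5)[0])
        for key in ("volume_mm3", "surface_area_mm2", "elongation", "flatness",
                    "sphericity", "convexity_ratio", "min_dihedral_deg"):
            assert d1.to_dict()[key] == pytest.approx(
                d0.to_dict()[key], rel=1e-9, abs=1e-9
            ), key
        assert d1.sharp_edge_count == d0.sharp_edge_count
        assert np.allclose(d1.extents_mm, d0.extents_mm, atol=1e-9)

    def test_rounding_is_report_time_only(self):
        m, _ = make_mesh("box", {})
        d = M.describe_3d(m, mass_g=0.5)
        assert d.volume_mm3 != round(d.volume_mm3, 2)  # full precision stored
        r = d.rounded()
        assert r["volume_mm3"] == round(d.volume_mm3, 2)
        assert r["mass_g"] == 0.5


@settings(max_examples=15, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 2**16),
    scale=st.floats(0.5, 4.0),
)
def test_similarity_scaling_covariance(seed, scale):
    """V ~ s^3, A ~ s^2, extents ~ s; dimensionless descriptors invariant."""
    m, _ = make_mesh("notched_box", {"rotate": True}, seed=seed)
    d0 = M.describe_3d(m)
    ms = M.TriMesh.from_arrays(m.vertices * scale, m.faces)
    d1 = M.describe_3d(ms)
    assert d1.volume_mm3 == pytest.approx(scale**3 * d0.volume_mm3, rel=1e-9)
    assert d1.surface_area_mm2 == pytest.approx(scale**2 * d0.surface_area_mm2, rel=1e-9)
    assert np.allclose(d1.extents_mm, scale * np.asarray(d0.extents_mm), rtol=1e-9)
    for key in ("elongation", "flatness", "sphericity", "convexity_ratio",
                "min_dihedral_deg"):
        assert d1.to_dict()[key] == pytest.approx(d0.to_dict()[key], rel=1e-9), key


def test_isoperimetric_bound_and_convexity_bound(mesh_suite):
    """Sphericity and convexity never exceed 1 on watertight fixtures."""
    for m, _ in mesh_suite:
        d = M.describe_3d(m)
        assert d.sphericity <= 1 + 1e-6, m.name
        assert 0 < d.convexity_ratio <= 1 + 1e-6, m.name
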