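"""Mesh volume, smoothing, membrane extrusion, centerline, quadrants."""

import numpy as np
import pytest

from aortamech import (MembraneModel, RegionSpec, SurfaceMesh,
                       SyntheticCaseSpec, centerline_and_diameters,
                       extract_segment_quadrants, extrude_membrane,
                       gen_fusiform_aneurysm, laplace_smooth,
                       max_diameter_plane, mesh_volume)
from aortamech.geometry import boundary_loops, cap_boundary_loops


def unit_cube(outward=True):
    nodes = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
                      [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]], float)
    faces = np.array([
        [0, 2, 1], [0, 3, 2],      # bottom (z=0, normal -z)
        [4, 5, 6], [4, 6, 7],      # top
        [0, 1, 5], [0, 5, 4],      # y=0
        [1, 2, 6], [1, 6, 5],      # x=1
        [2, 3, 7], [2, 7, 6],      # y=1
        [3, 0, 4], [3, 4, 7]])     # x=0
    if not outward:
        faces = faces[:, ::-1]
    return SurfaceMesh(nodes, faces)


def icosphere(subdivisions=3, radius=1.0):
    import trimesh

    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return SurfaceMesh(np.asarray(ico.vertices), np.asarray(ico.faces))


class TestVolume:
    def test_unit_cube(self):
        assert mesh_volume(unit_cube()) == pytest.approx(1.0, abs=1e-14)

    def test_inward_cube_is_negative(self):
        assert mesh_volume(unit_cube(outward=False)) == pytest.approx(-1.0)

    def test_icosphere_converges_from_below(self):
        exact = 4.0 * np.pi / 3.0
        vols = [mesh_volume(icosphere(s)) for s in (1, 2, 3)]
        assert vols[0] < vols[1] < vols[2] < exact
        assert vols[2] == pytest.approx(exact, rel=1e-2)

    def test_rigid_invariance(self):
        from scipy.spatial.transform import Rotation

        m = icosphere(2)
        r = Rotation.from_rotvec([0.3, -0.2, 0.9]).as_matrix()
        moved = SurfaceMesh(m.nodes @ r.T + [5.0, -3.0, 2.0], m.faces)
        assert mesh_volume(moved) == pytest.approx(mesh_volume(m), rel=1e-12)

    def test_open_tube_capped_or_raises(self, cylinder_case):
        seq, _ = cylinder_case
        v = mesh_volume(seq.mesh, cap_open=True)
        assert v == pytest.approx(np.pi * 100.0 * 80.0, rel=0.01)
        with pytest.raises(ValueError, match="open"):
            mesh_volume(seq.mesh, cap_open=False)

    def test_trimesh_oracle_agreement(self):
        import trimesh

        m = icosphere(2, radius=3.0)
        tm = trimesh.Trimesh(vertices=m.nodes, faces=m.faces, process=False)
        assert mesh_volume(m) == pytest.approx(tm.volume, rel=1e-12)


class TestSmoothing:
    def test_zero_iterations_identity(self):
        m = icosphere(2)
        out, loss = laplace_smooth(m, iterations=0)
        assert loss == 0.0
        assert np.array_equal(out.nodes, m.nodes)

    def test_sphere_shrinks(self):
        out, loss = laplace_smooth(icosphere(2), iterations=5, step=0.5)
        assert loss > 0.0

    def test_default_pipeline_loss_below_six_percent(self, fusiform_case):
        # reconstruction QC gate: volume loss < 6 %
        seq, _ = fusiform_case
        _, loss = laplace_smooth(seq.mesh, iterations=5, step=0.5)
        assert 0.0 <= loss < 0.06

    def test_step_validation(self):
        with pytest.raises(ValueError):
            laplace_smooth(icosphere(1), 1, step=0.0)
        with pytest.raises(ValueError):
            laplace_smooth(icosphere(1), -1)


class TestMembrane:
    def test_thickness_carried_and_nodes_untouched(self, fusiform_case):
        seq, _ = fusiform_case
        model = extrude_membrane(seq.mesh, h=0.01)
        assert model.h == 0.01
        assert model.mesh.nodes is seq.mesh.nodes  # membrane abstraction

    def test_sphere_normals_point_outward(self):
        m = icosphere(2)
        model = extrude_membrane(m, h=0.01)
        dots = np.einsum("ij,ij->i", model.node_normals, m.nodes)
        assert np.all(dots > 0)

    def test_invalid_thickness(self):
        with pytest.raises(ValueError):
            extrude_membrane(icosphere(1), h=0.0)

    def test_inconsistent_orientation_rejected(self):
        m = unit_cube()
        faces = m.faces.copy()
        faces[0] = faces[0, ::-1]
        with pytest.raises(ValueError, match="orientation|manifold"):
            MembraneModel(SurfaceMesh(m.nodes, faces), 0.01)


class TestCenterline:
    def test_cylinder_diameter_and_axis(self, cylinder_case):
        seq, _ = cylinder_case
        cl = centerline_and_diameters(seq.mesh)
        assert np.allclose(cl["diameter"], 20.0, rtol=0.01)
        # centroids on the axis
        assert np.abs(cl["centroid"][:, :2]).max() < 1e-6

    def test_fusiform_max_diameter_at_bump(self, fusiform_case):
        seq, _ = fusiform_case
        cl = centerline_and_diameters(seq.mesh)
        z_max, d_max = max_diameter_plane(cl)
        assert z_max == pytest.approx(60.0, abs=3.0)
        assert d_max == pytest.approx(40.0, rel=0.02)


class TestQuadrants:
    def test_sector_membership_and_partition(self, cylinder_case):
        seq, _ = cylinder_case
        region = RegionSpec(center=40.0, anterior=(0.0, 1.0, 0.0))
        parts = extract_segment_quadrants(seq.mesh, region)
        seg = parts["segment_nodes"]
        union = np.concatenate([parts["nodes"][q] for q in "ALPR"])
        assert sorted(union) == sorted(seg)          # disjoint partition
        assert len(set(union)) == len(union)
        # a node along +anterior from the centroid lands in quadrant A
        nodes = seq.mesh.nodes
        in_a = parts["nodes"]["A"]
        ang = np.degrees(np.arctan2(nodes[in_a, 1], nodes[in_a, 0]))
        assert np.all((ang > 44.9) & (ang < 135.1))  # +y sector center 90

    def test_rotation_invariance_with_corotated_anterior(self, cylinder_case):
        from scipy.spatial.transform import Rotation

        seq, _ = cylinder_case
        rot = Rotation.from_rotvec([0, 0, 0.7]).as_matrix()
        m2 = SurfaceMesh(seq.mesh.nodes @ rot.T, seq.mesh.faces)
        region1 = RegionSpec(center=40.0, anterior=(0.0, 1.0, 0.0))
        region2 = RegionSpec(center=40.0, anterior=rot @ [0.0, 1.0, 0.0])
        p1 = extract_segment_quadrants(seq.mesh, region1)
        p2 = extract_segment_quadrants(m2, region2)
        for q in "ALPR":
            assert np.array_equal(p1["nodes"][q], p2["nodes"][q])

    def test_segment_spans_enough_stations(self, cylinder_case):
        # 20-mm segment of a <=0.8-mm-pitch mesh covers >=20 axial stations
        seq, _ = cylinder_case
        region = RegionSpec(center=40.0)
        parts = extract_segment_quadrants(seq.mesh, region)
        z_levels = np.unique(np.round(
            seq.mesh.nodes[parts["segment_nodes"], 2], 6))
        assert z_levels.size >= 10  # 2-mm pitch fixture: 11 stations
        # at the imaging-derived pitch the same 20-mm window covers >= 20
        fine = SyntheticCaseSpec(n_circ=16, n_axial=100, length=80.0)
        assert 20.0 / (fine.length / fine.n_axial) >= 20

    def test_anterior_parallel_to_axis_rejected(self):
        with pytest.raises(ValueError, match="parallel"):
            RegionSpec(center=0.0, anterior=(0.0, 0.0, 1.0))

    def test_empty_segment_raises(self, cylinder_case):
        seq, _ = cylinder_case
        with pytest.raises(ValueError, match="no nodes"):
            extract_segment_quadrants(
                seq.mesh, RegionSpec(center=500.0, half_length=1.0))


class TestCapping:
    def test_caps_close_all_loops(self, cylinder_case):
        seq, _ = cylinder_case
        assert len(boundary_loops(seq.mesh)) == 2
        closed, mask = cap_boundary_loops(seq.mesh)
        assert len(boundary_loops(closed)) == 0
        assert mask.sum() == 2 * 48  # one fan triangle per ring edge
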