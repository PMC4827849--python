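"""mTBM tangent Jacobians, medial core and radial distance."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st_hyp

from hippomorph import conformal as cf
from hippomorph import morphometry as mm
from hippomorph import synthetic as syn

from conftest import make_cylinder_mesh


def rotation(theta=0.7, axis=2):
    c, s = np.cos(theta), np.sin(theta)
    R = np.eye(3)
    i, j = [(1, 2), (0, 2), (0, 1)][axis]
    R[i, i] = c
    R[j, j] = c
    R[i, j] = -s
    R[j, i] = s
    return R


class TestTangentJacobian:
    def test_identity_for_equal_surfaces(self, conformal_tube):
        om, grid, _ = conformal_tube
        V = om.mesh.vertices
        J, valid = mm.tangent_jacobian(V, V, om.mesh.faces, grid.face_uv)
        assert valid.all()
        assert np.abs(J - np.eye(2)).max() < 1e-10

    def test_uniform_scale(self, conformal_tube):
        om, grid, _ = conformal_tube
        V = om.mesh.vertices
        J, valid = mm.tangent_jacobian(V, 1.7 * V, om.mesh.faces, grid.face_uv)
        assert np.abs(J[valid] - 1.7 * np.eye(2)).max() < 1e-9

    def test_rigid_motion_invariance(self, conformal_tube):
        om, grid, _ = conformal_tube
        V = om.mesh.vertices
        moved = V @ rotation().T + np.array([4.0, -2.0, 9.0])
        J, valid = mm.tangent_jacobian(V, moved, om.mesh.faces, grid.face_uv)
        sv = np.linalg.svd(J[valid], compute_uv=False)
        assert np.abs(sv - 1.0).max() < 1e-9


class TestDeformationTensorLog:
    def test_closed_forms(self):
        assert np.allclose(mm.deformation_tensor_log(np.eye(2)), 0.0)
        s = 3.0
        assert np.allclose(
            mm.deformation_tensor_log(s * np.eye(2)),
            [np.log(s), 0.0, np.log(s)],
        )
        assert np.allclose(
            mm.deformation_tensor_log(np.diag([2.0, 1.0])),
            [np.log(2.0), 0.0, 0.0],
        )

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st_hyp.lists(st_hyp.floats(-1.2, 1.2), min_size=4, max_size=4))
    def test_norm_matches_matrix_log_frobenius(self, entries):
        """The sqrt(2)-weighted vector norm equals ||log (J^T J)^(1/2)||_F."""
        from scipy.linalg import logm

        J = np.array(entries).reshape(2, 2) + 2.0 * np.eye(2)
        if np.linalg.det(J) < 0.1:
            return
        vec = mm.deformation_tensor_log(J)
        S = 0.5 * logm(J.T @ J)  # independent oracle
        assert np.isclose(np.linalg.norm(vec), np.linalg.norm(S, "fro"), atol=1e-8)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            mm.deformation_tensor_log(np.array([[0.0, 0.0], [0.0, 1.0]]))


@pytest.fixture(scope="module")
def cylinder():
    mesh = make_cylinder_mesh(r=3.0, h=20.0, nu=64, nv=41)
    v = mesh.vertices[:, 2] / 20.0
    areas = mm.vertex_ring_areas(mesh.vertices, mesh.faces)
    return mesh, v, areas


class TestMedialCoreAndRadial:
    def test_core_on_axis(self, cylinder):
        mesh, v, areas = cylinder
        core = mm.medial_core(v, mesh.vertices, areas, n_levels=20)
        assert np.abs(core.points[:, :2]).max() < 0.02 * 3.0
        assert np.all(np.diff(core.v_levels) > 0)

    def test_translation_equivariance(self, cylinder):
        mesh, v, areas = cylinder
        t = np.array([5.0, -3.0, 2.0])
        c0 = mm.medial_core(v, mesh.vertices, areas, n_levels=10)
        c1 = mm.medial_core(v, mesh.vertices + t, areas, n_levels=10)
        assert np.allclose(c1.points - c0.points, t)

    def test_single_level_is_area_weighted_centroid(self, cylinder):
        mesh, v, areas = cylinder
        core = mm.medial_core(v, mesh.vertices, areas, n_levels=1)
        centroid = (mesh.vertices * areas[:, None]).sum(0) / areas.sum()
        assert np.allclose(core.points[0], centroid)

    def test_empty_band_raises(self, cylinder):
        mesh, v, areas = cylinder
        with pytest.raises(ValueError, match="fewer"):
            mm.medial_core(v, mesh.vertices, areas, n_levels=5000)

    def test_radial_distance_on_cylinder(self, cylinder):
        mesh, v, areas = cylinder
        core = mm.medial_core(v, mesh.vertices, areas, n_levels=20)
        rad = mm.radial_distance(mesh.vertices, v, core)
        interior = (v > 0.1) & (v < 0.9)
        assert np.abs(rad[interior] - 3.0).max() / 3.0 < 0.02

    def test_radial_homogeneity(self, cylinder):
        mesh, v, areas = cylinder
        core = mm.medial_core(v, mesh.vertices, areas, n_levels=20)
        rad = mm.radial_distance(mesh.vertices, v, core)
        s = 2.5
        core_s = mm.MedialCore(v_levels=core.v_levels, points=s * core.points)
        rad_s = mm.radial_distance(s * mesh.vertices, v, core_s)
        assert np.allclose(rad_s, s * rad)

    def test_vertex_on_core_is_zero(self):
        core = mm.MedialCore(
            v_levels=np.array([0.25, 0.75]),
            points=np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.0]]),
        )
        d = mm.radial_distance(np.array([[0.0, 0.0, 0.5]]), np.array([0.5]), core)
        assert d[0] == 0.0


class TestAssembleVertexStats:
    def test_identity_on_cylinder(self, cylinder_open):
        om = cylinder_open
        omega = cf.exact_harmonic_one_form(om)
        star = cf.conjugate_one_form(om, omega)
        grid = cf.integrate_holomorphic(om, omega, star)
        vs = mm.subject_vertex_stats(
            om.mesh.vertices, om.mesh.vertices, om.mesh.faces,
            grid.face_uv, grid.uv[:, 1], n_core_levels=10,
        )
        good = vs.mask
        assert np.abs(vs.combined[good, :3]).max() < 1e-8
        z = om.mesh.vertices[:, 2]
        interior = good & (z > 0.2) & (z < 0.8)
        assert np.allclose(vs.combined[interior, 3], 1.0, rtol=0.02)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            mm.assemble_vertex_stats(np.zeros((5, 3)), np.zeros(4))

    def test_all_flagged_rejected(self):
        with pytest.raises(ValueError, match="no usable"):
            mm.assemble_vertex_stats(
                np.zeros((4, 3)), np.zeros(4), valid=np.zeros(4, bool)
            )


@pytest.fixture(scope="module")
def implanted_pair(conformal_tube, tube_setup):
    """Known radial shrink applied analytically to a registered surface."""
    om, grid, _ = conformal_tube
    _, params, _ = tube_setup
    atrophy = syn.AtrophySpec(max_radial_shrink=0.15)
    s_grid, gamma, _ = syn.tube_frame(params, atrophy, dose=0)
    V = om.mesh.vertices
    d2 = ((V[:, None, :] - gamma[None, :, :]) ** 2).sum(axis=2)
    nearest = np.argmin(d2, axis=1)
    s_vertex = s_grid[nearest]
    w = syn.atrophy_window(s_vertex, atrophy)
    factor = 1.0 - 0.15 * w
    subject = gamma[nearest] + factor[:, None] * (V - gamma[nearest])
    return om, grid, V, subject, s_vertex, atrophy


class TestImplantedAtrophyRecovery:

    def test_radial_deficit_recovers_shrink(self, implanted_pair):
        om, grid, V, subject, s_vertex, atrophy = implanted_pair
        t_v = grid.uv[:, 1]
        vs_t = mm.subject_vertex_stats(
            V, V, om.mesh.faces, grid.face_uv, t_v, n_core_levels=30
        )
        vs_s = mm.subject_vertex_stats(
            V, subject, om.mesh.faces, grid.face_uv, t_v, n_core_levels=30
        )
        flat = syn.atrophy_window(s_vertex, atrophy) >= 0.999
        good = vs_t.mask & vs_s.mask & flat
        deficit = 1.0 - np.mean(vs_s.combined[good, 3]) / np.mean(
            vs_t.combined[good, 3]
        )
        assert abs(deficit - 0.15) < 0.03

    def test_mtbm_elevated_inside_window(self, implanted_pair):
        om, grid, V, subject, s_vertex, atrophy = implanted_pair
        t_v = grid.uv[:, 1]
        vs_s = mm.subject_vertex_stats(
            V, subject, om.mesh.faces, grid.face_uv, t_v, n_core_levels=30
        )
        w = syn.atrophy_window(s_vertex, atrophy)
        inside = vs_s.mask & (w >= 0.999)
        outside = vs_s.mask & (w == 0.0)
        norm = np.linalg.norm(vs_s.combined[:, :3], axis=1)
        assert np.mean(norm[inside]) > 3.0 * np.mean(norm[outside])

    def test_rigid_motion_leaves_stats_unchanged(self, implanted_pair):
        om, grid, V, subject, _, _ = implanted_pair
        t_v = grid.uv[:, 1]
        vs = mm.subject_vertex_stats(
            V, subject, om.mesh.faces, grid.face_uv, t_v, n_core_levels=20
        )
        moved = subject @ rotation(0.4, 1).T + np.array([3.0, 1.0, -7.0])
        vs_m = mm.subject_vertex_stats(
            V, moved, om.mesh.faces, grid.face_uv, t_v, n_core_levels=20
        )
        good = vs.mask & vs_m.mask
        assert np.abs(vs.combined[good] - vs_m.combined[good]).max() < 1e-6
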