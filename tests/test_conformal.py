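"""Conformal parameterization: 1-forms, uv grids, curvature, feature images."""

import numpy as np
import pytest

from hippomorph import conformal as cf
from hippomorph import surfaces as sf

from conftest import make_cylinder_mesh, open_cylinder


class TestCutEndHoles:
    def test_tube_becomes_cylinder(self, tube_setup):
        mesh, _, _ = tube_setup
        om = cf.cut_end_holes(mesh, k_ring=2)
        assert len(om.boundary_loops) == 2
        assert sf.check_topology(om.mesh).euler_characteristic == 0

    def test_sphere_two_antipodal_holes(self):
        import trimesh

        s = trimesh.creation.icosphere(subdivisions=3)
        om = cf.cut_end_holes(sf.mesh_from_arrays(s.vertices, s.faces))
        assert len(om.boundary_loops) == 2
        assert sf.check_topology(om.mesh).euler_characteristic == 0

    def test_deterministic(self, tube_setup):
        mesh, _, _ = tube_setup
        a = cf.cut_end_holes(mesh, k_ring=1)
        b = cf.cut_end_holes(mesh, k_ring=1)
        assert np.array_equal(a.orig_vertex_index, b.orig_vertex_index)
        assert a.boundary_loops == b.boundary_loops

    def test_torus_rejected(self):
        import trimesh

        t = trimesh.creation.torus(major_radius=3.0, minor_radius=1.0)
        with pytest.raises(ValueError, match="genus"):
            cf.cut_end_holes(sf.mesh_from_arrays(t.vertices, t.faces))


class TestHarmonicOneForm:
    def test_cylinder_potential_is_height(self, cylinder_open):
        omega = cf.exact_harmonic_one_form(cylinder_open)
        z = cylinder_open.mesh.vertices[:, 2]
        assert np.abs(omega.potential - z).max() < 1e-3

    def test_exactness(self, cylinder_open):
        omega = cf.exact_harmonic_one_form(cylinder_open)
        assert cf.one_form_closedness(cylinder_open, omega) < 1e-10

    def test_scale_invariance(self, cylinder_open):
        omega = cf.exact_harmonic_one_form(cylinder_open)
        scaled = open_cylinder(
            sf.mesh_from_arrays(
                3.7 * cylinder_open.mesh.vertices, cylinder_open.mesh.faces
            )
        )
        omega_s = cf.exact_harmonic_one_form(scaled)
        assert np.abs(omega.potential - omega_s.potential).max() < 1e-10


class TestConjugateOneForm:
    def test_cylinder_period_is_circumference_over_height(self):
        # unit-height cylinder of radius r: the conjugate period must be
        # the circumference 2 pi r (height-normalized)
        r = 1.5
        om = open_cylinder(make_cylinder_mesh(r=r, h=1.0))
        omega = cf.exact_harmonic_one_form(om)
        star = cf.conjugate_one_form(om, omega)
        period = abs(cf._loop_integral(om, star, om.boundary_loops[0]))
        assert np.isclose(period, 2 * np.pi * r, rtol=5e-3)

    def test_zero_form_maps_to_zero(self, cylinder_open):
        zero = cf.OneForm(
            edges=cylinder_open.edges,
            values=np.zeros(len(cylinder_open.edges)),
            potential=np.zeros(len(cylinder_open.mesh.vertices)),
        )
        star = cf.conjugate_one_form(cylinder_open, zero)
        assert np.abs(star.values).max() == 0.0

    def test_closedness_enforced(self, conformal_tube):
        om, _, _ = conformal_tube
        omega = cf.exact_harmonic_one_form(om)
        star = cf.conjugate_one_form(om, omega)
        assert cf.one_form_closedness(om, star) < 1e-8

    def test_loop_integral_path_independent(self, cylinder_open):
        """Any two homotopic circumferential loops give the same period."""
        omega = cf.exact_harmonic_one_form(cylinder_open)
        star = cf.conjugate_one_form(cylinder_open, omega)
        nu = 64
        loops = [list(range(k * nu, (k + 1) * nu)) for k in (0, 10, 20)]
        periods = [cf._loop_integral(cylinder_open, star, L) for L in loops]
        assert np.ptp(periods) < 1e-8 * max(1.0, abs(periods[0]))


class TestIntegrateHolomorphic:
    def test_cylinder_uv_matches_analytic(self, cylinder_open):
        omega = cf.exact_harmonic_one_form(cylinder_open)
        star = cf.conjugate_one_form(cylinder_open, omega)
        grid = cf.integrate_holomorphic(cylinder_open, omega, star)
        assert np.isclose(grid.period_u, 2 * np.pi, rtol=5e-3)
        distort = cf.angle_distortion_deg(cylinder_open, grid)
        assert np.median(distort) < 1.0
        # v takes the Dirichlet values exactly on the boundary loops
        v = grid.uv[:, 1]
        assert np.all(v[cylinder_open.boundary_loops[0]] == 0.0)
        assert np.all(v[cylinder_open.boundary_loops[1]] == 1.0)

    def test_conformal_factor_scales_quadratically(self, cylinder_open):
        omega = cf.exact_harmonic_one_form(cylinder_open)
        star = cf.conjugate_one_form(cylinder_open, omega)
        grid = cf.integrate_holomorphic(cylinder_open, omega, star)
        s = 2.5
        scaled = open_cylinder(
            sf.mesh_from_arrays(
                s * cylinder_open.mesh.vertices, cylinder_open.mesh.faces
            )
        )
        omega2 = cf.exact_harmonic_one_form(scaled)
        star2 = cf.conjugate_one_form(scaled, omega2)
        grid2 = cf.integrate_holomorphic(scaled, omega2, star2)
        ratio = grid2.conformal_factor / grid.conformal_factor
        assert np.allclose(ratio, s**2, rtol=1e-6)

    def test_positive_conformal_factor_and_area_identity(self, conformal_tube):
        om, grid, _ = conformal_tube
        assert np.all(grid.conformal_factor > 0)
        fuv = grid.face_uv
        area2 = 0.5 * (
            (fuv[:, 1, 0] - fuv[:, 0, 0]) * (fuv[:, 2, 1] - fuv[:, 0, 1])
            - (fuv[:, 2, 0] - fuv[:, 0, 0]) * (fuv[:, 1, 1] - fuv[:, 0, 1])
        )
        lam_face = grid.conformal_factor[om.mesh.faces].mean(axis=1)
        assert np.isclose((lam_face * area2).sum(), om.mesh.area, rtol=0.01)

    def test_tube_conformality(self, conformal_tube):
        om, grid, _ = conformal_tube
        assert np.median(cf.angle_distortion_deg(om, grid)) < 2.0


class TestMeanCurvature:
    def test_sphere(self):
        import trimesh

        r = 7.0
        s = trimesh.creation.icosphere(subdivisions=3, radius=r)
        H = cf.mean_curvature(sf.mesh_from_arrays(s.vertices, s.faces))
        assert np.abs(H * r - 1.0).max() < 0.05

    def test_cylinder_interior(self):
        r = 2.0
        mesh = make_cylinder_mesh(r=r, h=8.0, nu=48, nv=33)
        H = cf.mean_curvature(mesh)
        z = mesh.vertices[:, 2]
        interior = (z > 2.0) & (z < 6.0)
        assert np.allclose(H[interior], 1.0 / (2 * r), rtol=0.02)

    def test_flat_patch_is_zero(self):
        # large-radius cylinder locally approximates a plane: H -> small
        mesh = make_cylinder_mesh(r=100.0, h=8.0, nu=256, nv=17)
        H = cf.mean_curvature(mesh)
        z = mesh.vertices[:, 2]
        interior = (z > 2.0) & (z < 6.0)
        assert np.abs(H[interior]).max() < 0.01


class TestFeatureImage:
    def test_range_and_validity(self, conformal_tube):
        _, _, img = conformal_tube
        assert img.raster.min() == 0.0
        assert img.raster.max() == 255.0
        assert img.valid.all()

    def test_constant_field_warns_and_zeroes(self, conformal_tube):
        om, grid, _ = conformal_tube
        flat = cf.ConformalGrid(
            uv=grid.uv,
            period_u=grid.period_u,
            conformal_factor=np.ones(len(grid.uv)),
            mean_curvature=np.ones(len(grid.uv)),
            face_uv=grid.face_uv,
        )
        with pytest.warns(UserWarning, match="constant"):
            img = cf.feature_image(flat, resolution=(64, 32))
        assert np.all(img.raster == 0.0)

    def test_resolution_consistency(self, conformal_tube):
        _, grid, _ = conformal_tube
        coarse = cf.feature_image(grid, resolution=(64, 32)).raster
        fine = cf.feature_image(grid, resolution=(128, 64)).raster
        down = 0.25 * (
            fine[0::2, 0::2] + fine[1::2, 0::2] + fine[0::2, 1::2] + fine[1::2, 1::2]
        )
        # same underlying field sampled at two rates: agree in the bulk
        assert np.median(np.abs(down - coarse)) < 10.0

    def test_pgm_roundtrip(self, conformal_tube, tmp_path):
        _, _, img = conformal_tube
        path = tmp_path / "feat.pgm"
        cf.write_pgm(img, path)
        data = path.read_bytes()
        assert data.startswith(b"P5")
        H, W = img.raster.shape
        assert data.endswith(
            np.clip(np.rint(img.raster), 0, 255).astype(np.uint8).tobytes()
        )


def test_full_map_deterministic(tube_setup):
    mesh, _, _ = tube_setup
    om1, g1, i1 = cf.conformal_parameterize(mesh, k_ring=2, resolution=(64, 32))
    om2, g2, i2 = cf.conformal_parameterize(mesh, k_ring=2, resolution=(64, 32))
    assert np.array_equal(g1.uv, g2.uv)
    assert np.array_equal(i1.raster, i2.raster)
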