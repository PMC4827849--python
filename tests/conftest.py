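"""Shared fixtures: analytic meshes and a small synthetic tube."""

from __future__ import annotations

import numpy as np
import pytest

from hippomorph import conformal as cf
from hippomorph import surfaces as sf
from hippomorph import synthetic as syn


def make_cylinder_mesh(r=1.0, h=1.0, nu=64, nv=33):
    """Open right circular cylinder: radius r, height h, ends unclosed."""
    us = np.arange(nu) / nu * 2 * np.pi
    vs = np.linspace(0, h, nv)
    verts = np.array([[r * np.cos(u), r * np.sin(u), z] for z in vs for u in us])
    faces = []
    for iv in range(nv - 1):
        for iu in range(nu):
            a = iv * nu + iu
            b = iv * nu + (iu + 1) % nu
            c = (iv + 1) * nu + iu
            d = (iv + 1) * nu + (iu + 1) % nu
            faces += [[a, b, d], [a, d, c]]
    return sf.mesh_from_arrays(verts, np.array(faces))


def open_cylinder(mesh):
    """Wrap an open cylinder mesh as an OpenMesh with ordered loops (low z first)."""
    loops = sf.boundary_loops(mesh)
    z = mesh.vertices[:, 2]
    if np.mean(z[loops[0]]) > np.mean(z[loops[1]]):
        loops = [loops[1], loops[0]]
    return cf.OpenMesh(
        mesh=mesh,
        boundary_loops=loops,
        orig_vertex_index=np.arange(len(mesh.vertices)),
    )


@pytest.fixture(scope="session")
def tube_setup():
    """Default synthetic tube (noise on, ~1.6k vertices) plus its parameters."""
    params = syn.ShapeParams()
    atrophy = syn.AtrophySpec()
    vol = syn.make_tube_volume(params, atrophy, dose=0, noise_sd=0.25, seed=3)
    mesh = sf.refine_and_smooth(sf.extract_surface(vol, params.voxel_size), 10)
    return mesh, params, atrophy


@pytest.fixture(scope="session")
def conformal_tube(tube_setup):
    mesh, _, _ = tube_setup
    om, grid, img = cf.conformal_parameterize(mesh, k_ring=2, resolution=(128, 64))
    return om, grid, img


@pytest.fixture(scope="session")
def cylinder_open():
    mesh = make_cylinder_mesh()
    return open_cylinder(mesh)
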