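"""Per-vertex multivariate morphometry: mTBM plus radial distance.

After registration every subject surface is resampled on the template
connectivity, so corresponding vertices are comparable across subjects.  Two
complementary descriptors are computed per vertex:

* mTBM — the log-Euclidean vector of the surface deformation tensor
  (J^T J)^(1/2), where J is the 2x2 tangent-plane derivative of the
  template->subject correspondence.  It captures within-surface stretch and
  shear, and is invariant to rigid motion of either surface.
* radial distance — the Euclidean distance from each vertex to the medial
  core (the iso-parameter center line of the tube), capturing thickness
  change along the surface normal direction.

Stacked, they form a 4x1 statistic per vertex for group inference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MedialCore",
    "VertexStats",
    "tangent_jacobian",
    "deformation_tensor_log",
    "medial_core",
    "radial_distance",
    "assemble_vertex_stats",
    "subject_vertex_stats",
    "vertex_ring_areas",
]


@dataclass
class MedialCore:
    """Ordered iso-v center polyline: one 3-D point per v-band."""

    v_levels: np.ndarray  # band centers, strictly increasing
    points: np.ndarray  # (n_levels, 3)


@dataclass
class VertexStats:
    """Per-vertex 4-vector (mtbm1, mtbm2, mtbm3, radial) plus validity mask."""

    combined: np.ndarray  # (V, 4)
    mask: np.ndarray  # (V,), True where usable
    n_flagged: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.combined, columns=["mtbm1", "mtbm2", "mtbm3", "radial"]
        )
        df.insert(0, "vertex_id", np.arange(len(df)))
        df["mask"] = self.mask.astype(int)
        return df


def vertex_ring_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """One-third of the summed incident triangle areas per vertex."""
    v = np.asarray(vertices, float)
    f = np.asarray(faces)
    n = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    fa = 0.5 * np.linalg.norm(n, axis=1)
    out = np.zeros(len(v))
    for c in range(3):
        np.add.at(out, f[:, c], fa)
    return out / 3.0


def _ring_fit(vertices: np.ndarray, faces: np.ndarray, uv: np.ndarray) -> np.ndarray:
    """Per-vertex 3x2 least-squares map duv -> dx over the 1-ring edges.

    uv must be per-face unwrapped coordinates (F, 3, 2) so the periodic u
    seam does not corrupt the fit.
    """
    V = len(vertices)
    AtA = np.zeros((V, 2, 2))
    AtB = np.zeros((V, 2, 3))
    f = np.asarray(faces)
    for a, b in ((0, 1), (1, 2), (2, 0)):
        duv = uv[:, b] - uv[:, a]
        dx = vertices[f[:, b]] - vertices[f[:, a]]
        outer = duv[:, :, None] * duv[:, None, :]
        cross = duv[:, :, None] * dx[:, None, :]
        for end in (f[:, a], f[:, b]):
            np.add.at(AtA, end, outer)
            np.add.at(AtB, end, cross)
    T = np.linalg.solve(AtA + 1e-300 * np.eye(2), AtB)  # (V, 2, 3)
    return np.transpose(T, (0, 2, 1))  # (V, 3, 2)


def _orthonormal_frame(T: np.ndarray) -> np.ndarray:
    """Frames (V, 3, 2): e1 along the u direction, e2 = orthonormalized v."""
    e1 = T[:, :, 0]
    e1 = e1 / np.maximum(np.linalg.norm(e1, axis=1, keepdims=True), 1e-300)
    t2 = T[:, :, 1]
    t2 = t2 - (t2 * e1).sum(axis=1, keepdims=True) * e1
    e2 = t2 / np.maximum(np.linalg.norm(t2, axis=1, keepdims=True), 1e-300)
    return np.stack([e1, e2], axis=2)


def tangent_jacobian(
    template_vertices: np.ndarray,
    subject_vertices: np.ndarray,
    faces: np.ndarray,
    face_uv: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """2x2 tangent-plane derivative of the template->subject correspondence.

    Both surfaces share connectivity and the template's conformal (u, v)
    coordinates.  Per vertex, the 1-ring least-squares fit T (template) and
    S (subject) map uv displacements to 3-D edge vectors; since the map is
    the identity in uv, its derivative expressed in each surface's own
    orthonormal tangent frame (u direction, orthonormalized v direction) is

        J = (E_s^T S) (E_t^T T)^(-1).

    Because both frames are derived from the same uv directions they
    co-rotate with their surface, so rigid motions leave J unchanged and a
    uniform scale s gives J = sI.  Returns (J (V,2,2), valid mask); vertices
    with det J <= 0 are flagged invalid.
    """
    T = _ring_fit(np.asarray(template_vertices, float), faces, face_uv)
    S = _ring_fit(np.asarray(subject_vertices, float), faces, face_uv)
    Et = _orthonormal_frame(T)
    Es = _orthonormal_frame(S)
    Tt = np.einsum("vki,vkj->vij", Et, T)  # 2x2, invertible for healthy rings
    Ss = np.einsum("vki,vkj->vij", Es, S)
    J = np.einsum("vij,vjk->vik", Ss, np.linalg.inv(Tt))
    det = np.linalg.det(J)
    valid = np.isfinite(det) & (det > 0)
    return J, valid


def deformation_tensor_log(J: np.ndarray) -> np.ndarray:
    """Log-Euclidean 3-vector of the deformation tensor (J^T J)^(1/2).

    L = log((J^T J)^(1/2)) = 0.5 log(J^T J); returned as
    (L11, sqrt(2) L12, L22) so the vector 2-norm equals ||L||_F.
    Accepts a single 2x2 matrix or a stack (..., 2, 2).
    """
    J = np.asarray(J, float)
    single = J.ndim == 2
    if single:
        J = J[None]
    C = np.einsum("...ji,...jk->...ik", J, J)  # J^T J, SPD if det J != 0
    w, Q = np.linalg.eigh(C)
    if np.any(w <= 0):
        raise ValueError("non-positive-definite deformation tensor")
    L = 0.5 * np.einsum("...ij,...j,...kj->...ik", Q, np.log(w), Q)
    out = np.stack(
        [L[..., 0, 0], np.sqrt(2.0) * L[..., 0, 1], L[..., 1, 1]], axis=-1
    )
    return out[0] if single else out


def medial_core(
    v_coords: np.ndarray,
    subject_vertices: np.ndarray,
    vertex_areas: np.ndarray,
    n_levels: int = 100,
) -> MedialCore:
    """Area-weighted iso-v band centers, ordered by v.

    The v coordinate runs along the tube, so each of ``n_levels`` equal-width
    v bands collects a ring of surface points; its area-weighted centroid is
    one medial-core sample (the tube's center line).
    """
    v = np.asarray(v_coords, float)
    x = np.asarray(subject_vertices, float)
    w = np.asarray(vertex_areas, float)
    edges = np.linspace(0.0, 1.0, n_levels + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    # rounding keeps numerically-tied vertices (e.g. a ring sitting exactly
    # on a band edge) in one band instead of splitting it by float noise
    band = np.clip(np.digitize(np.round(v, 12), edges) - 1, 0, n_levels - 1)
    pts = np.zeros((n_levels, 3))
    for k in range(n_levels):
        sel = band == k
        if not np.any(sel):
            raise ValueError(
                f"empty iso-v band {k}/{n_levels}; use fewer medial-core levels"
            )
        wk = w[sel]
        pts[k] = (x[sel] * wk[:, None]).sum(axis=0) / wk.sum()
    return MedialCore(v_levels=centers, points=pts)


def radial_distance(
    subject_vertices: np.ndarray, v_coords: np.ndarray, core: MedialCore
) -> np.ndarray:
    """Distance from each vertex to the core evaluated at the vertex's v."""
    x = np.asarray(subject_vertices, float)
    v = np.asarray(v_coords, float)
    cx = np.stack(
        [np.interp(v, core.v_levels, core.points[:, c]) for c in range(3)], axis=1
    )
    return np.linalg.norm(x - cx, axis=1)


def assemble_vertex_stats(
    mtbm: np.ndarray, radial: np.ndarray, valid: np.ndarray | None = None
) -> VertexStats:
    """Stack mTBM (V,3) and radial (V,) into the per-vertex 4-vector."""
    mtbm = np.asarray(mtbm, float)
    radial = np.asarray(radial, float)
    if len(mtbm) != len(radial):
        raise ValueError(
            f"length mismatch: {len(mtbm)} mTBM rows vs {len(radial)} radial values"
        )
    if valid is None:
        valid = np.ones(len(radial), dtype=bool)
    valid = np.asarray(valid, bool) & np.all(np.isfinite(mtbm), axis=1)
    if not valid.any():
        raise ValueError("no usable vertices (all flagged)")
    combined = np.concatenate([mtbm, radial[:, None]], axis=1)
    combined[~valid] = np.nan
    return VertexStats(
        combined=combined, mask=valid, n_flagged=int((~valid).sum())
    )


def subject_vertex_stats(
    template_vertices: np.ndarray,
    subject_vertices: np.ndarray,
    faces: np.ndarray,
    template_face_uv: np.ndarray,
    template_v: np.ndarray,
    n_core_levels: int = 30,
) -> VertexStats:
    """Full morphometry for one registered subject on template connectivity."""
    J, valid = tangent_jacobian(
        template_vertices, subject_vertices, faces, template_face_uv
    )
    mtbm = np.full((len(J), 3), np.nan)
    mtbm[valid] = deformation_tensor_log(J[valid])
    areas = vertex_ring_areas(subject_vertices, faces)
    core = medial_core(template_v, subject_vertices, areas, n_levels=n_core_levels)
    rad = radial_distance(subject_vertices, template_v, core)
    return assemble_vertex_stats(mtbm, rad, valid)
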