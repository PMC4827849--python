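"""Conformal parameterization of tube-like genus-0 surfaces.

A closed genus-0 hippocampal surface is opened at its two ends into a
topological cylinder, on which a holomorphic 1-form ``omega + i omega*`` is
computed: ``omega = df`` with f the harmonic potential solving the cotangent
Laplace equation (f = 0 and 1 on the two boundary loops), and ``omega*`` the
closed 1-form closest to the Hodge star of ``omega`` in least squares.
Integrating the pair from a seed vertex yields per-vertex (u, v) coordinates
on a rectangle [0, U] x [0, 1]; u is periodic with period U (the cylinder is
unwrapped along an integration cut).  The map is angle-preserving up to
discretization, so the conformal factor lambda (local 3-D/2-D area ratio)
together with mean curvature H characterizes the surface up to rigid motion;
their standardized sum, rasterized over the rectangle, is the "feature image"
used to drive registration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import sparse
from scipy.interpolate import LinearNDInterpolator
from scipy.sparse.linalg import spsolve

from .surfaces import boundary_loops as _boundary_loops
from .surfaces import check_topology, mesh_from_arrays

__all__ = [
    "OpenMesh",
    "OneForm",
    "ConformalGrid",
    "FeatureImage",
    "cut_end_holes",
    "exact_harmonic_one_form",
    "conjugate_one_form",
    "integrate_holomorphic",
    "mean_curvature",
    "feature_image",
    "conformal_parameterize",
    "one_form_closedness",
    "angle_distortion_deg",
    "cotangent_laplacian",
]


# ---------------------------------------------------------------------------
# data containers


@dataclass
class OpenMesh:
    """Cylinder-topology mesh: exactly two ordered boundary loops, chi = 0."""

    mesh: trimesh.Trimesh
    boundary_loops: list[list[int]]
    orig_vertex_index: np.ndarray
    edges: np.ndarray = field(default=None)  # (E, 2), i < j
    face_edge_idx: np.ndarray = field(default=None)  # (F, 3)
    face_edge_sign: np.ndarray = field(default=None)  # (F, 3), +1 if i->j

    def __post_init__(self) -> None:
        if self.edges is None:
            self.edges, self.face_edge_idx, self.face_edge_sign = _index_edges(
                self.mesh.faces
            )


@dataclass
class OneForm:
    """Discrete 1-form: one scalar per undirected edge, oriented low->high.

    omega(j->i) = -omega(i->j) by construction (antisymmetry); a 1-form is
    closed when it sums to zero around every face boundary.
    """

    edges: np.ndarray
    values: np.ndarray
    potential: np.ndarray | None = None


@dataclass
class ConformalGrid:
    """Per-vertex planar coordinates on [0, U] x [0, 1] plus local features."""

    uv: np.ndarray  # (V, 2); u in [0, U), v in [0, 1]
    period_u: float
    conformal_factor: np.ndarray  # lambda > 0
    mean_curvature: np.ndarray
    face_uv: np.ndarray  # (F, 3, 2) per-corner uv with u unwrapped per face


@dataclass
class FeatureImage:
    """Rasterized conformal representation, dynamic range [0, 255].

    ``raster[iy, ix]`` samples the rectangle at v = (iy+.5)/H, u/U = (ix+.5)/W;
    the u axis (columns) is periodic.
    """

    raster: np.ndarray  # (H, W)
    valid: np.ndarray  # bool (H, W)


# ---------------------------------------------------------------------------
# mesh combinatorics helpers


def _index_edges(faces: np.ndarray):
    f = np.asarray(faces)
    he = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    und = np.sort(he, axis=1)
    edges, inv = np.unique(und, axis=0, return_inverse=True)
    sign = np.where(he[:, 0] < he[:, 1], 1.0, -1.0)
    F = len(f)
    face_edge_idx = inv.reshape(3, F).T
    face_edge_sign = sign.reshape(3, F).T
    return edges, face_edge_idx, face_edge_sign


def cotangent_laplacian(vertices: np.ndarray, faces: np.ndarray) -> sparse.csr_matrix:
    """Cotangent-weight Laplacian L with (L f)_i = sum_j w_ij (f_j - f_i)."""
    v = np.asarray(vertices, float)
    f = np.asarray(faces)
    n = len(v)
    rows, cols, vals = [], [], []
    for a, b, c in ((0, 1, 2), (1, 2, 0), (2, 0, 1)):
        # cotangent at corner c, weighting edge (a, b)
        e1 = v[f[:, a]] - v[f[:, c]]
        e2 = v[f[:, b]] - v[f[:, c]]
        cross = np.linalg.norm(np.cross(e1, e2), axis=1)
        cross = np.maximum(cross, 1e-300)
        cot = (e1 * e2).sum(axis=1) / cross
        w = 0.5 * cot
        rows.extend([f[:, a], f[:, b]])
        cols.extend([f[:, b], f[:, a]])
        vals.extend([w, w])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    W = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    D = sparse.diags(np.asarray(W.sum(axis=1)).ravel())
    return (W - D).tocsr()


def _vertex_rings(faces: np.ndarray, seeds: np.ndarray, k: int) -> set[int]:
    edges = np.concatenate(
        [faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]
    )
    nbr: dict[int, set[int]] = {}
    for a, b in edges:
        nbr.setdefault(int(a), set()).add(int(b))
        nbr.setdefault(int(b), set()).add(int(a))
    region = set(int(s) for s in seeds)
    frontier = set(region)
    for _ in range(k):
        nxt: set[int] = set()
        for u in frontier:
            nxt |= nbr.get(u, set())
        nxt -= region
        region |= nxt
        frontier = nxt
    return region


# ---------------------------------------------------------------------------
# operations


def cut_end_holes(mesh: trimesh.Trimesh, k_ring: int = 1) -> OpenMesh:
    """Open a closed genus-0 tube into a cylinder by removing two end disks.

    The two extreme vertices along the first principal axis of the vertex
    cloud are found (ties broken by lowest index); the ``k_ring``-ring of
    faces around each is deleted, leaving exactly two boundary loops.  The
    principal-axis sign is fixed so the dominant coordinate axis points
    positively, making the v = 0 end reproducible across similar subjects.
    """
    report = check_topology(mesh)
    if not report.passed:
        raise ValueError(f"cut_end_holes requires a closed genus-0 mesh: {report.reason or report}")

    v = mesh.vertices - mesh.vertices.mean(axis=0)
    _, _, Vt = np.linalg.svd(v, full_matrices=False)
    axis = Vt[0]
    dom = int(np.argmax(np.abs(axis)))
    if axis[dom] < 0:
        axis = -axis
    proj = v @ axis

    lo_seed = int(np.argmin(proj))  # argmin/argmax return first index on ties
    hi_seed = int(np.argmax(proj))
    lo_disk = _vertex_rings(mesh.faces, np.array([lo_seed]), k_ring)
    hi_disk = _vertex_rings(mesh.faces, np.array([hi_seed]), k_ring)
    # the disks must be separated by at least one ring of surviving faces
    if lo_disk & _vertex_rings(mesh.faces, np.array(sorted(hi_disk)), 1):
        raise ValueError("cut disks overlap; reduce k_ring or refine the mesh")

    # remove vertices strictly inside each disk (the k-1 ring); removing the
    # seed's k-ring faces keeps the k-ring vertices as the boundary loop
    kill_lo = _vertex_rings(mesh.faces, np.array([lo_seed]), k_ring - 1)
    kill_hi = _vertex_rings(mesh.faces, np.array([hi_seed]), k_ring - 1)
    kill = kill_lo | kill_hi
    keep_face = ~np.any(np.isin(mesh.faces, sorted(kill)), axis=1)
    faces = mesh.faces[keep_face]

    used = np.unique(faces)
    remap = -np.ones(len(mesh.vertices), dtype=np.int64)
    remap[used] = np.arange(len(used))
    new_faces = remap[faces]
    new_mesh = mesh_from_arrays(mesh.vertices[used], new_faces)

    loops = _boundary_loops(new_mesh)
    if len(loops) != 2:
        raise ValueError(f"cutting produced {len(loops)} boundary loops, expected 2")
    chi = check_topology(new_mesh).euler_characteristic
    if chi != 0:
        raise ValueError(f"cut surface has Euler characteristic {chi}, expected 0")

    # order loops: loop 0 = low end of the principal axis (will carry v = 0)
    mean_proj = [np.mean(proj[used[np.array(L)]]) for L in loops]
    if mean_proj[0] > mean_proj[1]:
        loops = [loops[1], loops[0]]
    return OpenMesh(mesh=new_mesh, boundary_loops=loops, orig_vertex_index=used)


def exact_harmonic_one_form(open_mesh: OpenMesh) -> OneForm:
    """omega = df with f harmonic, f = 0 / 1 on the two boundary loops."""
    mesh = open_mesh.mesh
    n = len(mesh.vertices)
    L = cotangent_laplacian(mesh.vertices, mesh.faces)
    f = np.zeros(n)
    b0 = np.array(open_mesh.boundary_loops[0])
    b1 = np.array(open_mesh.boundary_loops[1])
    f[b1] = 1.0
    boundary = np.concatenate([b0, b1])
    interior = np.setdiff1d(np.arange(n), boundary)
    if len(interior) == 0:
        raise ValueError("mesh has no interior vertices")
    L_ii = L[interior][:, interior]
    rhs = -L[interior][:, boundary] @ f[boundary]
    try:
        f[interior] = spsolve(L_ii.tocsc(), rhs)
    except RuntimeError as exc:  # pragma: no cover - singular system
        raise ValueError(f"singular Laplacian (disconnected mesh?): {exc}") from exc
    if not np.all(np.isfinite(f)):
        raise ValueError("singular Laplacian: harmonic solve returned non-finite values")
    e = open_mesh.edges
    return OneForm(edges=e, values=f[e[:, 1]] - f[e[:, 0]], potential=f)


def one_form_closedness(open_mesh: OpenMesh, form: OneForm) -> float:
    """Max |sum of the form around a face boundary| — 0 for closed forms."""
    sums = (form.values[open_mesh.face_edge_idx] * open_mesh.face_edge_sign).sum(axis=1)
    return float(np.max(np.abs(sums)))


def _face_gradient(vertices, faces, f):
    """Per-face intrinsic gradient of a vertex function."""
    p0 = vertices[faces[:, 0]]
    e1 = vertices[faces[:, 1]] - p0
    e2 = vertices[faces[:, 2]] - p0
    d1 = f[faces[:, 1]] - f[faces[:, 0]]
    d2 = f[faces[:, 2]] - f[faces[:, 0]]
    g11 = (e1 * e1).sum(1)
    g12 = (e1 * e2).sum(1)
    g22 = (e2 * e2).sum(1)
    det = np.maximum(g11 * g22 - g12 **2, 1e-300)
    a = (g22 * d1 - g12 * d2) / det
    b = (g11 * d2 - g12 * d1) / det
    return a[:, None] * e1 + b[:, None] * e2


def conjugate_one_form(open_mesh: OpenMesh, omega: OneForm) -> OneForm:
    """Closed 1-form omega* minimizing || omega* - star(omega) ||^2.

    star(omega) is evaluated per face by rotating the face gradient of the
    potential by 90 degrees about the face normal; the least-squares problem
    over edge values is solved subject to exact per-face closedness via its
    KKT system (the Schur complement is a face-adjacency Laplacian).
    """
    if omega.potential is None:
        raise ValueError("conjugate_one_form expects an exact form with potential")
    mesh = open_mesh.mesh
    v, fc = mesh.vertices, mesh.faces
    grad = _face_gradient(v, fc, omega.potential)
    normals = np.cross(v[fc[:, 1]] - v[fc[:, 0]], v[fc[:, 2]] - v[fc[:, 0]])
    areas2 = np.linalg.norm(normals, axis=1)
    unit_n = normals / np.maximum(areas2, 1e-300)[:, None]
    rot = np.cross(unit_n, grad)  # 90-degree rotation of grad f in the face
    area = 0.5 * areas2

    E = len(open_mesh.edges)
    F = len(fc)
    fe = open_mesh.face_edge_idx
    sg = open_mesh.face_edge_sign
    # directed edge vectors per face corner (v0->v1, v1->v2, v2->v0)
    dvec = np.stack(
        [v[fc[:, 1]] - v[fc[:, 0]], v[fc[:, 2]] - v[fc[:, 1]], v[fc[:, 0]] - v[fc[:, 2]]],
        axis=1,
    )
    t = (rot[:, None, :] * dvec).sum(axis=2)  # target on the directed edge
    t_oriented = t * sg  # target for the stored low->high orientation

    w = np.repeat(area, 3)
    idx = fe.ravel()
    D = np.zeros(E)
    b = np.zeros(E)
    np.add.at(D, idx, w)
    np.add.at(b, idx, w * t_oriented.ravel())
    x_bar = b / D

    A = sparse.coo_matrix(
        (sg.ravel(), (np.repeat(np.arange(F), 3), idx)), shape=(F, E)
    ).tocsr()
    Dinv = sparse.diags(1.0 / D)
    S = (A @ Dinv @ A.T).tocsc()
    rhs = A @ x_bar
    mu = spsolve(S, rhs)
    if not np.all(np.isfinite(mu)):
        raise ValueError("ill-conditioned conjugate-form system (singular Schur complement)")
    x = x_bar - Dinv @ (A.T @ mu)
    return OneForm(edges=open_mesh.edges, values=x, potential=None)


def _bfs_tree_integrate(open_mesh: OpenMesh, values: np.ndarray, seed: int) -> np.ndarray:
    """Integrate an edge 1-form over a BFS spanning tree from ``seed``."""
    n = len(open_mesh.mesh.vertices)
    e = open_mesh.edges
    adj_head = [[] for _ in range(n)]
    for k in range(len(e)):
        i, j = int(e[k, 0]), int(e[k, 1])
        adj_head[i].append((j, values[k]))
        adj_head[j].append((i, -values[k]))
    u = np.full(n, np.nan)
    u[seed] = 0.0
    queue = [seed]
    head = 0
    while head < len(queue):
        cur = queue[head]
        head += 1
        for nb, val in adj_head[cur]:
            if np.isnan(u[nb]):
                u[nb] = u[cur] + val
                queue.append(nb)
    if np.any(np.isnan(u)):
        raise ValueError("mesh is disconnected; cannot integrate 1-form")
    return u


def _loop_integral(open_mesh: OpenMesh, form: OneForm, loop: list[int]) -> float:
    e = open_mesh.edges
    lookup = {(int(a), int(b)): k for k, (a, b) in enumerate(e)}
    total = 0.0
    m = len(loop)
    for t in range(m):
        i, j = loop[t], loop[(t + 1) % m]
        if i < j:
            total += form.values[lookup[(i, j)]]
        else:
            total -= form.values[lookup[(j, i)]]
    return total


def integrate_holomorphic(
    open_mesh: OpenMesh,
    omega: OneForm,
    omega_star: OneForm,
    mean_curv: np.ndarray | None = None,
) -> ConformalGrid:
    """Integrate (omega*, omega) into per-vertex (u, v) rectangle coordinates.

    v is the harmonic potential itself (0 and 1 on the boundary loops); u is
    the tree integral of omega*, single-valued modulo the period U (the loop
    integral of omega* around a boundary loop).  Faces that straddle the
    periodic cut get per-face unwrapped u values.  The conformal factor is
    the vertex-ring ratio of 3-D to planar area.
    """
    mesh = open_mesh.mesh
    fc = mesh.faces
    v3 = mesh.vertices
    vcoord = omega.potential
    if vcoord is None:
        raise ValueError("omega must be the exact form carrying its potential")

    U = _loop_integral(open_mesh, omega_star, open_mesh.boundary_loops[0])
    star_vals = omega_star.values
    if U < 0:
        star_vals = -star_vals
        U = -U
    if U <= 0:
        raise ValueError("degenerate period: conjugate form has zero loop integral")

    seed = int(np.min(fc))
    u = _bfs_tree_integrate(
        open_mesh, star_vals, seed
    )
    u = np.mod(u, U)

    # per-face unwrapped u (shortest wrap relative to the first corner)
    uf = u[fc]
    d = uf - uf[:, [0]]
    d = (d + U / 2.0) % U - U / 2.0
    uf = uf[:, [0]] + d
    vf = vcoord[fc]
    face_uv = np.stack([uf, vf], axis=2)

    # orientation: make signed planar areas positive (flip u if needed)
    signed = 0.5 * (
        (uf[:, 1] - uf[:, 0]) * (vf[:, 2] - vf[:, 0])
        - (uf[:, 2] - uf[:, 0]) * (vf[:, 1] - vf[:, 0])
    )
    if np.median(signed) < 0:
        u = np.mod(-u, U)
        uf = -uf
        face_uv = np.stack([uf, vf], axis=2)
        signed = -signed
    flipped = np.nonzero(signed <= 0)[0]
    if len(flipped):
        raise ValueError(
            f"{len(flipped)} flipped uv triangles (e.g. faces {flipped[:10].tolist()})"
        )

    area3 = mesh.area_faces
    area2 = signed
    V = len(v3)
    acc3 = np.zeros(V)
    acc2 = np.zeros(V)
    for c in range(3):
        np.add.at(acc3, fc[:, c], area3)
        np.add.at(acc2, fc[:, c], area2)
    lam = acc3 / np.maximum(acc2, 1e-300)
    if np.any(lam <= 0):
        raise ValueError("non-positive conformal factor")

    if mean_curv is None:
        mean_curv = mean_curvature(mesh)
    uv = np.stack([u, vcoord], axis=1)
    return ConformalGrid(
        uv=uv,
        period_u=float(U),
        conformal_factor=lam,
        mean_curvature=np.asarray(mean_curv, float),
        face_uv=face_uv,
    )


def mean_curvature(mesh: trimesh.Trimesh) -> np.ndarray:
    """Signed mean curvature H = (k1 + k2)/2 per vertex.

    Computed from the cotangent Laplace-Beltrami applied to the coordinates
    (the mean-curvature normal), signed by the outward vertex normal: a
    sphere of radius r gives H = +1/r, a cylinder +1/(2r).  Vertices with a
    zero-area ring raise.
    """
    v = mesh.vertices
    fc = mesh.faces
    L = cotangent_laplacian(v, fc)
    A_mixed = _mixed_voronoi_area(v, fc)
    if np.any(A_mixed <= 0):
        bad = int(np.argmin(A_mixed))
        raise ValueError(f"zero-area vertex ring at vertex {bad}")
    # -(L x)/A_mixed approximates the Laplace-Beltrami of the embedding,
    # whose normal component is -(k1 + k2); halving gives H
    K = -np.asarray(L @ v) / (2.0 * A_mixed)[:, None]
    normals = mesh.vertex_normals
    H = (K * normals).sum(axis=1)
    return H


def _mixed_voronoi_area(v: np.ndarray, fc: np.ndarray) -> np.ndarray:
    """Meyer-style mixed Voronoi cell areas (accurate at irregular valences)."""
    p = [v[fc[:, c]] for c in range(3)]
    area = 0.5 * np.linalg.norm(np.cross(p[1] - p[0], p[2] - p[0]), axis=1)
    out = np.zeros(len(v))
    cots = []
    for c in range(3):
        e1 = p[(c + 1) % 3] - p[c]
        e2 = p[(c + 2) % 3] - p[c]
        cross = np.maximum(np.linalg.norm(np.cross(e1, e2), axis=1), 1e-300)
        cots.append((e1 * e2).sum(axis=1) / cross)
    cots = np.stack(cots, axis=1)
    obtuse = cots < 0  # negative cotangent = obtuse corner
    any_obtuse = obtuse.any(axis=1)
    for c in range(3):
        l_next = ((p[(c + 2) % 3] - p[c]) ** 2).sum(axis=1)  # edge to vertex c+2
        l_prev = ((p[(c + 1) % 3] - p[c]) ** 2).sum(axis=1)
        voronoi = 0.125 * (l_prev * cots[:, (c + 2) % 3] + l_next * cots[:, (c + 1) % 3])
        contrib = np.where(
            ~any_obtuse, voronoi, np.where(obtuse[:, c], area / 2.0, area / 4.0)
        )
        np.add.at(out, fc[:, c], contrib)
    return out


def feature_image(
    grid: ConformalGrid,
    resolution: tuple[int, int] = (256, 128),
) -> FeatureImage:
    """Rasterize the conformal representation onto the uv rectangle.

    lambda and H carry incommensurate units (area ratio vs 1/mm), so each is
    z-score standardized across vertices before summation; the summed field
    is linearly interpolated onto a W x H pixel grid (periodic in u) and
    scaled so min -> 0, max -> 255.
    """
    W, H = resolution

    def _z(x: np.ndarray) -> np.ndarray:
        sd = np.std(x)
        if sd < 1e-30:
            return np.zeros_like(x)
        return (x - np.mean(x)) / sd

    s = _z(grid.conformal_factor) + _z(grid.mean_curvature)

    un = grid.uv[:, 0] / grid.period_u  # normalized u in [0, 1)
    vn = grid.uv[:, 1]
    pts = np.concatenate(
        [
            np.stack([un - 1.0, vn], 1),
            np.stack([un, vn], 1),
            np.stack([un + 1.0, vn], 1),
        ]
    )
    vals = np.concatenate([s, s, s])
    interp = LinearNDInterpolator(pts, vals)
    ui = (np.arange(W) + 0.5) / W
    vi = (np.arange(H) + 0.5) / H
    UU, VV = np.meshgrid(ui, vi)
    raster = interp(UU, VV)
    valid = np.isfinite(raster)
    raster = np.where(valid, raster, 0.0)

    rmin = raster[valid].min() if valid.any() else 0.0
    rmax = raster[valid].max() if valid.any() else 0.0
    if rmax - rmin < 1e-30:
        warnings.warn("constant conformal representation; feature image set to 0")
        return FeatureImage(raster=np.zeros((H, W)), valid=valid)
    out = np.zeros((H, W))
    out[valid] = 255.0 * (raster[valid] - rmin) / (rmax - rmin)
    return FeatureImage(raster=out, valid=valid)


def write_pgm(img: FeatureImage, path, comment: str = "") -> None:
    """8-bit binary PGM dump of a feature image (plus nothing else)."""
    from pathlib import Path

    H, W = img.raster.shape
    data = np.clip(np.rint(img.raster), 0, 255).astype(np.uint8)
    header = f"P5\n# {comment}\n{W} {H}\n255\n".encode()
    Path(path).write_bytes(header + data.tobytes())


def conformal_parameterize(
    mesh: trimesh.Trimesh,
    k_ring: int = 1,
    resolution: tuple[int, int] = (256, 128),
    retry_k_rings: bool = True,
) -> tuple[OpenMesh, ConformalGrid, FeatureImage]:
    """Closed mesh -> (open mesh, conformal grid, feature image) in one call.

    A boundary sliver can flip in the plane for one cut-hole radius but not
    another, so by default the alternate hole sizes 1..3 are tried before
    giving up.
    """
    candidates = [k_ring]
    if retry_k_rings:
        candidates += [k for k in (1, 2, 3) if k != k_ring]
    err: Exception | None = None
    for k in candidates:
        try:
            om = cut_end_holes(mesh, k_ring=k)
            omega = exact_harmonic_one_form(om)
            omega_star = conjugate_one_form(om, omega)
            grid = integrate_holomorphic(om, omega, omega_star)
            img = feature_image(grid, resolution=resolution)
            return om, grid, img
        except ValueError as exc:
            err = exc
    raise ValueError(str(err))


def angle_distortion_deg(open_mesh: OpenMesh, grid: ConformalGrid) -> np.ndarray:
    """Per-face mean |3-D angle - uv angle| in degrees (conformality metric)."""
    v = open_mesh.mesh.vertices
    fc = open_mesh.mesh.faces

    def _angles(p0, p1, p2):
        out = []
        for a, b, c in ((p0, p1, p2), (p1, p2, p0), (p2, p0, p1)):
            u_ = b - a
            w_ = c - a
            cos = (u_ * w_).sum(axis=1) / np.maximum(
                np.linalg.norm(u_, axis=1) * np.linalg.norm(w_, axis=1), 1e-300
            )
            out.append(np.degrees(np.arccos(np.clip(cos, -1, 1))))
        return np.stack(out, axis=1)

    a3 = _angles(v[fc[:, 0]], v[fc[:, 1]], v[fc[:, 2]])
    fuv = grid.face_uv
    pad = lambda q: np.concatenate([q, np.zeros((len(q), 1))], axis=1)
    a2 = _angles(pad(fuv[:, 0]), pad(fuv[:, 1]), pad(fuv[:, 2]))
    return np.abs(a3 - a2).mean(axis=1)
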