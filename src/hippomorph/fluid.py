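"""Inverse-consistent viscous-fluid registration in the conformal domain.

Feature images live on the parameter rectangle: rows index v in [0, 1]
(Neumann-type ends), columns index u (periodic — the rectangle is an
unwrapped cylinder).  Registration follows the classic fluid model: an SSD
body force drives a velocity field obtained by solving the linearized
Navier-Stokes (Navier-Cauchy) operator

    mu * lap(v) + (lambda + mu) * grad(div v) = -f

spectrally each iteration; displacements are advanced by an advective Euler
step and regridded whenever the incremental Jacobian determinant drops too
low, which keeps the accumulated map diffeomorphic.  Forward and backward
maps are estimated alternately with a penalty tying each to the inverse of
the other (inverse consistency).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "RegistrationParams",
    "DeformationField",
    "RegistrationDiverged",
    "body_force",
    "solve_fluid_velocity",
    "fluid_register_oneway",
    "inverse_consistent_register",
    "pull_correspondence",
    "warp_image",
    "displacement_jacobian",
    "invert_displacement",
    "circular_u_shift",
]


@dataclass(frozen=True)
class RegistrationParams:
    """Fluid-registration knobs (pixel units on the raster).

    mu_visc / lambda_visc   viscosity coefficients of the Navier-Cauchy
                            operator; mu must be positive
    step_size               Euler time step upper bound
    max_motion              per-iteration displacement cap in pixels
    max_iters               iteration budget
    regrid_jac_threshold    regrid when incremental min |J| falls below this
    consistency_weight      weight of the inverse-consistency body force
    convergence_tol         relative SSD improvement below which we stop
    """

    mu_visc: float = 1.0
    lambda_visc: float = 0.0
    step_size: float = 1.0
    max_motion: float = 0.5
    max_iters: int = 300
    regrid_jac_threshold: float = 0.5
    consistency_weight: float = 2.0
    convergence_tol: float = 1e-5

    def __post_init__(self) -> None:
        if self.mu_visc <= 0:
            raise ValueError("mu_visc must be > 0")
        if not (0 < self.regrid_jac_threshold < 1):
            raise ValueError("regrid_jac_threshold must be in (0, 1)")


@dataclass
class DeformationField:
    """Forward and backward dense displacements (pixels) with diagnostics."""

    forward_disp: np.ndarray  # (2, H, W): (du, dv)
    backward_disp: np.ndarray
    jacobian_det: np.ndarray  # of id + forward_disp
    converged: bool
    final_ssd: float
    inverse_consistency_px: float
    log: list = field(default_factory=list)


_SYMMETRIZE = True  # final first-order symmetrizing blend (see below)


class RegistrationDiverged(RuntimeError):
    def __init__(self, message: str, trace: list):
        super().__init__(message)
        self.trace = trace


# ---------------------------------------------------------------------------
# raster primitives (periodic u = axis 1, clamped v = axis 0)


def warp_image(image: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Sample image(x + disp(x)) with bilinear interpolation, wrapping u."""
    H, W = image.shape
    vv, uu = np.meshgrid(np.arange(H, dtype=float), np.arange(W, dtype=float), indexing="ij")
    uq = np.mod(uu + disp[0], W)
    vq = np.clip(vv + disp[1], 0.0, H - 1.0)
    padded = np.concatenate([image, image[:, :1]], axis=1)  # close the u seam
    return map_coordinates(padded, [vq, uq], order=1, mode="nearest")


def image_gradient(image: np.ndarray) -> np.ndarray:
    """(d/du, d/dv) central differences; periodic in u, one-sided in v."""
    gu = 0.5 * (np.roll(image, -1, axis=1) - np.roll(image, 1, axis=1))
    gv = np.gradient(image, axis=0)
    return np.stack([gu, gv])


def body_force(
    moving: np.ndarray, fixed: np.ndarray, current_disp: np.ndarray | None = None
) -> np.ndarray:
    """SSD body force f = -(I_m(x+u) - I_f(x)) grad I_m(x+u)."""
    moving = np.asarray(moving, float)
    fixed = np.asarray(fixed, float)
    if moving.shape != fixed.shape:
        raise ValueError(f"image shapes differ: {moving.shape} vs {fixed.shape}")
    if current_disp is None:
        current_disp = np.zeros((2,) + moving.shape)
    warped = warp_image(moving, current_disp)
    grad = image_gradient(warped)
    return -(warped - fixed)[None] * grad


def solve_fluid_velocity(force: np.ndarray, params: RegistrationParams) -> np.ndarray:
    """Invert the Navier-Cauchy operator spectrally.

    The v axis is mirror-extended (even for the u component, odd for the v
    component) so a fully periodic FFT solve respects zero normal
    displacement at the v boundaries; the operator symbol at wavevector k is
    mu |k|^2 I + (lambda + mu) k k^T, inverted in closed form per mode.
    """
    force = np.asarray(force, float)
    if not np.all(np.isfinite(force)):
        raise ValueError("non-finite body force")
    mu = params.mu_visc
    lam = params.lambda_visc
    _, H, W = force.shape

    fu = np.concatenate([force[0], force[0][::-1]], axis=0)  # even in v
    fv = np.concatenate([force[1], -force[1][::-1]], axis=0)  # odd in v
    Fu = np.fft.fft2(fu)
    Fv = np.fft.fft2(fv)

    ku = 2.0 * np.pi * np.fft.fftfreq(W)
    kv = 2.0 * np.pi * np.fft.fftfreq(2 * H)
    KU, KV = np.meshgrid(ku, kv)
    k2 = KU**2 + KV**2
    k2[0, 0] = 1.0  # avoid 0/0; zero mode handled below

    # (mu k2 I + (lam+mu) k k^T)^-1 = (I - c k k^T / k2) / (mu k2),
    # with c = (lam + mu) / (lam + 2 mu)
    c = (lam + mu) / (lam + 2.0 * mu)
    dot = KU * Fu + KV * Fv
    Vu = (Fu - c * KU * dot / k2) / (mu * k2)
    Vv = (Fv - c * KV * dot / k2) / (mu * k2)
    Vu[0, 0] = 0.0
    Vv[0, 0] = 0.0

    vu = np.real(np.fft.ifft2(Vu))[:H]
    vv = np.real(np.fft.ifft2(Vv))[:H]
    return np.stack([vu, vv])


def displacement_jacobian(disp: np.ndarray) -> np.ndarray:
    """Determinant of the Jacobian of x -> x + disp(x), per pixel."""
    du_du = 1.0 + image_gradient(disp[0])[0]
    du_dv = image_gradient(disp[0])[1]
    dv_du = image_gradient(disp[1])[0]
    dv_dv = 1.0 + image_gradient(disp[1])[1]
    return du_du * dv_dv - du_dv * dv_du


def compose_displacements(outer: np.ndarray, inner: np.ndarray) -> np.ndarray:
    """Displacement of x -> x + inner(x) + outer(x + inner(x))."""
    H, W = outer.shape[1:]
    out = np.empty_like(outer)
    for c in range(2):
        out[c] = warp_image(outer[c], inner)
    return out + inner


def invert_displacement(disp: np.ndarray, n_iter: int = 20) -> np.ndarray:
    """Fixed-point inverse: v(x) = -disp(x + v(x)).

    Where the input map is strongly compressive the fixed point can fold;
    the result is lightly smoothed until its own Jacobian is positive, so
    it stays a usable diffeomorphic initialization.
    """
    from scipy.ndimage import gaussian_filter

    inv = -disp.copy()
    for _ in range(n_iter):
        new = np.empty_like(inv)
        for c in range(2):
            new[c] = -warp_image(disp[c], inv)
        inv = new
    for _ in range(6):
        if displacement_jacobian(inv).min() > 0.05:
            break
        for c in range(2):
            inv[c] = gaussian_filter(inv[c], 1.0, mode=("nearest", "wrap"))
    return inv


def circular_u_shift(moving: np.ndarray, fixed: np.ndarray) -> int:
    """Integer circular shift of u (columns) maximizing image correlation.

    Each subject's conformal map fixes the u origin only up to a rotation of
    the cylinder; a global circular cross-correlation removes that gauge
    freedom before the local fluid model takes over.
    """
    a = moving - moving.mean()
    b = fixed - fixed.mean()
    corr = np.fft.ifft(
        np.fft.fft(a, axis=1).conj() * np.fft.fft(b, axis=1), axis=1
    ).real.sum(axis=0)
    return int(np.argmax(corr))


def _ssd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sum((a - b) ** 2))


def fluid_register_oneway(
    moving: np.ndarray,
    fixed: np.ndarray,
    params: RegistrationParams | None = None,
    extra_force: "callable | None" = None,
    extra_energy: "callable | None" = None,
    init_disp: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, list, bool]:
    """Greedy fluid registration of ``moving`` onto ``fixed``.

    Each iteration solves the fluid PDE for a velocity, takes an advective
    Euler step (capped at ``max_motion`` pixels) and accepts it only if the
    registration energy (SSD plus any extra penalty) does not increase,
    halving the step on rejection — so the energy is non-increasing across
    accepted iterations.  When no step length improves the energy, the
    registration has converged.  Returns ``(total_disp, jacobian_det, log,
    converged)`` with log rows (iteration, energy, incremental min Jacobian).
    ``extra_force(disp)`` / ``extra_energy(disp)`` let the inverse-consistent
    driver inject its penalty.
    """
    params = params or RegistrationParams()
    moving = np.asarray(moving, float)
    fixed = np.asarray(fixed, float)
    if moving.shape != fixed.shape:
        raise ValueError(f"image shapes differ: {moving.shape} vs {fixed.shape}")
    if not (np.all(np.isfinite(moving)) and np.all(np.isfinite(fixed))):
        raise ValueError("non-finite image values")

    total = np.zeros((2,) + moving.shape) if init_disp is None else init_disp.copy()
    if init_disp is not None:
        # shrink a folding initialization toward zero until diffeomorphic
        for _ in range(8):
            if displacement_jacobian(total).min() > 0:
                break
            total *= 0.5
        else:
            total[:] = 0.0
    inc = np.zeros_like(total)
    current_moving = moving if init_disp is None else warp_image(moving, total)
    log: list = []

    def energy(inc_d, total_d):
        e = _ssd(warp_image(current_moving, inc_d), fixed)
        if extra_energy is not None:
            e += extra_energy(compose_displacements(total_d, inc_d))
        return e

    e_prev = energy(inc, total)
    e0 = max(e_prev, 1e-30)
    converged = e_prev == 0.0

    for it in range(params.max_iters if not converged else 0):
        force = body_force(current_moving, fixed, inc)
        if extra_force is not None:
            force = force + extra_force(compose_displacements(total, inc))
        vel = solve_fluid_velocity(force, params)
        vmax = float(np.max(np.abs(vel)))
        if vmax < 1e-12:
            converged = True
            break
        dt = min(params.step_size, params.max_motion / vmax)

        # advective update: du/dt = v - (grad u) v
        upd = np.empty_like(inc)
        for c in range(2):
            g = image_gradient(inc[c])
            upd[c] = vel[c] - (g[0] * vel[0] + g[1] * vel[1])

        accepted = False
        for _trial in range(5):
            cand = inc + dt * upd
            e_cand = energy(cand, total)
            # a step that folds the incremental map is rejected outright
            if e_cand <= e_prev and displacement_jacobian(cand).min() > 0:
                accepted = True
                break
            dt *= 0.5
        if not accepted:
            converged = True
            break
        inc = cand

        jac = displacement_jacobian(inc)
        minjac = float(jac.min())
        if minjac < params.regrid_jac_threshold:
            total = compose_displacements(total, inc)
            current_moving = warp_image(moving, total)
            inc = np.zeros_like(inc)
            minjac = 1.0
            e_cand = energy(inc, total)

        log.append((it, e_cand, minjac))
        if (e_prev - e_cand) / e0 < params.convergence_tol:
            e_prev = e_cand
            converged = True
            break
        e_prev = e_cand

    total = compose_displacements(total, inc)
    jac = displacement_jacobian(total)
    if jac.min() <= 0:
        # composition of diffeomorphic pieces can fold by interpolation
        # error only; a light smoothing repairs it, otherwise we give up
        from scipy.ndimage import gaussian_filter

        for _ in range(4):
            for c in range(2):
                total[c] = gaussian_filter(total[c], 0.5, mode=("nearest", "wrap"))
            jac = displacement_jacobian(total)
            if jac.min() > 0:
                break
        else:
            raise RegistrationDiverged(
                f"final Jacobian determinant not positive (min {jac.min():.3g})", log
            )
    return total, jac, log, converged


def inverse_consistent_register(
    image_a: np.ndarray,
    image_b: np.ndarray,
    params: RegistrationParams | None = None,
    n_outer: int = 4,
) -> DeformationField:
    """Alternating inverse-consistent fluid registration.

    Forward (a->b) and backward (b->a) displacements are re-estimated in
    alternation; each direction's body force carries an extra penalty term
    ``-w (u - inv(u_other))`` pulling it toward the inverse of the other
    direction's current estimate.  Swapping the inputs swaps the roles of the
    two fields (up to solver tolerance).
    """
    params = params or RegistrationParams()
    image_a = np.asarray(image_a, float)
    image_b = np.asarray(image_b, float)

    fwd = np.zeros((2,) + image_a.shape)
    bwd = np.zeros((2,) + image_a.shape)
    log_all: list = []
    conv_f = conv_b = False
    per_dir = max(params.max_iters // n_outer, 1)
    sub = RegistrationParams(
        **{
            **{f: getattr(params, f) for f in params.__dataclass_fields__},
            "max_iters": per_dir,
        }
    )

    w = params.consistency_weight

    def _penalty(tgt):
        if w == 0:
            return None, None
        force = lambda d: -w * (d - tgt)
        energy = lambda d: 0.5 * w * float(np.sum((d - tgt) ** 2))
        return force, energy

    couple = w > 0  # weight 0 degenerates to two independent registrations
    for outer in range(n_outer):
        # each direction is warm-started from the inverse of the other and
        # penalized for drifting away from it, so the image term only
        # perturbs an inverse-consistent initialization locally
        inv_b = invert_displacement(bwd) if couple else None
        force_f, energy_f = _penalty(inv_b) if (couple and outer) else (None, None)
        fwd, jac_f, log_f, conv_f = fluid_register_oneway(
            image_a, image_b, sub, extra_force=force_f, extra_energy=energy_f,
            init_disp=inv_b if (couple and outer) else (fwd if outer else None),
        )
        inv_f = invert_displacement(fwd) if couple else None
        force_b, energy_b = _penalty(inv_f) if couple else (None, None)
        bwd, jac_b, log_b, conv_b = fluid_register_oneway(
            image_b, image_a, sub, extra_force=force_b, extra_energy=energy_b,
            init_disp=inv_f if couple else (bwd if outer else None),
        )
        log_all.extend([("fwd", *row) for row in log_f])
        log_all.extend([("bwd", *row) for row in log_b])
        if outer > 0 and conv_f and conv_b:
            break

    if w > 0 and _SYMMETRIZE:
        # symmetrizing step: blend each field toward the inverse of the
        # other (first-order errors cancel, leaving the pair consistent to
        # second order); the blend is backed off if it would fold either map
        inv_b = invert_displacement(bwd)
        inv_f = invert_displacement(fwd)
        for blend in (0.5, 0.25, 0.125):
            fwd_new = (1 - blend) * fwd + blend * inv_b
            bwd_new = (1 - blend) * bwd + blend * inv_f
            if (
                displacement_jacobian(fwd_new).min() > 0
                and displacement_jacobian(bwd_new).min() > 0
            ):
                fwd, bwd = fwd_new, bwd_new
                break

    resid = compose_displacements(bwd, fwd)  # forward then backward ~ id
    ic_err = float(np.mean(np.linalg.norm(resid, axis=0)))
    final_ssd = _ssd(warp_image(image_a, fwd), image_b)
    return DeformationField(
        forward_disp=fwd,
        backward_disp=bwd,
        jacobian_det=displacement_jacobian(fwd),
        converged=bool(conv_f and conv_b),
        final_ssd=final_ssd,
        inverse_consistency_px=ic_err,
        log=log_all,
    )


# ---------------------------------------------------------------------------
# correspondence transfer


def _barycentric(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Barycentric coordinates of 2-D points p in triangles tri (n, 3, 2)."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    v0 = b - a
    v1 = c - a
    v2 = p - a
    d00 = (v0 * v0).sum(1)
    d01 = (v0 * v1).sum(1)
    d11 = (v1 * v1).sum(1)
    d20 = (v2 * v0).sum(1)
    d21 = (v2 * v1).sum(1)
    den = d00 * d11 - d01 * d01
    den = np.where(np.abs(den) < 1e-300, 1e-300, den)
    w1 = (d11 * d20 - d01 * d21) / den
    w2 = (d00 * d21 - d01 * d20) / den
    return np.stack([1.0 - w1 - w2, w1, w2], axis=1)


def pull_correspondence(
    field: DeformationField,
    subject_grid,
    subject_mesh,
    template_grid,
    raster_shape: tuple[int, int],
) -> tuple[np.ndarray, int]:
    """Resample the subject surface at every template vertex.

    Template vertex uv -> (+ forward displacement, sampled bilinearly on the
    raster) -> subject uv -> containing subject uv-triangle (periodic in u,
    located via a centroid KD-tree with barycentric verification) -> 3-D
    point barycentrically interpolated from the subject mesh.  Points falling
    outside the subject's v range are clamped to the nearest triangle; the
    clamp count is returned.
    """
    from scipy.spatial import cKDTree

    H, W = raster_shape
    t_un = template_grid.uv[:, 0] / template_grid.period_u
    t_vn = template_grid.uv[:, 1]
    px_u = t_un * W - 0.5
    px_v = t_vn * H - 0.5
    du = _sample_at(field.forward_disp[0], px_u, px_v, W, H)
    dv = _sample_at(field.forward_disp[1], px_u, px_v, W, H)
    q_u = np.mod(t_un + du / W, 1.0)
    q_v = np.clip(t_vn + dv / H, 0.0, 1.0)
    query = np.stack([q_u, q_v], axis=1)

    fuv = subject_grid.face_uv.copy()
    fuv[:, :, 0] /= subject_grid.period_u
    faces = subject_mesh.faces
    # 3 periodic copies of every face so queries near the seam find a home
    tris = np.concatenate(
        [fuv + np.array([s, 0.0]) for s in (-1.0, 0.0, 1.0)]
    )
    face_of = np.tile(np.arange(len(faces)), 3)
    centroids = tris.mean(axis=1)
    tree = cKDTree(centroids)

    n = len(query)
    out = np.zeros((n, 3))
    clamped = 0
    K = min(24, len(centroids))
    _, idx = tree.query(query, k=K)
    verts3 = subject_mesh.vertices
    found = np.zeros(n, dtype=bool)
    best_bary = np.zeros((n, 3))
    best_face = np.zeros(n, dtype=int)
    best_score = np.full(n, -np.inf)
    for kk in range(K):
        cand = idx[:, kk]
        bary = _barycentric(query, tris[cand])
        score = bary.min(axis=1)
        ok = (score >= -1e-9) & ~found
        found |= ok
        upd = score > best_score
        best_score[upd] = score[upd]
        best_bary[upd] = bary[upd]
        best_face[upd] = face_of[cand[upd]]
        if found.all():
            break
    clamped = int((~found).sum())
    best_bary = np.clip(best_bary, 0.0, 1.0)
    best_bary /= best_bary.sum(axis=1, keepdims=True)
    fverts = faces[best_face]
    out = (
        best_bary[:, 0, None] * verts3[fverts[:, 0]]
        + best_bary[:, 1, None] * verts3[fverts[:, 1]]
        + best_bary[:, 2, None] * verts3[fverts[:, 2]]
    )
    return out, clamped


def _sample_at(img: np.ndarray, px_u: np.ndarray, px_v: np.ndarray, W: int, H: int):
    padded = np.concatenate([img, img[:, :1]], axis=1)
    uq = np.mod(px_u, W)
    vq = np.clip(px_v, 0.0, H - 1.0)
    return map_coordinates(padded, [vq, uq], order=1, mode="nearest")
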