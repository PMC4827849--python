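"""Synthetic hippocampus-like cohorts with dose-graded implanted atrophy.

The hippocampus is, to first order, a bent tube ("banana"): a circular-arc
centerline swept by a tapered radius profile that closes to a genus-0 surface
at both ends.  This module rasterizes such tubes into binary volumes and
builds whole cohorts in which a localized radial shrink scales with an allele
dose covariate (0/1/2), so that every downstream stage — surface extraction,
conformal mapping, registration, morphometry and group inference — can be
exercised on data with known ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "ShapeParams",
    "AtrophySpec",
    "default_radius_profile",
    "make_tube_volume",
    "make_cohort",
    "tube_frame",
    "centerline_points",
    "effective_radius",
    "atrophy_window",
    "GROUP_LABELS",
]

#: group label per allele dose, mirroring carrier status nomenclature
GROUP_LABELS = {0: "noncarrier", 1: "heterozygote", 2: "homozygote"}


def default_radius_profile(max_radius: float) -> Callable[[np.ndarray], np.ndarray]:
    """Elliptic taper r(s) = r_max * sqrt(4 s (1-s)).

    Positive on (0,1), zero at both ends, so the swept tube closes smoothly
    (an ellipsoid-like cap rather than a flat disk).
    """

    def profile(s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        return max_radius * np.sqrt(np.clip(4.0 * s * (1.0 - s), 0.0, None))

    return profile


@dataclass(frozen=True)
class ShapeParams:
    """Geometry of the synthetic tube.

    length          arclength of the centerline arc [mm]
    max_radius      peak of the default radius profile [mm]
    bend_curvature  curvature of the planar centerline arc [1/mm]
    voxel_size      isotropic voxel edge [mm]
    grid_shape      voxels per axis
    radius_profile  optional override: arclength fraction in [0,1] -> mm
    """

    length: float = 36.0
    max_radius: float = 6.0
    bend_curvature: float = 1.0 / 45.0
    voxel_size: float = 1.0
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    radius_profile: Callable[[np.ndarray], np.ndarray] | None = None

    def profile(self) -> Callable[[np.ndarray], np.ndarray]:
        if self.radius_profile is not None:
            return self.radius_profile
        return default_radius_profile(self.max_radius)


@dataclass(frozen=True)
class AtrophySpec:
    """Localized multiplicative radial shrink, scaled by allele dose.

    The window in arclength is a Tukey profile: a flat core of width
    ``extent_s / 2`` centered at ``center_s`` where the full shrink applies,
    flanked by raised-cosine tapers of width ``extent_s / 4`` on each side
    (total support ``extent_s``).  Dose 0 must map to multiplier 0.
    """

    center_s: float = 0.5
    extent_s: float = 0.4
    max_radial_shrink: float = 0.15
    dose_scaling: Mapping[int, float] = field(
        default_factory=lambda: {0: 0.0, 1: 0.5, 2: 1.0}
    )

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_radial_shrink < 1.0):
            raise ValueError("max_radial_shrink must be in [0, 1)")
        if self.dose_scaling.get(0, 0.0) != 0.0:
            raise ValueError("dose 0 must map to multiplier 0")

    def multiplier(self, dose: int) -> float:
        try:
            return float(self.dose_scaling[int(dose)]) * self.max_radial_shrink
        except KeyError as exc:
            raise ValueError(f"unknown dose level {dose!r}") from exc


def atrophy_window(s: np.ndarray, spec: AtrophySpec) -> np.ndarray:
    """Tukey window w(s) in [0,1]: 1 on the flat core, cosine flanks, 0 outside."""
    s = np.asarray(s, dtype=float)
    half_support = spec.extent_s / 2.0
    half_core = spec.extent_s / 4.0
    d = np.abs(s - spec.center_s)
    w = np.zeros_like(s)
    w[d <= half_core] = 1.0
    flank = (d > half_core) & (d < half_support)
    t = (d[flank] - half_core) / (half_support - half_core)
    w[flank] = 0.5 * (1.0 + np.cos(np.pi * t))
    return w


def centerline_points(params: ShapeParams, s: np.ndarray) -> np.ndarray:
    """Points of the circular-arc centerline at arclength fractions s.

    The arc lies in the z = 0 plane, starts at the origin with tangent +x and
    bends toward +y; a zero curvature degenerates to a straight segment.
    """
    s = np.asarray(s, dtype=float)
    t = s * params.length
    kappa = params.bend_curvature
    if abs(kappa) < 1e-12:
        return np.stack([t, np.zeros_like(t), np.zeros_like(t)], axis=-1)
    R = 1.0 / kappa
    theta = t / R
    return np.stack(
        [R * np.sin(theta), R * (1.0 - np.cos(theta)), np.zeros_like(t)], axis=-1
    )


def _noise_series(noise_sd: float, rng: np.random.Generator, n_terms: int = 5):
    """Smooth random radius perturbation: truncated random cosine series.

    delta(s) = noise_sd * (1/sqrt(n)) * sum_k z_k * sqrt(2) cos(k pi s + phi_k)
    with z_k ~ N(0,1), phi_k ~ U(0, 2pi); E[Var_s delta] = noise_sd^2.
    """
    z = rng.standard_normal(n_terms)
    phi = rng.uniform(0.0, 2.0 * np.pi, n_terms)

    def delta(s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        k = np.arange(1, n_terms + 1)
        terms = np.sqrt(2.0) * np.cos(np.outer(s, k) * np.pi + phi)
        return noise_sd / np.sqrt(n_terms) * terms @ z

    return delta


def effective_radius(
    s: np.ndarray,
    params: ShapeParams,
    atrophy: AtrophySpec,
    dose: int,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Radius profile after noise and dose-scaled atrophy, r_eff(s).

    r_eff(s) = (r(s) + delta(s) * taper(s)) * (1 - m * w(s)),
    where m = dose_scaling(dose) * max_radial_shrink.  The noise is tapered by
    the relative base profile so the tube still closes at the ends.
    """
    s = np.asarray(s, dtype=float)
    base = params.profile()(s)
    peak = float(np.max(params.profile()(np.linspace(0, 1, 257))))
    if peak <= 0:
        raise ValueError("degenerate radius profile: non-positive peak radius")
    r = base.copy()
    if noise_sd > 0.0:
        rng = np.random.default_rng(seed)
        delta = _noise_series(noise_sd, rng)
        r = base + delta(s) * (base / peak)
    m = atrophy.multiplier(dose)
    r = r * (1.0 - m * atrophy_window(s, atrophy))
    interior = (s > 0.02) & (s < 0.98)
    if np.any(r[interior] <= 0.05 * peak):
        raise ValueError("degenerate radius: noise/atrophy collapsed the tube")
    return r


def tube_frame(
    params: ShapeParams,
    atrophy: AtrophySpec,
    dose: int = 0,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_arc_samples: int = 512,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Arclength samples, grid-centered centerline points and radii.

    Returns ``(s, gamma, r)`` where gamma is translated so the tube sits
    centered in the voxel grid (the same frame the rasterized volume and the
    meshes extracted from it live in).  Raises, naming the axis, if the tube
    would come within 3 voxels of the grid border.
    """
    s = np.linspace(0.0, 1.0, n_arc_samples)
    gamma = centerline_points(params, s)
    r = effective_radius(s, params, atrophy, dose, noise_sd, seed)

    grid = np.asarray(params.grid_shape, dtype=int)
    extent_mm = grid * params.voxel_size
    lo = (gamma - r[:, None]).min(axis=0)
    hi = (gamma + r[:, None]).max(axis=0)
    shift = 0.5 * extent_mm - 0.5 * (lo + hi)  # center the tube in the grid
    margin = 3.0 * params.voxel_size
    for ax, name in enumerate("xyz"):
        if (hi[ax] - lo[ax]) + 2.0 * margin > extent_mm[ax]:
            raise ValueError(
                f"tube exits grid along axis {name}: needs "
                f"{(hi[ax] - lo[ax]) + 2 * margin:.1f} mm, grid has {extent_mm[ax]:.1f} mm"
            )
    return s, gamma + shift, r


def make_tube_volume(
    params: ShapeParams,
    atrophy: AtrophySpec,
    dose: int = 0,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_arc_samples: int = 512,
) -> np.ndarray:
    """Rasterize the tube into a binary uint8 volume.

    A voxel center p is foreground iff the analytic tube inequality
    ``min_s ( |p - gamma(s)|^2 - r_eff(s)^2 ) <= 0`` holds, evaluated on a
    dense arclength grid.  The tube is centered in the voxel grid.
    """
    s, gamma, r = tube_frame(params, atrophy, dose, noise_sd, seed, n_arc_samples)
    grid = np.asarray(params.grid_shape, dtype=int)

    # voxel centers, restricted to the tube bounding box for speed
    centers = [
        (np.arange(grid[ax]) + 0.5) * params.voxel_size for ax in range(3)
    ]
    lo_idx = np.maximum(((gamma - r[:, None]).min(axis=0)) // params.voxel_size - 1, 0)
    hi_idx = np.minimum(
        ((gamma + r[:, None]).max(axis=0)) // params.voxel_size + 2, grid
    )
    lo_idx = lo_idx.astype(int)
    hi_idx = hi_idx.astype(int)
    sub = [centers[ax][lo_idx[ax] : hi_idx[ax]] for ax in range(3)]
    X, Y, Z = np.meshgrid(*sub, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)

    inside = np.zeros(pts.shape[0], dtype=bool)
    chunk = 32
    for k0 in range(0, n_arc_samples, chunk):
        g = gamma[k0 : k0 + chunk]
        rr = r[k0 : k0 + chunk]
        d2 = ((pts[:, None, :] - g[None, :, :]) ** 2).sum(axis=2)
        inside |= (d2 <= rr[None, :] ** 2).any(axis=1)

    vol = np.zeros(tuple(grid), dtype=np.uint8)
    box = vol[
        lo_idx[0] : hi_idx[0], lo_idx[1] : hi_idx[1], lo_idx[2] : hi_idx[2]
    ]
    box[...] = inside.reshape(box.shape)
    return vol


def _subject_seed(master_seed: int, index: int) -> int:
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(index),))
    return int(ss.generate_state(1)[0] % (2**31))


def make_cohort(
    n_per_dose: Mapping[int, int],
    params: ShapeParams,
    atrophy: AtrophySpec,
    noise_sd: float = 0.25,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Generate a cohort of tube volumes plus its table.

    Returns ``(table, volumes)``; ``table`` has columns
    ``subject_id,group,dose,seed``.  Subject seeds are derived reproducibly
    from the master seed, so the whole cohort is bit-reproducible.  When
    ``out_dir`` is given, masks are written as NIfTI-1 (uint8, affine =
    voxel_size * identity) and the table as ``cohort.csv``.
    """
    if any(n < 0 for n in n_per_dose.values()):
        raise ValueError("subject counts must be >= 0")
    if sum(n_per_dose.values()) == 0:
        raise ValueError("cohort must contain at least one subject")

    rows = []
    volumes: dict[str, np.ndarray] = {}
    index = 0
    for dose in sorted(n_per_dose):
        for j in range(n_per_dose[dose]):
            sid = f"sub-{dose}{j:03d}"
            subj_seed = _subject_seed(seed, index)
            vol = make_tube_volume(
                params, atrophy, dose=dose, noise_sd=noise_sd, seed=subj_seed
            )
            volumes[sid] = vol
            rows.append(
                {
                    "subject_id": sid,
                    "group": GROUP_LABELS.get(dose, f"dose{dose}"),
                    "dose": dose,
                    "seed": subj_seed,
                }
            )
            index += 1
    table = pd.DataFrame(rows, columns=["subject_id", "group", "dose", "seed"])

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        affine = np.diag([params.voxel_size] * 3 + [1.0])
        for sid, vol in volumes.items():
            nib.save(nib.Nifti1Image(vol, affine), out / f"{sid}.nii")
        table.to_csv(out / "cohort.csv", index=False)
    return table, volumes
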