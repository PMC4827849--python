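"""Property-level validation suites for the whole pipeline.

These functions re-derive, at desk scale, the quantitative guarantees the
package is built on: conformality of the parameterization, geometric
oracles with closed-form answers, registration recovery and inverse
consistency, permutation-test calibration under a true null, and power /
localization / dose-response behaviour on cohorts with implanted atrophy.
They are used by the test suite, by ``hippomorph validate`` and by the
acceptance script; everything is deterministic given the seed.
"""

from __future__ import annotations

import numpy as np
import trimesh

from . import conformal as cf
from . import fluid as fl
from . import morphometry as mm
from . import stats as st
from . import synthetic as syn
from . import surfaces as sf
from .pipeline import load_config, run_pipeline

__all__ = [
    "build_tube_mesh",
    "conformality_metrics",
    "geometry_oracle_metrics",
    "registration_metrics",
    "calibration_metrics",
    "power_localization_metrics",
    "dose_cdf_metrics",
    "run_validation",
]


def build_tube_mesh(
    seed: int = 3,
    noise_sd: float = 0.25,
    fine: bool = False,
    dose: int = 0,
    shrink: float = 0.15,
):
    """Smoothed synthetic-tube mesh (~1.6k vertices; ~4.6k when fine)."""
    if fine:
        params = syn.ShapeParams(voxel_size=0.6, grid_shape=(96, 96, 96))
    else:
        params = syn.ShapeParams()
    atrophy = syn.AtrophySpec(max_radial_shrink=shrink)
    vol = syn.make_tube_volume(params, atrophy, dose=dose, noise_sd=noise_sd, seed=seed)
    mesh = sf.refine_and_smooth(sf.extract_surface(vol, params.voxel_size), 10)
    return mesh, params, atrophy


def _analytic_cylinder(r=3.0, h=20.0, nu=64, nv=41):
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


def conformality_metrics(seed: int = 3) -> dict:
    """Angle distortion and 1-form residuals on a ~5k-vertex synthetic tube."""
    mesh, _, _ = build_tube_mesh(seed=seed, fine=True)
    err: Exception | None = None
    for k_ring in (2, 1, 3):  # a sliver can flip for one hole size only
        try:
            om = cf.cut_end_holes(mesh, k_ring=k_ring)
            omega = cf.exact_harmonic_one_form(om)
            omega_star = cf.conjugate_one_form(om, omega)
            grid = cf.integrate_holomorphic(om, omega, omega_star)
            err = None
            break
        except ValueError as exc:
            err = exc
    if err is not None:
        raise ValueError(str(err))
    distort = cf.angle_distortion_deg(om, grid)
    # total 3-D area reproduced by lambda-weighted planar area
    fuv = grid.face_uv
    area2 = 0.5 * np.abs(
        (fuv[:, 1, 0] - fuv[:, 0, 0]) * (fuv[:, 2, 1] - fuv[:, 0, 1])
        - (fuv[:, 2, 0] - fuv[:, 0, 0]) * (fuv[:, 1, 1] - fuv[:, 0, 1])
    )
    lam_face = grid.conformal_factor[om.mesh.faces].mean(axis=1)
    area_ratio = float((lam_face * area2).sum() / om.mesh.area)
    return {
        "n_vertices": int(len(mesh.vertices)),
        "median_angle_distortion_deg": float(np.median(distort)),
        "closedness_exact": cf.one_form_closedness(om, omega),
        "closedness_conjugate": cf.one_form_closedness(om, omega_star),
        "lambda_min": float(grid.conformal_factor.min()),
        "area_ratio": area_ratio,
    }


def geometry_oracle_metrics() -> dict:
    """Closed-form geometry checks: sphere H, cylinder radial distance, mTBM."""
    r_sphere = 10.0
    sph = trimesh.creation.icosphere(subdivisions=4, radius=r_sphere)
    H = cf.mean_curvature(sf.mesh_from_arrays(sph.vertices, sph.faces))
    sphere_err = float(np.max(np.abs(H - 1.0 / r_sphere)) * r_sphere)

    r_cyl = 3.0
    cyl = _analytic_cylinder(r=r_cyl)
    v = cyl.vertices[:, 2] / 20.0
    areas = mm.vertex_ring_areas(cyl.vertices, cyl.faces)
    core = mm.medial_core(v, cyl.vertices, areas, n_levels=20)
    rad = mm.radial_distance(cyl.vertices, v, core)
    interior = (v > 0.1) & (v < 0.9)
    radial_err = float(np.max(np.abs(rad[interior] - r_cyl)) / r_cyl)

    s = 2.0
    mtbm_identity = float(np.abs(mm.deformation_tensor_log(np.eye(2))).max())
    mtbm_scale = float(
        np.abs(
            mm.deformation_tensor_log(s * np.eye(2))
            - np.array([np.log(s), 0.0, np.log(s)])
        ).max()
    )
    return {
        "sphere_mean_curvature_rel_err": sphere_err,
        "cylinder_radial_rel_err": radial_err,
        "mtbm_identity_err": mtbm_identity,
        "mtbm_scale_err": mtbm_scale,
    }


def registration_metrics(seed: int = 0) -> dict:
    """Self-registration, synthetic-warp recovery and inverse consistency."""
    mesh, _, _ = build_tube_mesh(seed=seed + 3)
    om, grid, img = cf.conformal_parameterize(mesh, k_ring=2, resolution=(128, 64))
    raster = img.raster
    H, W = raster.shape

    # (a) self-registration: correspondence should be the identity, so the
    # downstream per-vertex mTBM norm must vanish
    field = fl.inverse_consistent_register(
        raster, raster, fl.RegistrationParams(max_iters=60)
    )
    pts, _ = fl.pull_correspondence(field, grid, om.mesh, grid, (H, W))
    J, valid = mm.tangent_jacobian(om.mesh.vertices, pts, om.mesh.faces, grid.face_uv)
    mtbm = mm.deformation_tensor_log(J[valid])
    self_mtbm_norm = float(np.linalg.norm(mtbm, axis=1).max())

    # (b) known smooth 2-pixel warp recovery
    vv, uu = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    bump = np.zeros((2, H, W))
    bump[0] = 2.0 * np.exp(-((((uu - 0.4 * W) % W) ** 2) / (2 * (W / 16) ** 2)
                             + (vv - 0.5 * H) ** 2 / (2 * (H / 8) ** 2)))
    bump[1] = -1.5 * np.exp(-((((uu - 0.7 * W) % W) ** 2) / (2 * (W / 14) ** 2)
                              + (vv - 0.6 * H) ** 2 / (2 * (H / 9) ** 2)))
    warped = fl.warp_image(raster, bump)
    disp, jac, _, _ = fl.fluid_register_oneway(
        raster, warped, fl.RegistrationParams(max_iters=300)
    )
    warp_rms = float(np.sqrt(np.mean((disp - bump) ** 2)))

    # (c) inverse consistency on a genuine subject pair
    mesh_b, _, _ = build_tube_mesh(seed=seed + 11)
    _, _, img_b = cf.conformal_parameterize(mesh_b, k_ring=2, resolution=(128, 64))
    shift = fl.circular_u_shift(img_b.raster, raster)
    pair = fl.inverse_consistent_register(
        np.roll(img_b.raster, -shift, axis=1), raster,
        fl.RegistrationParams(max_iters=160),
    )
    return {
        "self_mtbm_norm": self_mtbm_norm,
        "warp_recovery_rms_px": warp_rms,
        "min_jacobian": float(min(jac.min(), pair.jacobian_det.min())),
        "inverse_consistency_px": pair.inverse_consistency_px,
    }


def calibration_metrics(
    seed: int = 0,
    n_reps: int = 200,
    n_perm: int = 500,
    n_per_group: int = 20,
    n_vertices: int = 16,
    n_ks_vertices: int = 200,
) -> dict:
    """Type-I error of the vertex and map tests under a Gaussian null.

    Each Monte-Carlo rep draws two groups from one multivariate normal
    (so every rejection is a false positive), runs the shared-schedule
    permutation test and the nested suprathreshold-area correction, and
    counts rejections at alpha = 0.05.  A separate larger draw compares the
    permutation p-values with the analytic Hotelling's T^2 -> F p-values
    (two-sample Kolmogorov-Smirnov).
    """
    from scipy.stats import ks_2samp

    rng = np.random.default_rng(seed)
    areas = np.ones(n_vertices)
    vertex_hits = 0  # one designated vertex per rep: independent trials
    pooled_hits = 0
    pooled_trials = 0
    map_hits = 0
    for _ in range(n_reps):
        S = rng.standard_normal((n_per_group, n_vertices, 4))
        T = rng.standard_normal((n_per_group, n_vertices, 4))
        pm = st.overall_map_significance(
            S, T, areas, n_perm=n_perm, seed=int(rng.integers(2**31))
        )
        vertex_hits += int(pm.p_uncorrected[0] <= 0.05)
        pooled_hits += int((pm.p_uncorrected <= 0.05).sum())
        pooled_trials += n_vertices
        map_hits += int(pm.overall_p <= 0.05)

    S = rng.standard_normal((n_per_group, n_ks_vertices, 4))
    T = rng.standard_normal((n_per_group, n_ks_vertices, 4))
    p_perm, obs = st.vertex_permutation_test(S, T, n_perm=n_perm, seed=seed + 1)
    p_f = np.array(
        [st.hotelling_f_pvalue(m, n_per_group, n_per_group, 4) for m in obs]
    )
    ks = ks_2samp(p_perm, p_f)
    return {
        "vertex_type1_rate": vertex_hits / n_reps,
        "vertex_trials": n_reps,
        "pooled_vertex_type1_rate": pooled_hits / pooled_trials,
        "map_type1_rate": map_hits / n_reps,
        "n_reps": n_reps,
        "ks_statistic": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
    }


def binomial_interval(p0: float, n: int, z: float = 1.96) -> tuple[float, float]:
    half = z * np.sqrt(p0 * (1 - p0) / n)
    return p0 - half, p0 + half


def _true_window_mask(result, cohort_cfg) -> np.ndarray:
    """Template vertices inside the implanted atrophy window (w >= 0.5)."""
    params = cohort_cfg.shape_params()
    atrophy = cohort_cfg.atrophy_spec()
    s_grid, gamma, _ = syn.tube_frame(params, atrophy, dose=0, noise_sd=0.0, seed=0)
    verts = np.asarray(result.template_mesh.vertices)
    d2 = ((verts[:, None, :] - gamma[None, :, :]) ** 2).sum(axis=2)
    s_vertex = s_grid[np.argmin(d2, axis=1)]
    return syn.atrophy_window(s_vertex, atrophy) >= 0.5


def power_localization_metrics(
    seed: int = 0,
    n_per_group: int = 25,
    n_perm: int = 1000,
    shrink: float = 0.15,
    output_dir: str | None = None,
) -> dict:
    """Corrected significance and localization of an implanted 15% shrink.

    Runs the full pipeline on a two-group cohort (dose 0 vs homozygote dose
    2 with the given maximal radial shrink) and reports the map-level
    corrected p, the Dice overlap between the suprathreshold region and the
    true atrophy window, and the recovered radial deficit in the window.
    """
    import tempfile

    outdir = output_dir or tempfile.mkdtemp(prefix="hippomorph_power_")
    cfg = load_config(
        {
            "output_dir": outdir,
            "seed": seed,
            "n_perm": n_perm,
            "cohort": {
                "n_per_dose": {0: n_per_group, 2: n_per_group},
                "max_radial_shrink": shrink,
            },
            "contrasts": [
                {"name": "hom_vs_non", "doses_s": [2], "doses_t": [0]}
            ],
        }
    )
    result = run_pipeline(cfg)
    pmap, _, report = result.contrast_results["hom_vs_non"]

    truth = _true_window_mask(result, cfg.cohort)
    detected = pmap.p_uncorrected <= 0.05
    detected = np.where(np.isfinite(pmap.p_uncorrected), detected, False)
    w = result.vertex_areas
    inter = float(w[truth & detected].sum())
    dice = 2.0 * inter / max(float(w[truth].sum() + w[detected].sum()), 1e-30)

    # radial deficit in the window: group means of the 4th stat component
    cohort = result.cohort
    ids0 = cohort[cohort["dose"] == 0]["subject_id"]
    ids2 = cohort[cohort["dose"] == 2]["subject_id"]
    rad0 = np.nanmean(
        [result.stats_by_subject[i][:, 3] for i in ids0 if i in result.stats_by_subject],
        axis=0,
    )
    rad2 = np.nanmean(
        [result.stats_by_subject[i][:, 3] for i in ids2 if i in result.stats_by_subject],
        axis=0,
    )
    flat = _flat_core_mask(result, cfg.cohort)
    deficit = float(1.0 - np.nanmean(rad2[flat]) / np.nanmean(rad0[flat]))
    return {
        "overall_p": pmap.overall_p,
        "suprathreshold_area_mm2": pmap.suprathreshold_area,
        "dice": float(dice),
        "recovered_shrink": deficit,
        "n_per_group": n_per_group,
        "n_excluded": result.manifest["n_excluded"],
    }


def _flat_core_mask(result, cohort_cfg) -> np.ndarray:
    """Template vertices in the flat core of the window (full shrink)."""
    params = cohort_cfg.shape_params()
    atrophy = cohort_cfg.atrophy_spec()
    s_grid, gamma, _ = syn.tube_frame(params, atrophy, dose=0, noise_sd=0.0, seed=0)
    verts = np.asarray(result.template_mesh.vertices)
    d2 = ((verts[:, None, :] - gamma[None, :, :]) ** 2).sum(axis=2)
    s_vertex = s_grid[np.argmin(d2, axis=1)]
    return syn.atrophy_window(s_vertex, atrophy) >= 0.999


def dose_cdf_metrics(
    seed: int = 0,
    n_per_group: int = 15,
    n_perm: int = 500,
    output_dir: str | None = None,
) -> dict:
    """CDF deviation from the null line for three dose contrasts.

    Three groups carry 0 / 7 / 14 % implanted shrink; the p-value CDFs of
    the three pairwise contrasts, evaluated at abscissa 0.05, quantify the
    effect-size ordering (the 14% contrast should deviate most).
    """
    import tempfile

    outdir = output_dir or tempfile.mkdtemp(prefix="hippomorph_dose_")
    cfg = load_config(
        {
            "output_dir": outdir,
            "seed": seed,
            "n_perm": n_perm,
            "cohort": {
                "n_per_dose": {0: n_per_group, 1: n_per_group, 2: n_per_group},
                "max_radial_shrink": 0.14,
                "dose_scaling": {0: 0.0, 1: 0.5, 2: 1.0},
            },
            "contrasts": [
                {"name": "shrink07_vs_0", "doses_s": [1], "doses_t": [0]},
                {"name": "shrink14_vs_0", "doses_s": [2], "doses_t": [0]},
                {"name": "shrink14_vs_07", "doses_s": [2], "doses_t": [1]},
            ],
        }
    )
    result = run_pipeline(cfg)
    out = {}
    for name, (_pm, cdf, _rep) in result.contrast_results.items():
        out[name] = {
            "cdf_at_005": cdf.value_at(0.05),
            "deviation_from_null": cdf.value_at(0.05) - 0.05,
            "overall_p": _pm.overall_p,
        }
    out["n_per_group"] = n_per_group
    return out


def run_validation(seed: int = 0, n_perm: int = 500, fast: bool = True) -> dict:
    """Run the property suites at reduced scale; returns a pass/fail report."""
    report: dict = {"seed": seed, "checks": {}}
    if n_perm < 100:
        report["warning"] = "n_perm below minimum (100); calibration checks skipped"

    conf = conformality_metrics(seed=seed + 3)
    report["checks"]["conformality"] = {
        **conf,
        "pass": conf["median_angle_distortion_deg"] < 2.0
        and conf["closedness_exact"] < 1e-8
        and conf["closedness_conjugate"] < 1e-8,
    }
    geo = geometry_oracle_metrics()
    report["checks"]["geometry"] = {
        **geo,
        "pass": geo["sphere_mean_curvature_rel_err"] < 0.05
        and geo["cylinder_radial_rel_err"] < 0.02,
    }
    reg = registration_metrics(seed=seed)
    report["checks"]["registration"] = {
        **reg,
        "pass": reg["self_mtbm_norm"] < 1e-3
        and reg["warp_recovery_rms_px"] < 0.5
        and reg["min_jacobian"] > 0
        and reg["inverse_consistency_px"] < 0.5,
    }
    if n_perm >= 100:
        cal = calibration_metrics(
            seed=seed, n_reps=60 if fast else 200, n_perm=n_perm
        )
        lo_v, hi_v = binomial_interval(0.05, cal["vertex_trials"])
        lo_m, hi_m = binomial_interval(0.05, cal["n_reps"])
        report["checks"]["calibration"] = {
            **cal,
            "pass": lo_v <= cal["vertex_type1_rate"] <= hi_v
            and lo_m <= cal["map_type1_rate"] <= hi_m
            and cal["ks_pvalue"] > 0.01,
        }
    report["pass"] = all(c["pass"] for c in report["checks"].values())
    return report
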