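"""End-to-end orchestration: masks -> QC -> conformal maps -> registration ->
morphometry -> group contrasts, with per-stage caching and a run manifest.

A single declarative config (YAML or dict) drives one cohort analysis; a
fixed seed makes the whole run bit-reproducible.  Stages write their outputs
under the configured directory (``masks/ meshes/ grids/ fields/ stats/
contrasts/ manifest.json``) and record a hash of their inputs, so an
unchanged rerun skips straight to the cached results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import conformal as cf
from . import fluid as fl
from . import morphometry as mm
from . import stats as st
from . import synthetic as syn
from . import surfaces as sf

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_config"]


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class CohortConfig:
    n_per_dose: dict = field(default_factory=lambda: {0: 10, 2: 10})
    noise_sd: float = 0.25
    length: float = 36.0
    max_radius: float = 6.0
    bend_curvature: float = 1.0 / 45.0
    voxel_size: float = 1.0
    grid_shape: tuple = (64, 64, 64)
    atrophy_center_s: float = 0.5
    atrophy_extent_s: float = 0.4
    max_radial_shrink: float = 0.15
    dose_scaling: dict = field(default_factory=lambda: {0: 0.0, 1: 0.5, 2: 1.0})

    def shape_params(self) -> syn.ShapeParams:
        return syn.ShapeParams(
            length=self.length,
            max_radius=self.max_radius,
            bend_curvature=self.bend_curvature,
            voxel_size=self.voxel_size,
            grid_shape=tuple(self.grid_shape),
        )

    def atrophy_spec(self) -> syn.AtrophySpec:
        return syn.AtrophySpec(
            center_s=self.atrophy_center_s,
            extent_s=self.atrophy_extent_s,
            max_radial_shrink=self.max_radial_shrink,
            dose_scaling={int(k): float(v) for k, v in self.dose_scaling.items()},
        )


@dataclass(frozen=True)
class SurfaceConfig:
    n_smooth_iters: int = 10
    target_vertex_count: int | None = None
    presmooth_sigma: float = 1.0


@dataclass(frozen=True)
class ConformalConfig:
    k_ring: int = 2
    raster_width: int = 128
    raster_height: int = 64


@dataclass(frozen=True)
class RegistrationConfig:
    mu_visc: float = 1.0
    lambda_visc: float = 0.0
    max_iters: int = 160
    consistency_weight: float = 2.0
    regrid_jac_threshold: float = 0.5
    n_outer: int = 3

    def params(self) -> fl.RegistrationParams:
        return fl.RegistrationParams(
            mu_visc=self.mu_visc,
            lambda_visc=self.lambda_visc,
            max_iters=self.max_iters,
            consistency_weight=self.consistency_weight,
            regrid_jac_threshold=self.regrid_jac_threshold,
        )


@dataclass(frozen=True)
class ContrastConfig:
    name: str
    doses_s: tuple
    doses_t: tuple


@dataclass(frozen=True)
class PipelineConfig:
    output_dir: str = "hippomorph_run"
    seed: int = 0
    n_perm: int = 1000
    p_threshold: float = 0.05
    n_core_levels: int = 30
    template: str = "auto"  # subject id, or "auto" = first passing dose-0 id
    cohort: CohortConfig = field(default_factory=CohortConfig)
    surface: SurfaceConfig = field(default_factory=SurfaceConfig)
    conformal: ConformalConfig = field(default_factory=ConformalConfig)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    contrasts: tuple = (ContrastConfig("carriers_vs_noncarriers", (1, 2), (0,)),)


_BLOCKS = {
    "cohort": CohortConfig,
    "surface": SurfaceConfig,
    "conformal": ConformalConfig,
    "registration": RegistrationConfig,
}


def load_config(source: str | Path | dict) -> PipelineConfig:
    """Build a PipelineConfig from YAML (path or text) or a dict.

    Unknown keys anywhere in the document are rejected before any
    computation runs.
    """
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        data = yaml.safe_load(Path(source).read_text())
    elif isinstance(source, str):
        data = yaml.safe_load(source)
    else:
        data = dict(source)
    if data is None:
        data = {}

    top_fields = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - top_fields
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if key in _BLOCKS:
            cls = _BLOCKS[key]
            block_fields = {f.name for f in dataclasses.fields(cls)}
            bad = set(value) - block_fields
            if bad:
                raise ValueError(f"unknown keys in '{key}' block: {sorted(bad)}")
            if key == "cohort" and "n_per_dose" in value:
                value = dict(value)
                value["n_per_dose"] = {
                    int(k): int(v) for k, v in value["n_per_dose"].items()
                }
            kwargs[key] = cls(**value)
        elif key == "contrasts":
            kwargs[key] = tuple(
                ContrastConfig(
                    name=c["name"],
                    doses_s=tuple(c["doses_s"]),
                    doses_t=tuple(c["doses_t"]),
                )
                for c in value
            )
        else:
            kwargs[key] = value
    return PipelineConfig(**kwargs)


# ---------------------------------------------------------------------------
# results and manifest


@dataclass
class PipelineResult:
    manifest: dict
    cohort: pd.DataFrame
    template_id: str
    stats_by_subject: dict
    contrast_results: dict  # name -> (PMap, CdfCurve, report)
    vertex_areas: np.ndarray
    template_grid: cf.ConformalGrid
    template_mesh: "object"


def _hash_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _config_dict(cfg) -> dict:
    return json.loads(json.dumps(dataclasses.asdict(cfg), default=str))


class _StageCache:
    """Skips a stage when its recorded input hash matches."""

    def __init__(self, root: Path):
        self.root = root
        self.root.mkdir(parents=True, exist_ok=True)

    def fresh(self, stage: str, input_hash: str) -> bool:
        meta = self.root / stage / "stage.json"
        if not meta.exists():
            return False
        try:
            return json.loads(meta.read_text()).get("input_hash") == input_hash
        except json.JSONDecodeError:
            return False

    def mark(self, stage: str, input_hash: str) -> None:
        d = self.root / stage
        d.mkdir(parents=True, exist_ok=True)
        (d / "stage.json").write_text(json.dumps({"input_hash": input_hash}))


# ---------------------------------------------------------------------------
# the pipeline


def run_pipeline(
    config: PipelineConfig | dict | str | Path, stop_after: str | None = None
) -> PipelineResult:
    """Execute the morphometry pipeline described by ``config``.

    Subjects failing topology QC are excluded (with the reason recorded in
    the manifest) and the contrasts run on the remainder; any contrast
    failure raises after the manifest is written.  ``stop_after`` truncates
    the run after a named stage ("simulate", "qc", "morphometry").
    """
    if not isinstance(config, PipelineConfig):
        config = load_config(config)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cache = _StageCache(out)
    manifest: dict = {
        "config": _config_dict(config),
        "stages": {},
        "subjects": {},
        "version": 1,
    }

    # -- stage 1: synthetic cohort ------------------------------------------
    shape = config.cohort.shape_params()
    atrophy = config.cohort.atrophy_spec()
    sim_hash = _hash_obj([_config_dict(config.cohort), config.seed])
    masks_dir = out / "masks"
    if cache.fresh("masks", sim_hash):
        cohort = pd.read_csv(masks_dir / "cohort.csv")
        volumes = None  # regenerated lazily below if meshes are stale
        manifest["stages"]["simulate"] = {"cached": True}
    else:
        cohort, volumes = syn.make_cohort(
            config.cohort.n_per_dose,
            shape,
            atrophy,
            noise_sd=config.cohort.noise_sd,
            seed=config.seed,
            out_dir=masks_dir,
        )
        cache.mark("masks", sim_hash)
        manifest["stages"]["simulate"] = {"cached": False}

    if stop_after == "simulate":
        _write_manifest(out, manifest)
        return _partial_result(manifest, cohort)

    # -- stage 2: surfaces + QC ---------------------------------------------
    surf_hash = _hash_obj([sim_hash, _config_dict(config.surface)])
    meshes_dir = out / "meshes"
    meshes: dict = {}
    excluded: dict = {}
    if cache.fresh("meshes", surf_hash):
        import trimesh

        qc = json.loads((meshes_dir / "qc.json").read_text())
        for sid, entry in qc.items():
            if entry["passed"]:
                m = trimesh.load(meshes_dir / f"{sid}.ply", process=False)
                meshes[sid] = sf.mesh_from_arrays(m.vertices, m.faces)
            else:
                excluded[sid] = entry["reason"]
        manifest["stages"]["surfaces"] = {"cached": True}
    else:
        if volumes is None:
            cohort, volumes = syn.make_cohort(
                config.cohort.n_per_dose,
                shape,
                atrophy,
                noise_sd=config.cohort.noise_sd,
                seed=config.seed,
            )
        meshes_dir.mkdir(parents=True, exist_ok=True)
        qc = {}
        for sid in cohort["subject_id"]:
            try:
                mesh = sf.extract_surface(
                    volumes[sid],
                    voxel_size=shape.voxel_size,
                    presmooth_sigma=config.surface.presmooth_sigma,
                )
                report = sf.check_topology(mesh)
                if not report.passed:
                    excluded[sid] = report.reason or "topology QC failed"
                    qc[sid] = {"passed": False, "reason": excluded[sid]}
                    continue
                mesh = sf.refine_and_smooth(
                    mesh,
                    n_smooth_iters=config.surface.n_smooth_iters,
                    target_vertex_count=config.surface.target_vertex_count,
                )
                meshes[sid] = mesh
                mesh.export(meshes_dir / f"{sid}.ply")
                qc[sid] = {"passed": True, "reason": ""}
            except ValueError as exc:
                excluded[sid] = str(exc)
                qc[sid] = {"passed": False, "reason": str(exc)}
        (meshes_dir / "qc.json").write_text(json.dumps(qc, indent=2, sort_keys=True))
        cache.mark("meshes", surf_hash)
        manifest["stages"]["surfaces"] = {"cached": False}

    for sid in cohort["subject_id"]:
        manifest["subjects"][sid] = (
            {"status": "pass"}
            if sid in meshes
            else {"status": "excluded", "reason": excluded.get(sid, "unknown")}
        )
    if not meshes:
        _write_manifest(out, manifest)
        raise RuntimeError("no subject passed topology QC")

    # -- template selection --------------------------------------------------
    if config.template == "auto":
        candidates = sorted(
            cohort[cohort["dose"] == cohort["dose"].min()]["subject_id"]
        )
        template_id = next((s for s in candidates if s in meshes), None)
        if template_id is None:
            template_id = sorted(meshes)[0]
    else:
        template_id = config.template
        if template_id not in meshes:
            _write_manifest(out, manifest)
            raise RuntimeError(f"template subject {template_id!r} not available")
    manifest["template"] = template_id
    if stop_after == "qc":
        _write_manifest(out, manifest)
        return _partial_result(manifest, cohort, template_id)

    # -- stages 3-5: conformal maps, registration, morphometry ---------------
    stats_hash = _hash_obj(
        [
            surf_hash,
            _config_dict(config.conformal),
            _config_dict(config.registration),
            config.n_core_levels,
            template_id,
        ]
    )
    stats_dir = out / "stats"
    if cache.fresh("stats", stats_hash):
        stats_by_subject = {}
        for f in sorted(stats_dir.glob("sub-*.csv")):
            df = pd.read_csv(f, float_precision="round_trip")
            arr = df[["mtbm1", "mtbm2", "mtbm3", "radial"]].to_numpy(float)
            stats_by_subject[f.stem] = arr
        excl_file = stats_dir / "exclusions.json"
        if excl_file.exists():
            for sid, reason in json.loads(excl_file.read_text()).items():
                excluded[sid] = reason
                manifest["subjects"][sid] = {"status": "excluded", "reason": reason}
        # the template's conformal objects are cheap to rebuild and fully
        # determined by the cached template mesh
        t_open, t_grid, _timg = _parameterize_with_retry(
            meshes[template_id], config
        )
        for stage in ("parameterize", "register", "morphometry"):
            manifest["stages"][stage] = {"cached": True}
        return _finish(
            out, cache, config, manifest, cohort, template_id,
            stats_by_subject, t_open, t_grid, excluded, stats_hash,
        )

    grids: dict = {}
    opens: dict = {}
    images: dict = {}
    conformal_excluded: dict = {}
    for sid, mesh in meshes.items():
        try:
            om, grid, img = _parameterize_with_retry(mesh, config)
            opens[sid], grids[sid], images[sid] = om, grid, img
        except ValueError as exc:
            conformal_excluded[sid] = f"conformal failure: {exc}"
            excluded[sid] = conformal_excluded[sid]
            manifest["subjects"][sid] = {"status": "excluded", "reason": excluded[sid]}
    for sid in excluded:
        meshes.pop(sid, None)
    if template_id not in grids:
        _write_manifest(out, manifest)
        raise RuntimeError("template failed conformal parameterization")
    manifest["stages"]["parameterize"] = {"cached": False, "n": len(grids)}
    grids_dir = out / "grids"
    grids_dir.mkdir(exist_ok=True)
    for sid, grid in grids.items():
        _write_grid_summary(grids_dir / f"{sid}.json", grid)

    # -- stage 4: registration to template + correspondence ------------------
    t_img = images[template_id].raster
    t_grid = grids[template_id]
    t_open = opens[template_id]
    H, W = t_img.shape
    reg_params = config.registration.params()
    fields_dir = out / "fields"
    fields_dir.mkdir(exist_ok=True)
    resampled: dict = {}
    reg_log_rows = []
    for sid in sorted(grids):
        s_img = images[sid].raster
        shift = fl.circular_u_shift(s_img, t_img)
        moving = np.roll(s_img, -shift, axis=1)
        field = fl.inverse_consistent_register(
            moving, t_img, reg_params, n_outer=config.registration.n_outer
        )
        field.forward_disp[0] += shift  # undo the gauge pre-roll
        pts, n_clamped = fl.pull_correspondence(
            field, grids[sid], opens[sid].mesh, t_grid, (H, W)
        )
        resampled[sid] = pts
        reg_log_rows.append(
            {
                "subject_id": sid,
                "final_ssd": field.final_ssd,
                "min_jacobian": float(field.jacobian_det.min()),
                "inverse_consistency_px": field.inverse_consistency_px,
                "converged": bool(field.converged),
                "n_clamped": n_clamped,
                "u_shift": shift,
            }
        )
        np.save(fields_dir / f"{sid}_forward.npy", field.forward_disp.astype(np.float32))
    pd.DataFrame(reg_log_rows).to_csv(fields_dir / "registration_log.csv", index=False)
    manifest["stages"]["register"] = {"cached": False, "n": len(resampled)}

    # -- stage 5: morphometry -------------------------------------------------
    stats_dir.mkdir(exist_ok=True)
    t_verts = t_open.mesh.vertices
    t_faces = t_open.mesh.faces
    t_v = t_grid.uv[:, 1]
    stats_by_subject: dict = {}
    for sid, pts in resampled.items():
        vs = mm.subject_vertex_stats(
            t_verts, pts, t_faces, t_grid.face_uv, t_v,
            n_core_levels=config.n_core_levels,
        )
        stats_by_subject[sid] = vs.combined
        # %.17g round-trips float64 exactly, so cached reruns see
        # bit-identical statistics
        vs.to_frame().to_csv(stats_dir / f"{sid}.csv", index=False, float_format="%.17g")
    manifest["stages"]["morphometry"] = {"cached": False, "n": len(stats_by_subject)}
    (stats_dir / "exclusions.json").write_text(
        json.dumps(conformal_excluded, indent=2, sort_keys=True)
    )
    cache.mark("stats", stats_hash)
    if stop_after == "morphometry":
        _write_manifest(out, manifest)
        result = _partial_result(manifest, cohort, template_id)
        result.stats_by_subject = stats_by_subject
        result.template_grid = t_grid
        result.template_mesh = t_open.mesh
        result.vertex_areas = mm.vertex_ring_areas(t_verts, t_faces)
        return result
    return _finish(
        out, cache, config, manifest, cohort, template_id,
        stats_by_subject, t_open, t_grid, excluded, stats_hash,
    )


def _finish(
    out, cache, config, manifest, cohort, template_id,
    stats_by_subject, t_open, t_grid, excluded, stats_hash,
) -> PipelineResult:
    """Stage 6 (contrasts) plus manifest writing, with its own cache."""
    t_verts = t_open.mesh.vertices
    t_faces = t_open.mesh.faces
    vertex_areas = mm.vertex_ring_areas(t_verts, t_faces)
    contrasts_dir = out / "contrasts"
    contrasts_dir.mkdir(exist_ok=True)
    con_hash = _hash_obj(
        [
            stats_hash,
            [dataclasses.asdict(c) for c in config.contrasts],
            config.n_perm,
            config.seed,
            config.p_threshold,
        ]
    )
    contrast_results: dict = {}
    failures: list = []
    cached_contrasts = cache.fresh("contrasts", con_hash)
    for con in config.contrasts:
        try:
            if cached_contrasts:
                pmap, cdf, report = _load_contrast(contrasts_dir, con.name, config)
            else:
                pmap, cdf, report = st.run_group_contrast(
                    cohort[cohort["subject_id"].isin(stats_by_subject)],
                    stats_by_subject,
                    con.doses_s,
                    con.doses_t,
                    vertex_areas,
                    n_perm=config.n_perm,
                    seed=config.seed,
                    p_threshold=config.p_threshold,
                )
                pd.DataFrame(
                    {"vertex_id": np.arange(len(pmap.p_uncorrected)),
                     "m_value": pmap.m_value,
                     "p_uncorrected": pmap.p_uncorrected}
                ).to_csv(contrasts_dir / f"{con.name}_pmap.csv", index=False)
                cdf.to_frame().to_csv(contrasts_dir / f"{con.name}_cdf.csv", index=False)
                (contrasts_dir / f"{con.name}_summary.json").write_text(
                    json.dumps(report, indent=2, sort_keys=True)
                )
            contrast_results[con.name] = (pmap, cdf, report)
        except (ValueError, FileNotFoundError) as exc:
            failures.append(f"{con.name}: {exc}")
    if not cached_contrasts and not failures:
        cache.mark("contrasts", con_hash)
    manifest["stages"]["contrast"] = {
        "cached": bool(cached_contrasts),
        "completed": sorted(contrast_results),
        "failed": failures,
    }
    manifest["n_excluded"] = len(excluded)
    _write_manifest(out, manifest)
    if failures:
        raise RuntimeError("contrast failures: " + "; ".join(failures))
    return PipelineResult(
        manifest=manifest,
        cohort=cohort,
        template_id=template_id,
        stats_by_subject=stats_by_subject,
        contrast_results=contrast_results,
        vertex_areas=vertex_areas,
        template_grid=t_grid,
        template_mesh=t_open.mesh,
    )


def _load_contrast(contrasts_dir: Path, name: str, config: PipelineConfig):
    pdf = pd.read_csv(contrasts_dir / f"{name}_pmap.csv")
    report = json.loads((contrasts_dir / f"{name}_summary.json").read_text())
    cdf_df = pd.read_csv(contrasts_dir / f"{name}_cdf.csv")
    pmap = st.PMap(
        m_value=pdf["m_value"].to_numpy(float),
        p_uncorrected=pdf["p_uncorrected"].to_numpy(float),
        suprathreshold_area=float(report["suprathreshold_area"]),
        overall_p=float(report["overall_p"]),
        n_permutations=int(report["n_perm"]),
        seed=int(report["seed"]),
        p_threshold=config.p_threshold,
    )
    cdf = st.CdfCurve(
        p_sorted=cdf_df["p"].to_numpy(float),
        cum_fraction=cdf_df["cdf"].to_numpy(float),
    )
    return pmap, cdf, report


def _partial_result(manifest, cohort, template_id: str = "") -> PipelineResult:
    return PipelineResult(
        manifest=manifest,
        cohort=cohort,
        template_id=template_id,
        stats_by_subject={},
        contrast_results={},
        vertex_areas=np.zeros(0),
        template_grid=None,
        template_mesh=None,
    )


def _parameterize_with_retry(mesh, config: PipelineConfig):
    res = (config.conformal.raster_width, config.conformal.raster_height)
    return cf.conformal_parameterize(mesh, k_ring=config.conformal.k_ring, resolution=res)


def _write_grid_summary(path: Path, grid: cf.ConformalGrid) -> None:
    path.write_text(
        json.dumps(
            {
                "period_u": grid.period_u,
                "n_vertices": int(len(grid.uv)),
                "lambda_min": float(grid.conformal_factor.min()),
                "lambda_max": float(grid.conformal_factor.max()),
            },
            indent=2,
            sort_keys=True,
        )
    )


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
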