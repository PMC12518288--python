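"""End-to-end orchestration: preprocess -> scale -> spheres -> SR+ICP -> traits."""

from __future__ import annotations

import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import PointCloud, read_ply, write_ply
from .preprocess import PreprocessConfig, color_filter, crop_box, remove_outliers
from .registration import (
    RegistrationResult,
    SphereCenterSet,
    cloud_to_cloud_distance,
    register_all,
)
from .scale import (
    ViewScaleRecord,
    apply_scale,
    compute_scale_factors,
    find_rim_z,
    fit_circle_robust,
    metric_scale_factor,
    select_by_color,
    slice_ring,
)
from .spheres import ColorSpec, RansacConfig, estimate_all_centers
from .synth import default_sphere_specs
from .traits import TraitReport, extract_traits

__all__ = ["ScaleConfig", "IcpConfig", "PipelineConfig", "PipelineResult", "run_pipeline", "stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed fan-out from the single global seed."""
    return (int(global_seed) * 0x9E3779B1 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class ScaleConfig:
    reference_view: int = 2
    known_pot_diameter_cm: float | None = None
    slice_halfwidth_cm: float = 0.25
    pot_rgb_reference: tuple[int, int, int] = (170, 90, 60)
    pot_color_cap: float = 60.0


@dataclass
class IcpConfig:
    max_iter: int = 100
    rmse_tol: float = 1e-8
    max_corr_dist: float | None = None
    accumulate_target: bool = True
    dedup_voxel: float | None = None


@dataclass
class PipelineConfig:
    view_paths: list[str] = field(default_factory=list)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    scale: ScaleConfig = field(default_factory=ScaleConfig)
    ransac: RansacConfig = field(default_factory=RansacConfig)
    sphere_specs: list[ColorSpec] = field(default_factory=default_sphere_specs)
    icp: IcpConfig = field(default_factory=IcpConfig)
    leaf_labels: list[int] = field(default_factory=list)
    out_dir: str | None = None
    seed: int = 0
    skip_outlier_removal: bool = False


@dataclass
class PipelineResult:
    merged: PointCloud
    registration: RegistrationResult
    scale_records: list[ViewScaleRecord]
    sphere_centers: list[SphereCenterSet]
    traits: TraitReport | None
    report: dict


def _validate(config: PipelineConfig, views: list[PointCloud] | None) -> None:
    if views is None:
        if len(config.view_paths) != 6:
            raise ValueError(
                f"full registration needs exactly 6 views, got {len(config.view_paths)}"
            )
        missing = [p for p in config.view_paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing view files: {missing}")
    elif len(views) != 6:
        raise ValueError(f"full registration needs exactly 6 views, got {len(views)}")
    if not config.sphere_specs:
        raise ValueError("sphere_specs must be non-empty")


def run_pipeline(
    config: PipelineConfig, views: list[PointCloud] | None = None
) -> PipelineResult:
    """Run the full workflow; ``views`` may be passed in-memory (else read
    from ``config.view_paths``).  Deterministic for a fixed ``config.seed``."""
    _validate(config, views)
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    if views is None:
        views = [read_ply(p) for p in config.view_paths]
    timings["load"] = time.perf_counter() - t0

    # --- preprocess ---------------------------------------------------
    t0 = time.perf_counter()
    cleaned = []
    for k, v in enumerate(views):
        c = color_filter(v, config.preprocess)
        c = crop_box(c, config.preprocess)
        if not config.skip_outlier_removal and len(c) > config.preprocess.outlier_k:
            c = remove_outliers(c, config.preprocess)
        if len(c) == 0:
            raise ValueError(f"preprocess stage: view {k} is empty after filtering")
        cleaned.append(c)
    timings["preprocess"] = time.perf_counter() - t0

    # --- scale calibration -------------------------------------------
    t0 = time.perf_counter()
    gammas = []
    ring_centers = []
    for k, c in enumerate(cleaned):
        try:
            pot = select_by_color(
                c, config.scale.pot_rgb_reference, config.scale.pot_color_cap
            )
            z = find_rim_z(
                c,
                config.scale.pot_rgb_reference,
                config.scale.pot_color_cap,
                config.scale.slice_halfwidth_cm,
            )
            ring = slice_ring(pot, z, config.scale.slice_halfwidth_cm)
            center, gamma = fit_circle_robust(ring.points[:, :2])
        except ValueError as exc:
            raise ValueError(f"scale stage, view {k}: {exc}") from exc
        gammas.append(gamma)
        ring_centers.append(center)
    factors = compute_scale_factors(gammas, config.scale.reference_view)
    metric = 1.0
    if config.scale.known_pot_diameter_cm is not None:
        metric = metric_scale_factor(
            gammas[config.scale.reference_view],
            config.scale.known_pot_diameter_cm / 2.0,
        )
    records = []
    scaled = []
    for k, (c, gamma, f) in enumerate(zip(cleaned, gammas, factors)):
        total = f * metric
        scaled.append(apply_scale(c, total))
        records.append(
            ViewScaleRecord(
                view_index=k,
                gamma=gamma,
                scale_factor=total,
                ring_center=ring_centers[k],
                mu=gamma / gammas[config.scale.reference_view],
            )
        )
    timings["scale"] = time.perf_counter() - t0

    # --- sphere fitting ----------------------------------------------
    t0 = time.perf_counter()
    center_sets = []
    sphere_weights = []
    for k, c in enumerate(scaled):
        cfg = RansacConfig(**{
            **config.ransac.__dict__,
            "rng_seed": stage_seed(config.seed, f"spheres/view{k}"),
        })
        try:
            models = estimate_all_centers(c, config.sphere_specs, cfg)
        except Exception as exc:
            raise RuntimeError(f"sphere stage, view {k}: {exc}") from exc
        center_sets.append(SphereCenterSet.from_models(k, models))
        sphere_weights.append({int(l): float(m.weight) for l, m in models.items()})
    timings["spheres"] = time.perf_counter() - t0

    # --- registration -------------------------------------------------
    t0 = time.perf_counter()
    reg = register_all(
        scaled,
        center_sets,
        max_iter=config.icp.max_iter,
        rmse_tol=config.icp.rmse_tol,
        max_corr_dist=config.icp.max_corr_dist,
        accumulate_target=config.icp.accumulate_target,
        dedup_voxel=config.icp.dedup_voxel,
    )
    timings["registration"] = time.perf_counter() - t0

    # --- traits -------------------------------------------------------
    traits = None
    rim_z = None
    if reg.merged.labels is not None:
        t0 = time.perf_counter()
        try:
            rim_z = find_rim_z(
                reg.merged,
                config.scale.pot_rgb_reference,
                config.scale.pot_color_cap,
                config.scale.slice_halfwidth_cm,
            ) + config.scale.slice_halfwidth_cm
        except ValueError:
            rim_z = float(reg.merged.points[:, 2].min())
        from .synth import STEM_LABEL

        plant = reg.merged.select(reg.merged.labels >= STEM_LABEL)
        if len(plant) >= 3:
            try:
                traits = extract_traits(plant, config.leaf_labels, rim_z)
            except ValueError:
                traits = extract_traits(plant, [], rim_z)
        timings["traits"] = time.perf_counter() - t0

    report = {
        "seed": config.seed,
        "timings_s": {k: round(v, 4) for k, v in timings.items()},
        "gammas": [float(g) for g in gammas],
        "scale_factors": [float(r.scale_factor) for r in records],
        "mu_ratios": [float(r.mu) for r in records],
        "sphere_weights": sphere_weights,
        "per_view_rmse": [float(r) for r in reg.per_view_rmse],
        "per_view_overlap": [float(o) for o in reg.per_view_overlap],
        "rim_z": rim_z,
        "n_points_merged": len(reg.merged),
    }

    result = PipelineResult(reg.merged, reg, records, center_sets, traits, report)
    if config.out_dir:
        _write_outputs(config, result)
    return result


def _write_outputs(config: PipelineConfig, result: PipelineResult) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_ply(result.merged, out / "merged.ply")
    for k, t in enumerate(result.registration.refined):
        np.savetxt(
            out / f"transform_view{k}.txt", t.as_matrix(),
            header=f"view {k} -> view 0, row-major 4x4",
        )
    with open(out / "report.json", "w") as fh:
        json.dump(result.report, fh, indent=2)
    if result.traits is not None:
        (out / "traits.tsv").write_text(result.traits.to_tsv())


def evaluate_against_reference(
    merged: PointCloud, reference: PointCloud
) -> dict[str, float]:
    mean, std = cloud_to_cloud_distance(merged, reference)
    return {"mean_cm": mean, "std_cm": std}
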