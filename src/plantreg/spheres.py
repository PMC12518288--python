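"""Calibration-sphere localization by enhanced RANSAC.

The fitter improves on plain RANSAC with three ingredients that matter on
partial (hemispheric), noisy, outlier-ridden marker scans:

* a dynamic inlier threshold scaled by the ratio of local to global point
  spacing (clamped), so sparse regions are not starved of inliers;
* a weighted score w = (inlier fraction) / (mu + sigma + eps) over inlier
  surface residuals, rewarding tight shells rather than raw counts;
* geometric constraints over the top-K candidates (radius window around the
  nominal marker radius, center inside the dilated data bounding box),
  followed by Levenberg-Marquardt refinement on the surviving best model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

from .core import PointCloud, SphereModel

__all__ = [
    "RansacConfig",
    "ColorSpec",
    "DegenerateSampleError",
    "ConstraintError",
    "segment_spheres_by_color",
    "sphere_from_4_points",
    "dynamic_threshold",
    "score_candidate",
    "fit_sphere_ransac",
    "estimate_all_centers",
]

_EPS = 1e-12
_WEIGHT_CAP = 1.0 / _EPS


class DegenerateSampleError(ValueError):
    """Raised when four sampled points are (nearly) coplanar."""


class ConstraintError(RuntimeError):
    """No candidate model survived the geometric constraints."""


@dataclass
class RansacConfig:
    max_iterations: int = 1000
    base_threshold: float = 0.1          # cm
    top_k: int = 5
    density_k: int = 10
    threshold_clamp: tuple[float, float] = (0.5, 2.0)
    nominal_radius: float | None = None  # cm; enables the radius constraint
    radius_tolerance: float = 0.2        # fractional window around nominal
    rng_seed: int = 0
    second_lm_pass: bool = False

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.base_threshold <= 0:
            raise ValueError("base_threshold must be positive")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        lo, hi = self.threshold_clamp
        if not (lo <= 1.0 <= hi):
            raise ValueError("threshold_clamp must bracket 1")


@dataclass
class ColorSpec:
    """Reference color of one marker sphere."""

    label: int
    rgb_reference: tuple[int, int, int]
    max_distance: float = 60.0  # RGB Euclidean matching cap

    def __post_init__(self) -> None:
        self.rgb_reference = tuple(int(v) for v in self.rgb_reference)


def segment_spheres_by_color(
    cloud: PointCloud, specs: list[ColorSpec]
) -> list[PointCloud]:
    """Partition points among specs by nearest reference color within a cap.

    Returns one (possibly empty) sub-cloud per spec, disjoint by
    construction; points matching no spec are dropped.
    """
    if not specs:
        raise ValueError("specs must be non-empty")
    if len(cloud) == 0:
        return [cloud.select(np.zeros(0, dtype=bool)) for _ in specs]
    refs = np.array([s.rgb_reference for s in specs], dtype=np.float64)
    caps = np.array([s.max_distance for s in specs])
    d = np.linalg.norm(cloud.colors[:, None, :] - refs[None, :, :], axis=2)
    nearest = d.argmin(axis=1)
    within = d[np.arange(len(cloud)), nearest] <= caps[nearest]
    return [cloud.select(within & (nearest == i)) for i in range(len(specs))]


def sphere_from_4_points(p1, p2, p3, p4) -> tuple[np.ndarray, float]:
    """Unique sphere through four non-coplanar points.

    Solves the linear system arising from equating squared distances to the
    center.  Raises DegenerateSampleError when the tetrahedron volume is
    below 1e-9 x (bounding-box diagonal)^3.
    """
    pts = np.array([p1, p2, p3, p4], dtype=np.float64)
    edges = pts[1:] - pts[0]
    diag = np.linalg.norm(pts.max(axis=0) - pts.min(axis=0))
    volume = abs(np.linalg.det(edges)) / 6.0
    if volume <= 1e-9 * max(diag, _EPS) ** 3:
        raise DegenerateSampleError("sampled points are (nearly) coplanar")
    A = 2.0 * edges
    b = (pts[1:] ** 2).sum(axis=1) - (pts[0] ** 2).sum()
    center = np.linalg.solve(A, b)
    radius = float(np.linalg.norm(pts[0] - center))
    return center, radius


def _kth_nn_distances(points: np.ndarray, k: int) -> np.ndarray:
    """Per-point distance to the k-th nearest neighbor (excluding self)."""
    k = min(k, len(points) - 1)
    if k < 1:
        return np.zeros(len(points))
    tree = cKDTree(points)
    dists, _ = tree.query(points, k=k + 1)
    return dists[:, -1]


def _density_precompute(cloud: PointCloud, config: RansacConfig) -> dict:
    kth = _kth_nn_distances(cloud.points, config.density_k)
    return {"kth": kth, "global": float(np.median(kth)) if len(kth) else 0.0}

def dynamic_threshold(
    candidate: tuple[np.ndarray, float],
    cloud: PointCloud,
    config: RansacConfig,
    _precomputed: dict | None = None,
) -> float:
    """Density-adapted inlier threshold.

    t = t_base * clamp(local_spacing / global_spacing), where spacing is the
    median distance to the density_k-th nearest neighbor; "local" restricts
    to points within 2*t_base of the candidate surface and falls back to
    the global statistic when that shell is empty.
    """
    if len(cloud) == 0:
        raise ValueError("cloud must be non-empty")
    pre = _precomputed if _precomputed is not None else _density_precompute(cloud, config)
    center, radius = candidate
    g = pre["global"]
    if g <= 0:
        return config.base_threshold
    resid = np.abs(np.linalg.norm(cloud.points - center, axis=1) - radius)
    near = resid <= 2.0 * config.base_threshold
    local = float(np.median(pre["kth"][near])) if near.any() else g
    lo, hi = config.threshold_clamp
    ratio = float(np.clip(local / g, lo, hi))
    return config.base_threshold * ratio


def score_candidate(
    candidate: tuple[np.ndarray, float],
    cloud: PointCloud,
    threshold: float,
) -> tuple[np.ndarray, float, float, float]:
    """Inlier set and weighted score of a candidate sphere.

    Returns (inlier_indices, weight, mu, sigma) with
    weight = (|inliers|/|P|) / (mu + sigma + eps) over absolute surface
    residuals, capped at 1/eps; an empty inlier set scores 0.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    center, radius = candidate
    resid = np.abs(np.linalg.norm(cloud.points - center, axis=1) - radius)
    inliers = np.flatnonzero(resid <= threshold)
    if len(inliers) == 0:
        return inliers, 0.0, 0.0, 0.0
    r_in = resid[inliers]
    mu = float(r_in.mean())
    sigma = float(r_in.std())
    weight = min((len(inliers) / len(cloud)) / (mu + sigma + _EPS), _WEIGHT_CAP)
    return inliers, weight, mu, sigma


def _lm_refine(points: np.ndarray, center: np.ndarray, radius: float):
    def resid(p):
        return np.linalg.norm(points - p[:3], axis=1) - p[3]

    out = least_squares(resid, np.concatenate([center, [radius]]), method="lm")
    return out.x[:3], float(abs(out.x[3]))


def fit_sphere_ransac(cloud: PointCloud, config: RansacConfig) -> SphereModel:
    """Full enhanced-RANSAC loop with constraint filtering and LM polish.

    Deterministic for a fixed ``config.rng_seed``.
    """
    n = len(cloud)
    if n < 4:
        raise ValueError(f"sphere fitting needs at least 4 points, got {n}")
    rng = np.random.default_rng(config.rng_seed)
    pre = _density_precompute(cloud, config)

    # top-K candidates kept as (weight, center, radius, threshold, inliers)
    top: list[tuple[float, np.ndarray, float, float, np.ndarray]] = []
    for _ in range(config.max_iterations):
        idx = rng.choice(n, size=4, replace=False)
        try:
            center, radius = sphere_from_4_points(*cloud.points[idx])
        except DegenerateSampleError:
            continue
        t = dynamic_threshold((center, radius), cloud, config, pre)
        inliers, weight, _, _ = score_candidate((center, radius), cloud, t)
        if weight <= 0:
            continue
        top.append((weight, center, radius, t, inliers))
        top.sort(key=lambda c: -c[0])
        del top[config.top_k:]

    if not top:
        raise ConstraintError("no valid sphere candidate was generated")

    # geometric constraints over the top-K, then re-rank
    lo = cloud.points.min(axis=0)
    hi = cloud.points.max(axis=0)
    survivors = []
    reasons = []
    for weight, center, radius, t, inliers in top:
        if config.nominal_radius is not None:
            r_nom = config.nominal_radius
            if abs(radius - r_nom) / r_nom > config.radius_tolerance:
                reasons.append("radius outside nominal window")
                continue
            dil = r_nom
        else:
            dil = radius
        if np.any(center < lo - dil) or np.any(center > hi + dil):
            reasons.append("center outside dilated bounding box")
            continue
        survivors.append((weight, center, radius, t, inliers))
    if not survivors:
        raise ConstraintError(
            "all top-K candidates violated geometric constraints: "
            + "; ".join(sorted(set(reasons)))
        )

    weight, center, radius, t, inliers = max(survivors, key=lambda c: c[0])
    center, radius = _lm_refine(cloud.points[inliers], center, radius)
    t = dynamic_threshold((center, radius), cloud, config, pre)
    inliers, weight, mu, sigma = score_candidate((center, radius), cloud, t)
    if config.second_lm_pass and len(inliers) >= 4:
        center, radius = _lm_refine(cloud.points[inliers], center, radius)
        t = dynamic_threshold((center, radius), cloud, config, pre)
        inliers, weight, mu, sigma = score_candidate((center, radius), cloud, t)
    return SphereModel(
        center=center,
        radius=radius,
        inlier_indices=inliers,
        weight=weight,
        residual_mean=mu,
        residual_std=sigma,
    )


def estimate_all_centers(
    cloud: PointCloud,
    specs: list[ColorSpec],
    config: RansacConfig,
) -> dict[int, SphereModel]:
    """Segment markers by color and fit each; returns label -> SphereModel.

    Raises when fewer than three spheres are usable, since rigid
    registration needs at least three correspondences.
    """
    subclouds = segment_spheres_by_color(cloud, specs)
    models: dict[int, SphereModel] = {}
    for spec, sub in zip(specs, subclouds):
        if len(sub) < 4:
            continue
        cfg = RansacConfig(**{**config.__dict__, "rng_seed": config.rng_seed + spec.label})
        try:
            models[spec.label] = fit_sphere_ransac(sub, cfg)
        except (ConstraintError, ValueError):
            continue
    if len(models) < 3:
        raise ConstraintError(
            f"only {len(models)} calibration spheres usable; registration "
            "requires at least 3"
        )
    return models
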