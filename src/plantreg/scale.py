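"""Pot-rim scale calibration.

Each SfM view is reconstructed at an arbitrary scale.  Slicing a thin
horizontal band at the pot rim and fitting a circle gives a per-view pot
radius gamma_i; rescaling every view so its fitted radius matches the
reference view's (and optionally the known metric pot radius) puts all
views on a common scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .core import PointCloud

__all__ = [
    "ViewScaleRecord",
    "slice_ring",
    "fit_circle_2d",
    "compute_scale_factors",
    "metric_scale_factor",
    "apply_scale",
    "find_rim_z",
]


@dataclass
class ViewScaleRecord:
    """Per-view pot-rim fit and the scale applied to the view.

    ``mu`` is the ratio gamma_i / gamma_ref (diagnostic); ``scale_factor``
    is the multiplier actually applied so that the post-scaling rim radius
    equals the reference radius.
    """

    view_index: int
    gamma: float
    scale_factor: float
    ring_center: np.ndarray
    mu: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")
        self.ring_center = np.asarray(self.ring_center, dtype=np.float64).reshape(2)


def slice_ring(cloud: PointCloud, z_center: float, z_halfwidth: float) -> PointCloud:
    """Keep points with |z - z_center| <= z_halfwidth (order preserved)."""
    if z_halfwidth <= 0:
        raise ValueError("z_halfwidth must be positive")
    if len(cloud) == 0:
        return cloud
    return cloud.select(np.abs(cloud.points[:, 2] - z_center) <= z_halfwidth)


def fit_circle_2d(
    points: np.ndarray, refine: bool = True
) -> tuple[np.ndarray, float]:
    """Least-squares circle through M>=3 non-collinear 2D points.

    Uses the algebraic (Kasa) fit — exact on noiseless circles — with an
    optional geometric nonlinear refinement.
    """
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 2)
    m = len(pts)
    if m < 3:
        raise ValueError(f"circle fit needs at least 3 points, got {m}")
    centered = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] <= 1e-12 * max(sv[0], 1.0):
        raise ValueError("circle fit is degenerate: points are collinear")

    A = np.column_stack([2.0 * pts, np.ones(m)])
    b = (pts**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy, c = sol
    radius = float(np.sqrt(max(c + cx * cx + cy * cy, 0.0)))
    center = np.array([cx, cy])

    if refine and m > 3:
        def resid(p):
            return np.hypot(pts[:, 0] - p[0], pts[:, 1] - p[1]) - p[2]

        out = least_squares(resid, np.array([cx, cy, radius]), method="lm")
        center = out.x[:2]
        radius = float(out.x[2])
    return center, abs(radius)


def compute_scale_factors(gammas, reference_index: int):
    """Multipliers s_i with s_i * gamma_i = gamma_ref and s_ref = 1.

    The companion diagnostic ratios mu_i = gamma_i / gamma_ref are what the
    calibration prints; the applied factor is their reciprocal so that the
    post-scaling rim radii coincide.
    """
    g = np.asarray(gammas, dtype=np.float64)
    if np.any(g <= 0):
        raise ValueError("all gammas must be positive")
    if not (0 <= reference_index < len(g)):
        raise ValueError(f"reference_index {reference_index} out of range")
    factors = g[reference_index] / g
    factors[reference_index] = 1.0
    return factors


def metric_scale_factor(fitted_radius: float, known_radius: float) -> float:
    """Multiplier taking the fitted (reference-view) radius to metric cm."""
    if fitted_radius <= 0 or known_radius <= 0:
        raise ValueError("radii must be positive")
    return known_radius / fitted_radius


def apply_scale(cloud: PointCloud, factor: float) -> PointCloud:
    """Scale all coordinates about the frame origin; colors/labels untouched."""
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    return PointCloud(cloud.points * factor, cloud.colors, cloud.labels)


def select_by_color(cloud: PointCloud, rgb_reference, cap: float) -> PointCloud:
    """Points whose RGB lies within ``cap`` (Euclidean) of a reference color."""
    ref = np.asarray(rgb_reference, dtype=np.float64)
    d = np.linalg.norm(cloud.colors - ref, axis=1)
    return cloud.select(d <= cap)


def fit_circle_robust(
    points: np.ndarray, trim_sigma: float = 3.0
) -> tuple[np.ndarray, float]:
    """Circle fit with one trimmed re-fit pass to shed stray points."""
    center, radius = fit_circle_2d(points)
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 2)
    resid = np.abs(np.hypot(*(pts - center).T) - radius)
    scale = np.sqrt(np.mean(resid**2))
    if scale > 0:
        keep = resid <= trim_sigma * scale
        if keep.sum() >= 3 and keep.sum() < len(pts):
            center, radius = fit_circle_2d(pts[keep])
    return center, radius


def find_rim_z(
    cloud: PointCloud,
    pot_rgb_reference=(170, 90, 60),
    color_cap: float = 60.0,
    halfwidth: float = 0.25,
    percentile: float = 99.5,
) -> float:
    """Locate the z of a rim slice band just below the pot's top edge.

    Pot points are selected by RGB proximity to the pot color; the rim is
    taken at a high percentile of their z (robust to stray points), and the
    returned slice center sits half a band below it so the slice stays on
    the cylindrical wall.
    """
    if len(cloud) == 0:
        raise ValueError("cannot locate rim in an empty cloud")
    ref = np.asarray(pot_rgb_reference, dtype=np.float64)
    d = np.linalg.norm(cloud.colors - ref, axis=1)
    pot = cloud.points[d <= color_cap]
    if len(pot) < 10:
        raise ValueError(
            f"too few pot-colored points ({len(pot)}) to locate the rim; "
            "check scale.pot_rgb_reference"
        )
    top = np.percentile(pot[:, 2], percentile)
    return float(top - halfwidth)
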