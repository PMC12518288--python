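"""Synthetic multi-view acquisition generator with full ground truth.

Builds a world scene — cylindrical pot, six colored marker spheres on a
ring, and a parametric plant (stem + elliptical, optionally curved leaves)
— then derives each view by rotating the world about z (emulating the
rotating camera arm), applying per-view scale drift, hemispheric
visibility culling, Gaussian surface noise, dark leaf-edge points and
uniform outliers.  Every point carries a label, and the returned ground
truth records the transforms, scales, sphere centers and trait values
needed to test every pipeline stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import PointCloud, RigidTransform
from .spheres import ColorSpec
from .traits import TraitReport

__all__ = [
    "POT_LABEL",
    "STEM_LABEL",
    "LEAF_LABEL_BASE",
    "NOISE_LABEL",
    "LeafSpec",
    "SceneConfig",
    "SceneGroundTruth",
    "default_sphere_specs",
    "generate_scene",
    "sample_sphere_surface",
    "sample_leaf",
    "write_scene_bundle",
]

POT_LABEL = 6
STEM_LABEL = 7
LEAF_LABEL_BASE = 8
NOISE_LABEL = -1

_SPHERE_RGBS = [
    (230, 40, 40),    # red
    (40, 60, 230),    # blue
    (235, 220, 40),   # yellow
    (225, 40, 225),   # magenta
    (40, 220, 225),   # cyan
    (245, 140, 30),   # orange
]
_POT_RGB = (170, 90, 60)
_STEM_RGB = (90, 130, 60)
_LEAF_RGB = (45, 160, 70)


def default_sphere_specs() -> list[ColorSpec]:
    return [ColorSpec(label=i, rgb_reference=rgb) for i, rgb in enumerate(_SPHERE_RGBS)]


@dataclass
class LeafSpec:
    """One leaf: where it attaches and its true size/shape."""

    attach_frac: float = 0.5     # fraction of plant height above the rim
    azimuth_deg: float = 0.0
    tilt_deg: float = 30.0       # elevation of the major axis above horizontal
    length: float = 8.0          # cm, major-axis extent (arc length if curved)
    width: float = 3.0           # cm, minor-axis extent
    curvature: float = 0.0       # 1/cm bend along the major axis

    def __post_init__(self) -> None:
        if self.length <= 0 or self.width <= 0:
            raise ValueError("leaf length and width must be positive")


def _default_leaves() -> list[LeafSpec]:
    return [
        LeafSpec(0.35, 20.0, 25.0, 8.0, 3.0),
        LeafSpec(0.55, 140.0, 30.0, 7.0, 2.6),
        LeafSpec(0.75, 260.0, 35.0, 6.0, 2.2),
        LeafSpec(0.90, 80.0, 40.0, 5.0, 1.8),
    ]


@dataclass
class SceneConfig:
    pot_radius: float = 8.0
    pot_rim_z: float = 8.0
    marker_ring_radius: float = 16.0
    sphere_radius: float = 2.0
    sphere_colors: list[ColorSpec] = field(default_factory=default_sphere_specs)
    plant_height: float = 20.0
    stem_radius: float = 0.4
    leaf_specs: list[LeafSpec] = field(default_factory=_default_leaves)
    n_views: int = 6
    view_step_deg: float = 60.0
    view_scales: list[float] | None = None   # None: sampled from scale_range
    scale_range: tuple[float, float] = (0.9, 1.1)
    noise_sigma: float = 0.0
    outlier_fraction: float = 0.0
    dark_edge_fraction: float = 0.0
    visibility_culling: bool = True
    points_per_cm2: float = 25.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pot_radius", "pot_rim_z", "marker_ring_radius",
                     "sphere_radius", "plant_height", "stem_radius",
                     "points_per_cm2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"SceneConfig.{name} must be positive")
        for name in ("outlier_fraction", "dark_edge_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"SceneConfig.{name} must lie in [0, 1)")
        if self.n_views < 2:
            raise ValueError("SceneConfig.n_views must be >= 2")
        if self.noise_sigma < 0:
            raise ValueError("SceneConfig.noise_sigma must be >= 0")
        if len(self.sphere_colors) != 6:
            raise ValueError("SceneConfig.sphere_colors must list 6 specs")
        if self.view_scales is not None and len(self.view_scales) != self.n_views:
            raise ValueError("SceneConfig.view_scales must match n_views")


@dataclass
class SceneGroundTruth:
    true_pairwise_transforms: list[RigidTransform]
    true_cumulative_transforms: list[RigidTransform]
    true_view_scales: list[float]
    true_sphere_centers_world: dict[int, np.ndarray]
    true_traits: TraitReport
    leaf_arc_lengths: dict[int, float]
    world_cloud: PointCloud
    pot_rim_z: float


def _rot_z(angle_deg: float) -> RigidTransform:
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    return RigidTransform(
        np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]]), np.zeros(3)
    )


def sample_sphere_surface(
    center, radius: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """n points uniformly on the sphere, each exactly ``radius`` from center."""
    if n < 0:
        raise ValueError("n must be non-negative")
    if n == 0:
        return np.empty((0, 3))
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return np.asarray(center, dtype=np.float64) + radius * v


def _sample_cylinder(radius, z0, z1, n, rng):
    theta = rng.uniform(0.0, 2.0 * math.pi, n)
    z = rng.uniform(z0, z1, n)
    pts = np.column_stack([radius * np.cos(theta), radius * np.sin(theta), z])
    normals = np.column_stack([np.cos(theta), np.sin(theta), np.zeros(n)])
    return pts, normals


def _leaf_frame(spec: LeafSpec):
    az = math.radians(spec.azimuth_deg)
    tilt = math.radians(spec.tilt_deg)
    # local x (major axis) points outward and up; local y stays horizontal
    Rz = np.array([[math.cos(az), -math.sin(az), 0.0],
                   [math.sin(az), math.cos(az), 0.0],
                   [0.0, 0.0, 1.0]])
    Ry = np.array([[math.cos(tilt), 0.0, math.sin(tilt)],
                   [0.0, 1.0, 0.0],
                   [-math.sin(tilt), 0.0, math.cos(tilt)]])
    return Rz @ Ry


def _bend(u: np.ndarray, curvature: float):
    """Map arc-length coordinate u along the bent midline; returns (x, z, slope)."""
    if curvature == 0.0:
        return u, np.zeros_like(u), np.zeros_like(u)
    x = np.sin(curvature * u) / curvature
    z = (1.0 - np.cos(curvature * u)) / curvature
    return x, z, curvature * u


def sample_leaf(
    spec: LeafSpec,
    rng: np.random.Generator,
    density: float = 25.0,
    attach_point=(0.0, 0.0, 0.0),
):
    """Sample an elliptical (optionally bent) leaf patch.

    Returns (points, normals, truth) where truth records the chord-based
    ground-truth length (distance between the two midline endpoints), the
    width, and the arc length along the bent major axis.
    """
    a, b = spec.length / 2.0, spec.width / 2.0
    area = math.pi * a * b
    n = max(int(round(area * density)), 16)
    # rejection sampling of the ellipse interior in (u, v) arc coordinates
    u = np.empty(0)
    v = np.empty(0)
    while len(u) < n:
        cu = rng.uniform(-a, a, 2 * n)
        cv = rng.uniform(-b, b, 2 * n)
        keep = (cu / a) ** 2 + (cv / b) ** 2 <= 1.0
        u = np.concatenate([u, cu[keep]])
        v = np.concatenate([v, cv[keep]])
    u, v = u[:n], v[:n]

    x, z, phi = _bend(u, spec.curvature)
    local = np.column_stack([x, v, z])
    normals_local = np.column_stack([-np.sin(phi), np.zeros(n), np.cos(phi)])

    R = _leaf_frame(spec)
    attach = np.asarray(attach_point, dtype=np.float64)
    pts = local @ R.T + attach
    normals = normals_local @ R.T

    ex, ez, _ = _bend(np.array([-a, a]), spec.curvature)
    ends_local = np.column_stack([ex, np.zeros(2), ez])
    ends = ends_local @ R.T + attach
    truth = {
        "chord_length": float(np.linalg.norm(ends[1] - ends[0])),
        "width": float(spec.width),
        "arc_length": float(spec.length),
        "endpoints": ends,
    }
    return pts, normals, truth


def _sample_leaf_edge(spec, rng, n, attach_point):
    """Dark reconstruction artifacts hugging the leaf boundary."""
    phi = rng.uniform(0.0, 2.0 * math.pi, n)
    a, b = spec.length / 2.0, spec.width / 2.0
    u = a * np.cos(phi)
    v = b * np.sin(phi)
    x, z, ang = _bend(u, spec.curvature)
    local = np.column_stack([x, v, z])
    local += rng.normal(0.0, 0.08, local.shape)
    R = _leaf_frame(spec)
    return local @ R.T + np.asarray(attach_point, dtype=np.float64)


def _build_world(config: SceneConfig, rng: np.random.Generator):
    density = config.points_per_cm2
    parts = []  # (points, normals, rgb, label, closed_surface)

    pot_area = 2.0 * math.pi * config.pot_radius * config.pot_rim_z
    pts, nrm = _sample_cylinder(
        config.pot_radius, 0.0, config.pot_rim_z,
        max(int(pot_area * density), 100), rng,
    )
    parts.append((pts, nrm, _POT_RGB, POT_LABEL, True))

    centers = {}
    sph_n = max(int(4.0 * math.pi * config.sphere_radius**2 * density), 64)
    for spec in config.sphere_colors:
        ang = math.radians(spec.label * 360.0 / 6.0)
        c = np.array([
            config.marker_ring_radius * math.cos(ang),
            config.marker_ring_radius * math.sin(ang),
            config.sphere_radius,
        ])
        centers[spec.label] = c
        pts = sample_sphere_surface(c, config.sphere_radius, sph_n, rng)
        nrm = (pts - c) / config.sphere_radius
        parts.append((pts, nrm, spec.rgb_reference, spec.label, True))

    stem_top = config.pot_rim_z + config.plant_height
    stem_area = 2.0 * math.pi * config.stem_radius * config.plant_height
    pts, nrm = _sample_cylinder(
        config.stem_radius, config.pot_rim_z, stem_top,
        max(int(stem_area * density), 64), rng,
    )
    parts.append((pts, nrm, _STEM_RGB, STEM_LABEL, True))

    leaf_truths = {}
    edge_clouds = []
    for i, leaf in enumerate(config.leaf_specs):
        label = LEAF_LABEL_BASE + i
        az = math.radians(leaf.azimuth_deg)
        attach = np.array([
            config.stem_radius * math.cos(az),
            config.stem_radius * math.sin(az),
            config.pot_rim_z + leaf.attach_frac * config.plant_height,
        ])
        pts, nrm, truth = sample_leaf(leaf, rng, density, attach)
        parts.append((pts, nrm, _LEAF_RGB, label, False))
        leaf_truths[label] = truth
        if config.dark_edge_fraction > 0:
            n_edge = int(len(pts) * config.dark_edge_fraction)
            if n_edge:
                edge_clouds.append(_sample_leaf_edge(leaf, rng, n_edge, attach))
    return parts, centers, leaf_truths, edge_clouds


def generate_scene(
    config: SceneConfig,
) -> tuple[list[PointCloud], SceneGroundTruth]:
    """Generate the per-view clouds and the full ground-truth record."""
    rng = np.random.default_rng(config.rng_seed)
    parts, centers, leaf_truths, edge_clouds = _build_world(config, rng)

    world_pts = np.vstack([p for p, *_ in parts])
    world_normals = np.vstack([n for _, n, *_ in parts])
    world_colors = np.vstack([
        np.tile(np.asarray(rgb, dtype=np.int64), (len(p), 1))
        for p, _, rgb, _, _ in parts
    ])
    world_labels = np.concatenate([
        np.full(len(p), lab, dtype=np.int64) for p, _, _, lab, _ in parts
    ])
    closed_mask = np.concatenate([
        np.full(len(p), closed, dtype=bool) for p, _, _, _, closed in parts
    ])
    world = PointCloud(world_pts, world_colors, world_labels)

    if config.view_scales is not None:
        scales = [float(s) for s in config.view_scales]
    else:
        lo, hi = config.scale_range
        scales = rng.uniform(lo, hi, config.n_views).tolist()

    step = config.view_step_deg
    cumulative = [_rot_z(k * step) for k in range(config.n_views)]
    pairwise = [_rot_z(step) for _ in range(config.n_views - 1)]

    dark_pts_world = np.vstack(edge_clouds) if edge_clouds else np.empty((0, 3))

    views = []
    for k in range(config.n_views):
        vrng = np.random.default_rng([config.rng_seed, k + 1])
        inv = cumulative[k].inverse()
        pts = inv.apply(world_pts)
        nrm = world_normals @ inv.rotation.T
        if config.visibility_culling:
            keep = (~closed_mask) | (nrm[:, 1] >= 0.0)
        else:
            keep = np.ones(len(pts), dtype=bool)
        pts = pts[keep] / scales[k]
        colors = world_colors[keep]
        labels = world_labels[keep]

        extra_pts = []
        extra_colors = []
        extra_labels = []
        if len(dark_pts_world):
            dp = inv.apply(dark_pts_world) / scales[k]
            dc = vrng.integers(8, 46, size=(len(dp), 3))
            extra_pts.append(dp)
            extra_colors.append(dc)
            extra_labels.append(np.full(len(dp), NOISE_LABEL, dtype=np.int64))
        if config.outlier_fraction > 0:
            n_out = int(len(pts) * config.outlier_fraction / (1 - config.outlier_fraction))
            if n_out:
                lo = pts.min(axis=0)
                hi = pts.max(axis=0)
                span = hi - lo
                op = vrng.uniform(lo - 0.2 * span, hi + 0.2 * span, size=(n_out, 3))
                extra_pts.append(op)
                extra_colors.append(vrng.integers(0, 256, size=(n_out, 3)))
                extra_labels.append(np.full(n_out, NOISE_LABEL, dtype=np.int64))

        if extra_pts:
            pts = np.vstack([pts, *extra_pts])
            colors = np.vstack([colors, *extra_colors])
            labels = np.concatenate([labels, *extra_labels])
        if config.noise_sigma > 0:
            pts = pts + vrng.normal(0.0, config.noise_sigma, pts.shape)
        views.append(PointCloud(pts, colors, labels))

    plant_mask = world_labels >= STEM_LABEL
    plant = world.select(plant_mask)
    from .traits import crown_width as _crown
    leaves = [
        (lab, max(t["chord_length"], t["width"]), min(t["chord_length"], t["width"]))
        for lab, t in sorted(leaf_truths.items())
    ]
    truth = SceneGroundTruth(
        true_pairwise_transforms=pairwise,
        true_cumulative_transforms=cumulative,
        true_view_scales=scales,
        true_sphere_centers_world=centers,
        true_traits=TraitReport(
            plant_height=float(plant.points[:, 2].max() - config.pot_rim_z),
            crown_width=_crown(plant),
            leaves=leaves,
            reference_plane_z=config.pot_rim_z,
        ),
        leaf_arc_lengths={lab: t["arc_length"] for lab, t in leaf_truths.items()},
        world_cloud=world,
        pot_rim_z=config.pot_rim_z,
    )
    return views, truth


def write_scene_bundle(out_dir, views, truth: SceneGroundTruth, config: SceneConfig) -> None:
    """Persist a scene as PLY views + plain-text ground truth."""
    from pathlib import Path

    import yaml

    from .core import write_ply

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for k, v in enumerate(views):
        write_ply(v, out / f"view_{k}.ply")
    write_ply(truth.world_cloud, out / "world.ply")
    for k, t in enumerate(truth.true_cumulative_transforms):
        np.savetxt(
            out / f"true_transform_view{k}.txt", t.as_matrix(),
            header=f"view {k} -> view 0, row-major 4x4",
        )
    np.savetxt(out / "true_view_scales.txt", np.asarray(truth.true_view_scales))
    with open(out / "true_spheres.tsv", "w") as fh:
        fh.write("label\tx\ty\tz\n")
        for lab, c in sorted(truth.true_sphere_centers_world.items()):
            fh.write(f"{lab}\t{c[0]:.6f}\t{c[1]:.6f}\t{c[2]:.6f}\n")
    with open(out / "true_traits.tsv", "w") as fh:
        fh.write(truth.true_traits.to_tsv())
    cfg = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in config.__dict__.items()
        if not isinstance(v, list) or k == "view_scales"
    }
    cfg["leaf_specs"] = [l.__dict__ for l in config.leaf_specs]
    cfg["sphere_colors"] = [
        {"label": s.label, "rgb_reference": list(s.rgb_reference)}
        for s in config.sphere_colors
    ]
    with open(out / "scene_config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
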