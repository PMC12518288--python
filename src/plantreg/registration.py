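"""Marker-based self-registration (SR) and ICP fine alignment.

Fitted sphere centers sharing a label between adjacent views act as
corresponding point pairs; SVD gives the pairwise rigid motions, which are
chained into each view's transform to the 0-degree reference frame and then
refined with point-to-point ICP against the accumulated model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .core import PointCloud, RigidTransform, SphereModel

__all__ = [
    "SphereCenterSet",
    "TransformChain",
    "IcpResult",
    "RegistrationResult",
    "match_centers",
    "svd_rigid_transform",
    "build_chain",
    "icp_refine",
    "register_all",
    "cloud_to_cloud_distance",
]


@dataclass
class SphereCenterSet:
    """Labeled sphere centers observed in one view."""

    view_index: int
    labels: np.ndarray
    centers: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64).reshape(-1)
        self.centers = np.asarray(self.centers, dtype=np.float64).reshape(-1, 3)
        if len(self.labels) != len(self.centers):
            raise ValueError("labels and centers must have the same length")
        if len(np.unique(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique within a view")

    @classmethod
    def from_models(
        cls, view_index: int, models: dict[int, SphereModel]
    ) -> "SphereCenterSet":
        labels = np.array(sorted(models), dtype=np.int64)
        centers = np.array([models[l].center for l in labels], dtype=np.float64)
        return cls(view_index, labels, centers)


@dataclass
class TransformChain:
    """Pairwise view-(k+1)->view-k transforms and their cumulative chain."""

    pairwise: list[RigidTransform]
    cumulative: list[RigidTransform]


@dataclass
class IcpResult:
    transform: RigidTransform
    rmse: float
    rmse_history: list[float] = field(default_factory=list)
    iterations: int = 0


@dataclass
class RegistrationResult:
    chain: TransformChain
    refined: list[RigidTransform]
    merged: PointCloud
    per_view_rmse: list[float]
    per_view_overlap: list[float]


def match_centers(
    a: SphereCenterSet, b: SphereCenterSet
) -> tuple[np.ndarray, np.ndarray]:
    """Centers sharing a label, paired in ascending label order.

    Returns (a_centers, b_centers) as (M, 3) arrays; raises when fewer than
    three labels are shared (rigid registration needs >= 3 pairs).
    """
    shared = np.intersect1d(a.labels, b.labels)
    if len(shared) < 3:
        raise ValueError(
            f"views {a.view_index} and {b.view_index} share only "
            f"{len(shared)} sphere labels; at least 3 are required"
        )
    ia = {l: i for i, l in enumerate(a.labels)}
    ib = {l: i for i, l in enumerate(b.labels)}
    pa = np.array([a.centers[ia[l]] for l in shared])
    pb = np.array([b.centers[ib[l]] for l in shared])
    return pa, pb


def svd_rigid_transform(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares rigid motion mapping src onto dst (Kabsch/SVD).

    Reflections are prevented by sign-correcting the smallest singular
    vector so det(R) = +1.
    """
    src = np.asarray(src, dtype=np.float64).reshape(-1, 3)
    dst = np.asarray(dst, dtype=np.float64).reshape(-1, 3)
    if len(src) != len(dst):
        raise ValueError("src and dst must pair up")
    if len(src) < 3:
        raise ValueError(f"rigid fit needs at least 3 pairs, got {len(src)}")
    sc = src - src.mean(axis=0)
    sv = np.linalg.svd(sc, compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1.0):
        raise ValueError("rigid fit is degenerate: source points are collinear")
    dc = dst - dst.mean(axis=0)
    H = sc.T @ dc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = dst.mean(axis=0) - R @ src.mean(axis=0)
    return RigidTransform(R, t)


def build_chain(pairwise: list[RigidTransform]) -> TransformChain:
    """Compose 5 pairwise (k+1 -> k) transforms into view->reference chains.

    cumulative[0] is the identity; cumulative[k] = pairwise[0] ∘ ... ∘
    pairwise[k-1], so e.g. view 2 maps to the reference via the product of
    the first two pairwise transforms (the later link applied first).
    """
    if len(pairwise) != 5:
        raise ValueError(f"expected exactly 5 pairwise transforms, got {len(pairwise)}")
    cumulative = [RigidTransform.identity()]
    for p in pairwise:
        cumulative.append(cumulative[-1].compose(p))
    return TransformChain(list(pairwise), cumulative)


def icp_refine(
    source: PointCloud,
    target: PointCloud,
    max_iter: int = 100,
    rmse_tol: float = 1e-8,
    max_corr_dist: float | None = None,
    absolute_tol: bool = False,
) -> IcpResult:
    """Point-to-point ICP from source onto target.

    Alternates nearest-neighbor correspondence (within ``max_corr_dist``)
    with the SVD rigid fit until the change in RMSE falls below
    ``rmse_tol`` (or, with ``absolute_tol``, the RMSE itself does) or
    ``max_iter`` is hit.  Iterations that would increase the RMSE are
    rejected and terminate the loop, so the accepted RMSE sequence is
    non-increasing.
    """
    if len(source) == 0 or len(target) == 0:
        raise ValueError("ICP requires non-empty source and target clouds")
    tree = cKDTree(target.points)
    if max_corr_dist is None:
        d, _ = tree.query(target.points, k=min(2, len(target)))
        spacing = float(np.median(d[:, -1])) if len(target) > 1 else 1.0
        max_corr_dist = max(5.0 * spacing, 1e-6)

    current = RigidTransform.identity()
    pts = source.points.copy()
    history: list[float] = []
    prev_rmse = np.inf
    iterations = 0
    for it in range(max_iter):
        iterations = it + 1
        d, j = tree.query(pts, distance_upper_bound=max_corr_dist)
        valid = np.isfinite(d)
        if not valid.any():
            raise ValueError(
                f"ICP found no correspondences within max_corr_dist={max_corr_dist:g}"
            )
        # adaptive trimming: partial-overlap views should not let their
        # non-overlapping fringe drag the fit (keep d <= 3 x median)
        med = float(np.median(d[valid]))
        trimmed = valid & (d <= 3.0 * med + 1e-12)
        if trimmed.sum() >= 3:
            valid = trimmed
        rmse = float(np.sqrt(np.mean(d[valid] ** 2)))
        if rmse > prev_rmse:
            break
        history.append(rmse)
        prev_rmse = rmse
        if absolute_tol and rmse <= rmse_tol:
            break
        if len(history) >= 2 and abs(history[-2] - history[-1]) <= rmse_tol:
            break
        if valid.sum() < 3:
            break
        try:
            step = svd_rigid_transform(pts[valid], target.points[j[valid]])
        except ValueError:
            break
        current = step.compose(current)
        pts = current.apply(source.points)
    return IcpResult(current, history[-1] if history else prev_rmse, history, iterations)


def register_all(
    views: list[PointCloud],
    centers: list[SphereCenterSet],
    max_iter: int = 100,
    rmse_tol: float = 1e-8,
    max_corr_dist: float | None = None,
    accumulate_target: bool = True,
    dedup_voxel: float | None = None,
) -> RegistrationResult:
    """SR coarse alignment + sequential ICP refinement + merge.

    For each non-reference view the coarse transform is the cumulative SR
    chain; ICP then refines it against view 0 plus the already-aligned
    views (or view 0 alone with ``accumulate_target=False``).
    """
    if len(views) != len(centers):
        raise ValueError("views and center sets must align")
    n = len(views)
    pairwise = []
    for k in range(n - 1):
        try:
            src, dst = match_centers(centers[k + 1], centers[k])
            pairwise.append(svd_rigid_transform(src, dst))
        except ValueError as exc:
            raise ValueError(f"registering view {k + 1} -> {k}: {exc}") from exc
    chain = build_chain(pairwise) if n == 6 else TransformChain(
        pairwise, _accumulate(pairwise)
    )

    reference = views[0]
    aligned = [views[0]]
    refined = [RigidTransform.identity()]
    rmses = [0.0]
    overlaps = [1.0]
    for k in range(1, n):
        coarse = chain.cumulative[k]
        moved = views[k].transformed(coarse)
        try:
            icp = icp_refine(moved, reference, max_iter, rmse_tol, max_corr_dist)
        except ValueError as exc:
            raise ValueError(f"ICP for view {k}: {exc}") from exc
        total = icp.transform.compose(coarse)
        refined.append(total)
        rmses.append(icp.rmse)
        final = views[k].transformed(total)
        overlaps.append(_overlap_fraction(final, reference))
        aligned.append(final)
        if accumulate_target:
            reference = PointCloud.concatenate([reference, final])
    merged = PointCloud.concatenate(aligned)
    if dedup_voxel:
        merged = _voxel_dedup(merged, dedup_voxel)
    return RegistrationResult(chain, refined, merged, rmses, overlaps)


def _accumulate(pairwise: list[RigidTransform]) -> list[RigidTransform]:
    cumulative = [RigidTransform.identity()]
    for p in pairwise:
        cumulative.append(cumulative[-1].compose(p))
    return cumulative


def _overlap_fraction(cloud: PointCloud, reference: PointCloud, radius: float | None = None) -> float:
    tree = cKDTree(reference.points)
    if radius is None:
        d, _ = tree.query(reference.points, k=min(2, len(reference)))
        radius = 3.0 * float(np.median(d[:, -1])) if len(reference) > 1 else 1.0
    d, _ = tree.query(cloud.points, distance_upper_bound=max(radius, 1e-9))
    return float(np.isfinite(d).mean())


def _voxel_dedup(cloud: PointCloud, voxel: float) -> PointCloud:
    keys = np.floor(cloud.points / voxel).astype(np.int64)
    _, first = np.unique(keys, axis=0, return_index=True)
    return cloud.select(np.sort(first))


def cloud_to_cloud_distance(
    test: PointCloud, reference: PointCloud
) -> tuple[float, float]:
    """Mean and std of per-test-point nearest-neighbor distance to reference."""
    if len(test) == 0 or len(reference) == 0:
        raise ValueError("cloud_to_cloud_distance requires non-empty clouds")
    tree = cKDTree(reference.points)
    d, _ = tree.query(test.points)
    return float(np.mean(d)), float(np.std(d))
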