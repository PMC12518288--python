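"""Morphological trait extraction from a registered plant model.

Plant height is measured from a reference plane (by default the pot rim),
crown width is the diameter of the XY-projected convex hull, and leaf
length/width are straight-line distances between extreme cloud points
along the leaf's principal axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .core import PointCloud

__all__ = [
    "TraitReport",
    "plant_height",
    "crown_width",
    "leaf_axes",
    "extract_traits",
]


@dataclass
class TraitReport:
    plant_height: float
    crown_width: float
    leaves: list[tuple[int, float, float]] = field(default_factory=list)
    reference_plane_z: float = 0.0

    def __post_init__(self) -> None:
        if self.plant_height < 0 or self.crown_width < 0:
            raise ValueError("traits must be non-negative")
        for leaf_id, length, width in self.leaves:
            if length < width:
                raise ValueError(
                    f"leaf {leaf_id}: length ({length}) must be >= width ({width})"
                )

    def to_tsv(self) -> str:
        lines = ["plant_height_cm\tcrown_width_cm\tleaf_id\tleaf_length_cm\tleaf_width_cm"]
        if not self.leaves:
            lines.append(f"{self.plant_height:.4f}\t{self.crown_width:.4f}\t\t\t")
        for leaf_id, length, width in self.leaves:
            lines.append(
                f"{self.plant_height:.4f}\t{self.crown_width:.4f}\t"
                f"{leaf_id}\t{length:.4f}\t{width:.4f}"
            )
        return "\n".join(lines) + "\n"


def plant_height(plant: PointCloud, reference_z: float = 0.0) -> float:
    """Max z of the plant minus the reference plane z."""
    if len(plant) == 0:
        raise ValueError("plant cloud is empty")
    return float(plant.points[:, 2].max() - reference_z)


def crown_width(plant: PointCloud) -> float:
    """Diameter of the XY projection: the maximum pairwise horizontal distance.

    Computed over convex-hull vertices (the diameter is attained there),
    which matches the brute-force O(N^2) maximum.
    """
    if len(plant) < 2:
        raise ValueError("crown width needs at least 2 points")
    xy = plant.points[:, :2]
    if len(xy) > 3:
        try:
            xy = xy[ConvexHull(xy).vertices]
        except QhullError:
            pass  # collinear projections: fall through to all-pairs
    d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=2)
    return float(d.max())


def leaf_axes(
    leaf: PointCloud,
) -> tuple[float, float, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]:
    """Leaf length and width as point-to-point chords along principal axes.

    Axes come from the coordinate covariance (ordered by explained
    variance); the returned endpoints are actual cloud points with extreme
    projections, so each measurement is a literal two-point distance.
    """
    if len(leaf) < 3:
        raise ValueError("leaf must contain at least 3 points")
    pts = leaf.points
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[1] <= 1e-12 * max(evals[0], 1.0):
        raise ValueError("leaf points are degenerate (coincident or collinear)")

    proj1 = centered @ evecs[:, 0]
    proj2 = centered @ evecs[:, 1]
    p_lo, p_hi = pts[proj1.argmin()], pts[proj1.argmax()]
    q_lo, q_hi = pts[proj2.argmin()], pts[proj2.argmax()]
    length = float(np.linalg.norm(p_hi - p_lo))
    width = float(np.linalg.norm(q_hi - q_lo))
    if width > length:  # extreme chords can cross over on near-isotropic leaves
        length, width = width, length
        p_lo, p_hi, q_lo, q_hi = q_lo, q_hi, p_lo, p_hi
    return length, width, (p_lo, p_hi, q_lo, q_hi)


def extract_traits(
    plant: PointCloud,
    leaf_labels: list[int] | None = None,
    reference_z: float = 0.0,
) -> TraitReport:
    """Assemble the trait report; leaves are selected by their labels."""
    if len(plant) == 0:
        raise ValueError("plant cloud is empty")
    leaves: list[tuple[int, float, float]] = []
    if leaf_labels:
        if plant.labels is None:
            raise ValueError("plant cloud has no labels; cannot select leaves")
        available = sorted(set(np.unique(plant.labels).tolist()))
        for lab in leaf_labels:
            sel = plant.select(plant.labels == lab)
            if len(sel) < 3:
                raise ValueError(
                    f"leaf label {lab} selects {len(sel)} points; "
                    f"available labels: {available}"
                )
            length, width, _ = leaf_axes(sel)
            leaves.append((int(lab), length, width))
    return TraitReport(
        plant_height=plant_height(plant, reference_z),
        crown_width=crown_width(plant),
        leaves=leaves,
        reference_plane_z=reference_z,
    )
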