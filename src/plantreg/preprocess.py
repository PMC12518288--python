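"""Per-view cleanup: dark-noise color filter, ROI crop, statistical outlier removal.

The color rule is conjunctive: a point is "dark" only when all three
channels fall below the threshold, so saturated marker colors survive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core import PointCloud

__all__ = ["PreprocessConfig", "color_filter", "crop_box", "remove_outliers"]


@dataclass
class PreprocessConfig:
    channel_threshold: int = 50
    crop_min: tuple[float, float, float] | None = None
    crop_max: tuple[float, float, float] | None = None
    outlier_k: int = 20
    outlier_std_ratio: float = 2.0

    def __post_init__(self) -> None:
        if not (0 <= self.channel_threshold <= 255):
            raise ValueError("channel_threshold must lie in [0, 255]")
        if self.outlier_k < 1:
            raise ValueError("outlier_k must be >= 1")
        if self.outlier_std_ratio <= 0:
            raise ValueError("outlier_std_ratio must be positive")
        if self.crop_min is not None and self.crop_max is not None:
            lo = np.asarray(self.crop_min, dtype=float)
            hi = np.asarray(self.crop_max, dtype=float)
            if np.any(lo > hi):
                raise ValueError("crop_min must be <= crop_max componentwise")


def color_filter(cloud: PointCloud, config: PreprocessConfig) -> PointCloud:
    """Drop points whose R, G and B are all below the channel threshold."""
    if len(cloud) == 0:
        return cloud
    dark = np.all(cloud.colors < config.channel_threshold, axis=1)
    return cloud.select(~dark)


def crop_box(cloud: PointCloud, config: PreprocessConfig) -> PointCloud:
    """Keep points inside the axis-aligned box [crop_min, crop_max]."""
    if len(cloud) == 0:
        return cloud
    mask = np.ones(len(cloud), dtype=bool)
    if config.crop_min is not None:
        mask &= np.all(cloud.points >= np.asarray(config.crop_min, dtype=float), axis=1)
    if config.crop_max is not None:
        mask &= np.all(cloud.points <= np.asarray(config.crop_max, dtype=float), axis=1)
    return cloud.select(mask)


def remove_outliers(cloud: PointCloud, config: PreprocessConfig) -> PointCloud:
    """Statistical outlier removal on the mean-of-k-NN-distances statistic.

    A point is removed when its mean distance to its k nearest neighbors
    exceeds (global mean + std_ratio * global std) of that statistic.
    """
    n = len(cloud)
    if n <= config.outlier_k:
        raise ValueError(
            f"remove_outliers requires N > outlier_k (N={n}, k={config.outlier_k})"
        )
    tree = cKDTree(cloud.points)
    # k+1 because the query point itself is its own nearest neighbor
    dists, _ = tree.query(cloud.points, k=config.outlier_k + 1)
    mean_knn = dists[:, 1:].mean(axis=1)
    cutoff = mean_knn.mean() + config.outlier_std_ratio * mean_knn.std()
    return cloud.select(mean_knn <= cutoff)
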