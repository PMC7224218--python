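"""Gaussian-KDE hypervolumes of niches in k-dimensional score space.

A hypervolume is the region where the kernel density of the occurrence scores
reaches a boundary quantile (H_75 strips smoothing fringe; H_100 keeps any
positive density).  The region is represented by uniformly distributed random
points accepted by rejection sampling in a padded bounding box, so its volume
is box volume x acceptance rate — transparent and directly oracle-checkable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ._kde import kde_evaluate, silverman_bandwidth
from .errors import NicheShiftError

#: default count of region-representing random points
MIN_RANDOM_POINTS = 10_000


@dataclass
class Hypervolume:
    """KDE-backed region of k-dimensional environmental space."""

    points: np.ndarray          # (n, k) source occurrence scores
    bandwidth: np.ndarray       # (k,) Silverman bandwidths
    boundary_quantile: float    # p in (0, 100]
    threshold: float            # KDE density defining the boundary
    random_points: np.ndarray   # (m, k) uniform points inside the region
    volume: float               # PC-units^k
    centroid: np.ndarray        # (k,) density-weighted centroid of the region
    box_lo: np.ndarray = field(repr=False, default=None)
    box_hi: np.ndarray = field(repr=False, default=None)
    seed: int | None = None

    @property
    def ndim(self) -> int:
        return self.points.shape[1]

    def contains(self, query: np.ndarray) -> np.ndarray:
        """Boolean membership of query points in the retained region."""
        density = kde_evaluate(self.points, self.bandwidth, query)
        if self.boundary_quantile >= 100:
            return density > self.threshold
        return density >= self.threshold

    def export_points(self, path) -> None:
        """Random points as CSV for plotting."""
        header = ",".join(f"pc{i + 1}" for i in range(self.ndim))
        np.savetxt(path, self.random_points, delimiter=",", header=header,
                   comments="", fmt="%.8g")


@dataclass
class HypervolumeComparison:
    jaccard: float
    centroid_distance: float
    minimum_distance: float
    volume_1: float
    volume_2: float
    intersection_volume: float
    union_volume: float
    unique_fraction_1: float    # percent of volume_1 outside the intersection
    unique_fraction_2: float


def build_hypervolume(points: np.ndarray, boundary_quantile: float = 100.0,
                      n_random: int | None = None, seed: int | None = None,
                      box_pad: float = 3.0,
                      min_acceptance: float = 1e-4) -> Hypervolume:
    """Build the KDE hypervolume of a point cloud.

    The retained region is where the KDE density reaches the
    (100 - boundary_quantile)-th percentile of the density evaluated at the
    source points themselves; for the full boundary (quantile 100) the floor
    is zero, i.e. any positive density.  The sampling box is the point
    bounding box padded by ``box_pad`` bandwidths per axis.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n, k = pts.shape
    if not (0 < boundary_quantile <= 100):
        raise NicheShiftError("boundary_quantile must be in (0, 100]")
    if n_random is None:
        n_random = max(MIN_RANDOM_POINTS, 500 * k)
    if n_random < 1000:
        raise NicheShiftError("n_random must be >= 1000")

    bw = silverman_bandwidth(pts)
    density_at_points = kde_evaluate(pts, bw, pts)
    if boundary_quantile >= 100:
        threshold = 0.0
    else:
        threshold = float(np.percentile(density_at_points,
                                        100 - boundary_quantile))

    lo = pts.min(axis=0) - box_pad * bw
    hi = pts.max(axis=0) + box_pad * bw
    box_volume = float(np.prod(hi - lo))

    rng = np.random.default_rng(seed)
    draws = rng.uniform(lo, hi, size=(n_random, k))
    density = kde_evaluate(pts, bw, draws)
    accept = density > threshold if boundary_quantile >= 100 else density >= threshold
    rate = accept.mean()
    if rate < min_acceptance:
        raise NicheShiftError(
            f"acceptance rate {rate:.2g} below {min_acceptance}: increase n_random"
            " or lower the boundary quantile"
        )
    accepted = draws[accept]
    w = density[accept]
    centroid = (accepted * w[:, None]).sum(axis=0) / w.sum()

    return Hypervolume(
        points=pts, bandwidth=bw, boundary_quantile=float(boundary_quantile),
        threshold=threshold, random_points=accepted,
        volume=box_volume * float(rate), centroid=centroid,
        box_lo=lo, box_hi=hi, seed=seed,
    )


def compare_hypervolumes(hv1: Hypervolume, hv2: Hypervolume) -> HypervolumeComparison:
    """Jaccard similarity, centroid / minimum distance, and intersection
    metrics between two hypervolumes of the same dimensionality.

    The intersection volume is estimated by cross-membership: the fraction of
    each hypervolume's random points that fall inside the other's region,
    averaged across the two directions.
    """
    if hv1.ndim != hv2.ndim:
        raise NicheShiftError(
            f"dimension mismatch: {hv1.ndim} vs {hv2.ndim}"
        )
    if hv1.boundary_quantile != hv2.boundary_quantile:
        raise NicheShiftError("hypervolumes use different boundary quantiles")

    frac_1_in_2 = float(hv2.contains(hv1.random_points).mean())
    frac_2_in_1 = float(hv1.contains(hv2.random_points).mean())
    inter = 0.5 * (hv1.volume * frac_1_in_2 + hv2.volume * frac_2_in_1)
    inter = min(inter, hv1.volume, hv2.volume)
    union = hv1.volume + hv2.volume - inter

    tree = cKDTree(hv2.random_points)
    dmin, _ = tree.query(hv1.random_points, k=1)
    minimum = float(dmin.min())
    if inter > 0:
        minimum = 0.0

    return HypervolumeComparison(
        jaccard=float(inter / union) if union > 0 else 1.0,
        centroid_distance=float(np.linalg.norm(hv1.centroid - hv2.centroid)),
        minimum_distance=minimum,
        volume_1=hv1.volume, volume_2=hv2.volume,
        intersection_volume=inter, union_volume=union,
        unique_fraction_1=100.0 * (hv1.volume - inter) / hv1.volume,
        unique_fraction_2=100.0 * (hv2.volume - inter) / hv2.volume,
    )
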