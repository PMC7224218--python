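"""Pooled-background PCA environmental space and the gridded niche representation.

The environmental space is calibrated on the two ranges' *backgrounds* pooled
together — never on occurrences — and niches are represented as Gaussian-KDE
occurrence densities on an R x R grid bounded by the pooled background scores.
Percentile masks I_p strip low-availability fringe cells; the analogous-climate
mask is the intersection of the two ranges' masks.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._kde import kde_evaluate, kde_grid_2d, silverman_bandwidth
from .errors import GridMismatchError, NicheShiftError

logger = logging.getLogger(__name__)

DEFAULT_PERCENTILES = (75, 100)


# ---------------------------------------------------------------------------
# PCA environmental space
# ---------------------------------------------------------------------------

@dataclass
class EnvSpaceModel:
    """Standardised-PCA model of the pooled-background environmental space."""

    variables: list[str]
    center: np.ndarray                  # per-variable mean
    scale: np.ndarray                   # per-variable std (ddof=0)
    loadings: np.ndarray                # (n_vars, n_components), orthonormal columns
    explained_variance: np.ndarray      # eigenvalues of the scaled covariance
    explained_variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "variables": self.variables,
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_variance": self.explained_variance.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "EnvSpaceModel":
        d = json.loads(Path(path).read_text())
        return cls(
            variables=list(d["variables"]),
            center=np.asarray(d["center"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
            loadings=np.asarray(d["loadings"], dtype=float),
            explained_variance=np.asarray(d["explained_variance"], dtype=float),
            explained_variance_ratio=np.asarray(d["explained_variance_ratio"], dtype=float),
        )


def _as_table(data, variables: list[str] | None) -> tuple[np.ndarray, list[str]]:
    if isinstance(data, pd.DataFrame):
        cols = variables if variables is not None else [
            c for c in data.columns if np.issubdtype(data[c].dtype, np.number)
        ]
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise NicheShiftError(f"missing variable(s): {missing}")
        return data[cols].to_numpy(dtype=float), list(cols)
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    cols = variables if variables is not None else [f"v{i}" for i in range(arr.shape[1])]
    return arr, list(cols)


def fit_env_space(native_bg, invaded_bg, n_components: int = 2,
                  variables: list[str] | None = None) -> EnvSpaceModel:
    """Fit a standardised PCA on the two backgrounds pooled (concatenated).

    Occurrences must never be passed here: the space is defined by what is
    *available*, not by what is occupied.
    """
    x_nat, cols = _as_table(native_bg, variables)
    x_inv, cols_inv = _as_table(invaded_bg, variables)
    if cols != cols_inv:
        raise NicheShiftError(f"backgrounds carry different variables: {cols} vs {cols_inv}")
    pooled = np.vstack([x_nat, x_inv])
    if pooled.shape[0] < 3:
        raise NicheShiftError("need at least 3 pooled background points")
    if pooled.shape[1] < n_components:
        raise NicheShiftError(
            f"{pooled.shape[1]} variable(s) cannot support {n_components} components"
        )
    if not np.isfinite(pooled).all():
        raise NicheShiftError("backgrounds contain NaN/inf values")
    center = pooled.mean(axis=0)
    scale = pooled.std(axis=0)
    const = np.flatnonzero(scale == 0)
    if const.size:
        raise NicheShiftError(f"constant variable: {cols[const[0]]!r}")
    z = (pooled - center) / scale
    # SVD of the standardised matrix; eigenvalues of the covariance = s^2 / n
    _, s, vt = np.linalg.svd(z, full_matrices=False)
    eigvals = s**2 / pooled.shape[0]
    loadings = vt.T[:, :n_components]
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
    total = eigvals.sum()
    return EnvSpaceModel(
        variables=cols,
        center=center,
        scale=scale,
        loadings=loadings,
        explained_variance=eigvals[:n_components],
        explained_variance_ratio=eigvals[:n_components] / total,
    )


def project(points, model: EnvSpaceModel) -> np.ndarray:
    """Project points (table with the model's variables) into PC scores."""
    x, _ = _as_table(points, model.variables if isinstance(points, pd.DataFrame) else None)
    if x.shape[0] == 0:
        return np.empty((0, model.n_components))
    if x.shape[1] != len(model.variables):
        raise NicheShiftError(
            f"expected {len(model.variables)} variables, got {x.shape[1]}"
        )
    return (x - model.center) / model.scale @ model.loadings


# ---------------------------------------------------------------------------
# Grid geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """An R x R grid over 2-D score space. Cells are half-open [lo, hi) except
    the last cell along each axis, which is closed so extreme points bin inside."""

    xmin: float
    xmax: float
    ymin: float
    ymax: float
    resolution: int = 100

    @property
    def cell_width(self) -> tuple[float, float]:
        r = self.resolution
        return (self.xmax - self.xmin) / r, (self.ymax - self.ymin) / r

    def x_centers(self) -> np.ndarray:
        wx, _ = self.cell_width
        return self.xmin + wx * (np.arange(self.resolution) + 0.5)

    def y_centers(self) -> np.ndarray:
        _, wy = self.cell_width
        return self.ymin + wy * (np.arange(self.resolution) + 0.5)

    def cell_index(self, scores: np.ndarray) -> np.ndarray:
        """(n, 2) integer cell indices; points exactly on the max bound go in
        the last cell."""
        s = np.atleast_2d(np.asarray(scores, dtype=float))
        wx, wy = self.cell_width
        ix = np.floor((s[:, 0] - self.xmin) / wx).astype(int)
        iy = np.floor((s[:, 1] - self.ymin) / wy).astype(int)
        r = self.resolution
        return np.column_stack([np.clip(ix, 0, r - 1), np.clip(iy, 0, r - 1)])

    def contains(self, scores: np.ndarray) -> np.ndarray:
        s = np.atleast_2d(np.asarray(scores, dtype=float))
        return (
            (s[:, 0] >= self.xmin) & (s[:, 0] <= self.xmax)
            & (s[:, 1] >= self.ymin) & (s[:, 1] <= self.ymax)
        )


def build_grid(bg_scores_native: np.ndarray, bg_scores_invaded: np.ndarray,
               resolution: int = 100) -> GridSpec:
    """Grid bounded by the pooled backgrounds' per-axis min/max."""
    if resolution < 10:
        raise NicheShiftError("grid resolution must be >= 10")
    a = np.atleast_2d(np.asarray(bg_scores_native, dtype=float))[:, :2]
    b = np.atleast_2d(np.asarray(bg_scores_invaded, dtype=float))[:, :2]
    if a.shape[0] < 1 or b.shape[0] < 1:
        raise NicheShiftError("each background needs at least one point")
    pooled = np.vstack([a, b])
    lo = pooled.min(axis=0)
    hi = pooled.max(axis=0)
    for axis in range(2):
        if hi[axis] <= lo[axis]:
            raise NicheShiftError(f"degenerate grid axis {axis}: max equals min")
    return GridSpec(xmin=lo[0], xmax=hi[0], ymin=lo[1], ymax=hi[1],
                    resolution=resolution)


# ---------------------------------------------------------------------------
# Densities and masks
# ---------------------------------------------------------------------------

@dataclass
class NicheGrid:
    """Gridded niche: occurrence density surface plus background availability."""

    spec: GridSpec
    z: np.ndarray                       # occurrence density, masked to own I_100, sums to 1
    z_corrected: np.ndarray             # background-ratio-corrected variant, sums to 1
    bg_density: np.ndarray              # background KDE at cell centers (unnormalised)
    masks: dict[int, np.ndarray] = field(default_factory=dict)   # p -> bool (R, R)
    n_occurrences: int = 0
    n_clipped: int = 0

    def mask(self, p: int | float) -> np.ndarray:
        key = int(p)
        if key not in self.masks:
            raise NicheShiftError(
                f"mask I_{key} not computed (available: {sorted(self.masks)})"
            )
        return self.masks[key]

    def check_compatible(self, other: "NicheGrid") -> None:
        if self.spec != other.spec:
            raise GridMismatchError("niche grids do not share bounds/resolution")


def background_mask(bg_scores: np.ndarray, grid: GridSpec, p: float,
                    bg_density: np.ndarray | None = None,
                    bandwidth: np.ndarray | None = None) -> np.ndarray:
    """Availability mask I_p.

    I_100 keeps every cell whose background density reaches the minimum density
    observed at the background points themselves, plus every cell that contains
    a background point.  For p < 100 the threshold is the (100-p)-th percentile
    of background density evaluated at the background points (strict >), which
    strips the low-availability fringe produced by kernel smoothing.
    """
    if not (0 < p <= 100):
        raise NicheShiftError(f"percentile p must be in (0, 100], got {p}")
    scores = np.atleast_2d(np.asarray(bg_scores, dtype=float))[:, :2]
    if bandwidth is None:
        bandwidth = silverman_bandwidth(scores)
    if bg_density is None:
        bg_density = kde_grid_2d(scores, bandwidth, grid.x_centers(), grid.y_centers())
    at_points = kde_evaluate(scores, bandwidth, scores)
    if p == 100:
        mask = bg_density >= at_points.min()
        idx = grid.cell_index(scores)
        mask[idx[:, 0], idx[:, 1]] = True
        return mask
    threshold = np.percentile(at_points, 100 - p)
    return bg_density > threshold


def occurrence_density(occ_scores: np.ndarray, bg_scores: np.ndarray,
                       grid: GridSpec,
                       percentiles: tuple[int, ...] = DEFAULT_PERCENTILES) -> NicheGrid:
    """Gaussian-KDE occurrence density on the grid, masked by the range's own
    I_100 availability and normalised to unit mass.

    Occurrences marginally outside the pooled bounds (projection jitter) are
    clipped onto the bounds with a logged count rather than rejected.
    """
    occ = np.atleast_2d(np.asarray(occ_scores, dtype=float))[:, :2]
    bg = np.atleast_2d(np.asarray(bg_scores, dtype=float))[:, :2]
    if occ.shape[0] < 5:
        raise NicheShiftError(
            f"only {occ.shape[0]} occurrences: too few for kernel density estimation"
        )
    inside = grid.contains(occ)
    n_clipped = int((~inside).sum())
    if n_clipped == occ.shape[0]:
        raise NicheShiftError("all occurrences fall outside the grid bounds")
    if n_clipped:
        logger.warning("clipping %d occurrence(s) outside grid bounds", n_clipped)
        occ = occ.copy()
        occ[:, 0] = np.clip(occ[:, 0], grid.xmin, grid.xmax)
        occ[:, 1] = np.clip(occ[:, 1], grid.ymin, grid.ymax)

    xc, yc = grid.x_centers(), grid.y_centers()
    occ_bw = silverman_bandwidth(occ)
    bg_bw = silverman_bandwidth(bg)
    z_raw = kde_grid_2d(occ, occ_bw, xc, yc)
    bg_density = kde_grid_2d(bg, bg_bw, xc, yc)

    masks = {
        int(p): background_mask(bg, grid, p, bg_density=bg_density, bandwidth=bg_bw)
        for p in percentiles
    }
    if 100 not in masks:
        masks[100] = background_mask(bg, grid, 100, bg_density=bg_density,
                                     bandwidth=bg_bw)

    i100 = masks[100]
    z = np.where(i100, z_raw, 0.0)
    total = z.sum()
    if total <= 0:
        raise NicheShiftError("occurrence density has zero mass inside I_100")
    z = z / total

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(bg_density > 0, z_raw / bg_density, 0.0)
    z_corr = np.where(i100, ratio, 0.0)
    corr_total = z_corr.sum()
    z_corr = z_corr / corr_total if corr_total > 0 else z_corr

    return NicheGrid(
        spec=grid, z=z, z_corrected=z_corr, bg_density=bg_density,
        masks=masks, n_occurrences=occ.shape[0], n_clipped=n_clipped,
    )
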