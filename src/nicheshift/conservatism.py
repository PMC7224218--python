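"""Permutation tests of niche equivalency and similarity.

Both tests compare the observed Schoener's D against a null distribution and
use a one-tailed "greater" decision rule: niche conservatism is inferred when
the observed overlap exceeds 95% of the null values (p <= alpha with the
add-one permutation p-value).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._kde import kde_grid_2d, silverman_bandwidth
from .envspace import GridSpec, NicheGrid, background_mask
from .errors import NicheShiftError

EQUIVALENCY = "equivalency"
SIMILARITY_BOTH = "similarity-N<->P"
SIMILARITY_ONE = "similarity-N->P"

_SCHEME_ALIASES = {
    "N<->P": SIMILARITY_BOTH,
    "N↔P": SIMILARITY_BOTH,
    "both": SIMILARITY_BOTH,
    SIMILARITY_BOTH: SIMILARITY_BOTH,
    "N->P": SIMILARITY_ONE,
    "N→P": SIMILARITY_ONE,
    "invaded-only": SIMILARITY_ONE,
    SIMILARITY_ONE: SIMILARITY_ONE,
}


@dataclass
class TestResult:
    observed_d: float
    null_d: np.ndarray
    p_value: float
    n_reps: int
    scheme: str
    alpha: float = 0.05
    seed: int | None = None

    @property
    def conserved(self) -> bool:
        """Niche conservatism inferred (observed overlap beats the null)."""
        return bool(self.p_value <= self.alpha)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "scheme": self.scheme,
            "observed_d": self.observed_d,
            "p_value": self.p_value,
            "n_reps": self.n_reps,
            "alpha": self.alpha,
            "conserved": self.conserved,
            "seed": self.seed,
            "null_d": [float(v) for v in self.null_d],
        }, indent=1))

    def null_histogram(self, path: str | Path, bins: int = 20) -> None:
        counts, edges = np.histogram(self.null_d, bins=bins, range=(0.0, 1.0))
        with open(path, "w") as fh:
            fh.write("bin_lo,bin_hi,count\r\n")
            for lo, hi, c in zip(edges[:-1], edges[1:], counts):
                fh.write(f"{lo},{hi},{c}\r\n")


def _permutation_p(null: np.ndarray, observed: float) -> float:
    """Add-one permutation p-value for the 'greater' alternative."""
    return float((1.0 + np.sum(null >= observed)) / (null.size + 1.0))


class _DensityRebuilder:
    """Caches the background side of a NicheGrid so permutation reps only pay
    for the occurrence KDE."""

    def __init__(self, bg_scores: np.ndarray, grid: GridSpec,
                 fallback_bandwidth: np.ndarray | None = None) -> None:
        self.grid = grid
        bg = np.atleast_2d(np.asarray(bg_scores, dtype=float))[:, :2]
        self.bg_bw = silverman_bandwidth(bg)
        self.xc = grid.x_centers()
        self.yc = grid.y_centers()
        self.bg_density = kde_grid_2d(bg, self.bg_bw, self.xc, self.yc)
        self.i100 = background_mask(bg, grid, 100, bg_density=self.bg_density,
                                    bandwidth=self.bg_bw)
        self.fallback_bw = fallback_bandwidth

    def density(self, occ_scores: np.ndarray) -> np.ndarray:
        occ = np.atleast_2d(np.asarray(occ_scores, dtype=float))[:, :2]
        try:
            bw = silverman_bandwidth(occ)
        except NicheShiftError:
            if self.fallback_bw is None:
                raise
            bw = self.fallback_bw
        z = np.where(self.i100, kde_grid_2d(occ, bw, self.xc, self.yc), 0.0)
        total = z.sum()
        if total <= 0:
            raise NicheShiftError("permuted occurrence density has zero mass")
        return z / total


def _d_between(z1: np.ndarray, z2: np.ndarray) -> float:
    return float(1.0 - 0.5 * np.abs(z1 - z2).sum())


def equivalency_test(occ_scores_native: np.ndarray, occ_scores_invaded: np.ndarray,
                     bg_scores_native: np.ndarray, bg_scores_invaded: np.ndarray,
                     grid: GridSpec, n_reps: int = 1000,
                     seed: int | None = None, alpha: float = 0.05) -> TestResult:
    """Niche equivalency: pooled occurrences are randomly reassigned to the two
    ranges (preserving group sizes), both densities rebuilt, and D recomputed
    for each of the n_reps permutations."""
    if n_reps < 1:
        raise NicheShiftError("n_reps must be >= 1")
    occ_nat = np.atleast_2d(np.asarray(occ_scores_native, dtype=float))[:, :2]
    occ_inv = np.atleast_2d(np.asarray(occ_scores_invaded, dtype=float))[:, :2]
    if occ_nat.shape[0] < 5 or occ_inv.shape[0] < 5:
        raise NicheShiftError("each occurrence set needs >= 5 records")

    pooled = np.vstack([occ_nat, occ_inv])
    pooled_bw = silverman_bandwidth(pooled)
    builder_nat = _DensityRebuilder(bg_scores_native, grid, pooled_bw)
    builder_inv = _DensityRebuilder(bg_scores_invaded, grid, pooled_bw)

    observed = _d_between(builder_nat.density(occ_nat), builder_inv.density(occ_inv))

    rng = np.random.default_rng(seed)
    n1 = occ_nat.shape[0]
    null = np.empty(n_reps)
    for r in range(n_reps):
        perm = rng.permutation(pooled.shape[0])
        z1 = builder_nat.density(pooled[perm[:n1]])
        z2 = builder_inv.density(pooled[perm[n1:]])
        null[r] = _d_between(z1, z2)

    return TestResult(
        observed_d=observed, null_d=null, p_value=_permutation_p(null, observed),
        n_reps=n_reps, scheme=EQUIVALENCY, alpha=alpha, seed=seed,
    )


def _shift_surface(z: np.ndarray, di: int, dj: int) -> np.ndarray:
    """Translate a density surface by whole cells, dropping mass shifted off
    the grid edge."""
    out = np.zeros_like(z)
    r, c = z.shape
    src_i = slice(max(0, -di), min(r, r - di))
    src_j = slice(max(0, -dj), min(c, c - dj))
    dst_i = slice(max(0, di), min(r, r + di))
    dst_j = slice(max(0, dj), min(c, c + dj))
    out[dst_i, dst_j] = z[src_i, src_j]
    return out


def _centroid_cell(z: np.ndarray) -> tuple[int, int]:
    total = z.sum()
    ci = (z.sum(axis=1) * np.arange(z.shape[0])).sum() / total
    cj = (z.sum(axis=0) * np.arange(z.shape[1])).sum() / total
    return int(round(ci)), int(round(cj))


def _random_translation(z: np.ndarray, mask: np.ndarray,
                        rng: np.random.Generator, max_tries: int = 100) -> np.ndarray:
    cells = np.argwhere(mask)
    if cells.shape[0] == 0:
        raise NicheShiftError("background mask has no cells to place a centroid in")
    ci, cj = _centroid_cell(z)
    for _ in range(max_tries):
        ti, tj = cells[rng.integers(cells.shape[0])]
        shifted = _shift_surface(z, int(ti) - ci, int(tj) - cj)
        shifted = np.where(mask, shifted, 0.0)
        total = shifted.sum()
        if total > 0:
            return shifted / total
    raise NicheShiftError(
        "background mask too small: no admissible centroid placement found"
    )


def similarity_test(grid_native: NicheGrid, grid_invaded: NicheGrid,
                    scheme: str = "N<->P", n_reps: int = 1000,
                    seed: int | None = None, alpha: float = 0.05,
                    mask_percentile: int = 100) -> TestResult:
    """Niche similarity: the observed density pattern(s) are translated so the
    centroid lands on a uniformly drawn background cell, then D is recomputed.

    scheme "N<->P": both niches are randomly re-centred each rep.
    scheme "N->P": only the invaded niche is re-centred.
    """
    if scheme not in _SCHEME_ALIASES:
        raise NicheShiftError(
            f"unknown scheme {scheme!r}: expected one of 'N<->P', 'N->P'"
        )
    scheme = _SCHEME_ALIASES[scheme]
    if n_reps < 1:
        raise NicheShiftError("n_reps must be >= 1")
    grid_native.check_compatible(grid_invaded)

    z_nat = grid_native.z / grid_native.z.sum()
    z_inv = grid_invaded.z / grid_invaded.z.sum()
    observed = _d_between(z_nat, z_inv)

    mask_nat = grid_native.mask(mask_percentile)
    mask_inv = grid_invaded.mask(mask_percentile)
    rng = np.random.default_rng(seed)
    null = np.empty(n_reps)
    for r in range(n_reps):
        sim_inv = _random_translation(z_inv, mask_inv, rng)
        if scheme == SIMILARITY_BOTH:
            sim_nat = _random_translation(z_nat, mask_nat, rng)
        else:
            sim_nat = z_nat
        null[r] = _d_between(sim_nat, sim_inv)

    return TestResult(
        observed_d=observed, null_d=null, p_value=_permutation_p(null, observed),
        n_reps=n_reps, scheme=scheme, alpha=alpha, seed=seed,
    )
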