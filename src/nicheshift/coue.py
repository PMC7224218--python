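"""Niche-change decomposition on the gridded environmental space.

Stability / unfilling / expansion are density-mass fractions computed inside
analogous climate (cells available in both ranges at the chosen availability
percentile), so expansion is never conflated with climates that simply do not
exist in the other range.  Overlap is Schoener's D over the full grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .envspace import NicheGrid
from .errors import NicheShiftError

TOPOLOGY_CLASSES = (
    "overlap-complete",
    "invaded-subset",
    "native-subset",
    "partial-overlap",
    "disjunct",
)

#: fraction of a niche's density mass that defines its occupied cell set.
#: 1.0 means "every cell with positive density"; the default trims the
#: low-density kernel-smoothing fringe, which is never ecologically occupied,
#: while keeping nearly all of the estimated niche mass.
DEFAULT_OCCUPANCY_MASS = 0.94


@dataclass
class COUEMetrics:
    """Stability / unfilling / expansion at each requested availability
    percentile, centroid shift, topology class, and Schoener's D."""

    stability: dict[int, float]
    unfilling: dict[int, float]
    expansion: dict[int, float]
    centroid_shift: np.ndarray
    centroid_shift_magnitude: float
    topology: dict[int, str]
    schoener_d: float
    expansion_nonanalog: dict[int, float]
    expansion_nonanalog_flag: dict[int, bool] = field(default_factory=dict)

    def as_table(self) -> dict[str, dict[int, float]]:
        """Metric -> {percentile -> value}, percentages for S/U/E."""
        return {
            "stability_pct": {p: 100 * v for p, v in self.stability.items()},
            "unfilling_pct": {p: 100 * v for p, v in self.unfilling.items()},
            "expansion_pct": {p: 100 * v for p, v in self.expansion.items()},
            "expansion_nonanalog_pct": {
                p: 100 * v for p, v in self.expansion_nonanalog.items()
            },
        }


def _surface(grid: NicheGrid, corrected: bool) -> np.ndarray:
    return grid.z_corrected if corrected else grid.z


def occupied_mask(grid: NicheGrid, p: int | float,
                  occupancy_mass: float = DEFAULT_OCCUPANCY_MASS,
                  corrected: bool = False) -> np.ndarray:
    """Cells occupied by the niche at availability percentile p.

    The density surface is restricted to the range's own I_p mask, then the
    smallest set of highest-density cells holding at least ``occupancy_mass``
    of the remaining mass is kept.  With occupancy_mass=1.0 this reduces to
    "every masked cell with z > 0".
    """
    if not (0 < occupancy_mass <= 1):
        raise NicheShiftError("occupancy_mass must be in (0, 1]")
    z = np.where(grid.mask(p), _surface(grid, corrected), 0.0)
    total = z.sum()
    if total <= 0:
        raise NicheShiftError(f"niche has zero density mass inside I_{int(p)}")
    if occupancy_mass >= 1.0:
        return z > 0
    flat = np.sort(z.ravel())[::-1]
    cum = np.cumsum(flat)
    k = int(np.searchsorted(cum, occupancy_mass * total))
    cutoff = flat[min(k, flat.size - 1)]
    return z >= cutoff if cutoff > 0 else z > 0


def _analogous(grid_native: NicheGrid, grid_invaded: NicheGrid, p) -> np.ndarray:
    grid_native.check_compatible(grid_invaded)
    analog = grid_native.mask(p) & grid_invaded.mask(p)
    if not analog.any():
        raise NicheShiftError(
            "empty analogous mask: the two ranges share no environmental space"
            f" at I_{int(p)}"
        )
    return analog


def niche_dyn_indices(grid_native: NicheGrid, grid_invaded: NicheGrid,
                      p: int | float = 75,
                      occupancy_mass: float = DEFAULT_OCCUPANCY_MASS,
                      corrected: bool = False) -> tuple[float, float, float]:
    """(stability, unfilling, expansion) density-mass fractions in analogous space.

    expansion  = invaded mass on analogous cells the native niche does not occupy
                 / invaded mass on analogous cells
    stability  = 1 - expansion
    unfilling  = native mass on analogous cells the invaded niche does not occupy
                 / native mass on analogous cells
    """
    analog = _analogous(grid_native, grid_invaded, p)
    z_nat = np.where(analog, _surface(grid_native, corrected), 0.0)
    z_inv = np.where(analog, _surface(grid_invaded, corrected), 0.0)
    occ_nat = occupied_mask(grid_native, p, occupancy_mass, corrected) & analog
    occ_inv = occupied_mask(grid_invaded, p, occupancy_mass, corrected) & analog

    inv_total = z_inv.sum()
    nat_total = z_nat.sum()
    if inv_total <= 0 or nat_total <= 0:
        raise NicheShiftError("a niche carries no density mass in analogous space")
    expansion = z_inv[~occ_nat].sum() / inv_total
    stability = 1.0 - expansion
    unfilling = z_nat[~occ_inv].sum() / nat_total
    return float(stability), float(unfilling), float(expansion)


def centroid(grid: NicheGrid, corrected: bool = False) -> np.ndarray:
    """Density-weighted mean of cell centers."""
    z = _surface(grid, corrected)
    total = z.sum()
    if total <= 0:
        raise NicheShiftError("zero-mass density surface")
    xc = grid.spec.x_centers()
    yc = grid.spec.y_centers()
    cx = (z.sum(axis=1) * xc).sum() / total
    cy = (z.sum(axis=0) * yc).sum() / total
    return np.array([cx, cy])


def centroid_shift(grid_native: NicheGrid, grid_invaded: NicheGrid,
                   corrected: bool = False) -> np.ndarray:
    """Invaded-niche centroid minus native-niche centroid, in PC units."""
    grid_native.check_compatible(grid_invaded)
    return centroid(grid_invaded, corrected) - centroid(grid_native, corrected)


def topology_class(grid_native: NicheGrid, grid_invaded: NicheGrid,
                   p: int | float = 75, containment: float = 0.95,
                   occupancy_mass: float = DEFAULT_OCCUPANCY_MASS) -> str:
    """One of the five occupied-set topology patterns.

    Containment fractions are cell counts of the occupied sets at I_p; 95%
    mutual containment counts as complete overlap.
    """
    grid_native.check_compatible(grid_invaded)
    occ_nat = occupied_mask(grid_native, p, occupancy_mass)
    occ_inv = occupied_mask(grid_invaded, p, occupancy_mass)
    n_nat = occ_nat.sum()
    n_inv = occ_inv.sum()
    inter = (occ_nat & occ_inv).sum()
    if n_nat == 0 or n_inv == 0:
        raise NicheShiftError("empty occupied set")
    frac_inv_in_nat = inter / n_inv
    frac_nat_in_inv = inter / n_nat
    if frac_inv_in_nat >= containment and frac_nat_in_inv >= containment:
        return "overlap-complete"
    if frac_inv_in_nat >= containment:
        return "invaded-subset"
    if frac_nat_in_inv >= containment:
        return "native-subset"
    if inter > 0:
        return "partial-overlap"
    return "disjunct"


def schoener_d(grid_native: NicheGrid, grid_invaded: NicheGrid,
               corrected: bool = False) -> float:
    """Schoener's D = 1 - 0.5 * sum |z1 - z2| over the full grid, after
    renormalising each surface to unit mass.  0 = no overlap, 1 = identical."""
    grid_native.check_compatible(grid_invaded)
    z1 = _surface(grid_native, corrected)
    z2 = _surface(grid_invaded, corrected)
    t1, t2 = z1.sum(), z2.sum()
    if t1 <= 0 or t2 <= 0:
        raise NicheShiftError("zero-mass density surface")
    return float(1.0 - 0.5 * np.abs(z1 / t1 - z2 / t2).sum())


def nonanalog_expansion(grid_native: NicheGrid, grid_invaded: NicheGrid,
                        p: int | float = 100, threshold: float = 0.01,
                        corrected: bool = False) -> tuple[float, bool]:
    """Fraction of invaded-niche mass lying outside the native range's I_p —
    expansion into climate that does not exist in the native range."""
    grid_native.check_compatible(grid_invaded)
    z_inv = _surface(grid_invaded, corrected)
    total = z_inv.sum()
    if total <= 0:
        raise NicheShiftError("zero-mass invaded surface")
    frac = float(z_inv[~grid_native.mask(p)].sum() / total)
    return frac, frac > threshold


def compute_coue_metrics(grid_native: NicheGrid, grid_invaded: NicheGrid,
                         percentiles: tuple[int, ...] = (75, 100),
                         occupancy_mass: float = DEFAULT_OCCUPANCY_MASS,
                         corrected: bool = False,
                         nonanalog_threshold: float = 0.01) -> COUEMetrics:
    """All COUE metrics at each requested availability percentile."""
    stability, unfilling, expansion = {}, {}, {}
    topo, nonanalog, flags = {}, {}, {}
    for p in percentiles:
        s, u, e = niche_dyn_indices(grid_native, grid_invaded, p,
                                    occupancy_mass, corrected)
        stability[int(p)], unfilling[int(p)], expansion[int(p)] = s, u, e
        topo[int(p)] = topology_class(grid_native, grid_invaded, p,
                                      occupancy_mass=occupancy_mass)
        frac, flag = nonanalog_expansion(grid_native, grid_invaded, p,
                                         nonanalog_threshold, corrected)
        nonanalog[int(p)], flags[int(p)] = frac, flag
    shift = centroid_shift(grid_native, grid_invaded, corrected)
    return COUEMetrics(
        stability=stability, unfilling=unfilling, expansion=expansion,
        centroid_shift=shift, centroid_shift_magnitude=float(np.linalg.norm(shift)),
        topology=topo, schoener_d=schoener_d(grid_native, grid_invaded, corrected),
        expansion_nonanalog=nonanalog, expansion_nonanalog_flag=flags,
    )
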