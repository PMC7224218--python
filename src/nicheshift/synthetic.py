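"""Synthetic two-range environmental backgrounds and species occurrences with
known niche dynamics.

Backgrounds are Gaussian point clouds in k environmental dimensions (with
throwaway lon/lat coordinates so geographic operations like thinning and
rasterisation stay exercisable).  Occurrences are drawn from the background
points with probability proportional to a Gaussian suitability kernel, so the
realised niche dynamics — centroid shift, unfilling, expansion — are known
exactly and recoverable downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import norm

from .errors import ConfigurationError, DegenerateSimulationError
from .occurrences import OccurrenceSet
from .raster import Raster, RasterStack

# geographic boxes the two ranges live in (lon_min, lon_max, lat_min, lat_max)
NATIVE_BOX = (0.0, 10.0, 0.0, 10.0)
INVADED_BOX = (20.0, 30.0, 0.0, 10.0)


def _env_columns(k: int) -> list[str]:
    return [f"env{i + 1}" for i in range(k)]


@dataclass
class BackgroundConfig:
    """Configuration of the paired range backgrounds."""

    n_points: int = 2000
    k: int = 2
    offset: float | np.ndarray = 0.0     # mean displacement of the invaded cloud
    spread: float | np.ndarray = 1.0     # per-axis standard deviation
    nonanalog_frac: float = 0.0          # invaded points forced outside the native envelope
    resolution: float | None = None      # raster cell size (lon/lat units), if gridded output wanted
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 10:
            raise ConfigurationError("n_points must be >= 10")
        if self.k < 2:
            raise ConfigurationError("dimension k must be >= 2")
        if not (0 <= self.nonanalog_frac < 1):
            raise ConfigurationError("nonanalog_frac must be in [0, 1)")
        if self.resolution is not None and self.resolution <= 0:
            raise ConfigurationError("raster resolution must be positive")
        self.offset = np.broadcast_to(
            np.asarray(self.offset, dtype=float), (self.k,)).copy()
        self.spread = np.broadcast_to(
            np.asarray(self.spread, dtype=float), (self.k,)).copy()
        if np.any(self.spread <= 0):
            raise ConfigurationError("spread must be positive on every axis")


@dataclass
class NicheTruth:
    """Ground-truth niche dynamics injected into a simulation."""

    centroid_native: np.ndarray
    centroid_shift: np.ndarray
    niche_sd: np.ndarray
    unfilling_frac: float = 0.0
    expansion_frac: float = 0.0
    n_native: int = 500
    n_invaded: int = 500
    seed: int = 0
    #: displacement of the secondary (expansion) kernel; default 2 x sd on axis 0
    expansion_offset: np.ndarray | None = None
    #: axis along which the unfilling slice is cut (lower tail excluded)
    unfilling_axis: int = 1

    def __post_init__(self) -> None:
        self.centroid_native = np.asarray(self.centroid_native, dtype=float)
        k = self.centroid_native.size
        self.centroid_shift = np.broadcast_to(
            np.asarray(self.centroid_shift, dtype=float), (k,)).copy()
        self.niche_sd = np.broadcast_to(
            np.asarray(self.niche_sd, dtype=float), (k,)).copy()
        if np.any(self.niche_sd <= 0):
            raise ConfigurationError("niche_sd must be positive on every axis")
        for name in ("unfilling_frac", "expansion_frac"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ConfigurationError(f"{name} must be in [0, 1)")
        if self.n_native <= 0 or self.n_invaded <= 0:
            raise ConfigurationError("occurrence counts must be positive")
        if self.expansion_offset is None:
            off = np.zeros(k)
            off[0] = 2.0 * self.niche_sd[0]
            self.expansion_offset = off
        else:
            self.expansion_offset = np.broadcast_to(
                np.asarray(self.expansion_offset, dtype=float), (k,)).copy()
        if not (0 <= self.unfilling_axis < k):
            raise ConfigurationError("unfilling_axis out of range")

    @property
    def centroid_invaded(self) -> np.ndarray:
        return self.centroid_native + self.centroid_shift

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "centroid_native": self.centroid_native.tolist(),
            "centroid_shift": self.centroid_shift.tolist(),
            "niche_sd": self.niche_sd.tolist(),
            "unfilling_frac": self.unfilling_frac,
            "expansion_frac": self.expansion_frac,
            "n_native": self.n_native,
            "n_invaded": self.n_invaded,
            "seed": self.seed,
            "expansion_offset": self.expansion_offset.tolist(),
            "unfilling_axis": self.unfilling_axis,
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "NicheTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            centroid_native=np.asarray(d["centroid_native"], dtype=float),
            centroid_shift=np.asarray(d["centroid_shift"], dtype=float),
            niche_sd=np.asarray(d["niche_sd"], dtype=float),
            unfilling_frac=d["unfilling_frac"],
            expansion_frac=d["expansion_frac"],
            n_native=d["n_native"],
            n_invaded=d["n_invaded"],
            seed=d["seed"],
            expansion_offset=np.asarray(d["expansion_offset"], dtype=float),
            unfilling_axis=d["unfilling_axis"],
        )


@dataclass
class Backgrounds:
    native: pd.DataFrame
    invaded: pd.DataFrame
    config: BackgroundConfig

    @property
    def variables(self) -> list[str]:
        return _env_columns(self.config.k)


def make_env_backgrounds(cfg: BackgroundConfig) -> Backgrounds:
    """Generate the two range backgrounds.

    The native cloud is centred at the origin.  The invaded cloud is offset by
    ``cfg.offset``; exactly round(nonanalog_frac * n) of its points are pushed
    outside the native per-axis envelope (along axis 0), and the remainder are
    resampled until they fall inside it, so the realised non-analogous
    fraction equals the target up to rounding.
    """
    rng = np.random.default_rng(cfg.seed)
    k, n = cfg.k, cfg.n_points
    native = rng.normal(0.0, cfg.spread, size=(n, k))
    lo, hi = native.min(axis=0), native.max(axis=0)

    invaded = rng.normal(cfg.offset, cfg.spread, size=(n, k))
    # resample points outside the native envelope until inside
    for _ in range(200):
        outside = ~np.all((invaded >= lo) & (invaded <= hi), axis=1)
        if not outside.any():
            break
        invaded[outside] = rng.normal(cfg.offset, cfg.spread,
                                      size=(int(outside.sum()), k))
    outside = ~np.all((invaded >= lo) & (invaded <= hi), axis=1)
    if outside.any():
        # stubborn points (offset far beyond the envelope): place uniformly inside
        margin = 0.01 * (hi - lo)
        invaded[outside] = rng.uniform(lo + margin, hi - margin,
                                       size=(int(outside.sum()), k))

    n_out = int(round(cfg.nonanalog_frac * n))
    if n_out:
        idx = rng.choice(n, size=n_out, replace=False)
        invaded[idx, 0] = hi[0] + rng.uniform(0.1, 1.0, size=n_out) * cfg.spread[0]

    cols = _env_columns(k)
    nat_df = pd.DataFrame(native, columns=cols)
    inv_df = pd.DataFrame(invaded, columns=cols)
    for df, box in ((nat_df, NATIVE_BOX), (inv_df, INVADED_BOX)):
        df["lon"] = rng.uniform(box[0], box[1], size=n)
        df["lat"] = rng.uniform(box[2], box[3], size=n)
    return Backgrounds(native=nat_df, invaded=inv_df, config=cfg)


@dataclass
class SpeciesSimulation:
    native: OccurrenceSet
    invaded: OccurrenceSet
    truth: NicheTruth
    backgrounds: Backgrounds = field(repr=False, default=None)


def _kernel_weights(points: np.ndarray, centroid: np.ndarray,
                    sd: np.ndarray) -> np.ndarray:
    u = (points - centroid) / sd
    return np.exp(-0.5 * (u * u).sum(axis=1))


def _support_mass(centroid: np.ndarray, sd: np.ndarray,
                  lo: np.ndarray, hi: np.ndarray) -> float:
    """Gaussian kernel mass inside the axis-aligned background envelope."""
    per_axis = norm.cdf((hi - centroid) / sd) - norm.cdf((lo - centroid) / sd)
    return float(np.prod(per_axis))


def _draw(rng: np.random.Generator, bg: pd.DataFrame, env: np.ndarray,
          weights: np.ndarray, n: int) -> pd.DataFrame:
    total = weights.sum()
    if total <= 0:
        raise DegenerateSimulationError("suitability kernel has no support mass")
    idx = rng.choice(len(bg), size=n, replace=True, p=weights / total)
    return bg.iloc[idx].reset_index(drop=True)


def simulate_species(truth: NicheTruth, backgrounds: Backgrounds,
                     species: str = "synthetic") -> SpeciesSimulation:
    """Draw native and invaded occurrence sets realising the given truth.

    Native occurrences follow the Gaussian kernel at the native centroid over
    the native background.  Invaded occurrences follow the shifted kernel with
    a lower-tail slice of mass ``unfilling_frac`` (along ``unfilling_axis``)
    excluded, and a share ``expansion_frac`` drawn from the displaced
    secondary kernel.
    """
    cols = backgrounds.variables
    rng = np.random.default_rng(truth.seed)
    nat_env = backgrounds.native[cols].to_numpy()
    inv_env = backgrounds.invaded[cols].to_numpy()

    for label, env, centroid in (
        ("native", nat_env, truth.centroid_native),
        ("invaded", inv_env, truth.centroid_invaded),
    ):
        mass = _support_mass(centroid, truth.niche_sd,
                             env.min(axis=0), env.max(axis=0))
        if mass < 0.01:
            raise DegenerateSimulationError(
                f"{label} kernel mass {mass:.2%} inside background support"
                " (>= 99% falls outside)"
            )

    nat_rows = _draw(rng, backgrounds.native, nat_env,
                     _kernel_weights(nat_env, truth.centroid_native, truth.niche_sd),
                     truth.n_native)

    c_inv = truth.centroid_invaded
    w_primary = _kernel_weights(inv_env, c_inv, truth.niche_sd)
    if truth.unfilling_frac > 0:
        a = truth.unfilling_axis
        cut = c_inv[a] + truth.niche_sd[a] * norm.ppf(truth.unfilling_frac)
        w_primary = np.where(inv_env[:, a] < cut, 0.0, w_primary)
    n_exp = int(round(truth.expansion_frac * truth.n_invaded))
    inv_parts = [_draw(rng, backgrounds.invaded, inv_env, w_primary,
                       truth.n_invaded - n_exp)]
    if n_exp:
        w_secondary = _kernel_weights(inv_env, c_inv + truth.expansion_offset,
                                      truth.niche_sd)
        inv_parts.append(_draw(rng, backgrounds.invaded, inv_env,
                               w_secondary, n_exp))
    inv_rows = pd.concat(inv_parts, ignore_index=True)

    native = OccurrenceSet(species=species, range_label="native", data=nat_rows)
    invaded = OccurrenceSet(species=species, range_label="invaded", data=inv_rows)
    return SpeciesSimulation(native=native, invaded=invaded, truth=truth,
                             backgrounds=backgrounds)


def make_raster_stack(background: pd.DataFrame, resolution: float,
                      variables: list[str] | None = None) -> RasterStack:
    """Rasterise a background point table onto a lon/lat grid, one layer per
    environmental variable, by nearest-neighbour lookup of the points."""
    if resolution <= 0:
        raise ConfigurationError("raster resolution must be positive")
    if variables is None:
        variables = [c for c in background.columns if c not in ("lon", "lat")]
    lon = background["lon"].to_numpy(dtype=float)
    lat = background["lat"].to_numpy(dtype=float)
    xll = lon.min() + resolution / 2
    yll = lat.min() + resolution / 2
    ncols = max(1, int(np.ceil((lon.max() - lon.min()) / resolution)))
    nrows = max(1, int(np.ceil((lat.max() - lat.min()) / resolution)))
    xs = xll + resolution * np.arange(ncols)
    ys = yll + resolution * (nrows - 1 - np.arange(nrows))
    xx, yy = np.meshgrid(xs, ys)
    tree = cKDTree(np.column_stack([lon, lat]))
    _, nearest = tree.query(np.column_stack([xx.ravel(), yy.ravel()]), k=1)
    layers = {}
    for v in variables:
        vals = background[v].to_numpy(dtype=float)[nearest].reshape(nrows, ncols)
        layers[v] = Raster(data=vals, xll=xll, yll=yll, cellsize=resolution)
    return RasterStack(layers=layers)
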