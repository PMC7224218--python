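"""Minimal raster container plus ESRI ASCII grid I/O.

ESRI ASCII grids are plain text, which keeps every artifact of the pipeline
human-readable and diffable.  Cells are registered by center (``xllcenter`` /
``yllcenter``); row 0 of ``data`` is the *top* row of the grid, following the
ASCII-grid convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import NicheShiftError

_DEFAULT_NODATA = -9999.0


@dataclass
class Raster:
    """A single-band raster with cell-center registration."""

    data: np.ndarray            # (nrows, ncols); row 0 = northernmost row
    xll: float                  # x of the lower-left cell *center*
    yll: float                  # y of the lower-left cell *center*
    cellsize: float
    nodata: float = _DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise NicheShiftError("raster data must be 2-D")
        if self.cellsize <= 0:
            raise NicheShiftError("cellsize must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask of nodata cells."""
        return ~np.isfinite(self.data) | (self.data == self.nodata)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of every cell center, row-major from the top row."""
        nrows, ncols = self.data.shape
        xs = self.xll + self.cellsize * np.arange(ncols)
        ys = self.yll + self.cellsize * (nrows - 1 - np.arange(nrows))
        xx, yy = np.meshgrid(xs, ys)
        return xx.ravel(), yy.ravel()

    def values(self) -> np.ndarray:
        """Flat cell values aligned with :meth:`cell_centers`, nodata as NaN."""
        out = self.data.astype(float).copy()
        out[self.mask] = np.nan
        return out.ravel()


@dataclass
class RasterStack:
    """Named co-registered raster layers."""

    layers: dict[str, Raster] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {r.shape for r in self.layers.values()}
        if len(shapes) > 1:
            raise NicheShiftError(f"raster layers disagree on shape: {shapes}")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def __getitem__(self, name: str) -> Raster:
        return self.layers[name]

    def __len__(self) -> int:
        return len(self.layers)

    def table(self, variables: list[str] | None = None) -> np.ndarray:
        """(n_cells, n_vars) matrix of cell values (NaN where nodata)."""
        names = variables if variables is not None else self.names
        missing = [v for v in names if v not in self.layers]
        if missing:
            raise NicheShiftError(f"missing raster layer(s): {missing}")
        return np.column_stack([self.layers[v].values() for v in names])

    def combined_mask(self) -> np.ndarray:
        """Cells that are nodata in any layer."""
        first = next(iter(self.layers.values()))
        out = np.zeros(first.shape, dtype=bool)
        for r in self.layers.values():
            out |= r.mask
        return out


def write_ascii_grid(raster: Raster, path: str | Path) -> None:
    nrows, ncols = raster.data.shape
    data = raster.data.copy()
    data[~np.isfinite(data)] = raster.nodata
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcenter {raster.xll!r}\n"
        f"yllcenter {raster.yll!r}\n"
        f"cellsize {raster.cellsize!r}\n"
        f"nodata_value {raster.nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, data, fmt="%.10g")


def read_ascii_grid(path: str | Path) -> Raster:
    meta: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcenter", "yllcenter", "xllcorner",
                "yllcorner", "cellsize", "nodata_value",
            }:
                meta[parts[0].lower()] = float(parts[1])
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        data = np.loadtxt(fh)
    if "ncols" not in meta or "nrows" not in meta:
        raise NicheShiftError(f"{path}: not an ESRI ASCII grid")
    data = np.atleast_2d(data)
    cellsize = meta["cellsize"]
    # corner registration -> center registration
    xll = meta.get("xllcenter", meta.get("xllcorner", 0.0) + cellsize / 2.0)
    yll = meta.get("yllcenter", meta.get("yllcorner", 0.0) + cellsize / 2.0)
    return Raster(data=data, xll=xll, yll=yll, cellsize=cellsize,
                  nodata=meta.get("nodata_value", _DEFAULT_NODATA))
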