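"""Occurrence records: the curated point data for one species in one range."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import NicheShiftError

REQUIRED_COLUMNS = ("species", "lon", "lat", "range_label")


@dataclass
class OccurrenceSet:
    """Point records for one species in one range, with optional pre-extracted
    environmental columns."""

    species: str
    range_label: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in ("lon", "lat") if c not in self.data.columns]
        if missing:
            raise NicheShiftError(f"occurrence table missing column(s): {missing}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def env_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in REQUIRED_COLUMNS]

    def env_values(self, variables: list[str] | None = None) -> np.ndarray:
        cols = variables if variables is not None else self.env_columns
        missing = [c for c in cols if c not in self.data.columns]
        if missing:
            raise NicheShiftError(f"occurrence table missing variable(s): {missing}")
        return self.data[cols].to_numpy(dtype=float)

    def to_frame(self) -> pd.DataFrame:
        out = self.data.copy()
        out.insert(0, "species", self.species)
        out.insert(3, "range_label", self.range_label)
        # drop duplicated metadata columns if data already carried them
        return out.loc[:, ~out.columns.duplicated()]


def read_occurrences(path: str | Path) -> OccurrenceSet:
    """Read an occurrence CSV (columns species,lon,lat,range_label,+env vars).

    Coordinates are validated row-by-row; malformed rows are reported with
    their 1-based line number (header = line 1).
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise NicheShiftError(f"{path}: empty occurrence file")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise NicheShiftError(f"{path}: missing required column(s): {missing}")
    lon = pd.to_numeric(df["lon"], errors="coerce")
    lat = pd.to_numeric(df["lat"], errors="coerce")
    bad = (
        lon.isna() | lat.isna()
        | (lon < -180) | (lon > 180) | (lat < -90) | (lat > 90)
    )
    if bad.any():
        lines = [int(i) + 2 for i in np.flatnonzero(bad.to_numpy())][:10]
        raise NicheShiftError(
            f"{path}: invalid coordinates at line(s) {lines}"
        )
    species = df["species"].iloc[0]
    range_label = df["range_label"].iloc[0]
    body = df.drop(columns=["species", "range_label"])
    body.insert(0, "lon", body.pop("lon"))
    body.insert(1, "lat", body.pop("lat"))
    return OccurrenceSet(species=str(species), range_label=str(range_label), data=body)


def write_occurrences(occ: OccurrenceSet, path: str | Path) -> None:
    occ.to_frame().to_csv(path, index=False, lineterminator="\r\n")
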