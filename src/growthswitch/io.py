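"""Tidy CSV readers and writers for all pipeline artifacts.

One canonical long format per artifact (one observation per row); vendor
plate-reader exports should be converted to the plate schema first.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import (
    LengthTrack, PLATE_COLUMNS, PRODUCTION_COLUMNS, PlateSeries,
    ProductionSeries,
)

__all__ = [
    "read_plate_csv", "write_plate_csv",
    "read_production_csv", "write_production_csv",
    "read_tracks_csv", "write_tracks_csv",
]

# pandas' default float formatting is the shortest round-trip repr, which is
# both deterministic and lossless
_FLOAT_FMT = None


class SchemaError(ValueError):
    """Input file does not match the expected tidy schema."""


def read_plate_csv(path) -> PlateSeries:
    """Read a tidy plate series (columns ``PLATE_COLUMNS``)."""
    df = pd.read_csv(path)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    dup = df.duplicated(subset=["well", "time_min"])
    if dup.any():
        rows = (df.index[dup] + 2).tolist()   # 1-based incl. header
        raise SchemaError(f"{path}: duplicate (well, time) at file rows {rows}")
    return PlateSeries(df)


def write_plate_csv(series: PlateSeries, path) -> None:
    series.df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_production_csv(path) -> list[ProductionSeries]:
    """Read production runs; one series per (strain, replicate)."""
    df = pd.read_csv(path)
    missing = [c for c in PRODUCTION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    out = []
    for (_, _), sub in df.groupby(["strain", "replicate"], sort=True):
        out.append(ProductionSeries(sub.reset_index(drop=True)))
    return out


def write_production_csv(series_list, path) -> None:
    if isinstance(series_list, ProductionSeries):
        series_list = [series_list]
    df = pd.concat([s.df for s in series_list], ignore_index=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_tracks_csv(path) -> list[LengthTrack]:
    """Read lineage tracks (columns cell_id, time_min, length_um)."""
    df = pd.read_csv(path)
    required = ["cell_id", "time_min", "length_um"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    tracks = []
    for cell_id, sub in df.groupby("cell_id", sort=True):
        sub = sub.sort_values("time_min")
        tracks.append(LengthTrack(
            str(cell_id),
            sub["time_min"].to_numpy(dtype=float),
            sub["length_um"].to_numpy(dtype=float),
        ))
    return tracks


def write_tracks_csv(tracks: list[LengthTrack], path,
                     division_log: pd.DataFrame | None = None,
                     log_path=None) -> None:
    rows = []
    for tr in tracks:
        for t, ln in zip(tr.times, tr.lengths):
            rows.append((tr.cell_id, t, ln))
    df = pd.DataFrame(rows, columns=["cell_id", "time_min", "length_um"])
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    if division_log is not None and log_path is not None:
        division_log.to_csv(log_path, index=False, float_format=_FLOAT_FMT)
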