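"""Occurrence gridding and predictor feature extraction.

Raw occurrence records (id, lon, lat) are collapsed onto unique grid cells of
the environment stack — the modelling unit — and feature rows are extracted
per cell for model training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import EmptyInputError
from .raster_io import EnvStack

logger = logging.getLogger(__name__)

__all__ = ["PresenceGrid", "FeatureTable", "grid_occurrences", "extract_features",
           "read_occurrences", "write_occurrences"]


@dataclass
class PresenceGrid:
    """Unique presence cells with per-cell raw record counts."""

    cells: list[tuple[int, int]]
    source_counts: dict[tuple[int, int], int]
    n_records: int = 0
    n_dropped_nodata: int = 0
    n_dropped_offgrid: int = 0

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def cell_set(self) -> set[tuple[int, int]]:
        return set(self.cells)


@dataclass
class FeatureTable:
    """Training matrix: one row per cell/point, named predictor columns, 0/1 label."""

    frame: pd.DataFrame  # predictor columns only
    labels: np.ndarray
    kinds: dict[str, str]
    ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.frame) != len(self.labels):
            raise ValueError("frame and labels length mismatch")
        if not self.ids:
            self.ids = list(range(len(self.frame)))

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def predictors(self) -> list[str]:
        return list(self.frame.columns)


def grid_occurrences(
    records: Sequence[tuple[float, float]], stack: EnvStack
) -> PresenceGrid:
    """Map occurrence coordinates to unique unmasked grid cells.

    Duplicate records in the same cell are collapsed (counts retained);
    records on nodata cells or outside the grid are dropped with a logged
    count — field coordinates are messy and a hard error would be hostile.
    """
    if len(records) == 0:
        raise EmptyInputError("no occurrence records supplied")
    ref = next(iter(stack.layers.values()))
    counts: dict[tuple[int, int], int] = {}
    off_grid = on_nodata = 0
    for x, y in records:
        cell = ref.point_to_cell(float(x), float(y))
        if cell is None:
            off_grid += 1
            continue
        if stack.joint_mask[cell]:
            on_nodata += 1
            continue
        counts[cell] = counts.get(cell, 0) + 1
    if off_grid:
        logger.warning("grid_occurrences: dropped %d off-grid records", off_grid)
    if on_nodata:
        logger.warning("grid_occurrences: dropped %d records on nodata cells", on_nodata)
    cells = sorted(counts)
    return PresenceGrid(
        cells=cells,
        source_counts=counts,
        n_records=len(records),
        n_dropped_nodata=on_nodata,
        n_dropped_offgrid=off_grid,
    )


def extract_features(
    cells: Sequence[tuple[int, int]], stack: EnvStack, label: int
) -> FeatureTable:
    """One feature row per (row, col) cell, carrying every stack layer's value.

    Cells hitting nodata on any layer are dropped and logged; it is an error
    only if nothing survives.
    """
    kept = []
    dropped = 0
    for cell in cells:
        if stack.joint_mask[tuple(cell)]:
            dropped += 1
        else:
            kept.append(tuple(cell))
    if dropped:
        logger.warning("extract_features: dropped %d nodata cells", dropped)
    if not kept:
        raise EmptyInputError("no valid cells to extract features from")
    arr = stack.cell_values(np.asarray(kept, dtype=int))
    frame = pd.DataFrame(arr, columns=stack.names)
    return FeatureTable(
        frame=frame,
        labels=np.full(len(kept), int(label)),
        kinds=dict(stack.kinds),
        ids=list(kept),
    )


def read_occurrences(path: str | Path) -> list[tuple[float, float]]:
    """Read an occurrence file: delimited text with header id,lon,lat."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    try:
        lon, lat = cols["lon"], cols["lat"]
    except KeyError:
        raise EmptyInputError(f"{path}: occurrence file needs 'lon' and 'lat' columns")
    return list(zip(df[lon].astype(float), df[lat].astype(float)))


def write_occurrences(points: Sequence[tuple[float, float]], path: str | Path) -> None:
    df = pd.DataFrame(points, columns=["lon", "lat"])
    df.insert(0, "id", [f"P{i + 1:03d}" for i in range(len(df))])
    df.to_csv(path, index=False)
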