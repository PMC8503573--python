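"""Natural-breaks classification and the suitability x quality overlay.

The final product is a small-integer map: habitat suitability and predicted
compound content are each min-max normalised, combined cell-wise (product by
default — a high-quality growing area must score high on both), and the
combined score is cut into k classes (default 4, class 1 = least suitable)
by exact Fisher-Jenks natural breaks, the 1-D partition minimising total
within-class sum of squared deviations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ClassificationError, AlignmentError, ConfigurationError, NormalizationError
from .raster_io import RasterGrid

logger = logging.getLogger(__name__)

__all__ = ["ClassifiedMap", "jenks_breaks", "classify_raster", "overlay_quality_suitability"]


@dataclass
class ClassifiedMap:
    """Integer class raster (1..k) with the break values that produced it."""

    classes: RasterGrid  # integer codes stored as floats; 1 = least suitable
    breaks: list[float]  # ascending; maximum value of classes 1..k-1
    k: int
    normalization: dict = field(default_factory=dict)  # min/max used per input layer

    def class_counts(self) -> dict[int, int]:
        vals = self.classes.values[~self.classes.mask].astype(int)
        return {int(c): int(n) for c, n in zip(*np.unique(vals, return_counts=True))}


def jenks_breaks(values, k: int) -> list[float]:
    """Exact Fisher-Jenks natural breaks.

    Dynamic programme over the sorted distinct values (with multiplicities)
    minimising total within-class sum of squared deviations from class means.
    Class boundaries never split tied values — classification is by value, so
    equal values must share a class.  Breaks are the maximum value of each of
    the first k-1 classes; ties in the DP are resolved toward the smaller
    lower class for determinism.
    """
    values = np.asarray(values, dtype=float).ravel()
    if k < 2:
        raise ClassificationError("k must be >= 2")
    distinct, counts = np.unique(values, return_counts=True)
    m = len(distinct)
    if m < k:
        raise ClassificationError(f"need >= {k} distinct values, got {m}")

    # prefix sums over distinct values weighted by multiplicity
    w = counts.astype(float)
    cw = np.concatenate([[0.0], np.cumsum(w)])
    cs = np.concatenate([[0.0], np.cumsum(w * distinct)])
    cs2 = np.concatenate([[0.0], np.cumsum(w * distinct**2)])

    def seg_cost(i: np.ndarray | int, j: int) -> np.ndarray | float:
        """SSD of distinct[i..j] inclusive (0-based), weighted by counts."""
        n = cw[j + 1] - cw[i]
        s = cs[j + 1] - cs[i]
        s2 = cs2[j + 1] - cs2[i]
        return s2 - s * s / n

    INF = np.inf
    # D[c][j]: min cost of splitting distinct[0..j] into c+1 classes
    D = np.full((k, m), INF)
    back = np.zeros((k, m), dtype=int)
    D[0, :] = np.array([seg_cost(0, j) for j in range(m)])
    for c in range(1, k):
        for j in range(c, m):
            starts = np.arange(c, j + 1)  # class c starts at distinct[start]
            costs = D[c - 1, starts - 1] + seg_cost(starts, j)
            i = int(np.argmin(costs))  # first minimum -> smallest lower class
            D[c, j] = costs[i]
            back[c, j] = starts[i]

    breaks: list[float] = []
    j = m - 1
    for c in range(k - 1, 0, -1):
        start = back[c, j]
        breaks.append(float(distinct[start - 1]))  # max of the class below
        j = start - 1
    breaks.reverse()
    return breaks


def classify_raster(grid: RasterGrid, breaks: list[float]) -> ClassifiedMap:
    """Assign class c = 1 + number of breaks strictly below the cell value.

    Breaks are class maxima: a value exactly equal to a break falls in the
    lower class.  Nodata propagates.
    """
    breaks = [float(b) for b in breaks]
    if any(b2 <= b1 for b1, b2 in zip(breaks, breaks[1:])):
        raise ConfigurationError(f"breaks must be strictly ascending, got {breaks}")
    k = len(breaks) + 1
    cls = np.ones(grid.values.shape)
    for b in breaks:
        cls += (grid.values > b).astype(float)
    classes = RasterGrid(header=grid.header, values=cls, mask=grid.mask.copy())
    return ClassifiedMap(classes=classes, breaks=breaks, k=k)


def _minmax(grid: RasterGrid, name: str) -> tuple[np.ndarray, float, float]:
    vals = grid.values[~grid.mask]
    lo, hi = float(vals.min()), float(vals.max())
    if hi <= lo:
        raise NormalizationError(f"layer {name!r} is constant; cannot min-max normalise")
    return (grid.values - lo) / (hi - lo), lo, hi


def overlay_quality_suitability(
    suitability: RasterGrid,
    quality: RasterGrid,
    k: int = 4,
    subsample: int = 10_000,
    seed: int = 0,
    combine: str = "product",
) -> ClassifiedMap:
    """Combine suitability and quality into a k-class growing-area map.

    Both layers are min-max normalised over unmasked cells and combined
    cell-wise (``product`` by default, ``min`` as the alternative
    intersection semantics).  Natural breaks are computed on the combined
    values — on a seeded random subsample of at most ``subsample`` cells when
    the raster is larger, since the exact DP is O(k n^2) — then applied to
    the full raster.
    """
    diff = suitability.header.same_georeference(quality.header)
    if diff:
        raise AlignmentError(f"suitability and quality differ on header field(s) {diff}")
    if combine not in ("product", "min"):
        raise ConfigurationError(f"combine must be 'product' or 'min', got {combine!r}")
    mask = suitability.mask | quality.mask
    s_norm, s_lo, s_hi = _minmax(suitability, "suitability")
    q_norm, q_lo, q_hi = _minmax(quality, "quality")
    combined = s_norm * q_norm if combine == "product" else np.minimum(s_norm, q_norm)
    combined_grid = RasterGrid(header=suitability.header, values=combined, mask=mask)

    vals = combined[~mask]
    if len(vals) > subsample:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        vals = rng.choice(vals, size=subsample, replace=False)
        logger.info("overlay: natural breaks computed on a %d-cell subsample", subsample)
    breaks = jenks_breaks(vals, k)
    out = classify_raster(combined_grid, breaks)
    out.normalization = {
        "suitability": {"min": s_lo, "max": s_hi},
        "quality": {"min": q_lo, "max": q_hi},
        "combine": combine,
    }
    return out
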