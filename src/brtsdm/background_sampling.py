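"""Rule-based background (pseudo-absence) screening and sampling.

Presence–background modelling needs contrast points.  Following the
cultivation literature for the target gentian, cells are deemed
environmentally unsuitable — hence eligible as background — when annual
precipitation falls outside the 250–400 mm band or elevation is below 800 m.
Each ensemble iteration draws a fresh equal-size background sample from the
eligible cells, excluding presence cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ConsistencyError, SamplingError
from .occurrence_processing import FeatureTable, PresenceGrid, extract_features
from .raster_io import EnvStack

logger = logging.getLogger(__name__)

__all__ = ["ScreeningRule", "screen_background_mask", "sample_background_points",
           "build_training_set"]


@dataclass(frozen=True)
class ScreeningRule:
    """Thresholds defining background-eligible (unsuitable) cells.

    A cell is eligible iff precip < precip_low OR precip > precip_high OR
    elev < elev_min — all strict inequalities, so cells exactly on a
    threshold are NOT eligible.
    """

    precip_layer: str = "precip"
    precip_low: float = 250.0
    precip_high: float = 400.0
    elev_layer: str = "elev"
    elev_min: float = 800.0

    def __post_init__(self) -> None:
        if not self.precip_low < self.precip_high:
            raise ConfigurationError(
                f"precip_low must be < precip_high, got {self.precip_low}, {self.precip_high}"
            )


def screen_background_mask(stack: EnvStack, rule: ScreeningRule) -> np.ndarray:
    """Boolean grid, True where a cell is background-eligible."""
    for name in (rule.precip_layer, rule.elev_layer):
        if name not in stack:
            raise ConfigurationError(f"screening rule references missing layer {name!r}")
    precip = stack[rule.precip_layer].values
    elev = stack[rule.elev_layer].values
    eligible = (precip < rule.precip_low) | (precip > rule.precip_high) | (elev < rule.elev_min)
    eligible &= ~stack.joint_mask
    return eligible


def sample_background_points(
    eligible: np.ndarray, n: int, exclude: PresenceGrid, seed: int
) -> list[tuple[int, int]]:
    """Draw n distinct eligible cells uniformly, excluding presence cells."""
    pool = eligible.copy()
    for r, c in exclude.cells:
        pool[r, c] = False
    rows, cols = np.nonzero(pool)
    available = len(rows)
    if available < n:
        raise SamplingError(
            f"need {n} background cells but only {available} are eligible "
            "after excluding presence cells"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    idx = rng.choice(available, size=n, replace=False)
    return [(int(rows[i]), int(cols[i])) for i in idx]


def build_training_set(
    presence: PresenceGrid, background: list[tuple[int, int]], stack: EnvStack
) -> FeatureTable:
    """Stack presence rows (label 1) on background rows (label 0).

    Row count is |presence| + |background|; with the study design of equal
    background size this doubles the presence-cell count.
    """
    overlap = presence.cell_set & set(background)
    if overlap:
        raise ConsistencyError(f"presence and background cells overlap: {sorted(overlap)[:5]}")
    pres = extract_features(presence.cells, stack, label=1)
    back = extract_features(background, stack, label=0)
    frame = pd.concat([pres.frame, back.frame], ignore_index=True)
    labels = np.concatenate([pres.labels, back.labels])
    return FeatureTable(frame=frame, labels=labels, kinds=dict(stack.kinds),
                        ids=pres.ids + back.ids)
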