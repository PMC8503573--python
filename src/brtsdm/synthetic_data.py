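"""Synthetic environments, occurrences and compound tables with known truth.

The study system is a presence–background habitat model for a medicinal
gentian driven by climate, terrain and soil rasters, plus linear
climate–compound relationships for its root iridoids.  This module generates
stand-in data with the same statistical structure so every downstream stage
(gridding, background screening, boosting, stepwise regression, overlay) can
be exercised and validated against a known truth function.

Layers are built as a smooth spatial gradient plus a moving-average-smoothed
Gaussian field (continuous) or nearest-seed Voronoi patches of integer codes
(categorical).  The true suitability surface combines a soft elevation
threshold, a precipitation plateau band and optional per-code categorical
effects through a logistic link.  All randomness flows from a single master
seed through `numpy.random.SeedSequence` spawning, one child stream per
layer / operation, so scenes are reproducible end to end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigurationError, SamplingError
from .raster_io import CATEGORICAL, CONTINUOUS, EnvStack, GridHeader, RasterGrid, build_stack

logger = logging.getLogger(__name__)

__all__ = [
    "LayerSpec",
    "TruthParams",
    "generate_env_stack",
    "compute_true_suitability",
    "sample_occurrences",
    "simulate_compound_contents",
    "demo_scene",
]


@dataclass(frozen=True)
class LayerSpec:
    """Recipe for one synthetic layer.

    Continuous layers: value = mean + gradient across the grid + smoothed
    Gaussian noise with standard deviation `sd`.  `gradient` is the total
    west->east and south->north change across the grid extent.  Categorical
    layers: `n_patches` Voronoi patches coded 1..n_patches.
    """

    name: str
    kind: str = CONTINUOUS
    mean: float = 0.0
    sd: float = 1.0
    gradient: tuple[float, float] = (0.0, 0.0)  # (west->east, south->north)
    smooth_window: int = 3
    n_patches: int = 5


@dataclass
class TruthParams:
    """Parameters of the known true-suitability function.

    suitability = logistic(logistic_scale * (s_elev + s_precip + s_cat))

    where each component score is centred so that it contributes 0 at its
    reference point and ranges over [-weight/2, +weight/2]:

    * s_elev rises smoothly with elevation and crosses 0 at
      ``elevation_threshold`` (softness ``elev_scale`` map units);
    * s_precip is maximal (+weight/2) on the plateau inside ``precip_band``
      and decays smoothly outside it (softness ``precip_scale``);
    * s_cat adds ``categorical_effects[code]`` for the soil-type layer.

    With all weights and categorical effects zero the surface is uniformly
    0.5 (logistic of 0) for any logistic_scale.
    """

    elevation_threshold: float = 1500.0
    precip_band: tuple[float, float] = (250.0, 400.0)
    logistic_scale: float = 6.0
    categorical_effects: dict[int, float] = field(default_factory=dict)
    seed: int = 0
    elev_layer: str = "elev"
    precip_layer: str = "precip"
    categorical_layer: str | None = None
    elev_scale: float = 250.0
    precip_scale: float = 60.0
    elev_weight: float = 1.0
    precip_weight: float = 1.0

    def __post_init__(self) -> None:
        low, high = self.precip_band
        if not low < high:
            raise ConfigurationError(f"precip_band must be (low, high), got {self.precip_band}")
        if not self.logistic_scale > 0:
            raise ConfigurationError("logistic_scale must be > 0")


def _logistic(z: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float)))


def generate_env_stack(
    header: GridHeader, specs: Sequence[LayerSpec], seed: int
) -> EnvStack:
    """Generate a stack of synthetic predictor layers; deterministic given seed."""
    if not specs:
        raise ConfigurationError("layer specification list is empty")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(specs))
    grids: dict[str, RasterGrid] = {}
    kinds: dict[str, str] = {}
    nrows, ncols = header.nrows, header.ncols
    # fractional position of cell centers across the extent, in [0, 1]
    xfrac = (np.arange(ncols) + 0.5) / ncols
    yfrac = (nrows - np.arange(nrows) - 0.5) / nrows  # row 0 = north
    XF, YF = np.meshgrid(xfrac, yfrac)

    for spec, child in zip(specs, children):
        rng = np.random.default_rng(child)
        if spec.kind == CONTINUOUS:
            gx, gy = spec.gradient
            base = spec.mean + gx * (XF - 0.5) + gy * (YF - 0.5)
            if spec.sd > 0:
                noise = rng.standard_normal((nrows, ncols))
                if spec.smooth_window > 1:
                    noise = ndimage.uniform_filter(noise, size=spec.smooth_window, mode="nearest")
                s = noise.std()
                if s > 0:
                    noise = noise * (spec.sd / s)
                base = base + noise
            values = base
        elif spec.kind == CATEGORICAL:
            k = spec.n_patches
            if k < 1:
                raise ConfigurationError(f"layer {spec.name!r}: n_patches must be >= 1")
            seeds_rc = rng.uniform(size=(k, 2)) * [nrows, ncols]
            R, C = np.meshgrid(np.arange(nrows) + 0.5, np.arange(ncols) + 0.5, indexing="ij")
            d2 = (R[..., None] - seeds_rc[:, 0]) ** 2 + (C[..., None] - seeds_rc[:, 1]) ** 2
            values = np.argmin(d2, axis=-1).astype(float) + 1.0
        else:
            raise ConfigurationError(f"layer {spec.name!r}: unknown kind {spec.kind!r}")
        grids[spec.name] = RasterGrid.from_array(values, header)
        kinds[spec.name] = spec.kind
    return build_stack(grids, kinds)


def compute_true_suitability(stack: EnvStack, params: TruthParams) -> RasterGrid:
    """Evaluate the true-suitability function on a stack; values in [0, 1]."""
    for name in (params.elev_layer, params.precip_layer):
        if name not in stack:
            raise ConfigurationError(f"truth function references missing layer {name!r}")
    elev = stack[params.elev_layer].values
    precip = stack[params.precip_layer].values

    s_elev = params.elev_weight * (
        _logistic((elev - params.elevation_threshold) / params.elev_scale) - 0.5
    )
    low, high = params.precip_band
    dist = np.maximum.reduce([low - precip, precip - high, np.zeros_like(precip)])
    plateau = np.exp(-((dist / params.precip_scale) ** 2))
    s_precip = params.precip_weight * (plateau - 0.5)

    s_cat = np.zeros_like(elev)
    if params.categorical_layer is not None:
        if params.categorical_layer not in stack:
            raise ConfigurationError(
                f"truth function references missing layer {params.categorical_layer!r}"
            )
        codes = stack[params.categorical_layer].values
        for code, eff in params.categorical_effects.items():
            s_cat[codes == code] = eff

    suit = _logistic(params.logistic_scale * (s_elev + s_precip + s_cat))
    mask = stack.joint_mask.copy()
    return RasterGrid(header=stack.header, values=suit, mask=mask)


def sample_occurrences(
    suitability: RasterGrid, n: int, seed: int
) -> list[tuple[float, float]]:
    """Draw n occurrence points with probability proportional to suitability.

    Cells are drawn with replacement (so downstream deduplication is
    exercised) and each point is jittered uniformly inside its cell.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows, cols = np.nonzero(~suitability.mask)
    weights = suitability.values[rows, cols].astype(float)
    weights = np.clip(weights, 0.0, None)
    total = weights.sum()
    if total <= 0:
        raise SamplingError("suitability is zero on every unmasked cell")
    idx = rng.choice(len(rows), size=n, replace=True, p=weights / total)
    h = suitability.header
    jit = rng.uniform(size=(n, 2))
    points = []
    for k, i in enumerate(idx):
        r, c = int(rows[i]), int(cols[i])
        x = h.xllcorner + (c + jit[k, 0]) * h.cellsize
        y = h.yllcorner + (h.nrows - r - 1 + jit[k, 1]) * h.cellsize
        points.append((float(x), float(y)))
    return points


def simulate_compound_contents(
    points: Sequence[tuple[float, float]],
    stack: EnvStack,
    equations: Sequence,
    noise_sd: dict[str, float],
    seed: int,
) -> pd.DataFrame:
    """Simulate a compound-content sample table at the given points.

    Each equation (see `quality_regression.RegressionEquation`) is evaluated
    at the point's cell predictor values and Gaussian noise with the
    compound's `noise_sd` is added.  Contents are clipped at zero from below
    (negative concentrations are not physical); clip events are logged.
    Points off the grid or on nodata cells are skipped with a logged count.
    Returns a table with columns id, lon, lat, one per compound, one per
    stack layer ("% dry mass" is assumed for contents).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    for eq in equations:
        for pred in eq.coefficients:
            if pred not in stack:
                raise ConfigurationError(
                    f"equation for {eq.response!r} uses missing layer {pred!r}"
                )
    ref = next(iter(stack.layers.values()))
    records = []
    skipped = 0
    clipped = 0
    for i, (x, y) in enumerate(points):
        cell = ref.point_to_cell(x, y)
        if cell is None or stack.joint_mask[cell]:
            skipped += 1
            continue
        r, c = cell
        env = {name: float(stack[name].values[r, c]) for name in stack.names}
        rec = {"id": f"S{i + 1:03d}", "lon": x, "lat": y}
        for eq in equations:
            content = eq.evaluate(env) + rng.normal(0.0, noise_sd.get(eq.response, 0.0))
            if content < 0:
                content = 0.0
                clipped += 1
            rec[eq.response] = content
        rec.update(env)
        records.append(rec)
    if skipped:
        logger.warning("simulate_compound_contents: skipped %d off-grid/nodata points", skipped)
    if clipped:
        logger.info("simulate_compound_contents: clipped %d negative contents to 0", clipped)
    return pd.DataFrame.from_records(records)


# -- canned demo scene ---------------------------------------------------------

def demo_scene(seed: int, size: int = 32, n_occurrences: int = 60, n_samples: int = 50):
    """A small, strong-signal scene used by the demo pipeline and the docs.

    Returns (stack, truth_suitability, occurrence_points, sample_table).
    The scene has a precipitation gradient spanning the suitable 250–400 mm
    band, an elevation gradient crossing both the 800 m background-screening
    floor and the 1500 m optimum, a temperature and a seasonality layer, and
    two categorical layers (soil type with mild effects, vegetation inert).
    """
    from .quality_regression import builtin_equations

    ss = np.random.SeedSequence(seed)
    s_stack, s_occ, s_chem = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3))
    header = GridHeader(ncols=size, nrows=size, xllcorner=0.0, yllcorner=0.0,
                        cellsize=1000.0)
    specs = [
        LayerSpec("precip", CONTINUOUS, mean=325.0, sd=15.0, gradient=(350.0, 0.0)),
        LayerSpec("elev", CONTINUOUS, mean=1400.0, sd=60.0, gradient=(0.0, 1800.0)),
        LayerSpec("bio1", CONTINUOUS, mean=6.0, sd=0.8, gradient=(0.0, -4.0)),
        LayerSpec("bio3", CONTINUOUS, mean=1300.0, sd=60.0, gradient=(150.0, 0.0)),
        LayerSpec("soil", CATEGORICAL, n_patches=5),
        LayerSpec("veg", CATEGORICAL, n_patches=4),
    ]
    stack = generate_env_stack(header, specs, seed=s_stack)
    params = TruthParams(
        elevation_threshold=1500.0,
        precip_band=(250.0, 400.0),
        logistic_scale=8.0,
        categorical_layer="soil",
        categorical_effects={1: 0.15, 2: -0.1},
        seed=seed,
    )
    truth = compute_true_suitability(stack, params)
    occ = sample_occurrences(truth, n_occurrences, seed=s_occ)
    # the published climate-compound equations serve as the generative truth,
    # remapped onto the scene's layer names (annual precipitation plays BIO4)
    eqs = _remap_equations(builtin_equations(), {"BIO1": "bio1", "BIO3": "bio3", "BIO4": "precip"})
    noise = calibrate_noise_sd(eqs, stack, target_r2=0.35)
    chem_points = sample_occurrences(truth, n_samples, seed=s_chem)
    samples = simulate_compound_contents(chem_points, stack, eqs, noise, seed=s_chem)
    return stack, truth, occ, samples


def calibrate_noise_sd(equations, stack: EnvStack, target_r2: float = 0.35) -> dict[str, float]:
    """Noise level per compound giving an expected population R^2 near target.

    With additive Gaussian noise, R^2 = var(signal) / (var(signal) + sd^2), so
    sd = signal_sd * sqrt((1 - R^2) / R^2).  Signal variance is taken over the
    stack's unmasked cells.
    """
    if not 0 < target_r2 < 1:
        raise ConfigurationError("target_r2 must be in (0, 1)")
    cells = stack.valid_cells()
    out = {}
    for eq in equations:
        names = list(eq.coefficients)
        vals = stack.cell_values(cells, names)
        signal = eq.intercept + vals @ np.array([eq.coefficients[n] for n in names])
        sd = float(signal.std() * np.sqrt((1.0 - target_r2) / target_r2))
        out[eq.response] = sd if sd > 0 else 1e-6
    return out


def _remap_equations(equations, mapping: dict[str, str]):
    from .quality_regression import RegressionEquation

    out = []
    for eq in equations:
        out.append(
            RegressionEquation(
                response=eq.response,
                intercept=eq.intercept,
                coefficients={mapping.get(k, k): v for k, v in eq.coefficients.items()},
                r_squared=eq.r_squared,
            )
        )
    return out
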