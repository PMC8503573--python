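"""Background-resampled BRT ensemble: suitability, uncertainty, RC, AUC.

The study design refits the boosted-trees model against a fresh random
background sample many times (200 in the full configuration) to wash out the
arbitrariness of any single background draw.  Cell-wise mean and standard
deviation of the per-iteration suitability rasters give the prediction and
its uncertainty; per-predictor relative contributions are averaged across
iterations; per-iteration model quality is the held-out cross-validated AUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import rankdata

from .background_sampling import (
    ScreeningRule,
    build_training_set,
    sample_background_points,
    screen_background_mask,
)
from .brt_core import FitConfig, cv_select_trees, fit_brt, predict_brt, relative_influence
from .errors import (
    ConfigurationError,
    EmptyInputError,
    EnsembleError,
    SamplingError,
    UndefinedStatisticError,
)
from .occurrence_processing import PresenceGrid
from .raster_io import EnvStack, RasterGrid

logger = logging.getLogger(__name__)

__all__ = ["EnsembleSummary", "MainFactorSelection", "run_ensemble", "auc",
           "select_main_factors", "group_rc"]


@dataclass
class EnsembleSummary:
    """Aggregated outputs of the background-resampled ensemble."""

    mean_suitability: RasterGrid
    sd_suitability: RasterGrid
    rc_table: dict[str, tuple[float, float]]  # predictor -> (mean %, sd %)
    auc_per_iteration: list[float]
    n_trees_per_iteration: list[int]
    n_iterations: int
    n_failed: int = 0

    @property
    def auc_mean(self) -> float:
        return float(np.mean(self.auc_per_iteration))

    @property
    def auc_sd(self) -> float:
        return float(np.std(self.auc_per_iteration))

    def rc_means(self) -> dict[str, float]:
        return {k: v[0] for k, v in self.rc_table.items()}


@dataclass
class MainFactorSelection:
    """Predictors above the RC threshold, in descending order of influence."""

    selected: list[str]
    rc_values: dict[str, float]
    cumulative_rc: float
    rc_threshold: float
    meets_main_factor_criterion: bool = field(default=False)  # cumulative > 95%


def auc(scores, labels) -> float:
    """Area under the ROC curve by the Mann-Whitney pair-counting statistic.

    Equals the fraction of (presence, background) pairs ranked correctly,
    ties counted 1/2, computed via midranks.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedStatisticError("AUC needs both classes present")
    ranks = rankdata(scores)  # midranks handle ties as half-wins
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def run_ensemble(
    presence: PresenceGrid,
    stack: EnvStack,
    rule: ScreeningRule,
    config: FitConfig,
    n_iterations: int = 200,
    seed: int = 0,
) -> EnsembleSummary:
    """Run the background-resampled BRT ensemble.

    Per iteration: a fresh seeded background draw of size |presence|, a
    2|presence|-row training set, cross-validated selection of the tree
    count, a final fit, and a full-raster prediction.  Aggregates cell-wise
    mean and population standard deviation, the per-iteration held-out AUC
    and the iteration-averaged RC table (renormalised to 100%).  Failed
    iterations are skipped and logged; more than 10% failures aborts.
    """
    if len(presence) == 0:
        raise EmptyInputError("presence grid is empty")
    if n_iterations < 1:
        raise ConfigurationError("n_iterations must be >= 1")
    eligible = screen_background_mask(stack, rule)
    n_pool = int(eligible.sum()) - len(presence.cell_set & set(map(tuple, np.argwhere(eligible))))
    if n_pool < len(presence):
        raise SamplingError(
            f"only {n_pool} background-eligible cells for {len(presence)} presence cells"
        )

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_iterations)
    shape = (stack.header.nrows, stack.header.ncols)
    acc = np.zeros(shape)
    acc2 = np.zeros(shape)
    rc_rows: list[dict[str, float]] = []
    aucs: list[float] = []
    n_trees_used: list[int] = []
    n_ok = 0
    n_failed = 0
    for i, child in enumerate(children):
        s_bg, s_fit = (int(c.generate_state(1)[0] % (2**31)) for c in child.spawn(2))
        try:
            background = sample_background_points(eligible, len(presence), presence, seed=s_bg)
            train = build_training_set(presence, background, stack)
            cfg = replace(config, seed=s_fit)
            cv = cv_select_trees(train, cfg)
            model = fit_brt(train, cfg, cv.n_trees_optimal)
            raster = predict_brt(model, stack)
            rc_rows.append(relative_influence(model))
            aucs.append(cv.cv_auc)
            n_trees_used.append(cv.n_trees_optimal)
        except Exception as exc:  # noqa: BLE001 - any stage failure skips the iteration
            n_failed += 1
            logger.warning("ensemble iteration %d failed: %s", i, exc)
            if n_failed > 0.1 * n_iterations:
                raise EnsembleError(
                    f"{n_failed} of {i + 1} iterations failed (> 10% of {n_iterations})"
                ) from exc
            continue
        acc += raster.values * ~raster.mask
        acc2 += raster.values**2 * ~raster.mask
        n_ok += 1

    mean = acc / n_ok
    var = np.maximum(acc2 / n_ok - mean**2, 0.0)
    mask = stack.joint_mask.copy()
    mean_grid = RasterGrid(header=stack.header, values=mean, mask=mask)
    sd_grid = RasterGrid(header=stack.header, values=np.sqrt(var), mask=mask.copy())

    names = stack.names
    rc_mat = np.array([[row.get(n, 0.0) for n in names] for row in rc_rows])
    rc_mean = rc_mat.mean(axis=0)
    rc_mean = rc_mean / rc_mean.sum() * 100.0
    rc_sd = rc_mat.std(axis=0)
    rc_table = {n: (float(m), float(s)) for n, m, s in zip(names, rc_mean, rc_sd)}

    return EnsembleSummary(
        mean_suitability=mean_grid,
        sd_suitability=sd_grid,
        rc_table=rc_table,
        auc_per_iteration=aucs,
        n_trees_per_iteration=n_trees_used,
        n_iterations=n_ok,
        n_failed=n_failed,
    )


def select_main_factors(
    rc_table: dict[str, float], rc_threshold: float = 2.0
) -> MainFactorSelection:
    """Predictors whose RC exceeds the threshold, descending by RC.

    ``meets_main_factor_criterion`` is set when the cumulative RC of the
    selection exceeds 95%, the study's bar for calling the selection the
    "main ecological factors".
    """
    if not rc_table:
        raise EmptyInputError("RC table is empty")
    if any(v < 0 for v in rc_table.values()):
        raise ConfigurationError("RC values must be non-negative")
    selected = sorted(
        (name for name, rc in rc_table.items() if rc > rc_threshold),
        key=lambda n: (-rc_table[n], n),
    )
    cumulative = float(sum(rc_table[n] for n in selected))
    return MainFactorSelection(
        selected=selected,
        rc_values={n: float(rc_table[n]) for n in selected},
        cumulative_rc=cumulative,
        rc_threshold=rc_threshold,
        meets_main_factor_criterion=cumulative > 95.0,
    )


def group_rc(rc_table: dict[str, float], groups: dict[str, str]) -> dict[str, float]:
    """Sum RC values by factor group (climatic, soil, terrain, ...)."""
    missing = [n for n in rc_table if n not in groups]
    if missing:
        raise ConfigurationError(f"predictors with no group assignment: {missing}")
    out: dict[str, float] = {}
    for name, rc in rc_table.items():
        out[groups[name]] = out.get(groups[name], 0.0) + rc
    return out
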