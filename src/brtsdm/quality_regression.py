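"""Stepwise climate-compound regressions and raster application.

Medicinal quality is proxied by root iridoid contents (swertiamarin,
gentiopicroside, sweroside, loganic acid, total iridoids) modelled as linear
functions of the main ecological factors via classic forward-entry /
backward-removal stepwise ordinary least squares.  Fitted (or externally
supplied) equations are then evaluated cell-wise over the environment stack
to produce compound-content rasters.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .errors import ConfigurationError, DegenerateFitError, EmptyInputError
from .raster_io import EnvStack, RasterGrid

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionEquation",
    "stepwise_regression",
    "partial_f_test",
    "apply_equation",
    "builtin_equations",
    "fit_compound_equations",
    "read_sample_table",
]

_RSS_TINY = 1e-12


@dataclass
class RegressionEquation:
    """A linear content model: intercept + sum(coefficient * predictor)."""

    response: str
    intercept: float
    coefficients: dict[str, float]
    r_squared: float | None = None
    n: int | None = None
    p_values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.r_squared is not None and not 0.0 <= self.r_squared <= 1.0:
            raise ConfigurationError(f"r_squared must be in [0, 1], got {self.r_squared}")

    @property
    def intercept_only(self) -> bool:
        return not self.coefficients

    def evaluate(self, values: Mapping[str, float]) -> float:
        return self.intercept + sum(c * float(values[p]) for p, c in self.coefficients.items())

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "r_squared": self.r_squared,
            "n": self.n,
            "p_values": dict(self.p_values),
        }


def partial_f_test(
    rss_reduced: float, rss_full: float, df_added: int, n: int, p_full: int
) -> tuple[float, float]:
    """Partial F statistic and p-value for adding df_added terms.

    F = ((RSS_reduced - RSS_full) / df_added) / (RSS_full / (n - p_full - 1)).
    A (near-)zero full-model RSS with a real reduction yields F = inf, p = 0.
    """
    df_resid = n - p_full - 1
    if df_added < 1 or df_resid < 1:
        raise ConfigurationError(
            f"non-positive degrees of freedom (df_added={df_added}, df_resid={df_resid})"
        )
    diff = rss_reduced - rss_full
    if diff < -1e-9 * max(1.0, rss_reduced):
        raise ConfigurationError("rss_reduced must be >= rss_full")
    diff = max(diff, 0.0)
    if rss_full <= _RSS_TINY:
        if diff <= _RSS_TINY:
            return 0.0, 1.0
        return float("inf"), 0.0
    F = (diff / df_added) / (rss_full / df_resid)
    p = float(f_dist.sf(F, df_added, df_resid))
    return float(F), p


def _ols(y: np.ndarray, cols: list[np.ndarray]) -> tuple[np.ndarray, float, int]:
    """OLS of y on [1, cols...]; returns (coefs incl. intercept, RSS, rank)."""
    X = np.column_stack([np.ones(len(y))] + cols)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid), int(rank)


def stepwise_regression(
    y: Sequence[float],
    X: pd.DataFrame,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> RegressionEquation:
    """Forward-entry / backward-removal stepwise OLS.

    At each round the candidate with the smallest partial-F p-value is added
    if p < p_enter, then any included term with drop-one p > p_remove is
    removed (largest p first); iteration stops when nothing changes.
    Perfectly collinear candidates are skipped with a log entry.
    """
    if p_enter > p_remove:
        raise ConfigurationError("p_enter must be <= p_remove (else the loop can cycle)")
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n != len(X):
        raise ConfigurationError("y and X length mismatch")
    if n <= len(X.columns) + 1:
        raise ConfigurationError(
            f"need n > candidates + 1 (n={n}, candidates={len(X.columns)})"
        )
    tss = float(((y - y.mean()) ** 2).sum())
    if tss <= _RSS_TINY:
        raise DegenerateFitError("response is constant")

    candidates = list(X.columns)
    cols = {c: X[c].to_numpy(dtype=float) for c in candidates}
    included: list[str] = []
    rss_current = tss

    for _ in range(10 * len(candidates) + 10):
        changed = False
        # forward entry
        best: tuple[float, str, float] | None = None  # (p, name, rss_new)
        for name in candidates:
            if name in included:
                continue
            trial = included + [name]
            _, rss_new, rank = _ols(y, [cols[c] for c in trial])
            if rank < len(trial) + 1:
                logger.info("stepwise: candidate %r is collinear with the model; skipped", name)
                continue
            _, p = partial_f_test(rss_current, rss_new, 1, n, len(trial))
            if best is None or p < best[0] - 1e-15 or (p == best[0] and name < best[1]):
                best = (p, name, rss_new)
        if best is not None and best[0] < p_enter:
            included.append(best[1])
            rss_current = best[2]
            changed = True
        # backward removal
        while len(included) > 0:
            worst: tuple[float, str, float] | None = None
            for name in included:
                reduced = [c for c in included if c != name]
                _, rss_red, _ = _ols(y, [cols[c] for c in reduced])
                _, p = partial_f_test(rss_red, rss_current, 1, n, len(included))
                if worst is None or p > worst[0]:
                    worst = (p, name, rss_red)
            if worst is not None and worst[0] > p_remove:
                included.remove(worst[1])
                rss_current = worst[2]
                changed = True
            else:
                break
        if not changed:
            break

    beta, rss, _ = _ols(y, [cols[c] for c in included])
    r2 = 1.0 - rss / tss
    p_values: dict[str, float] = {}
    for i, name in enumerate(included):
        reduced = [c for c in included if c != name]
        _, rss_red, _ = _ols(y, [cols[c] for c in reduced])
        _, p = partial_f_test(rss_red, rss, 1, n, len(included))
        p_values[name] = p
    return RegressionEquation(
        response=getattr(y, "name", "y") if hasattr(y, "name") else "y",
        intercept=float(beta[0]),
        coefficients={name: float(beta[i + 1]) for i, name in enumerate(included)},
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        n=n,
        p_values=p_values,
    )


def apply_equation(eq: RegressionEquation, stack: EnvStack) -> RasterGrid:
    """Evaluate a content equation cell-wise over the stack (grid calculator).

    Negative predicted contents are retained (the overlay normalises them
    away) but counted in the log, flagging extrapolation beyond the fitted
    range.
    """
    missing = [p for p in eq.coefficients if p not in stack]
    if missing:
        raise ConfigurationError(f"equation {eq.response!r} needs missing layer(s) {missing}")
    values = np.full((stack.header.nrows, stack.header.ncols), eq.intercept, dtype=float)
    for pred, coef in eq.coefficients.items():
        values += coef * stack[pred].values
    mask = stack.joint_mask.copy()
    n_neg = int((values[~mask] < 0).sum())
    if n_neg:
        logger.info("apply_equation[%s]: %d cells predict negative content", eq.response, n_neg)
    return RasterGrid(header=stack.header, values=values, mask=mask)


def builtin_equations() -> list[RegressionEquation]:
    """The five published climate-compound equations, with their reported R².

    Units convention (assumed, not stated with the equations): BIO1 in deg C,
    BIO3 dimensionless (sd x 100), BIO4 in mm, contents in % dry mass.
    """
    return [
        RegressionEquation("swertiamarin", 0.021, {"BIO1": 0.037, "BIO4": 0.001},
                           r_squared=0.365),
        RegressionEquation("gentiopicroside", -0.581, {"BIO1": 0.53, "BIO4": 0.021},
                           r_squared=0.327),
        RegressionEquation("sweroside", -0.05, {"BIO4": 0.000352}, r_squared=0.349),
        RegressionEquation("loganic_acid_and_gentiopicroside", 14.493,
                           {"BIO3": -0.01, "BIO4": 0.02}, r_squared=0.304),
        RegressionEquation("total_iridoids", -1.208, {"BIO1": 0.697, "BIO4": 0.032},
                           r_squared=0.336),
    ]


def fit_compound_equations(
    table: pd.DataFrame,
    compounds: Sequence[str],
    candidates: Sequence[str],
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> list[RegressionEquation]:
    """Stepwise-fit one equation per compound from a sample table."""
    missing = [c for c in list(compounds) + list(candidates) if c not in table.columns]
    if missing:
        raise ConfigurationError(f"sample table is missing columns {missing}")
    X = table[list(candidates)]
    out = []
    for compound in compounds:
        eq = stepwise_regression(table[compound].to_numpy(dtype=float), X,
                                 p_enter=p_enter, p_remove=p_remove)
        eq.response = compound
        out.append(eq)
    return out


def read_sample_table(path: str | Path) -> pd.DataFrame:
    """Read a compound sample table: delimited text, header id,lon,lat,<columns>."""
    df = pd.read_csv(path)
    if len(df) == 0:
        raise EmptyInputError(f"{path}: sample table is empty")
    return df


def equations_to_json(equations: Sequence[RegressionEquation]) -> str:
    return json.dumps([eq.to_dict() for eq in equations], indent=2)


def equations_from_json(text: str) -> list[RegressionEquation]:
    return [
        RegressionEquation(
            response=d["response"],
            intercept=float(d["intercept"]),
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            r_squared=d.get("r_squared"),
            n=d.get("n"),
            p_values=d.get("p_values", {}),
        )
        for d in json.loads(text)
    ]
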