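"""End-to-end orchestration: grid -> ensemble -> quality -> classify.

The pipeline is configured from a flat INI file, runs each stage in order,
writes every intermediate product to the output directory (stages are
re-runnable in isolation from those files) and emits a JSON run report that,
together with the config and master seed, fully determines the run.
"""

from __future__ import annotations

import configparser
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .background_sampling import ScreeningRule
from .brt_core import FitConfig
from .classification_overlay import overlay_quality_suitability
from .ensemble_evaluation import run_ensemble, select_main_factors
from .errors import ConfigurationError
from .occurrence_processing import grid_occurrences, read_occurrences
from .quality_regression import (
    apply_equation,
    builtin_equations,
    equations_to_json,
    fit_compound_equations,
    read_sample_table,
)
from .raster_io import CONTINUOUS, RasterGrid, read_manifest, write_asc

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]

_RESERVED_COLUMNS = {"id", "lon", "lat"}


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; mirrors the INI schema one-to-one."""

    # [paths]
    output_dir: Path
    stack_manifest: Path
    occurrences: Path
    samples: Path
    # [screening]
    rule: ScreeningRule = field(default_factory=ScreeningRule)
    # [brt]
    fit: FitConfig = field(default_factory=FitConfig)
    # [ensemble]
    n_iterations: int = 200
    rc_threshold: float = 2.0
    # [quality]
    equation_source: str = "fitted"  # or "builtin"
    compounds: list[str] | None = None
    p_enter: float = 0.05
    p_remove: float = 0.10
    # [classify]
    classes: int = 4
    combine: str = "product"
    subsample: int = 10_000
    # [run]
    seed: int = 0

    @classmethod
    def from_ini(cls, path: str | Path, **overrides) -> "PipelineConfig":
        cp = configparser.ConfigParser()
        read = cp.read(path)
        if not read:
            raise ConfigurationError(f"cannot read config file {path}")
        base = Path(path).parent

        def p(section: str, key: str) -> Path:
            raw = cp.get(section, key)
            q = Path(raw)
            return q if q.is_absolute() else base / q

        rule = ScreeningRule(
            precip_layer=cp.get("screening", "precip_layer", fallback="precip"),
            precip_low=cp.getfloat("screening", "precip_low", fallback=250.0),
            precip_high=cp.getfloat("screening", "precip_high", fallback=400.0),
            elev_layer=cp.get("screening", "elev_layer", fallback="elev"),
            elev_min=cp.getfloat("screening", "elev_min", fallback=800.0),
        )
        fit = FitConfig(
            tree_complexity=cp.getint("brt", "tree_complexity", fallback=4),
            learning_rate=cp.getfloat("brt", "learning_rate", fallback=0.005),
            bag_fraction=cp.getfloat("brt", "bag_fraction", fallback=0.75),
            step_size=cp.getint("brt", "step_size", fallback=10),
            n_folds=cp.getint("brt", "n_folds", fallback=10),
            max_trees=cp.getint("brt", "max_trees", fallback=10_000),
            min_obs_in_node=cp.getint("brt", "min_obs_in_node", fallback=10),
            patience=cp.getint("brt", "patience", fallback=5),
        )
        compounds_raw = cp.get("quality", "compounds", fallback="").strip()
        cfg = cls(
            output_dir=p("paths", "output_dir"),
            stack_manifest=p("paths", "stack_manifest"),
            occurrences=p("paths", "occurrences"),
            samples=p("paths", "samples"),
            rule=rule,
            fit=fit,
            n_iterations=cp.getint("ensemble", "n_iterations", fallback=200),
            rc_threshold=cp.getfloat("ensemble", "rc_threshold", fallback=2.0),
            equation_source=cp.get("quality", "equations", fallback="fitted"),
            compounds=[c.strip() for c in compounds_raw.split(",") if c.strip()] or None,
            p_enter=cp.getfloat("quality", "p_enter", fallback=0.05),
            p_remove=cp.getfloat("quality", "p_remove", fallback=0.10),
            classes=cp.getint("classify", "classes", fallback=4),
            combine=cp.get("classify", "combine", fallback="product"),
            subsample=cp.getint("classify", "subsample", fallback=10_000),
            seed=cp.getint("run", "seed", fallback=0),
        )
        for key, value in overrides.items():
            if value is not None:
                setattr(cfg, key, value)
        return cfg

    def validate(self) -> None:
        for name in ("stack_manifest", "occurrences"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise ConfigurationError(f"{name} does not exist: {path}")
        if self.equation_source not in ("fitted", "builtin"):
            raise ConfigurationError(
                f"quality equations must be 'fitted' or 'builtin', got {self.equation_source!r}"
            )
        if self.equation_source == "fitted" and not Path(self.samples).exists():
            raise ConfigurationError(f"samples file does not exist: {self.samples}")

    def echo(self) -> dict:
        d = {
            "output_dir": str(self.output_dir),
            "stack_manifest": str(self.stack_manifest),
            "occurrences": str(self.occurrences),
            "samples": str(self.samples),
            "screening": vars(self.rule).copy() if hasattr(self.rule, "__dict__")
            else {k: getattr(self.rule, k) for k in
                  ("precip_layer", "precip_low", "precip_high", "elev_layer", "elev_min")},
            "brt": {k: getattr(self.fit, k) for k in
                    ("tree_complexity", "learning_rate", "bag_fraction", "step_size",
                     "n_folds", "max_trees", "min_obs_in_node", "patience")},
            "n_iterations": self.n_iterations,
            "rc_threshold": self.rc_threshold,
            "equation_source": self.equation_source,
            "compounds": self.compounds,
            "classes": self.classes,
            "combine": self.combine,
            "subsample": self.subsample,
            "seed": self.seed,
        }
        return d


@dataclass
class RunReport:
    """Everything needed to audit and reproduce a run."""

    config: dict
    seed: int
    counts: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)
    auc_mean: float = float("nan")
    auc_sd: float = float("nan")
    auc_per_iteration: list[float] = field(default_factory=list)
    n_trees_per_iteration: list[int] = field(default_factory=list)
    n_iterations: int = 0
    rc_table: dict = field(default_factory=dict)
    selected_factors: list[str] = field(default_factory=list)
    selected_rc: dict = field(default_factory=dict)
    cumulative_rc: float = 0.0
    equations: list[dict] = field(default_factory=list)
    breaks: list[float] = field(default_factory=list)
    class_counts: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    outputs: dict = field(default_factory=dict)

    def to_json(self, deterministic: bool = False) -> str:
        d = {k: v for k, v in self.__dict__.items()}
        if deterministic:
            d.pop("timings_s", None)
        return json.dumps(d, indent=2, default=str)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def _minmax01(grid: RasterGrid) -> np.ndarray:
    vals = grid.values[~grid.mask]
    lo, hi = vals.min(), vals.max()
    if hi <= lo:
        raise ConfigurationError("constant compound layer cannot be normalised")
    return (grid.values - lo) / (hi - lo)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages, writing rasters/tables/report to the output dir."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config.echo(), seed=config.seed)
    t0 = time.perf_counter()

    def tick(stage: str, start: float) -> None:
        report.timings_s[stage] = round(time.perf_counter() - start, 3)

    # -- load stack -----------------------------------------------------------
    t = time.perf_counter()
    stack = read_manifest(config.stack_manifest)
    tick("load_stack", t)

    # -- grid occurrences -----------------------------------------------------
    t = time.perf_counter()
    records = read_occurrences(config.occurrences)
    presence = grid_occurrences(records, stack)
    report.counts.update(
        n_occurrence_records=presence.n_records,
        n_presence_cells=len(presence),
        n_dropped_offgrid=presence.n_dropped_offgrid,
        n_dropped_nodata=presence.n_dropped_nodata,
    )
    if presence.n_dropped_offgrid or presence.n_dropped_nodata:
        report.warnings.append(
            f"dropped {presence.n_dropped_offgrid} off-grid and "
            f"{presence.n_dropped_nodata} nodata occurrence records"
        )
    pd.DataFrame(presence.cells, columns=["row", "col"]).to_csv(
        out / "presence_cells.csv", index=False
    )
    report.outputs["presence_cells"] = "presence_cells.csv"
    tick("grid_occurrences", t)

    # -- ensemble -------------------------------------------------------------
    t = time.perf_counter()
    fit = FitConfig(**{**{k: getattr(config.fit, k) for k in
                          ("tree_complexity", "learning_rate", "bag_fraction", "step_size",
                           "n_folds", "max_trees", "min_obs_in_node", "patience")},
                       "seed": config.seed})
    summary = run_ensemble(
        presence, stack, config.rule, fit,
        n_iterations=config.n_iterations, seed=config.seed,
    )
    write_asc(summary.mean_suitability, out / "mean_suitability.asc")
    write_asc(summary.sd_suitability, out / "sd_suitability.asc")
    rc_df = pd.DataFrame(
        [(n, m, s) for n, (m, s) in summary.rc_table.items()],
        columns=["predictor", "rc_mean_pct", "rc_sd_pct"],
    )
    rc_df.to_csv(out / "rc_table.csv", index=False)
    pd.DataFrame({"iteration": range(len(summary.auc_per_iteration)),
                  "cv_auc": summary.auc_per_iteration,
                  "n_trees": summary.n_trees_per_iteration}).to_csv(
        out / "auc_per_iteration.csv", index=False)
    report.outputs.update(mean_suitability="mean_suitability.asc",
                          sd_suitability="sd_suitability.asc",
                          rc_table="rc_table.csv",
                          auc_per_iteration="auc_per_iteration.csv")
    report.auc_mean = summary.auc_mean
    report.auc_sd = summary.auc_sd
    report.auc_per_iteration = summary.auc_per_iteration
    report.n_trees_per_iteration = summary.n_trees_per_iteration
    report.n_iterations = summary.n_iterations
    report.rc_table = {n: {"mean": m, "sd": s} for n, (m, s) in summary.rc_table.items()}
    if summary.n_failed:
        report.warnings.append(f"{summary.n_failed} ensemble iterations failed and were skipped")
    tick("ensemble", t)

    # -- main factors ---------------------------------------------------------
    selection = select_main_factors(summary.rc_means(), config.rc_threshold)
    report.selected_factors = selection.selected
    report.selected_rc = selection.rc_values
    report.cumulative_rc = selection.cumulative_rc

    # -- quality regressions --------------------------------------------------
    t = time.perf_counter()
    if config.equation_source == "builtin":
        equations = builtin_equations()
    else:
        table = read_sample_table(config.samples)
        candidates = [
            n for n in selection.selected
            if stack.kinds.get(n) == CONTINUOUS and n in table.columns
        ]
        if not candidates:
            raise ConfigurationError(
                "no continuous main factor is available as a sample-table column"
            )
        compounds = config.compounds or [
            c for c in table.columns if c not in _RESERVED_COLUMNS and c not in stack.names
        ]
        equations = fit_compound_equations(table, compounds, candidates,
                                           p_enter=config.p_enter, p_remove=config.p_remove)
    report.equations = [eq.to_dict() for eq in equations]
    (out / "equations.json").write_text(equations_to_json(equations) + "\n")
    report.outputs["equations"] = "equations.json"

    compound_grids = []
    n_negative = 0
    for eq in equations:
        usable = all(p in stack for p in eq.coefficients)
        if not usable or eq.intercept_only:
            report.warnings.append(
                f"equation for {eq.response} not mappable (intercept-only or missing layers)"
            )
            continue
        grid = apply_equation(eq, stack)
        n_negative += int((grid.values[~grid.mask] < 0).sum())
        write_asc(grid, out / f"content_{eq.response}.asc")
        report.outputs[f"content_{eq.response}"] = f"content_{eq.response}.asc"
        compound_grids.append(grid)
    if not compound_grids:
        raise ConfigurationError("no compound equation could be mapped onto the stack")
    if n_negative:
        report.warnings.append(f"{n_negative} cell predictions of negative content (kept)")
    quality_vals = np.mean([_minmax01(g) for g in compound_grids], axis=0)
    quality = RasterGrid(header=stack.header, values=quality_vals,
                         mask=stack.joint_mask.copy())
    write_asc(quality, out / "quality.asc")
    report.outputs["quality"] = "quality.asc"
    tick("quality", t)

    # -- classification overlay ----------------------------------------------
    t = time.perf_counter()
    classified = overlay_quality_suitability(
        summary.mean_suitability, quality,
        k=config.classes, subsample=config.subsample, seed=config.seed,
        combine=config.combine,
    )
    write_asc(classified.classes, out / "growing_area_classes.asc")
    sidecar = {"breaks": classified.breaks, "k": classified.k,
               "normalization": classified.normalization,
               "class_counts": classified.class_counts()}
    (out / "growing_area_classes.json").write_text(json.dumps(sidecar, indent=2) + "\n")
    report.outputs["classes"] = "growing_area_classes.asc"
    report.outputs["classes_sidecar"] = "growing_area_classes.json"
    report.breaks = classified.breaks
    report.class_counts = {str(k): v for k, v in classified.class_counts().items()}
    tick("classify", t)

    report.timings_s["total"] = round(time.perf_counter() - t0, 3)
    report.write(out / "report.json")
    report.outputs["report"] = "report.json"
    logger.info("pipeline complete: %d iterations, AUC %.3f +/- %.3f",
                report.n_iterations, report.auc_mean, report.auc_sd)
    return report
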