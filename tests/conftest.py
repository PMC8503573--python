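import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from brtsdm import (
    EnvStack,
    GridHeader,
    RasterGrid,
    build_stack,
    demo_scene,
)
from brtsdm.occurrence_processing import FeatureTable

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def header8() -> GridHeader:
    return GridHeader(ncols=8, nrows=8, xllcorner=100.0, yllcorner=40.0, cellsize=0.5)


@pytest.fixture
def tiny_stack(header8) -> EnvStack:
    """Deterministic 8x8 stack: precip/elev gradients plus a categorical layer."""
    rows, cols = np.meshgrid(np.arange(8), np.arange(8), indexing="ij")
    precip = 150.0 + 40.0 * cols  # 150..430 west->east
    elev = 400.0 + 250.0 * (7 - rows)  # 400..2150 south->north (row 0 = north)
    soil = (cols % 3 + 1).astype(float)
    grids = {
        "precip": RasterGrid.from_array(precip, header8),
        "elev": RasterGrid.from_array(elev, header8),
        "soil": RasterGrid.from_array(soil, header8),
    }
    return build_stack(grids, {"precip": "continuous", "elev": "continuous",
                               "soil": "categorical"})


def make_feature_table(X: np.ndarray, y, names=None, kinds=None) -> FeatureTable:
    names = names or [f"x{j}" for j in range(X.shape[1])]
    frame = pd.DataFrame(np.asarray(X, dtype=float), columns=names)
    return FeatureTable(frame=frame, labels=np.asarray(y, dtype=int),
                        kinds=kinds or {n: "continuous" for n in names})


@pytest.fixture(scope="session")
def demo() -> tuple:
    """The strong-signal demo scene used by the scaled-down study design."""
    return demo_scene(42, size=32, n_occurrences=60, n_samples=50)


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One full demo-scale pipeline run (10 ensemble iterations, seed 42)."""
    from brtsdm.pipeline import PipelineConfig, run_pipeline
    from brtsdm.raster_io import write_stack
    from brtsdm.occurrence_processing import write_occurrences

    base = tmp_path_factory.mktemp("demo_run")
    scene = base / "scene"
    stack, truth, occ, samples = demo_scene(42, size=32, n_occurrences=60, n_samples=50)
    manifest = write_stack(stack, scene)
    write_occurrences(occ, scene / "occurrences.csv")
    samples.to_csv(scene / "samples.csv", index=False)
    cfg = PipelineConfig(
        output_dir=base / "out",
        stack_manifest=manifest,
        occurrences=scene / "occurrences.csv",
        samples=scene / "samples.csv",
        n_iterations=10,
        seed=42,
    )
    cfg.fit = type(cfg.fit)(max_trees=300)
    report = run_pipeline(cfg)
    return cfg, report
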