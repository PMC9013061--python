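import numpy as np
import pytest

from msirecal.pipeline import PipelineConfig, run_pipeline
from msirecal.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def orbitrap_small():
    """A 20x20 Orbitrap-like acquisition with 5 ppm sine drift, fully recalibrated.

    Shared across modules to keep the suite fast; tests must not mutate it.
    """
    cfg = SimulationConfig(n_rows=20, n_cols=20, seed=1)
    dataset, roi, truth = simulate_dataset(cfg)
    result = run_pipeline(dataset, roi, cfg.reference_mz, PipelineConfig(seed=1))
    return cfg, dataset, roi, truth, result


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
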