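import warnings

import numpy as np
import pytest

from hlafinemap.pipeline_io import PipelineConfig, run_pipeline, simulate_to_dir
from hlafinemap.synthetic_cohorts import build_default_scenario

warnings.filterwarnings("ignore", category=RuntimeWarning)

SEED = 1


@pytest.fixture(scope="session")
def default_scenario():
    return build_default_scenario(seed=SEED)


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory, default_scenario):
    """Default three-cohort simulation persisted to disk (shared across tests)."""
    region, specs = default_scenario
    path = tmp_path_factory.mktemp("simdefault")
    cohorts = simulate_to_dir(region, specs, path)
    return path, cohorts


@pytest.fixture(scope="session")
def pipeline_report(tmp_path_factory, sim_dir):
    """One full pipeline run on the shared default simulation."""
    path, _cohorts = sim_dir
    out = tmp_path_factory.mktemp("pipeout")
    return run_pipeline(PipelineConfig(seed=SEED, input_dir=str(path), outdir=str(out)))


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
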