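import numpy as np
import pytest

from postfire_mca.pipeline import load_inputs
from postfire_mca.raster import Raster
from postfire_mca.synthgen import (
    SyntheticScenario,
    build_truth,
    write_scenario_inputs,
)


@pytest.fixture(scope="session")
def default_scenario():
    return SyntheticScenario(seed=7)


@pytest.fixture(scope="session")
def truth(default_scenario):
    """Full in-memory synthetic scenario with true composite maps."""
    return build_truth(default_scenario)


@pytest.fixture(scope="session")
def input_dir(tmp_path_factory, default_scenario):
    """An on-disk input directory for pipeline-level tests."""
    d = tmp_path_factory.mktemp("scenario_inputs")
    write_scenario_inputs(default_scenario, d)
    return d


@pytest.fixture(scope="session")
def loaded_inputs(input_dir):
    return load_inputs(input_dir)


@pytest.fixture
def small_raster():
    """4x4 grid, 10 m cells, NW origin at (0, 40)."""
    return Raster(data=np.arange(16, dtype=float).reshape(4, 4),
                  west=0.0, north=40.0, cellsize=10.0)
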