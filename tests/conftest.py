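import numpy as np
import pytest

from parasdm import GridLayer, default_template, generate_env_layers, make_study_system


@pytest.fixture
def template():
    return default_template(20, 20)


@pytest.fixture
def env_layers(template):
    return generate_env_layers(template, 3, smoothness=3.0, seed=11)


@pytest.fixture(scope="session")
def study_system():
    """Canonical synthetic host-parasite system on a 100x100 grid."""
    return make_study_system(seed=5)


def make_layer(values, kind="continuous", cellsize=0.5, xll=0.0, yll=0.0, name=""):
    values = np.asarray(values, dtype=float)
    return GridLayer(values.shape[0], values.shape[1], xll, yll, cellsize,
                     values=values, kind=kind, name=name)


@pytest.fixture
def make_grid():
    return make_layer
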