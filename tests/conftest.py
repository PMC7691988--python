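import numpy as np
import pytest

from nucyto import CellSimParams, MicropatternSpec

DEFAULT_CHANNELS = {"dna": "dna", "cell": "actin", "marker": "marker"}


@pytest.fixture
def square_spec() -> MicropatternSpec:
    return MicropatternSpec("square", 1200)


@pytest.fixture
def rect5_spec() -> MicropatternSpec:
    return MicropatternSpec("rectangle", 1200, aspect_ratio=5)


@pytest.fixture
def noiseless_params() -> CellSimParams:
    return CellSimParams(shot_noise=False, read_noise_sigma=0.0, seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
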