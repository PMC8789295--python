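import numpy as np
import pytest

from overflowsel import DropletDesign, ModelParameters, droplet_glucose_mol


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    """Default (literature) parameter set with one droplet's glucose."""
    return ModelParameters()


@pytest.fixture(scope="session")
def droplet_glc() -> float:
    return droplet_glucose_mol()


@pytest.fixture(scope="session")
def design() -> DropletDesign:
    return DropletDesign(n_droplets=30_000)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
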