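import numpy as np
import pytest
from hypothesis import settings

from veqr.label_store import default_chest_scheme
from veqr.phantoms import PhantomSpec, generate_phantom

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scheme():
    return default_chest_scheme()


@pytest.fixture(scope="session")
def full_phantom(scheme):
    """One full multi-organ phantom (64^3, seed 3) shared across tests."""
    lm, truth = generate_phantom(PhantomSpec(seed=3), scheme)
    return lm, truth


@pytest.fixture()
def lung_mask(full_phantom):
    return full_phantom[1]["lung"]


def random_mask(rng: np.random.Generator, shape, p=0.3) -> np.ndarray:
    return rng.random(shape) < p
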