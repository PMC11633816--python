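import numpy as np
import pytest

from segsense.phantoms import PhantomSpec, generate_cohort, generate_phantom


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    return PhantomSpec(seed=7)


@pytest.fixture(scope="session")
def phantom_volume(default_spec):
    return generate_phantom(default_spec, 0)


@pytest.fixture(scope="session")
def small_cohort():
    """Three tiny patients — enough for LOO plumbing tests."""
    spec = PhantomSpec(n_patients=3, slices_per_patient=(2, 3), slice_size=48, seed=11)
    return generate_cohort(spec)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_softmax(rng: np.random.Generator, n_pixels: int, n_classes: int) -> np.ndarray:
    """Random valid probability map (rows sum to 1)."""
    z = rng.normal(size=(n_pixels, n_classes))
    e = np.exp(z - z.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def random_onehot(rng: np.random.Generator, n_pixels: int, n_classes: int) -> np.ndarray:
    labels = rng.integers(0, n_classes, n_pixels)
    return np.eye(n_classes)[labels]
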