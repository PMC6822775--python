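import numpy as np
import pytest

from phydca.profiles import ProfileMatrix
from phydca.simulate import exact_distribution, make_planted_model


@pytest.fixture
def tiny_ppm() -> ProfileMatrix:
    """2 genomes x 2 domains: g1 has both domains, g2 only dA."""
    return ProfileMatrix(("g1", "g2"), ("dA", "dB"),
                         np.array([[1, 1], [1, 0]], dtype=np.uint8))


@pytest.fixture
def random_ppm() -> ProfileMatrix:
    rng = np.random.default_rng(123)
    entries = (rng.random((100, 10)) < rng.uniform(0.2, 0.8, 10)).astype(np.uint8)
    species = tuple(f"g{a:03d}" for a in range(100))
    domains = tuple(f"d{i:02d}" for i in range(10))
    return ProfileMatrix(species, domains, entries)


@pytest.fixture(scope="session")
def planted4():
    """Small planted model with its exhaustive state table.

    Returns (model, states, probabilities, ppm) where ppm lists all 2^4
    states once; combined with the probabilities as row weights this is a
    sampling-noise-free data set for the model.
    """
    model = make_planted_model(4, 2, 1, J_scale=1.0, h_range=(-0.5, 0.5),
                               seed=3)
    states, probs = exact_distribution(model)
    ppm = ProfileMatrix(tuple(f"s{k:02d}" for k in range(len(states))),
                        model.domain_ids(), states.astype(np.uint8))
    return model, states, probs, ppm
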