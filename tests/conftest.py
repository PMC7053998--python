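import numpy as np
import pytest

from melodytrf.markov import generate_melody, random_markov_spec


@pytest.fixture(scope="session")
def small_spec():
    """Order-1 source over 6 pitches and 3 IOI classes."""
    return random_markov_spec(n_pitches=6, n_iois=3, order=1, seed=11)


@pytest.fixture(scope="session")
def small_melody(small_spec):
    return generate_melody(small_spec, 120, seed=21, piece_id="fixture")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
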