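import numpy as np
import pytest

import srk
from srk.inverse import build_leadfield
from srk.preprocess import channel_subset_indices


@pytest.fixture(scope="session")
def montage():
    return srk.make_montage()


@pytest.fixture(scope="session")
def characterization_leadfield(montage):
    """The 33-electrode / 660-source spherical lead field of the mapping path."""
    keep = channel_subset_indices(montage.labels)
    labels = tuple(montage.labels[i] for i in keep)
    return build_leadfield(montage.positions[keep], labels, n_sources=660, seed=1)


@pytest.fixture(scope="session")
def effect_session():
    """One synthetic session with the default Knowledge-only planted effects.

    Shared across test modules (simulation is the expensive step); tests
    must not mutate it.
    """
    from srk.simulate import SimulationConfig, knowledge_effect_map, simulate_session

    cfg = SimulationConfig(seed=101, effect_map=knowledge_effect_map(1.5))
    return simulate_session(cfg)


@pytest.fixture(scope="session")
def null_session():
    """A zero-effect synthetic session (artifact rates at defaults)."""
    from srk.simulate import SimulationConfig, simulate_session

    return simulate_session(SimulationConfig(seed=202))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
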