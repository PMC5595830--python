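import numpy as np
import pytest

from actiflow.synthetic import (
    MarkovChainSpec,
    ToyComplexSpec,
    build_toy_complex,
    crystal_fragment,
    simulate_markov_chain,
)

ALL_ARCHETYPE_PLACEMENTS = [
    ("apolar", 4.4),
    ("aromatic_face", 3.8),
    ("aromatic_edge", 3.8),
    ("hbond_donor", 2.9),
    ("hbond_acceptor", 2.9),
    ("electrostatic_positive", 3.8),
    ("electrostatic_negative", 3.8),
]


@pytest.fixture(scope="session")
def inactive_fragment():
    return crystal_fragment("inactive")


@pytest.fixture(scope="session")
def active_fragment():
    return crystal_fragment("active")


@pytest.fixture(scope="session")
def full_toy_complex():
    return build_toy_complex(ToyComplexSpec(ALL_ARCHETYPE_PLACEMENTS))


@pytest.fixture(scope="session")
def two_state_trajectory():
    """Long trajectory of the standard 2-state chain T=[[.9,.1],[.2,.8]]."""
    T = np.array([[0.9, 0.1], [0.2, 0.8]])
    return T, simulate_markov_chain(MarkovChainSpec(T, n_frames=100_000, seed=7))
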