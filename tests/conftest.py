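"""Shared fixtures: deterministic RNGs and session-scoped simulations."""

import numpy as np
import pytest

import plastcomp as pc


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def default_ancestor():
    return pc.build_ancestor(pc.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def default_truth():
    return pc.simulate(pc.SimulationConfig(seed=11))


def random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
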