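import numpy as np
import pytest

from rnagrow.fragments import synth_fragment_library
from rnagrow.model import Conformation
from rnagrow.templates import build_ideal_aform


@pytest.fixture(scope="session")
def ideal_a4():
    return build_ideal_aform("AAAA")


@pytest.fixture(scope="session")
def ideal_a30():
    return build_ideal_aform("A" * 30)


@pytest.fixture(scope="session")
def single_conformer_a4_lib():
    """Zero-noise, single-conformer rA4 library (degenerate growth input)."""
    return synth_fragment_library("AAAA", 1, noise=0.0, unstack_prob=0.0, seed=0)


@pytest.fixture(scope="session")
def noisy_a4_lib():
    """Small low-noise rA4 library shared across growth tests."""
    return synth_fragment_library("AAAA", 60, noise=3.0, unstack_prob=0.0, seed=11)


def make_conformation(sequence, atoms):
    """Build a Conformation from [(res_idx, name, element, xyz), ...]."""
    return Conformation(
        sequence,
        [a[1] for a in atoms],
        [a[0] for a in atoms],
        [a[2] for a in atoms],
        np.array([a[3] for a in atoms], float),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
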