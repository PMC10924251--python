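import numpy as np
import pytest

from phagedms.demo import random_target
from phagedms.variant_model import ProteinTarget, enumerate_saturation_library


@pytest.fixture(scope="session")
def tiny_target() -> ProteinTarget:
    """M-D-H-K toy protein, mutagenized over residues 2-4."""
    return ProteinTarget(name="tiny", dna_seq="ATGGATCATAAA", mut_start=2, mut_end=4)


@pytest.fixture(scope="session")
def toy_target() -> ProteinTarget:
    """28-residue random target (window 2-28), the standard bench scenario."""
    return random_target(n_residues=28, seed=7)


@pytest.fixture(scope="session")
def toy_library(toy_target):
    return enumerate_saturation_library(toy_target)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
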