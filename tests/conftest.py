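from __future__ import annotations

import numpy as np
import pytest

import pyromap as pm
from pyromap.fixtures import fig2b, fig2b_config

BASES = np.array(list("ACGT"))


def random_dna(n: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(BASES[rng.integers(0, 4, n)])


@pytest.fixture(scope="session")
def worked_example():
    return fig2b()


@pytest.fixture(scope="session")
def worked_bundle(worked_example):
    ref = pm.encode_reference(worked_example.records)
    return pm.IndexBundle.build(ref)


@pytest.fixture(scope="session")
def worked_config():
    return fig2b_config()


@pytest.fixture(scope="session")
def small_ref():
    """A 3 kb random reference and its index, shared across tests."""
    seq = random_dna(3000, seed=7)
    ref = pm.encode_reference([("chrS", seq)])
    return seq, pm.IndexBundle.build(ref)
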