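"""Shared fixtures: deterministic toy-model samples and random structures.

Everything here uses the internal pair-weight engine so the suite never
depends on the thermodynamic engine except where a test explicitly asks
for it.
"""

from __future__ import annotations

import pytest

from ensembletree.engines import NussinovEngine
from ensembletree.sampling import Composition, random_sequence, toy_sample


@pytest.fixture(scope="session")
def toy_engine():
    return NussinovEngine(pair_weight=2.0)


def make_random_samples(n_samples: int, *, n: int = 40, N: int = 64, seed: int = 0):
    """Deterministic list of toy-model StructureSamples over random
    sequences (small enough for brute-force oracles)."""
    out = []
    for k in range(n_samples):
        x = random_sequence(n, Composition.uniform(), seed * 1000 + k)
        out.append(toy_sample(x, N, seed * 2000 + k + 1))
    return out


def make_random_structures(count: int, *, n: int = 40, seed: int = 0):
    """Deterministic list of valid random structures (toy-model draws)."""
    structs = []
    k = 0
    while len(structs) < count:
        x = random_sequence(n, Composition.uniform(), seed * 3000 + k)
        samp = toy_sample(x, 8, seed * 4000 + k + 7)
        structs.extend(samp.structures)
        k += 1
    return structs[:count]


@pytest.fixture(scope="session")
def random_samples():
    return make_random_samples(50)


@pytest.fixture(scope="session")
def random_structures():
    return make_random_structures(100)
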