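"""Seed management.

All randomness in the package flows from a single master seed, split
deterministically into named sub-streams so that any one stage (sequence
generation, sampling, target draw, oracle lies) can be replayed in
isolation.
"""

from __future__ import annotations

import numpy as np

__all__ = ["spawn_seed", "spawn_rng"]

_MOD = 2**31 - 1


def spawn_seed(master: int, *labels: object) -> int:
    """Derive a reproducible 31-bit child seed from ``master`` and labels."""
    ss = np.random.SeedSequence([int(master) % _MOD, *(abs(hash(str(x))) % _MOD for x in labels)])
    return int(ss.generate_state(1)[0]) % _MOD


def spawn_rng(master: int, *labels: object) -> np.random.Generator:
    """A numpy Generator on the sub-stream identified by ``labels``."""
    return np.random.default_rng(spawn_seed(master, *labels))
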