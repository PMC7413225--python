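"""Sequence generation, Boltzmann sampling, q-filtration, target choice.

The q-Boltzmann ensemble Omega^q of a target ``s`` over a sequence of
length ``n`` contains the structures whose 0-1-signature Hamming distance
to ``s`` is at most ``q * n``.  At ``q = 0.05`` it emulates a Boltzmann
ensemble constrained by chemical probing data of the target.  The sampler
here is rejection filtration over a signature-biased proposal: plain
rejection from the unrestricted ensemble is infeasible at small ``q``
(the unrestricted mean normalized distance to a random target is about
0.21), so the proposal engine receives a per-nucleotide pseudo-energy
bonus toward the target's paired/unpaired state and the exact admission
rule ``d_sn(s', target) <= q*n`` is then applied to every proposal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from ._rng import spawn_seed
from .engines import FoldingEngine, NussinovEngine, ViennaEngine
from .structures import (
    RnaSequence,
    SecondaryStructure,
    StructureSample,
    signature_distance,
)

__all__ = [
    "Composition",
    "QFiltration",
    "random_sequence",
    "boltzmann_sample",
    "toy_sample",
    "q_filter_stream",
    "q_boltzmann_sample",
    "choose_target",
]

DEFAULT_SIGNATURE_BIAS = 1.0  # kcal/mol-equivalent per-nucleotide bonus


@dataclass(frozen=True)
class Composition:
    """Nucleotide composition (probabilities of A, U, C, G; sum to 1)."""

    a: float
    u: float
    c: float
    g: float

    def __post_init__(self):
        vals = (self.a, self.u, self.c, self.g)
        if any(v < 0 or v > 1 for v in vals):
            raise ValueError("composition probabilities must lie in [0, 1]")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ValueError(f"composition must sum to 1, got {sum(vals)!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.u, self.c, self.g])

    @classmethod
    def uniform(cls) -> "Composition":
        return cls(0.25, 0.25, 0.25, 0.25)

    @classmethod
    def gc_rich(cls) -> "Composition":
        """30% G, 30% C, 20% A, 20% U."""
        return cls(0.2, 0.2, 0.3, 0.3)

    @classmethod
    def au_rich(cls) -> "Composition":
        """30% A, 30% U, 20% G, 20% C."""
        return cls(0.3, 0.3, 0.2, 0.2)

    @classmethod
    def named(cls, name: str) -> "Composition":
        try:
            return {"uniform": cls.uniform, "gcrich": cls.gc_rich, "aurich": cls.au_rich}[
                name.replace("-", "").replace("_", "").lower()
            ]()
        except KeyError:
            raise ValueError(f"unknown composition {name!r}") from None


def random_sequence(n: int, comp: Composition, seed: int) -> RnaSequence:
    """I.i.d. random RNA sequence of length ``n`` with the given
    nucleotide composition; reproducible under a fixed seed."""
    if n < 1:
        raise ValueError("sequence length must be positive")
    rng = np.random.default_rng(int(seed))
    letters = np.array(list("AUCG"))
    return RnaSequence("".join(rng.choice(letters, size=n, p=comp.as_array())))


def boltzmann_sample(
    sequence: RnaSequence, count: int, engine: FoldingEngine, seed: int
) -> StructureSample:
    """Multiset of ``count`` structures from the engine's Boltzmann
    distribution for ``sequence``."""
    try:
        return engine.sample(sequence, count, seed)
    except Exception as exc:
        raise RuntimeError(
            f"folding engine {getattr(engine, 'name', engine)!r} failed on "
            f"sequence of length {len(sequence)}: {exc}"
        ) from exc


def toy_sample(sequence: RnaSequence, count: int, seed: int, pair_weight: float = 2.0) -> StructureSample:
    """Sample from the internal pair-weight toy model (no external engine)."""
    return NussinovEngine(pair_weight=pair_weight).sample(sequence, count, seed)


@dataclass(frozen=True)
class QFiltration:
    """Admission rule of the q-Boltzmann ensemble: keep ``s'`` iff
    ``d_sn(s', target) <= q * n``."""

    target: SecondaryStructure
    q: float

    def __post_init__(self):
        if not (0.0 <= self.q <= 1.0):
            raise ValueError("q must lie in [0, 1]")

    @property
    def radius(self) -> float:
        return self.q * self.target.n

    def admits(self, s: SecondaryStructure) -> bool:
        return signature_distance(s, self.target) <= self.radius


def q_filter_stream(
    structures: Iterable[SecondaryStructure],
    filt: QFiltration,
    count: int,
    *,
    min_admission_rate: float = 1e-4,
    check_after: int = 10_000,
) -> StructureSample:
    """First ``count`` structures of the stream admitted by ``filt``.

    Raises if, after ``check_after`` proposals, the admission rate falls
    below ``min_admission_rate`` — the advice then is to use a
    signature-biased proposal (see :func:`q_boltzmann_sample`).
    """
    admitted = []
    proposed = 0
    for s in structures:
        proposed += 1
        if filt.admits(s):
            admitted.append(s)
            if len(admitted) == count:
                break
        if proposed >= check_after and len(admitted) < min_admission_rate * proposed:
            raise RuntimeError(
                f"q-filtration admission rate {len(admitted)}/{proposed} below "
                f"{min_admission_rate}; use a signature-biased proposal engine"
            )
    if len(admitted) < count:
        raise RuntimeError(
            f"stream exhausted with {len(admitted)}/{count} admitted structures"
        )
    return StructureSample(admitted)


def q_boltzmann_sample(
    sequence: RnaSequence,
    target: SecondaryStructure,
    q: float,
    count: int,
    seed: int,
    *,
    engine: Optional[FoldingEngine] = None,
    bias: float = DEFAULT_SIGNATURE_BIAS,
    min_admission_rate: float = 1e-4,
    ensure_target_membership: bool = True,
) -> StructureSample:
    """Sample ``count`` structures from the q-Boltzmann ensemble of
    ``target`` via a signature-biased proposal plus exact rejection.

    With the default ViennaRNA proposal, each nucleotide receives a
    pseudo-energy bonus of magnitude ``bias`` toward the paired/unpaired
    state of the target's signature; every proposal is then tested against
    the exact rule ``d_sn <= q*n``.  An engine without signature-bias
    support is used as an unbiased proposal stream (feasible only for
    generous ``q``).
    """
    if engine is None:
        engine = ViennaEngine(signature_bias=(target.signature(), bias))
    elif hasattr(engine, "with_signature_bias"):
        engine = engine.with_signature_bias(target.signature(), bias)
    filt = QFiltration(target, q)
    stream = engine.sample_stream(sequence, seed)
    sample = q_filter_stream(stream, filt, count, min_admission_rate=min_admission_rate)
    structures, counts = list(sample.structures), list(sample.counts)
    if ensure_target_membership and target not in sample:
        # the target belongs to its own q-ensemble (distance 0); the
        # framework assumes the probing ensemble contains the target, so a
        # draw that happened to miss it gets one copy, displacing one copy
        # of a least-frequent member to keep N fixed
        k = min(range(len(counts)), key=lambda a: (counts[a], -a))
        if counts[k] > 1:
            counts[k] -= 1
        else:
            del structures[k], counts[k]
        structures.append(target)
        counts.append(1)
    return StructureSample(structures, counts, sequence=sequence)


def choose_target(sample: StructureSample, seed: int) -> SecondaryStructure:
    """Draw the target uniformly from the multiset (multiplicity-weighted
    over distinct structures); reproducible under a fixed seed."""
    rng = np.random.default_rng(spawn_seed(seed, "target"))
    k = int(rng.choice(len(sample.structures), p=sample.probabilities()))
    return sample.structures[k]
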