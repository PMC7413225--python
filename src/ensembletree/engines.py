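"""Folding engines: the pluggable source of structures for a sequence.

An engine provides two capabilities:

``mfe(sequence)``
    the single most stable structure, and

``sample(sequence, count, seed)``
    a reproducible multiset of ``count`` structures drawn from the
    engine's equilibrium (Boltzmann) distribution.

Two implementations are shipped.  :class:`ViennaEngine` wraps the
ViennaRNA thermodynamic folder (Turner energies, partition function,
stochastic backtracking) and is the production engine.
:class:`NussinovEngine` is an internal, dependency-free toy model — a
pair-counting partition function ``Z = sum_s w^{|s|}`` over all
pseudoknot-free structures with canonical pairs and minimum loop size 3 —
with exact stochastic backtracking.  It exists so the whole framework can
be exercised deterministically and cheaply; it makes no claim of
thermodynamic realism (see docs/methods.md).
"""

from __future__ import annotations

import random
from typing import Dict, Iterator, List, Optional, Protocol, Sequence, Tuple, runtime_checkable

import numpy as np

from .structures import (
    MIN_LOOP,
    Pair,
    RnaSequence,
    SecondaryStructure,
    StructureSample,
)

__all__ = [
    "FoldingEngine",
    "ViennaEngine",
    "NussinovEngine",
    "UniformEngine",
    "enumerate_structures",
    "count_structures",
    "make_engine",
]

CANONICAL = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")})


@runtime_checkable
class FoldingEngine(Protocol):
    """Contract every folding engine satisfies."""

    name: str

    def mfe(self, sequence: RnaSequence) -> SecondaryStructure: ...

    def sample(self, sequence: RnaSequence, count: int, seed: int) -> StructureSample: ...


# ---------------------------------------------------------------------------
# ViennaRNA


class ViennaEngine:
    """Thermodynamic engine backed by the ViennaRNA Python bindings.

    Parameters
    ----------
    signature_bias
        Optional ``(signature, strength)``: a 0/1 per-nucleotide vector and
        a pseudo-energy magnitude in kcal/mol.  Each position receives a
        soft-constraint bonus of ``strength`` toward the state (paired or
        unpaired) given by the signature.  This realizes the
        signature-biased proposal distribution used by the q-filtered
        sampler; with no bias the engine samples the unrestricted
        Boltzmann ensemble.
    """

    name = "vienna"

    def __init__(self, signature_bias: Optional[Tuple[Sequence[int], float]] = None):
        try:
            import RNA  # noqa: F401
        except ImportError as exc:  # pragma: no cover
            raise ImportError(
                "ViennaEngine requires the ViennaRNA Python bindings "
                "(conda package 'viennarna'); use NussinovEngine otherwise"
            ) from exc
        self._RNA = RNA
        self.signature_bias = signature_bias

    def _fold_compound(self, sequence: RnaSequence):
        RNA = self._RNA
        md = RNA.md()
        md.uniq_ML = 1
        fc = RNA.fold_compound(str(sequence), md)
        if self.signature_bias is not None:
            sig, strength = self.signature_bias
            if len(sig) != len(sequence):
                raise ValueError("signature bias length does not match sequence")
            for k, bit in enumerate(sig, start=1):
                # sc_add_up adds an energy contribution to the unpaired state:
                # reward unpaired where the signature says unpaired, penalize
                # it where the signature says paired.
                fc.sc_add_up(k, -strength if not bit else +strength)
        return fc

    def with_signature_bias(self, signature: Sequence[int], strength: float) -> "ViennaEngine":
        """A copy of this engine whose sampling distribution is tilted
        toward the given 0/1 signature (used as q-filtration proposal)."""
        return ViennaEngine(signature_bias=(signature, strength))

    def mfe(self, sequence: RnaSequence) -> SecondaryStructure:
        fc = self._fold_compound(sequence)
        db, _ = fc.mfe()
        from .structures import parse_dotbracket

        return parse_dotbracket(db)

    def sample(self, sequence: RnaSequence, count: int, seed: int) -> StructureSample:
        from .structures import parse_dotbracket

        if count < 1:
            raise ValueError("sample count must be positive")
        fc = self._fold_compound(sequence)
        _, emfe = fc.mfe()
        fc.exp_params_rescale(emfe)
        fc.pf()
        self._RNA.init_rand(int(seed))
        dbs = fc.pbacktrack(int(count))
        if len(dbs) != count:  # pragma: no cover
            raise RuntimeError(f"stochastic backtracking returned {len(dbs)}/{count} structures")
        return StructureSample((parse_dotbracket(db) for db in dbs), sequence=sequence)

    def sample_stream(self, sequence: RnaSequence, seed: int, batch: int = 512) -> Iterator[SecondaryStructure]:
        """Endless stream of Boltzmann-sampled structures (for filtration)."""
        from .structures import parse_dotbracket

        fc = self._fold_compound(sequence)
        _, emfe = fc.mfe()
        fc.exp_params_rescale(emfe)
        fc.pf()
        self._RNA.init_rand(int(seed))
        while True:
            for db in fc.pbacktrack(batch):
                yield parse_dotbracket(db)

    def pair_probabilities(self, sequence: RnaSequence) -> Dict[Pair, float]:
        """Exact equilibrium base-pair probabilities from the partition
        function (independent of sampling; used as an oracle in tests)."""
        fc = self._fold_compound(sequence)
        _, emfe = fc.mfe()
        fc.exp_params_rescale(emfe)
        fc.pf()
        bpp = fc.bpp()
        out: Dict[Pair, float] = {}
        n = len(sequence)
        for i in range(1, n + 1):
            for j in range(i + 1, n + 1):
                p = bpp[i][j]
                if p > 0:
                    out[(i, j)] = float(p)
        return out


# ---------------------------------------------------------------------------
# Toy pair-weight model (Nussinov-style)


class _PairWeightDP:
    """Inside partition function Z(i, j) = sum over structures of w^#pairs,
    over canonical pairs with minimum loop size; 0-based half-open logic
    hidden behind 1-based public indices."""

    def __init__(self, sequence: RnaSequence, weight: float):
        self.seq = str(sequence)
        self.n = len(self.seq)
        self.w = float(weight)
        self._z: Optional[np.ndarray] = None

    def _can_pair(self, a: int, b: int) -> bool:  # 0-based
        return (self.seq[a], self.seq[b]) in CANONICAL and b - a > MIN_LOOP

    def z(self) -> np.ndarray:
        """Z over 0-based closed intervals; Z[i, j] with j < i is 1 (empty)."""
        if self._z is not None:
            return self._z
        n, w = self.n, self.w
        z = np.ones((n, n))
        for span in range(1, n):
            for i in range(0, n - span):
                j = i + span
                total = z[i, j - 1] if j - 1 >= i else 1.0
                for k in range(i, j - MIN_LOOP):
                    if self._can_pair(k, j):
                        left = z[i, k - 1] if k - 1 >= i else 1.0
                        inner = z[k + 1, j - 1] if j - 1 >= k + 1 else 1.0
                        total += w * left * inner
                z[i, j] = total
        self._z = z
        return z

    def partition(self) -> float:
        return float(self.z()[0, self.n - 1]) if self.n > 1 else 1.0

    def backtrack(self, rng: random.Random) -> SecondaryStructure:
        z = self.z()
        w = self.w
        pairs: List[Pair] = []
        stack: List[Tuple[int, int]] = [(0, self.n - 1)]
        while stack:
            i, j = stack.pop()
            if j <= i:
                continue
            r = rng.random() * z[i, j]
            acc = z[i, j - 1] if j - 1 >= i else 1.0
            if r < acc:
                stack.append((i, j - 1))
                continue
            chosen = None
            for k in range(i, j - MIN_LOOP):
                if self._can_pair(k, j):
                    left = z[i, k - 1] if k - 1 >= i else 1.0
                    inner = z[k + 1, j - 1] if j - 1 >= k + 1 else 1.0
                    acc += w * left * inner
                    if r < acc:
                        chosen = k
                        break
            if chosen is None:  # numerical edge: take the last feasible k
                chosen = max(k for k in range(i, j - MIN_LOOP) if self._can_pair(k, j))
            pairs.append((chosen + 1, j + 1))
            stack.append((i, chosen - 1))
            stack.append((chosen + 1, j - 1))
        return SecondaryStructure(pairs, self.n)


class NussinovEngine:
    """Seedable toy folding engine over a pair-counting partition function.

    Each structure ``s`` has weight ``w^{|s|}`` (``w`` = ``pair_weight``);
    ``mfe`` is the maximum-pair structure (the w -> infinity limit) and
    ``sample`` draws i.i.d. structures by exact stochastic backtracking.
    As ``w -> 0`` the empty structure dominates.
    """

    name = "nussinov"

    def __init__(self, pair_weight: float = 2.0):
        if pair_weight < 0:
            raise ValueError("pair weight must be non-negative")
        self.pair_weight = float(pair_weight)
        self._dp_cache: Dict[str, _PairWeightDP] = {}

    def _dp(self, sequence: RnaSequence) -> _PairWeightDP:
        key = str(sequence)
        if key not in self._dp_cache:
            if len(self._dp_cache) > 8:
                self._dp_cache.clear()
            self._dp_cache[key] = _PairWeightDP(sequence, self.pair_weight)
        return self._dp_cache[key]

    def mfe(self, sequence: RnaSequence) -> SecondaryStructure:
        seq = str(sequence)
        n = len(seq)
        best = np.zeros((n, n), dtype=np.int64)
        for span in range(1, n):
            for i in range(0, n - span):
                j = i + span
                b = best[i, j - 1]
                for k in range(i, j - MIN_LOOP):
                    if (seq[k], seq[j]) in CANONICAL:
                        left = best[i, k - 1] if k - 1 >= i else 0
                        inner = best[k + 1, j - 1] if j - 1 >= k + 1 else 0
                        b = max(b, 1 + left + inner)
                best[i, j] = b
        # deterministic traceback: prefer j unpaired, then smallest k
        pairs: List[Pair] = []
        stack = [(0, n - 1)]
        while stack:
            i, j = stack.pop()
            if j <= i:
                continue
            if best[i, j] == (best[i, j - 1] if j - 1 >= i else 0):
                stack.append((i, j - 1))
                continue
            for k in range(i, j - MIN_LOOP):
                if (seq[k], seq[j]) in CANONICAL:
                    left = best[i, k - 1] if k - 1 >= i else 0
                    inner = best[k + 1, j - 1] if j - 1 >= k + 1 else 0
                    if best[i, j] == 1 + left + inner:
                        pairs.append((k + 1, j + 1))
                        stack.append((i, k - 1))
                        stack.append((k + 1, j - 1))
                        break
        return SecondaryStructure(pairs, n)

    def sample(self, sequence: RnaSequence, count: int, seed: int) -> StructureSample:
        if count < 1:
            raise ValueError("sample count must be positive")
        dp = self._dp(sequence)
        rng = random.Random(int(seed))
        return StructureSample(
            (dp.backtrack(rng) for _ in range(count)), sequence=sequence
        )

    def sample_stream(self, sequence: RnaSequence, seed: int, batch: int = 0) -> Iterator[SecondaryStructure]:
        dp = self._dp(sequence)
        rng = random.Random(int(seed))
        while True:
            yield dp.backtrack(rng)


# ---------------------------------------------------------------------------
# Exact enumeration / uniform sampling


def _enumerate(seq: str, i: int, j: int, limit: List[int]) -> Iterator[frozenset]:
    """All pair sets over 0-based closed [i, j]; raises if limit exhausted."""
    if j - i <= MIN_LOOP:
        yield frozenset()
        return
    for rest in _enumerate(seq, i, j - 1, limit):
        limit[0] -= 1
        if limit[0] < 0:
            raise OverflowError("structure enumeration limit exceeded")
        yield rest
    for k in range(i, j - MIN_LOOP):
        if (seq[k], seq[j]) in CANONICAL:
            for left in _enumerate(seq, i, k - 1, limit):
                for inner in _enumerate(seq, k + 1, j - 1, limit):
                    limit[0] -= 1
                    if limit[0] < 0:
                        raise OverflowError("structure enumeration limit exceeded")
                    yield left | inner | {(k + 1, j + 1)}


def enumerate_structures(sequence: RnaSequence, limit: int = 100_000) -> List[SecondaryStructure]:
    """Exhaustively enumerate all secondary structures of a (short)
    sequence under the canonical-pair / minimum-loop rules."""
    seq = str(sequence)
    n = len(seq)
    return [
        SecondaryStructure(p, n) for p in _enumerate(seq, 0, n - 1, [limit])
    ]


def count_structures(sequence: RnaSequence) -> int:
    """Exact count of secondary structures (integer Nussinov DP, w = 1)."""
    seq = str(sequence)
    n = len(seq)
    z: Dict[Tuple[int, int], int] = {}

    def Z(i: int, j: int) -> int:
        if j - i <= MIN_LOOP:
            return 1
        if (i, j) in z:
            return z[(i, j)]
        total = Z(i, j - 1)
        for k in range(i, j - MIN_LOOP):
            if (seq[k], seq[j]) in CANONICAL:
                total += Z(i, k - 1) * Z(k + 1, j - 1)
        z[(i, j)] = total
        return total

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 4 * n + 100))
    try:
        return Z(0, n - 1)
    finally:
        sys.setrecursionlimit(old)


class UniformEngine:
    """Samples structures uniformly from the exact count of all secondary
    structures (big-integer DP + exact backtracking); intended for short
    sequences (n <= 120)."""

    name = "uniform"

    def __init__(self, max_length: int = 120):
        self.max_length = max_length

    def _tables(self, seq: str):
        n = len(seq)
        z = [[1] * n for _ in range(n)]
        for span in range(1, n):
            for i in range(0, n - span):
                j = i + span
                total = z[i][j - 1] if j - 1 >= i else 1
                for k in range(i, j - MIN_LOOP):
                    if (seq[k], seq[j]) in CANONICAL:
                        left = z[i][k - 1] if k - 1 >= i else 1
                        inner = z[k + 1][j - 1] if j - 1 >= k + 1 else 1
                        total += left * inner
                z[i][j] = total
        return z

    def mfe(self, sequence: RnaSequence) -> SecondaryStructure:
        return NussinovEngine().mfe(sequence)

    def sample(self, sequence: RnaSequence, count: int, seed: int) -> StructureSample:
        seq = str(sequence)
        n = len(seq)
        if n > self.max_length:
            raise ValueError(f"UniformEngine is restricted to n <= {self.max_length}")
        z = self._tables(seq)
        rng = random.Random(int(seed))

        def draw() -> SecondaryStructure:
            pairs: List[Pair] = []
            stack = [(0, n - 1)]
            while stack:
                i, j = stack.pop()
                if j - i <= MIN_LOOP:
                    continue
                r = rng.randrange(z[i][j])
                acc = z[i][j - 1] if j - 1 >= i else 1
                if r < acc:
                    stack.append((i, j - 1))
                    continue
                for k in range(i, j - MIN_LOOP):
                    if (seq[k], seq[j]) in CANONICAL:
                        left = z[i][k - 1] if k - 1 >= i else 1
                        inner = z[k + 1][j - 1] if j - 1 >= k + 1 else 1
                        acc += left * inner
                        if r < acc:
                            pairs.append((k + 1, j + 1))
                            stack.append((i, k - 1))
                            stack.append((k + 1, j - 1))
                            break
            return SecondaryStructure(pairs, n)

        return StructureSample((draw() for _ in range(count)), sequence=sequence)


def make_engine(name: str, **kwargs) -> FoldingEngine:
    """Engine factory used by the CLI and the experiment drivers."""
    name = name.lower()
    if name == "vienna":
        return ViennaEngine(**kwargs)
    if name == "nussinov":
        return NussinovEngine(**kwargs)
    if name == "uniform":
        return UniformEngine(**kwargs)
    raise ValueError(f"unknown engine {name!r} (choose vienna, nussinov or uniform)")
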