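"""Entropy calculus on structure samples.

A base-pair query is the Bernoulli random variable X_ij indicating
whether the target contains the pair (i, j); its distribution in a sample
is the pair probability p_ij, and its entropy

    H(X_ij) = -p_ij log2 p_ij - (1 - p_ij) log2(1 - p_ij)

measures (in bits) the information gained by asking the query.  The
structural entropy of a sample is the Shannon entropy of its empirical
distribution p(s) = f(s)/N.  Querying a pair splits the sample into the
structures containing it and the rest; the entropy reduction of the split
equals H(X_ij) exactly (the chain rule for a Bernoulli conditioning
variable), so the maximally informative query is the pair with p_ij
nearest 1/2.  A sample with structural entropy E <= 1 always carries a
distinguished structure of probability at least f(E), the inverse of the
binary entropy on [1/2, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .structures import Pair, SecondaryStructure, StructureSample

__all__ = [
    "PairQuery",
    "SplitResult",
    "binary_entropy",
    "pair_entropy",
    "structural_entropy",
    "split_by_pair",
    "conditional_entropy",
    "entropy_reduction",
    "max_entropy_pair",
    "distinguished_bound",
    "distinguished_structure",
]

ATOL = 1e-9


def binary_entropy(p: float) -> float:
    """Entropy in bits of a Bernoulli(p) variable; 0 log 0 := 0."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"probability out of range: {p!r}")
    if p in (0.0, 1.0):
        return 0.0
    return float(-p * math.log2(p) - (1.0 - p) * math.log2(1.0 - p))


def _binary_entropy_vec(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p, dtype=float)
    mask = (p > 0) & (p < 1)
    pm = p[mask]
    out[mask] = -pm * np.log2(pm) - (1 - pm) * np.log2(1 - pm)
    return out


@dataclass(frozen=True)
class PairQuery:
    """A base-pair query: the pair, its sample probability and entropy."""

    pair: Pair
    probability: float
    entropy: float


@dataclass
class SplitResult:
    """Bipartition of a sample by one base-pair query.

    ``child1`` holds the structures containing the pair (probability
    renormalized by p_ij), ``child0`` the complement (renormalized by
    1 - p_ij).  Either may be None when the pair is certain.
    """

    pair: Pair
    probability: float
    child0: Optional[StructureSample]
    child1: Optional[StructureSample]


def pair_entropy(sample: StructureSample, pair: Pair) -> float:
    """H(X_ij) of a pair in a sample, from p_ij = f(i,j)/N."""
    pair = (int(pair[0]), int(pair[1]))
    freq = sum(int(c) for s, c in zip(sample.structures, sample.counts) if pair in s.pairs)
    return binary_entropy(freq / sample.size)


def structural_entropy(sample: StructureSample) -> float:
    """Shannon entropy (bits) of the sample distribution p(s) = f(s)/N;
    bounded by log2 N."""
    p = sample.probabilities()
    return float(-(p * np.log2(p)).sum())


def split_by_pair(sample: StructureSample, pair: Pair) -> SplitResult:
    """Split the multiset into the structures containing ``pair`` and the
    rest; the multiset union of the children equals the parent."""
    pair = (int(pair[0]), int(pair[1]))
    has = np.array([pair in s.pairs for s in sample.structures])
    freq = int(sample.counts[has].sum())
    p = freq / sample.size
    idx1 = np.flatnonzero(has)
    idx0 = np.flatnonzero(~has)
    child1 = sample.subset(idx1) if len(idx1) else None
    child0 = sample.subset(idx0) if len(idx0) else None
    return SplitResult(pair=pair, probability=p, child0=child0, child1=child1)


def conditional_entropy(sample: StructureSample, pair: Pair) -> float:
    """H(Omega | X_ij) = (1 - p_ij) H(Omega_0) + p_ij H(Omega_1); an empty
    side contributes 0."""
    split = split_by_pair(sample, pair)
    h0 = structural_entropy(split.child0) if split.child0 is not None else 0.0
    h1 = structural_entropy(split.child1) if split.child1 is not None else 0.0
    return (1.0 - split.probability) * h0 + split.probability * h1


def entropy_reduction(sample: StructureSample, pair: Pair) -> float:
    """R(Omega, X_ij) = H(Omega) - H(Omega | X_ij); equals H(X_ij)."""
    return structural_entropy(sample) - conditional_entropy(sample, pair)


def max_entropy_pair(sample: StructureSample) -> Optional[PairQuery]:
    """The maximum-entropy base pair of a sample, or None when every pair
    occurring in the sample is certain (entropy 0).

    Ties are broken by |p_ij - 1/2| ascending (equivalent to entropy
    descending), then lexicographically on (i, j), making the choice — and
    hence the ensemble tree — deterministic.
    """
    pairs, m = sample.pair_table()
    if not pairs:
        return None
    freq = sample.counts @ m.astype(np.int64)
    N = sample.size
    informative = (freq > 0) & (freq < N)
    if not informative.any():
        return None
    idx = np.flatnonzero(informative)
    p = freq[idx] / N
    dev = np.abs(p - 0.5)
    # lexicographic tie-break on (i, j): pairs are stored sorted, so the
    # first index attaining the minimal deviation wins
    best = idx[int(np.argmin(dev))]
    pbest = freq[best] / N
    return PairQuery(pair=pairs[best], probability=float(pbest), entropy=binary_entropy(pbest))


def distinguished_bound(entropy: float) -> float:
    """f(E): the unique root in [1/2, 1] of binary_entropy(p) = E, found by
    bisection to 1e-10.  f(1) = 1/2, f(0) = 1; strictly decreasing."""
    if not (0.0 <= entropy <= 1.0):
        raise ValueError(f"the bound is defined for entropies in [0, 1], got {entropy!r}")
    lo, hi = 0.5, 1.0  # binary_entropy is strictly decreasing on [1/2, 1]
    while hi - lo > 1e-10:
        mid = (lo + hi) / 2
        if binary_entropy(mid) > entropy:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def distinguished_structure(sample: StructureSample) -> Tuple[SecondaryStructure, float]:
    """The maximum-multiplicity structure of a sample and its p(s); ties
    broken lexicographically on the dot-bracket serialization."""
    best_count = int(sample.counts.max())
    candidates = [
        s for s, c in zip(sample.structures, sample.counts) if int(c) == best_count
    ]
    winner = min(candidates, key=lambda s: s.to_dotbracket())
    return winner, best_count / sample.size
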