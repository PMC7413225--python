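"""Oracles answering base-pair queries, with and without lies.

Identification of the target is a Rényi–Ulam game: the questioner asks
whether base pair (i, j) is in the target, and the oracle answers with
context-dependent, independent random lies — a truthful "No" is flipped
with probability e0 and a truthful "Yes" with probability e1.  Repeating
a query shrinks the effective error rates: under equal prior odds, k
concordant identical answers are wrong with probability
e^k / (e^k + (1-e)^k).

The experimentally motivated oracle answers by *modularity*: cut the
sequence at (i, j) into the enclosed fragment and the remainder glued at
the cut points, fold (or probe) each fragment separately, embed the two
per-nucleotide profiles back into full length, and compare with the
full-sequence profile by Hamming distance.  If (i, j) really is a pair of
the target, the fragments tend to refold into the same arcs, so the
distance is small; the verdict is "paired" iff the distance is strictly
below a threshold theta.  The false omission and false discovery rates of
this classifier are the game's e0 and e1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._rng import spawn_rng
from .engines import FoldingEngine
from .sampling import Composition, random_sequence
from .structures import (
    Pair,
    RnaSequence,
    SecondaryStructure,
    signature_of,
)

__all__ = [
    "ErrorRates",
    "QueryRecord",
    "FragmentPair",
    "ModularityDecision",
    "truthful_answer",
    "noisy_answer",
    "repeated_answer",
    "posterior_error_after_k",
    "extract",
    "embed",
    "default_theta",
    "modularity_answer",
    "KnownTargetOracle",
    "ModularityOracle",
    "splitting_experiment",
    "error_rate_curves",
]

#: Threshold calibrated on length-500 sequences.
THETA_REFERENCE = 31
THETA_REFERENCE_LENGTH = 500


@dataclass(frozen=True)
class ErrorRates:
    """Lie rates: e0 for truthful-No answers, e1 for truthful-Yes."""

    e0: float
    e1: float

    def __post_init__(self):
        for v in (self.e0, self.e1):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"error rate out of range: {v!r}")


@dataclass(frozen=True)
class QueryRecord:
    """Audit record of one delivered query answer."""

    pair: Pair
    truthful: int
    delivered: int
    node_key: str = ""


def truthful_answer(target: SecondaryStructure, pair: Pair) -> int:
    """1 iff ``pair`` is a base pair of the target."""
    return int(tuple(pair) in target.pairs)


def noisy_answer(
    target: SecondaryStructure,
    pair: Pair,
    rates: ErrorRates,
    rng: np.random.Generator,
    *,
    node_key: str = "",
) -> Tuple[int, QueryRecord]:
    """One answer with an independent context-dependent lie."""
    truth = truthful_answer(target, pair)
    flip_p = rates.e1 if truth else rates.e0
    delivered = truth ^ int(rng.random() < flip_p)
    return delivered, QueryRecord(tuple(pair), truth, delivered, node_key)


def posterior_error_after_k(rates: ErrorRates, k: int) -> ErrorRates:
    """Posterior error rates after k independent concordant answers,
    under equal prior odds: e^[k] = e^k / (e^k + (1-e)^k)."""
    if k < 1:
        raise ValueError("k must be >= 1")

    def post(e: float) -> float:
        if e in (0.0, 1.0):
            return e
        return e**k / (e**k + (1.0 - e) ** k)

    return ErrorRates(post(rates.e0), post(rates.e1))


def repeated_answer(
    target: SecondaryStructure,
    pair: Pair,
    rates: ErrorRates,
    k: int,
    rng: np.random.Generator,
    *,
    node_key: str = "",
) -> Tuple[int, ErrorRates]:
    """Ask the same query k times and aggregate.

    k = 1: a single noisy answer.  k = 2: accept two concordant answers,
    re-asking the pair on disagreement until two in a row agree.  Odd k:
    majority vote.  Returns the aggregated bit and the posterior error
    rates after k concordant answers.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        bit, _ = noisy_answer(target, pair, rates, rng, node_key=node_key)
        return bit, rates
    if k == 2:
        prev, _ = noisy_answer(target, pair, rates, rng, node_key=node_key)
        while True:
            cur, _ = noisy_answer(target, pair, rates, rng, node_key=node_key)
            if cur == prev:
                return cur, posterior_error_after_k(rates, 2)
            prev = cur
    if k % 2 == 0:
        raise ValueError("even repetition counts other than 2 are not supported")
    votes = sum(noisy_answer(target, pair, rates, rng, node_key=node_key)[0] for _ in range(k))
    return int(votes > k // 2), posterior_error_after_k(rates, k)


# ---------------------------------------------------------------------------
# Fragmentation


@dataclass(frozen=True)
class FragmentPair:
    """The cut at (i, j): the enclosed fragment ``inner`` = x_i..x_j and
    the remainder ``outer`` = x_1..x_{i-1} x_{j+1}..x_n glued at the cut
    points.  Lengths sum to n and embedding inverts extraction."""

    inner: object
    outer: object
    i: int
    j: int
    n: int


def extract(x, i: int, j: int) -> FragmentPair:
    """Cut a sequence (or any per-position vector) at positions i..j
    (1-based, inclusive)."""
    seq = str(x) if isinstance(x, RnaSequence) else x
    n = len(seq)
    if not (1 <= i < j <= n):
        raise ValueError(f"cut ({i},{j}) out of range for n={n}")
    if isinstance(seq, np.ndarray):
        inner = seq[i - 1 : j]
        outer = np.concatenate([seq[: i - 1], seq[j:]])
    else:
        inner = seq[i - 1 : j]
        outer = seq[: i - 1] + seq[j:]
    if isinstance(x, RnaSequence):
        inner = RnaSequence(inner)
        outer = RnaSequence(outer) if len(outer) else outer
    return FragmentPair(inner=inner, outer=outer, i=i, j=j, n=n)


def embed(inner, outer, i: int, j: int):
    """Inverse of :func:`extract`: place ``inner`` at positions i..j and
    ``outer`` around it, restoring a full-length vector."""
    inner_s = str(inner) if isinstance(inner, RnaSequence) else inner
    outer_s = str(outer) if isinstance(outer, RnaSequence) else outer
    m = len(inner_s)
    n = m + len(outer_s)
    if m != j - i + 1:
        raise ValueError(f"inner length {m} does not match cut ({i},{j})")
    if isinstance(inner_s, np.ndarray) or isinstance(outer_s, np.ndarray):
        inner_a = np.asarray(inner_s)
        outer_a = np.asarray(outer_s)
        return np.concatenate([outer_a[: i - 1], inner_a, outer_a[i - 1 :]])
    if isinstance(inner_s, str):
        return outer_s[: i - 1] + inner_s + outer_s[i - 1 :]
    return list(outer_s[: i - 1]) + list(inner_s) + list(outer_s[i - 1 :])


def default_theta(n: int) -> int:
    """Length-calibrated signature-distance threshold: the reference value
    31 was calibrated at n = 500 and is scaled linearly."""
    return max(1, round(THETA_REFERENCE * n / THETA_REFERENCE_LENGTH))


@dataclass(frozen=True)
class ModularityDecision:
    """Distance between the full profile and the re-embedded fragment
    profiles, the threshold, and the verdict (1 iff distance < theta)."""

    pair: Pair
    distance: int
    theta: float
    verdict: int


def _fragment_profile(
    x: RnaSequence, i: int, j: int, engine: FoldingEngine
) -> np.ndarray:
    """MFE signatures of the two fragments, embedded back to full length."""
    frag = extract(x, i, j)
    inner_sig = signature_of(engine.mfe(frag.inner))
    if isinstance(frag.outer, RnaSequence) and len(frag.outer) > 0:
        outer_sig = signature_of(engine.mfe(frag.outer))
    else:
        outer_sig = np.zeros(0, dtype=np.uint8)
    return np.asarray(embed(inner_sig, outer_sig, i, j), dtype=np.uint8)


def modularity_answer(
    x: RnaSequence,
    pair: Pair,
    full_signature: Sequence[int],
    engine: FoldingEngine,
    theta: Optional[float] = None,
) -> Tuple[int, ModularityDecision]:
    """Answer a base-pair query from probing profiles via modularity.

    The fragments cut at ``pair`` are folded to their MFE structures (the
    in-silico stand-in for fragment probing), their signatures re-embedded,
    and compared to ``full_signature`` by Hamming distance; the verdict is
    "paired" iff the distance is strictly below ``theta``.
    """
    i, j = int(pair[0]), int(pair[1])
    if theta is None:
        theta = default_theta(len(x))
    full = np.asarray(full_signature, dtype=np.uint8)
    if len(full) != len(x):
        raise ValueError("full signature length does not match sequence")
    prof = _fragment_profile(x, i, j, engine)
    dist = int(np.count_nonzero(prof != full))
    verdict = int(dist < theta)
    return verdict, ModularityDecision(pair=(i, j), distance=dist, theta=theta, verdict=verdict)


# ---------------------------------------------------------------------------
# Oracle objects for tree walks


class KnownTargetOracle:
    """Query-answering oracle with a known target and independent lies.

    ``repeats`` > 1 re-asks each query (see :func:`repeated_answer`).
    Every delivered answer is recorded.
    """

    def __init__(
        self,
        target: SecondaryStructure,
        rates: ErrorRates = ErrorRates(0.0, 0.0),
        seed: int = 0,
        repeats: int = 1,
    ):
        self.target = target
        self.rates = rates
        self.repeats = int(repeats)
        self.rng = spawn_rng(seed, "oracle")
        self.records: List[QueryRecord] = []

    def answer(self, pair: Pair, node_key: str = "") -> int:
        if self.repeats == 1:
            bit, rec = noisy_answer(self.target, pair, self.rates, self.rng, node_key=node_key)
        else:
            bit, _ = repeated_answer(
                self.target, pair, self.rates, self.repeats, self.rng, node_key=node_key
            )
            rec = QueryRecord(tuple(pair), truthful_answer(self.target, pair), bit, node_key)
        self.records.append(rec)
        return bit


class ModularityOracle:
    """Oracle answering through fragment folding and profile comparison;
    needs only the full-length probing profile, never the target."""

    def __init__(
        self,
        sequence: RnaSequence,
        full_signature: Sequence[int],
        engine: FoldingEngine,
        theta: Optional[float] = None,
    ):
        self.sequence = sequence
        self.full_signature = np.asarray(full_signature, dtype=np.uint8)
        self.engine = engine
        self.theta = default_theta(len(sequence)) if theta is None else theta
        self.decisions: List[ModularityDecision] = []

    def answer(self, pair: Pair, node_key: str = "") -> int:
        bit, dec = modularity_answer(
            self.sequence, pair, self.full_signature, self.engine, self.theta
        )
        self.decisions.append(dec)
        return bit


# ---------------------------------------------------------------------------
# Splitting experiment (threshold calibration at desk scale)


def splitting_experiment(
    lengths: Sequence[int],
    n_sequences: int,
    engine: FoldingEngine,
    seed: int,
    *,
    composition: Optional[Composition] = None,
    random_splits_per_sequence: Optional[int] = None,
) -> pd.DataFrame:
    """Distances between full-sequence MFE signatures and re-embedded
    fragment signatures, for modular vs. random cuts.

    For each random sequence the MFE structure s is computed; every base
    pair of s defines a *modular* cut, and an equal number (by default) of
    uniformly drawn non-pair cuts define *random* cuts.  For each cut the
    fragments are refolded, re-embedded, and the signature and base-pair
    distances to s recorded.  Sweeping a threshold over the resulting
    distance distributions yields the e0/e1 calibration curves
    (:func:`error_rate_curves`).
    """
    comp = composition or Composition.uniform()
    rows = []
    for n in lengths:
        for snum in range(n_sequences):
            sseed = np.random.SeedSequence([seed % (2**31), n, snum]).generate_state(1)[0] % (2**31)
            x = random_sequence(n, comp, sseed)
            s = engine.mfe(x)
            full_sig = signature_of(s)
            modular_cuts = sorted(s.pairs)
            rng = np.random.default_rng(sseed + 1)
            k = random_splits_per_sequence or len(modular_cuts)
            random_cuts = []
            guard = 0
            while len(random_cuts) < k and guard < 50 * max(k, 1):
                guard += 1
                i = int(rng.integers(1, n - 4))
                j = int(rng.integers(i + 4, n + 1))
                if (i, j) not in s.pairs:
                    random_cuts.append((i, j))
            for kind, cuts in (("modular", modular_cuts), ("random", random_cuts)):
                for (i, j) in cuts:
                    frag = extract(x, i, j)
                    s_in = engine.mfe(frag.inner)
                    inner_sig = signature_of(s_in)
                    pairs_in = {(a + i - 1, b + i - 1) for a, b in s_in.pairs}
                    pairs_out = set()
                    outer_sig = np.zeros(0, dtype=np.uint8)
                    if isinstance(frag.outer, RnaSequence) and len(frag.outer) > 0:
                        s_out = engine.mfe(frag.outer)
                        outer_sig = signature_of(s_out)

                        def lift(k0: int) -> int:
                            return k0 if k0 <= i - 1 else k0 + (j - i + 1)

                        pairs_out = {(lift(a), lift(b)) for a, b in s_out.pairs}
                    prof = np.asarray(embed(inner_sig, outer_sig, i, j), dtype=np.uint8)
                    combined = pairs_in | pairs_out
                    dbp = len(s.pairs ^ combined)
                    dsn = int(np.count_nonzero(prof != full_sig))
                    rows.append(
                        {
                            "length": n,
                            "sequence": snum,
                            "i": i,
                            "j": j,
                            "kind": kind,
                            "d_sn": dsn,
                            "d_bp": dbp,
                        }
                    )
    return pd.DataFrame(rows)


def error_rate_curves(df: pd.DataFrame, thetas: Sequence[int]) -> pd.DataFrame:
    """FOR/FDR curves from a splitting-experiment table.

    For a threshold theta the verdict is "paired" iff d_sn < theta;
    "positive" means the cut is a true pair of s (kind == modular).
    e1 = FDR = FP / (FP + TP) among verdict-1 cuts; e0 = FOR =
    FN / (FN + TN) among verdict-0 cuts.
    """
    is_pos = (df["kind"] == "modular").to_numpy()
    d = df["d_sn"].to_numpy()
    rows = []
    for theta in thetas:
        pred = d < theta
        tp = int(np.sum(pred & is_pos))
        fp = int(np.sum(pred & ~is_pos))
        fn = int(np.sum(~pred & is_pos))
        tn = int(np.sum(~pred & ~is_pos))
        e1 = fp / (fp + tp) if (fp + tp) else np.nan
        e0 = fn / (fn + tn) if (fn + tn) else np.nan
        rows.append({"theta": theta, "e0": e0, "e1": e1, "tp": tp, "fp": fp, "fn": fn, "tn": tn})
    return pd.DataFrame(rows)
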