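"""Walking the ensemble tree under an oracle and scoring the outcome.

A run asks, at each interior node on the way down, whether the node's
maximum-entropy pair is in the target; the answer (possibly a lie)
selects the child.  The walk ends in a leaf Omega*, whose
maximum-multiplicity structure s* is reported as the identified target.
With truthful answers the target provably stays in every traversed node;
under independent lies the chance that the leaf still contains the
target is (1 - e0)^l0 * (1 - e1)^l1, where l0 and l1 count the No- and
Yes-answers along the truthful path.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Sequence, Union

import numpy as np

from .infotheory import distinguished_structure
from .oracle import ErrorRates, QueryRecord, truthful_answer
from .structures import SecondaryStructure, basepair_distance
from .tree import EnsembleTree, EnsembleTreeNode

__all__ = [
    "PathResult",
    "RunMetrics",
    "identify_path",
    "theoretical_leaf_probability",
    "evaluate_run",
    "aggregate_metrics",
]

AnswerFn = Union[Callable[..., int], object]


@dataclass
class PathResult:
    """Outcome of one tree walk."""

    leaf: EnsembleTreeNode
    records: List[QueryRecord]
    l0: int
    l1: int
    distinguished: SecondaryStructure
    distinguished_p: float
    path_nodes: List[EnsembleTreeNode] = field(default_factory=list)

    @property
    def path_length(self) -> int:
        return self.l0 + self.l1


def identify_path(tree: EnsembleTree, answer_fn: AnswerFn) -> PathResult:
    """Descend from the root to a leaf, answering each node's query.

    ``answer_fn`` is either an oracle object with an
    ``answer(pair, node_key)`` method or a bare callable ``pair -> bit``.
    l0/l1 count delivered No/Yes answers (what the walk used).  If an
    answer points at an empty child (cannot happen for query pairs chosen
    from the sample, kept as a safety net), the walk halts at the current
    node.
    """
    ask = answer_fn.answer if hasattr(answer_fn, "answer") else answer_fn
    node = tree.root
    records: List[QueryRecord] = []
    path = [node]
    l0 = l1 = 0
    while node.query is not None:
        pair = node.query.pair
        try:
            bit = int(ask(pair, node.key))
        except TypeError:
            bit = int(ask(pair))
        records.append(QueryRecord(pair, -1, bit, node.key))
        if node.children is None:  # pragma: no cover - structural safety net
            break
        child = node.children[bit]
        if child.size == 0:  # pragma: no cover - cannot occur by construction
            break
        if bit:
            l1 += 1
        else:
            l0 += 1
        node = child
        path.append(node)
    s_star, p_star = distinguished_structure(node.sample)
    return PathResult(
        leaf=node,
        records=records,
        l0=l0,
        l1=l1,
        distinguished=s_star,
        distinguished_p=p_star,
        path_nodes=path,
    )


def theoretical_leaf_probability(l0: int, l1: int, rates: ErrorRates) -> float:
    """P(target in leaf) = (1 - e0)^l0 * (1 - e1)^l1."""
    if l0 < 0 or l1 < 0:
        raise ValueError("answer counts must be non-negative")
    return (1.0 - rates.e0) ** l0 * (1.0 - rates.e1) ** l1


@dataclass
class RunMetrics:
    """Per-run indicators and the base-pair-distance trace along the path."""

    target_in_leaf: bool
    identified: bool
    l0: int
    l1: int
    l1_true: int
    dbp_trace: List[float]


def evaluate_run(result: PathResult, target: SecondaryStructure) -> RunMetrics:
    """Score one walk against the known target.

    ``l1_true`` counts queried pairs on the path actually present in the
    target (truth-confirmed Yes-answers), next to the delivered ``l1``.
    The trace holds, for each node on the path, the multiplicity-weighted
    mean base-pair distance from the target to the node's sub-sample.
    """
    leaf_sample = result.leaf.sample
    in_leaf = target in leaf_sample
    identified = result.distinguished == target
    l1_true = sum(truthful_answer(target, r.pair) for r in result.records)
    trace = []
    for node in result.path_nodes:
        sub = node.sample
        d = sum(
            int(c) * basepair_distance(target, s)
            for s, c in zip(sub.structures, sub.counts)
        )
        trace.append(d / sub.size)
    return RunMetrics(
        target_in_leaf=bool(in_leaf),
        identified=bool(identified),
        l0=result.l0,
        l1=result.l1,
        l1_true=l1_true,
        dbp_trace=trace,
    )


def aggregate_metrics(runs: Sequence[RunMetrics]) -> Dict[str, object]:
    """Summaries across runs: the three identification probabilities (the
    conditional is reported as None when no run has the target in its
    leaf, never imputed), and the l1 histogram."""
    if not runs:
        raise ValueError("need at least one run")
    in_leaf = np.array([r.target_in_leaf for r in runs], dtype=float)
    ident = np.array([r.identified for r in runs], dtype=float)
    out: Dict[str, object] = {
        "n_runs": len(runs),
        "p_in_leaf": float(in_leaf.mean()),
        "p_in_leaf_std": float(in_leaf.std(ddof=0)),
        "p_identified": float(ident.mean()),
        "p_identified_std": float(ident.std(ddof=0)),
        "l1_histogram": dict(sorted(Counter(r.l1 for r in runs).items())),
        "l1_true_histogram": dict(sorted(Counter(r.l1_true for r in runs).items())),
        "mean_l0": float(np.mean([r.l0 for r in runs])),
        "mean_l1": float(np.mean([r.l1 for r in runs])),
    }
    mask = in_leaf > 0
    if mask.any():
        out["p_identified_given_in_leaf"] = float(ident[mask].mean())
        out["n_in_leaf"] = int(mask.sum())
    else:
        out["p_identified_given_in_leaf"] = None
        out["n_in_leaf"] = 0
    return out
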