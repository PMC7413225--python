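"""The ensemble tree: recursive maximum-entropy bipartition of a sample.

Starting from a Boltzmann sample of N structures, each node is split on
its maximum-entropy base pair — the query whose answer is most uncertain —
into the sub-sample containing the pair (child 1) and its complement
(child 0).  Splitting halts when a node is homogeneous (structural
entropy 0) or at the maximum level L = floor(log2 N) + 1, so the height
is at most L - 1 (10 for N = 1024).  Nodes store index lists into the
root's distinct-structure table, never copies, keeping memory at O(L*N);
each level costs O(N * n^2) pair-frequency work, so construction is
O(L * N * n^2) overall.

Levels are counted from the root at level 0; a "frontier" at level t is
the partition of the full multiset carried by the tree at depth t: the
nodes at level t together with leaves halted above t.  Frontier sizes
always sum to N.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from .infotheory import PairQuery, binary_entropy
from .structures import StructureSample

__all__ = [
    "EnsembleTreeNode",
    "EnsembleTree",
    "build_tree",
    "default_max_level",
    "level_frontier",
    "mean_entropy_by_level",
    "mean_query_entropy_by_level",
]


def default_max_level(N: int) -> int:
    """L = floor(log2 N) + 1; e.g. 11 for N = 1024."""
    if N < 1:
        raise ValueError("sample size must be positive")
    return int(math.floor(math.log2(N))) + 1


@dataclass
class EnsembleTreeNode:
    """One node of the ensemble tree.

    ``key`` is the bit string of answers leading here (root: "");
    ``indices`` index the root sample's distinct-structure table.
    ``query`` is None exactly at halted leaves (homogeneous or at the
    last level).
    """

    key: str
    indices: np.ndarray
    size: int
    entropy: float
    query: Optional[PairQuery] = None
    children: Optional[Tuple["EnsembleTreeNode", "EnsembleTreeNode"]] = None
    _tree: Optional["EnsembleTree"] = field(default=None, repr=False)

    @property
    def level(self) -> int:
        return len(self.key)

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    @property
    def sample(self) -> StructureSample:
        """Materialize this node's sub-sample (a view of the root sample)."""
        return self._tree.sample.subset(self.indices)


@dataclass
class EnsembleTree:
    """The full hierarchy plus provenance (engine tag, seed)."""

    root: EnsembleTreeNode
    sample: StructureSample
    max_level: int
    engine: str = "unknown"
    seed: Optional[int] = None

    def nodes(self) -> List[EnsembleTreeNode]:
        """Depth-first (0-child first) list of all nodes."""
        out: List[EnsembleTreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            if node.children is not None:
                stack.append(node.children[1])
                stack.append(node.children[0])
        return out

    def leaves(self) -> List[EnsembleTreeNode]:
        return [v for v in self.nodes() if v.is_leaf]

    @property
    def height(self) -> int:
        return max(v.level for v in self.leaves())

    def to_text(self) -> str:
        """Deterministic serialization: one ``key TAB pair TAB size TAB
        entropy`` line per node, depth first."""
        lines = []
        for v in self.nodes():
            q = f"{v.query.pair[0]},{v.query.pair[1]}" if v.query else "-"
            lines.append(f"{v.key or '@'}\t{q}\t{v.size}\t{v.entropy:.9f}")
        return "\n".join(lines) + "\n"


def build_tree(sample: StructureSample, max_level: Optional[int] = None) -> EnsembleTree:
    """Construct the ensemble tree of a sample by recursive maximum-entropy
    splits (deterministic: ties are fixed by the query selection rule)."""
    if any(s.pseudoknotted for s in sample.structures):
        raise ValueError("ensemble trees require pseudoknot-free structures")
    N = sample.size
    L = default_max_level(N) if max_level is None else int(max_level)
    if L < 1:
        raise ValueError("maximum level must be >= 1")

    pairs, m = sample.pair_table()
    m64 = m.astype(np.int64)
    counts = sample.counts
    log_counts = np.log2(counts.astype(float))

    def node_entropy(idx: np.ndarray, size: int) -> float:
        if len(idx) == 1:
            return 0.0
        c = counts[idx]
        # H = log2(size) - sum(c * log2 c)/size, avoiding per-node division
        return max(0.0, float(math.log2(size) - (c * log_counts[idx]).sum() / size))

    tree = EnsembleTree(root=None, sample=sample, max_level=L)  # type: ignore[arg-type]

    def grow(key: str, idx: np.ndarray) -> EnsembleTreeNode:
        size = int(counts[idx].sum())
        ent = node_entropy(idx, size)
        node = EnsembleTreeNode(key=key, indices=idx, size=size, entropy=ent, _tree=tree)
        if ent <= 0.0 or len(key) >= L - 1:
            return node
        freq = counts[idx] @ m64[idx]
        informative = (freq > 0) & (freq < size)
        # a node with entropy > 0 has >= 2 distinct structures, which must
        # differ in at least one pair, so a candidate always exists
        cand = np.flatnonzero(informative)
        if len(cand) == 0:  # pragma: no cover - defensive
            return node
        p = freq[cand] / size
        best = cand[int(np.argmin(np.abs(p - 0.5)))]
        pbest = freq[best] / size
        node.query = PairQuery(
            pair=pairs[best], probability=float(pbest), entropy=binary_entropy(pbest)
        )
        col = m[idx, best].astype(bool)
        node.children = (
            grow(key + "0", idx[~col]),
            grow(key + "1", idx[col]),
        )
        return node

    tree.root = grow("", np.arange(len(sample.structures)))
    return tree


def level_frontier(tree: EnsembleTree, t: int) -> List[EnsembleTreeNode]:
    """The partition of the sample at level ``t``: nodes at level t plus
    leaves halted at levels < t.  Sizes always sum to N."""
    if not (0 <= t < tree.max_level):
        raise ValueError(f"level {t} outside [0, {tree.max_level})")
    out: List[EnsembleTreeNode] = []
    stack = [tree.root]
    while stack:
        v = stack.pop()
        if v.level == t or (v.is_leaf and v.level < t):
            out.append(v)
        elif v.children is not None:
            stack.append(v.children[1])
            stack.append(v.children[0])
    return out


def _frontier_mean(
    tree: EnsembleTree, t: int, value: Callable[[EnsembleTreeNode], float], weighting: str
) -> float:
    nodes = level_frontier(tree, t)
    if weighting == "size":
        total = sum(v.size for v in nodes)
        return sum(v.size * value(v) for v in nodes) / total
    if weighting == "uniform":
        return sum(value(v) for v in nodes) / len(nodes)
    raise ValueError(f"unknown weighting {weighting!r}")


def mean_entropy_by_level(
    trees: Sequence[EnsembleTree], *, weighting: str = "size"
) -> np.ndarray:
    """Mean structural entropy H(Omega_t) per level, averaged over the
    frontier of each tree (size-weighted by default, halted leaves carried
    forward) and then across trees."""
    if not trees:
        raise ValueError("need at least one tree")
    L = max(tr.max_level for tr in trees)
    out = np.zeros(L)
    for t in range(L):
        vals = [
            _frontier_mean(tr, min(t, tr.max_level - 1), lambda v: v.entropy, weighting)
            for tr in trees
        ]
        out[t] = float(np.mean(vals))
    return out


def mean_query_entropy_by_level(
    trees: Sequence[EnsembleTree], *, weighting: str = "size"
) -> np.ndarray:
    """Mean entropy H(X_t) of the queried base pairs at each level,
    averaged over the interior nodes at exactly that level (size-weighted
    by default); NaN at levels where no tree queries."""
    if not trees:
        raise ValueError("need at least one tree")
    L = max(tr.max_level for tr in trees)
    out = np.full(L, np.nan)
    for t in range(L):
        vals: List[float] = []
        for tr in trees:
            nodes = [v for v in level_frontier(tr, min(t, tr.max_level - 1))
                     if v.level == t and v.query is not None]
            if not nodes:
                continue
            if weighting == "size":
                total = sum(v.size for v in nodes)
                vals.append(sum(v.size * v.query.entropy for v in nodes) / total)
            else:
                vals.append(sum(v.query.entropy for v in nodes) / len(nodes))
        if vals:
            out[t] = float(np.mean(vals))
    return out
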