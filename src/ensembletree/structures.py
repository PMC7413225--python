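"""RNA secondary structures, samples and their elementary statistics.

Coordinates are 1-based and inclusive throughout: a base pair ``(i, j)``
pairs the i-th with the j-th nucleotide, ``1 <= i < j <= n``.  Structures
are pseudoknot-free sets of base pairs with a minimum hairpin loop of 3
unpaired bases (``j - i >= 4``), the convention enforced by all standard
folding engines.  Conversion to 0-based indexing happens only at I/O
boundaries.

A :class:`StructureSample` is a multiset of ``N`` structures over one
sequence length; ``p(s) = f(s)/N`` and the sample pair probability is
``p_ij = f(i,j)/N``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "RnaSequence",
    "SecondaryStructure",
    "StructureSample",
    "GreyscaleDiagram",
    "parse_dotbracket",
    "write_dotbracket",
    "signature_of",
    "signature_distance",
    "basepair_distance",
    "pair_probabilities",
    "greyscale_diagram",
    "read_fasta",
    "read_ct",
    "write_ct",
    "write_sample_archive",
    "read_sample_archive",
]

BASES = frozenset("AUCG")
MIN_LOOP = 3  # minimum number of unpaired bases in a hairpin loop

Pair = Tuple[int, int]


class RnaSequence:
    """An RNA sequence over the alphabet {A, U, C, G}.

    ``T`` is accepted on input and normalized to ``U``; case is folded to
    upper case.
    """

    __slots__ = ("bases",)

    def __init__(self, bases: str):
        bases = str(bases).strip().upper().replace("T", "U")
        bad = set(bases) - BASES
        if bad:
            raise ValueError(f"illegal characters in RNA sequence: {sorted(bad)}")
        if not bases:
            raise ValueError("empty RNA sequence")
        self.bases = bases

    def __len__(self) -> int:
        return len(self.bases)

    def __str__(self) -> str:
        return self.bases

    def __repr__(self) -> str:
        return f"RnaSequence({self.bases!r})"

    def __eq__(self, other) -> bool:
        return isinstance(other, RnaSequence) and self.bases == other.bases

    def __hash__(self) -> int:
        return hash(self.bases)

    def __getitem__(self, k):
        # 0-based slicing/access, as for plain strings
        return self.bases[k]


def _check_nested(pairs: Sequence[Pair]) -> Optional[Tuple[Pair, Pair]]:
    """Return a crossing pair of arcs if one exists, else None."""
    ordered = sorted(pairs)
    open_stack: List[Pair] = []
    for p in ordered:
        i, j = p
        while open_stack and open_stack[-1][1] < i:
            open_stack.pop()
        if open_stack and i < open_stack[-1][1] < j:
            return open_stack[-1], p
        open_stack.append(p)
    return None


class SecondaryStructure:
    """A pseudoknot-free RNA secondary structure: a set of base pairs.

    Parameters
    ----------
    pairs
        Iterable of 1-based ``(i, j)`` tuples with ``i < j``.
    n
        Sequence length.
    allow_pseudoknots
        If True, crossing arcs are stored rather than rejected (storage
        only; the tree and oracle machinery refuse pseudoknotted input).
    """

    __slots__ = ("pairs", "n", "pseudoknotted")

    def __init__(self, pairs: Iterable[Pair], n: int, *, allow_pseudoknots: bool = False):
        n = int(n)
        if n < 1:
            raise ValueError("sequence length must be positive")
        norm = frozenset((int(i), int(j)) for i, j in pairs)
        seen: Dict[int, Pair] = {}
        for i, j in norm:
            if not (1 <= i < j <= n):
                raise ValueError(f"base pair ({i},{j}) out of range for n={n}")
            if j - i < MIN_LOOP + 1:
                raise ValueError(
                    f"base pair ({i},{j}) violates the minimum hairpin loop "
                    f"(need j - i >= {MIN_LOOP + 1})"
                )
            for k in (i, j):
                if k in seen:
                    raise ValueError(f"base {k} occurs in two pairs {seen[k]} and ({i},{j})")
                seen[k] = (i, j)
        crossing = _check_nested(sorted(norm))
        if crossing is not None and not allow_pseudoknots:
            raise ValueError(f"crossing base pairs {crossing[0]} and {crossing[1]} (pseudoknot)")
        self.pairs = norm
        self.n = n
        self.pseudoknotted = crossing is not None

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SecondaryStructure)
            and self.n == other.n
            and self.pairs == other.pairs
        )

    def __hash__(self) -> int:
        return hash((self.n, self.pairs))

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: Pair) -> bool:
        return tuple(pair) in self.pairs

    def __repr__(self) -> str:
        return f"SecondaryStructure({self.to_dotbracket()!r})"

    def to_dotbracket(self) -> str:
        return write_dotbracket(self)

    def signature(self) -> np.ndarray:
        return signature_of(self)


def parse_dotbracket(text: str, *, allow_pseudoknots: bool = False) -> SecondaryStructure:
    """Parse a dot-bracket string into a :class:`SecondaryStructure`.

    Only ``.``, ``(`` and ``)`` are accepted; positions are 1-based.
    """
    text = text.strip()
    pairs: List[Pair] = []
    stack: List[int] = []
    for pos, c in enumerate(text, start=1):
        if c == "(":
            stack.append(pos)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {pos}")
            pairs.append((stack.pop(), pos))
        elif c != ".":
            raise ValueError(f"illegal character {c!r} at position {pos}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return SecondaryStructure(pairs, len(text), allow_pseudoknots=allow_pseudoknots)


def write_dotbracket(s: SecondaryStructure) -> str:
    """Serialize a structure as a dot-bracket string of length ``n``."""
    out = ["."] * s.n
    for i, j in s.pairs:
        out[i - 1] = "("
        out[j - 1] = ")"
    return "".join(out)


def signature_of(s: SecondaryStructure) -> np.ndarray:
    """The 0-1 signature: entry ``k`` is 1 iff base ``k+1`` is paired.

    The signature is the in-silico stand-in for a per-nucleotide chemical
    probing profile (paired/unpaired at nucleotide resolution).
    """
    sig = np.zeros(s.n, dtype=np.uint8)
    for i, j in s.pairs:
        sig[i - 1] = 1
        sig[j - 1] = 1
    return sig


def signature_distance(s: SecondaryStructure, t: SecondaryStructure) -> int:
    """Hamming distance between the structures' 0-1 signatures (d_sn)."""
    if s.n != t.n:
        raise ValueError(f"length mismatch: {s.n} vs {t.n}")
    return int(np.count_nonzero(signature_of(s) != signature_of(t)))


def basepair_distance(s: SecondaryStructure, t: SecondaryStructure) -> int:
    """Cardinality of the symmetric difference of the pair sets (d_bp)."""
    if s.n != t.n:
        raise ValueError(f"length mismatch: {s.n} vs {t.n}")
    return len(s.pairs ^ t.pairs)


class StructureSample:
    """A multiset of ``N`` secondary structures over one sequence.

    Stored as distinct structures with multiplicities ``f(s)`` (first-seen
    order, which makes serialization deterministic).  Derived quantities:
    ``p(s) = f(s)/N`` and pair probabilities ``p_ij = f(i,j)/N``.
    """

    def __init__(
        self,
        structures: Iterable[SecondaryStructure],
        counts: Optional[Sequence[int]] = None,
        *,
        sequence: Optional[RnaSequence] = None,
    ):
        if counts is None:
            distinct: List[SecondaryStructure] = []
            index: Dict[SecondaryStructure, int] = {}
            cnt: List[int] = []
            for s in structures:
                k = index.get(s)
                if k is None:
                    index[s] = len(distinct)
                    distinct.append(s)
                    cnt.append(1)
                else:
                    cnt[k] += 1
            self.structures = tuple(distinct)
            self.counts = np.asarray(cnt, dtype=np.int64)
        else:
            self.structures = tuple(structures)
            self.counts = np.asarray(list(counts), dtype=np.int64)
            if len(self.structures) != len(self.counts):
                raise ValueError("structures and counts length mismatch")
            if len(set(self.structures)) != len(self.structures):
                raise ValueError("duplicate distinct structures")
            if np.any(self.counts < 1):
                raise ValueError("multiplicities must be positive")
        if not self.structures:
            raise ValueError("empty structure sample")
        ns = {s.n for s in self.structures}
        if len(ns) != 1:
            raise ValueError("structures of differing lengths in one sample")
        self.n = ns.pop()
        if sequence is not None and len(sequence) != self.n:
            raise ValueError("sequence length does not match structures")
        self.sequence = sequence
        self._pair_cache: Optional[Tuple[List[Pair], np.ndarray]] = None

    @property
    def size(self) -> int:
        """Total multiset cardinality N."""
        return int(self.counts.sum())

    def __len__(self) -> int:
        return self.size

    def __iter__(self) -> Iterator[SecondaryStructure]:
        for s, c in zip(self.structures, self.counts):
            for _ in range(int(c)):
                yield s

    def probabilities(self) -> np.ndarray:
        """p(s) = f(s)/N over distinct structures, in storage order."""
        return self.counts / self.size

    def multiplicity(self, s: SecondaryStructure) -> int:
        for t, c in zip(self.structures, self.counts):
            if t == s:
                return int(c)
        return 0

    def __contains__(self, s: SecondaryStructure) -> bool:
        return self.multiplicity(s) > 0

    def pair_table(self) -> Tuple[List[Pair], np.ndarray]:
        """Distinct pairs (sorted) and the membership matrix.

        Returns ``(pairs, M)`` where ``M[a, b] = 1`` iff distinct structure
        ``a`` contains ``pairs[b]``.  Cached; this is the workhorse of the
        ensemble-tree construction.
        """
        if self._pair_cache is None:
            all_pairs = sorted({p for s in self.structures for p in s.pairs})
            col = {p: b for b, p in enumerate(all_pairs)}
            m = np.zeros((len(self.structures), len(all_pairs)), dtype=np.uint8)
            for a, s in enumerate(self.structures):
                for p in s.pairs:
                    m[a, col[p]] = 1
            self._pair_cache = (all_pairs, m)
        return self._pair_cache

    def subset(self, idx: Sequence[int]) -> "StructureSample":
        """Sub-multiset given indices into the distinct-structure table."""
        idx = list(idx)
        return StructureSample(
            [self.structures[a] for a in idx],
            self.counts[idx],
            sequence=self.sequence,
        )


def pair_probabilities(sample: StructureSample) -> Dict[Pair, float]:
    """Sample pair probabilities ``p_ij = f(i,j)/N``, only pairs with p > 0."""
    pairs, m = sample.pair_table()
    freq = sample.counts @ m.astype(np.int64)
    N = sample.size
    return {p: float(f) / N for p, f in zip(pairs, freq) if f > 0}


@dataclass
class GreyscaleDiagram:
    """Superimposed arc diagram of a sample: each pair (i, j) with p_ij > 0
    drawn as an arc of greyscale ``1 - p_ij`` (0 = black = certain pair)."""

    n: int
    arcs: List[Tuple[int, int, float]] = field(default_factory=list)

    def to_svg(self) -> str:
        """Render as an SVG string: arcs above a horizontal backbone,
        greyscale mapped linearly to 8-bit grey."""
        scale = 8.0
        width = (self.n + 1) * scale
        maxspan = max((j - i for i, j, _ in self.arcs), default=4)
        height = maxspan * scale / 2 + 3 * scale
        lines = [
            f'<svg xmlns="http://www.w3.org/2000/svg" width="{width:.0f}" '
            f'height="{height:.0f}" viewBox="0 0 {width:.0f} {height:.0f}">',
            f'<line x1="{scale:.1f}" y1="{height - scale:.1f}" x2="{self.n * scale:.1f}" '
            f'y2="{height - scale:.1f}" stroke="black" stroke-width="1"/>',
        ]
        for i, j, grey in sorted(self.arcs):
            level = int(round(255 * min(max(grey, 0.0), 1.0)))
            x1, x2 = i * scale, j * scale
            r = (x2 - x1) / 2
            y = height - scale
            lines.append(
                f'<path d="M {x1:.1f} {y:.1f} A {r:.1f} {r:.1f} 0 0 1 {x2:.1f} {y:.1f}" '
                f'fill="none" stroke="rgb({level},{level},{level})" stroke-width="1"/>'
            )
        lines.append("</svg>")
        return "\n".join(lines)


def greyscale_diagram(sample: StructureSample) -> GreyscaleDiagram:
    """Build the greyscale arc diagram of a sample."""
    probs = pair_probabilities(sample)
    return GreyscaleDiagram(
        n=sample.n, arcs=[(i, j, 1.0 - p) for (i, j), p in sorted(probs.items())]
    )


# ---------------------------------------------------------------------------
# File formats


def read_fasta(path) -> List[Tuple[str, RnaSequence]]:
    """Read (id, sequence) records from a FASTA file; T is normalized to U."""
    from Bio import SeqIO

    return [(rec.id, RnaSequence(str(rec.seq))) for rec in SeqIO.parse(str(path), "fasta")]


def read_ct(path) -> Tuple[RnaSequence, SecondaryStructure]:
    """Read a single structure in connect (CT) format.

    Only columns 1 (index), 2 (base) and 5 (pairing partner) are
    interpreted; pairs are deduplicated symmetrically.
    """
    bases: List[str] = []
    pairs: set = set()
    with open(path) as fh:
        header = fh.readline().split()
        if not header:
            raise ValueError("empty CT file")
        n = int(header[0])
        for line in fh:
            fields = line.split()
            if len(fields) < 6:
                continue
            k, base, partner = int(fields[0]), fields[1], int(fields[4])
            bases.append(base)
            if partner > 0:
                pairs.add((min(k, partner), max(k, partner)))
            if k == n:
                break
    seq = RnaSequence("".join(bases))
    if len(seq) != n:
        raise ValueError(f"CT header says n={n} but {len(seq)} bases were read")
    return seq, SecondaryStructure(pairs, n)


def write_ct(path, sequence: RnaSequence, s: SecondaryStructure, *, title: str = "") -> None:
    """Write a single structure in connect (CT) format."""
    if len(sequence) != s.n:
        raise ValueError("sequence/structure length mismatch")
    partner = [0] * (s.n + 1)
    for i, j in s.pairs:
        partner[i], partner[j] = j, i
    with open(path, "w") as fh:
        fh.write(f"{s.n} {title}\n")
        for k in range(1, s.n + 1):
            fh.write(
                f"{k} {sequence[k - 1]} {k - 1} {(k + 1) if k < s.n else 0} {partner[k]} {k}\n"
            )


def write_sample_archive(
    path, sample: StructureSample, *, engine: str = "unknown", seed: Optional[int] = None
) -> None:
    """Plain-text sample archive: a header line followed by one
    ``dot-bracket TAB multiplicity`` line per distinct structure."""
    seq = str(sample.sequence) if sample.sequence is not None else "." * sample.n
    with open(path, "w") as fh:
        fh.write(f"# sequence={seq} N={sample.size} engine={engine} seed={seed}\n")
        for s, c in zip(sample.structures, sample.counts):
            fh.write(f"{s.to_dotbracket()}\t{int(c)}\n")


def read_sample_archive(path) -> StructureSample:
    """Read a sample archive written by :func:`write_sample_archive`."""
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError("missing archive header")
        meta = dict(tok.split("=", 1) for tok in header[1:].split() if "=" in tok)
        structures: List[SecondaryStructure] = []
        counts: List[int] = []
        for line in fh:
            if not line.strip():
                continue
            db, cnt = line.split("\t")
            structures.append(parse_dotbracket(db))
            counts.append(int(cnt))
    seq = meta.get("sequence")
    sequence = RnaSequence(seq) if seq and set(seq) <= set("AUCGT") else None
    return StructureSample(structures, counts, sequence=sequence)
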