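# ensembletree

Identify a target RNA secondary structure inside a Boltzmann ensemble by
asking a small number of maximally informative base-pair questions.

## The problem

Chemical probing (SHAPE and friends) reports, per nucleotide, whether a
base is likely paired or unpaired — but not *with whom* it pairs.  Even
with probing constraints, many secondary structures remain consistent
with the data, and thermodynamic samplers return an ensemble Ω of
candidate folds rather than the one structure the molecule actually
assumes (the *target* s).  This package implements an
information-theoretic search for the target inside such an ensemble,
aimed at people who work with Boltzmann samples of RNA secondary
structures and want to rank, split, or interrogate them.

## The method

A sample Ω′ of N structures (multiplicities f(s), probabilities
p(s) = f(s)/N) assigns every base pair (i, j) a probability
p\_ij = Σ\_s p(s) δ\_ij(s) and hence a query entropy

    H(X_ij) = −p_ij log2 p_ij − (1 − p_ij) log2(1 − p_ij).

Asking whether (i, j) is in the target splits Ω′ into the structures
containing the pair and the rest.  Two elementary facts drive the
method: the entropy reduction of the split equals H(X\_ij) exactly, and
the maximum-entropy pair (p\_ij nearest ½) gives the most balanced
possible split.  Recursively splitting on maximum-entropy pairs yields
the **ensemble tree**, halting at homogeneous nodes or at level
L = log2 N + 1 (11 for N = 1024).  Answering the L − 1 queries along a
root-to-leaf path — with answers that may independently lie at rates e0
(No-answers) and e1 (Yes-answers), a Rényi–Ulam game — lands in a leaf
Ω\* that contains the target with probability
(1 − e0)^l0 (1 − e1)^l1.  A leaf with structural entropy
H(Ω\*) ≤ 1 bit provably carries a *distinguished* structure of
probability at least f(H), the inverse binary entropy on [½, 1]
(f(1) = 0.5, f(0.469) ≈ 0.9), and that structure is reported as the
identification.

Queries can be answered experimentally through *modularity*: cut the
sequence at (i, j), probe (here: fold) the enclosed fragment and the
remainder glued at the cut points, re-embed the two per-nucleotide
profiles, and compare with the full-length profile; a Hamming distance
below a threshold θ confirms the pair.  The classifier's false omission
and discovery rates are the game's e0 and e1.  Probing-constrained
ensembles are emulated by the q-Boltzmann ensemble: structures whose 0-1
signature distance to the target is at most q·n (q = 0.05 mimics
SHAPE-constrained sampling), drawn by a signature-biased proposal with
exact rejection.

## Worked example

```python
from ensembletree import (Composition, ErrorRates, KnownTargetOracle, ViennaEngine,
                          boltzmann_sample, build_tree, choose_target,
                          identify_path, random_sequence, theoretical_leaf_probability)

x = random_sequence(300, Composition.uniform(), seed=31)
sample = boltzmann_sample(x, 1024, ViennaEngine(), seed=32)   # Boltzmann multiset, N = 1024
target = choose_target(sample, seed=33)                       # Boltzmann-weighted draw
tree = build_tree(sample)                                     # max level 11

truthful = identify_path(tree, KnownTargetOracle(target))
print(truthful.l0, truthful.l1)
print(theoretical_leaf_probability(truthful.l0, truthful.l1, ErrorRates(0.05, 0.01)))
```

prints

```
4 6
0.7666...
```

the truthful path answers four queries No and six Yes, so with lie rates
e0 = 0.05 and e1 = 0.01 a noisy walk keeps the target in its leaf with
probability 0.95⁴ · 0.99⁶ ≈ 0.767.  Running 400 noisy walks on this tree
(`examples/03_identify_with_noisy_oracle.py`) measures 0.777 — within
Monte-Carlo noise of the closed form — and identifies the target exactly
in 77.7% of walks.  The other scripts in `examples/` demonstrate
greyscale arc diagrams, the per-level entropy drain of the tree
(≈ 1 bit per level: 9.99 at the root down to 0.29 in the leaves for a
200-nt sequence), the modularity oracle's distance distributions
(medians 14 vs 42 at 150 nt), and q-filtration (mean signature distance
collapsing from 0.151 n to 0.006 n at q = 0.05).

A thin CLI mirrors the library: `ensembletree sample | stats | tree |
identify | oracle | bench-identify | bench-q | bench-robustness |
bench-classes | bench-modularity`.

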