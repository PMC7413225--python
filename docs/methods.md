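# Methods

This note records the model, the defaults, and the design decisions
behind `ensembletree`, in the spirit of a statistical software methods
appendix.  Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Model and procedure

An RNA sequence x of length n is assumed to be in thermodynamic
equilibrium over its pseudoknot-free secondary structures,
p(s) ∝ exp(−E(s)/RT).  We work with finite samples Ω′ of N structures
drawn from that distribution (multiset with multiplicities f(s)); all
ensemble quantities — p(s) = f(s)/N, pair probabilities
p_ij = f(i,j)/N, structural entropy H(Ω′) = −Σ p(s) log2 p(s) — are
sample quantities.  The identification procedure is:

1. build the ensemble tree by recursively splitting each sub-sample on
   its maximum-entropy base pair, halting at entropy 0 or at level
   L = ⌊log2 N⌋ + 1;
2. walk from root to leaf, answering each node's query about the target
   through an oracle that lies independently with rates e0 (truthful
   answer No) and e1 (truthful answer Yes);
3. report the leaf's maximum-multiplicity (distinguished) structure.

Two exact identities, verified as invariants in the test suite, justify
the query rule: the entropy reduction of a pair query equals the query's
own entropy (chain rule for a Bernoulli conditioning variable), and the
maximum-entropy pair minimizes |P(Ω₀) − P(Ω₁)| over all pairs.  The
probability that a leaf's distinguished structure dominates is bounded
through f(E), the inverse of the binary entropy on [½, 1], computed by
bisection to 1e−10.

Assumptions worth making explicit: the target is a member of the
ensemble (the framework identifies a member, it does not predict folds
de novo); structures are nested (pseudoknots are storable but rejected
by the tree and oracle machinery); lies are independent across queries.

## Structures and conventions

* Coordinates are 1-based inclusive; conversion happens only at I/O
  boundaries (CT, FASTA, dot-bracket, SVG).
* Minimum hairpin loop of 3 unpaired bases (j − i ≥ 4), the convention
  of standard folding engines, enforced at construction.
* The 0-1 signature (bit k = 1 iff base k is paired) stands in for a
  per-nucleotide probing profile; d_sn is the Hamming distance of
  signatures, d_bp the symmetric-difference size of pair sets.

## Engines

* **ViennaEngine** (production): ViennaRNA fold compounds with
  `uniq_ML=1`; MFE, partition function with rescaling, stochastic
  backtracking; optional per-nucleotide soft-constraint bias (below).
  Reproducibility through ViennaRNA's own RNG seed.
* **NussinovEngine** (toy, test default): pair-counting partition
  function Z = Σ_s w^{|s|} over canonical pairs (Watson–Crick + GU) with
  minimum loop 3, default pair weight w = 2 (chosen so that typical toy
  samples are neither degenerate-empty nor saturated); exact stochastic
  backtracking, deterministic under a Python `random.Random` seed.  It
  is a study vehicle for the combinatorics, not a thermodynamic model:
  it has no stacking, no loop penalties, no temperature.
* **UniformEngine**: exact uniform sampling over all structures via
  big-integer counting DP, restricted to n ≤ 120; used for the
  sample-class comparison.

## Synthetic data: what it emulates and what it does not

Benchmarks run on i.i.d. random sequences with named compositions
(uniform 25/25/25/25; GC-rich 20% A, 20% U, 30% C, 30% G; AU-rich the
mirror image), lengths 100–300, N = 1024 (512–2048 in the robustness
grid), lie rates e0 = 0.05 and e1 = 0.01, and targets drawn
Boltzmann-weighted from the unrestricted sample.  Random sequences lack
the conserved helices, modular domains and reduced ensemble diversity of
natural RNAs, and the MFE signature used by the modularity oracle is a
noise-free stand-in for reactivity data; passing benchmarks therefore
demonstrate the machinery's statistical behavior under the stated model,
not accuracy on curated natural RNAs with measured SHAPE profiles (the
profile interface accepts real 0/1-called reactivities unchanged).

## The q-Boltzmann sampler

Ω^q = {s′ : d_sn(s′, s) ≤ q·n} emulates a probing-constrained ensemble
(q = 0.05 by convention).  Plain rejection from the unrestricted
ensemble is infeasible (unrestricted mean d_sn/n ≈ 0.2), so sampling
uses a *signature-biased proposal*: every nucleotide receives a
pseudo-energy bonus of magnitude 1 kcal/mol toward the target's
paired/unpaired state (ViennaRNA soft constraints), after which the
admission rule d_sn ≤ q·n is applied exactly to every proposal.  The
bias magnitude is configurable; 1 kcal/mol is of the order of published
SHAPE pseudo-energy discrimination and makes the *unfiltered* proposal's
mean d_sn/n land near 0.03, the dispersion reported for
probing-constrained ensembles.  Because the framework presupposes that
the ensemble contains the target (and the target trivially satisfies
d = 0), the sampler guarantees membership: if a filtered draw happens to
miss the target, one copy replaces one copy of a least-frequent member
(a no-op at q = 0.05 and n = 300, where the target's multiplicity is
typically large).

Two caveats are documented rather than hidden.  First, bias-then-filter
fixes the *support* exactly but not the within-ball distribution: it is
tilted toward signature-compatible structures relative to the true
restricted Boltzmann distribution.  Second, the exact restricted
Boltzmann distribution on the ball assigns the target itself a small
probability, so "how concentrated a probing ensemble is around its
target" is model-dependent; our identification rates for q-filtered
ensembles (reported by the acceptance script) are what this construction
yields, and are several points below rates reported elsewhere for more
concentrated probe-ensemble constructions.

## Oracles

* Known-target oracle: truthful bit δ_ij(s) flipped with probability e0
  or e1; k-fold repetition reduces the effective error to
  e^[k] = e^k / (e^k + (1−e)^k) under equal prior odds (k = 2 uses
  ask-until-two-concordant, odd k a majority vote).
* Modularity oracle: cut at (i, j), MFE-fold the fragment and the glued
  remainder, re-embed the two signatures (ε ∘ ξ = id holds for
  sequences, signatures and numeric profiles), Hamming-compare against
  the full profile, confirm iff distance < θ (strict).  θ defaults to
  round(31 · n/500): the reference calibration was performed at 500 nt
  and the threshold is scaled linearly with length, a documented choice
  in the absence of a stated length dependence.  The full calibration
  sweep (thousands of sequences × all O(n²) cuts × O(n³) folds) is
  O(n⁶) and is reproduced only directionally at desk scale: modular cut
  distances sit well below random cut distances, the false omission rate
  falls and the false discovery rate rises with θ (assessed as signed
  trend tests — Spearman rank correlation — because FOR/FDR are not
  pointwise monotone near θ = 0: random cuts in unpaired regions can
  leave the fold unchanged, producing genuine distance-0 false
  positives).

## Numerical and tie-breaking choices

* All entropies in bits; 0·log 0 := 0; float comparisons at 1e−9.
* Query selection: argmin |p_ij − ½|, ties broken lexicographically on
  (i, j) — trees are byte-identical across rebuilds.
* Distinguished-structure ties broken lexicographically on dot-bracket.
* A homogeneous node's entropy is exactly 0 (guarding against float
  round-off triggering a split with no candidate pair).
* Tree nodes hold index lists into the root's distinct-structure table:
  O(L·N) memory, O(L·N·n²) time via vectorized pair-frequency counts.
* Level statistics use *frontier* semantics (leaves halted above level t
  are carried into level t's partition, so frontier sizes always sum to
  N), size-weighted within a tree and then averaged across trees; a
  node-uniform weighting is available as an option.

## Problem sizes

The default benchmark scale is 100 sequences per condition (the
reference studies use 1000; `full_scale=True` restores that), with
Monte-Carlo standard errors reported next to every point estimate.  The
acceptance script uses 150 sequences × 4 walks for the n = 300
identification benchmark, 300 sequences for the n = 200 leaf-entropy
mean (its between-sequence spread is large, std ≈ 0.2), and 50
sequences × 2 walks for the q-filtration benchmark.

## Known limitations

* No pseudoknots in the tree/oracle path (fragment modularity breaks
  down when loops cross); no tertiary interactions.
* No continuous reactivity noise model: profiles are 0/1 vectors.
* The toy engine's ensembles are flatter than thermodynamic ones; tests
  that need realistic concentration use the ViennaRNA engine.
* The uniform sampler's big-integer DP is quadratic in memory and
  restricted to n ≤ 120.
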