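"""Identify a hidden target by querying a lying oracle.

A target structure is drawn from the Boltzmann sample; the walk down the
ensemble tree asks whether each node's maximum-entropy pair is in the
target, with answers lying independently at rates e0 (No) and e1 (Yes).
The fraction of walks ending in a target-containing leaf matches the
closed form (1-e0)^l0 (1-e1)^l1 along the truthful path.
"""

from ensembletree import (
    Composition,
    ErrorRates,
    KnownTargetOracle,
    ViennaEngine,
    boltzmann_sample,
    build_tree,
    choose_target,
    evaluate_run,
    identify_path,
    random_sequence,
    theoretical_leaf_probability,
)

x = random_sequence(300, Composition.uniform(), seed=31)
sample = boltzmann_sample(x, 1024, ViennaEngine(), seed=32)
target = choose_target(sample, seed=33)
tree = build_tree(sample)
rates = ErrorRates(e0=0.05, e1=0.01)

truthful = identify_path(tree, KnownTargetOracle(target))
p_theory = theoretical_leaf_probability(truthful.l0, truthful.l1, rates)
print(f"truthful path: l0={truthful.l0} No-answers, l1={truthful.l1} Yes-answers")
print(f"theoretical P(target in leaf) = 0.95^{truthful.l0} * 0.99^{truthful.l1} = {p_theory:.3f}")

hits = ident = 0
trials = 400
for k in range(trials):
    res = identify_path(tree, KnownTargetOracle(target, rates, seed=k))
    m = evaluate_run(res, target)
    hits += m.target_in_leaf
    ident += m.identified
print(f"empirical over {trials} noisy walks: P(target in leaf) = {hits / trials:.3f}, "
      f"P(distinguished = target) = {ident / trials:.3f}")
print("(the empirical membership rate should sit within Monte-Carlo noise of the closed form)")
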