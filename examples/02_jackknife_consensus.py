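"""Jackknife trees and the consensus network.

Simulates five genomes, resamples genes 60 times (removing 40% each
replicate), builds NJ trees on inversion distances, and keeps every
split supported by at least 10% of the trees. Split weights are the
jackknife support of the corresponding bifurcation.
"""

import numpy as np

from gonet import (
    ConsensusConfig,
    JackknifeConfig,
    consensus_network,
    evolve,
    assign_branch_inversions,
    identity_permutation,
    jackknife_trees,
    yule_tree,
)

rng = np.random.default_rng(7)
tree = yule_tree(5, rng)
assign_branch_inversions(tree, 3.0, rng)
gs = evolve(identity_permutation(60), tree, rng)

cfg = JackknifeConfig(removal_fraction=0.40, replicates=60, seed=1)
trees = jackknife_trees(gs, cfg)
net = consensus_network(trees, ConsensusConfig(inclusion_threshold=0.10))

print(f"{len(trees)} jackknife trees over {len(gs)} taxa")
print("splits with >= 10% support (weight = fraction of trees):")
for s in sorted(net.nontrivial(), key=str):
    print(f"  {s}  support={net.weight(s):.2f}")
print("Conflicting splits with moderate support would appear side by")
print("side here; a tree can only ever show one of them.")
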