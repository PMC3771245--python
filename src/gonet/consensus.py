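"""Consensus networks: splits occurring in enough of a set of trees.

A split enters the network iff it occurs in at least a threshold
fraction of the input trees (10% by default); its weight is that
fraction (the jackknife support of the bifurcation). Only topologies
are read from the trees. No filtering beyond the frequency threshold is
applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import dendropy

from .splits import Split, SplitSystem, splits_from_tree

__all__ = ["ConsensusConfig", "consensus_network"]


@dataclass(frozen=True)
class ConsensusConfig:
    """inclusion_threshold: minimum fraction of trees a split must occur in.

    The comparison is done in exact rational arithmetic (the float is
    read via its shortest decimal repr), so a split present in exactly
    10 of 100 trees meets the default threshold of 0.10 and one present
    in 9 of 100 does not.
    """

    inclusion_threshold: float | Fraction = 0.10

    def __post_init__(self) -> None:
        t = self.threshold_fraction
        if not (0 < t <= 1):
            raise ValueError("inclusion_threshold must be in (0, 1]")

    @property
    def threshold_fraction(self) -> Fraction:
        t = self.inclusion_threshold
        return t if isinstance(t, Fraction) else Fraction(str(t))


def consensus_network(
    trees: Sequence[dendropy.Tree], cfg: ConsensusConfig = ConsensusConfig()
) -> SplitSystem:
    """Build the consensus network of a tree collection.

    All trees must be over the same taxon set; multifurcating trees
    simply contribute fewer splits. Trivial splits occur in every tree
    and therefore always appear with weight 1.
    """
    if not trees:
        raise ValueError("consensus network requires at least one tree")
    threshold = cfg.threshold_fraction
    total = len(trees)
    counts: dict[Split, int] = {}
    taxa: frozenset[str] | None = None
    for tree in trees:
        tree_splits = splits_from_tree(tree, topology_only=True)
        tset = frozenset(tree_splits.taxa)
        if taxa is None:
            taxa = tset
        elif tset != taxa:
            raise ValueError("input trees are over different taxon sets")
        for s in tree_splits:
            counts[s] = counts.get(s, 0) + 1
    ss = SplitSystem(tuple(sorted(taxa)))
    for s, c in sorted(counts.items(), key=lambda kv: str(kv[0])):
        freq = Fraction(c, total)
        if freq >= threshold:
            ss.add(s, float(freq))
    return ss
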