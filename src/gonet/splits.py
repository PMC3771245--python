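"""Splits, split systems, and the network-vs-tree evaluation metrics.

A *split* is a bipartition of the taxon set; every edge of an unrooted
phylogenetic tree induces one. A split is *trivial* if one side is a
single taxon. A split network is encoded here simply as a weighted set
of splits (a :class:`SplitSystem`); drawing the network is out of scope,
but the systems can be written to SplitsTree-readable NEXUS.

Three classical structure predicates are provided:

- compatibility (pairwise): the system is displayed by a single tree;
- weak compatibility: the Bandelt-Dress triple condition, guaranteed by
  split decomposition and parsimony splits;
- circularity: all splits are arcs of one cyclic taxon ordering,
  guaranteed by Neighbor-Net.

Evaluation against a known true tree counts shared/missed/spurious
*nontrivial* splits, ignoring weights: sensitivity = tp/(tp+fn) is the
probability that a true-tree split appears in the network, and the
positive predictive value ppv = tp/(tp+fp) the probability that a
network split is in the true tree.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy

__all__ = [
    "Split",
    "SplitSystem",
    "EvaluationResult",
    "is_trivial",
    "are_compatible",
    "is_compatible",
    "is_weakly_compatible",
    "is_circular",
    "splits_from_tree",
    "evaluate",
]


@dataclass(frozen=True)
class Split:
    """A bipartition of a taxon set, in canonical orientation.

    ``side_a`` is the side containing the lexicographically smallest
    taxon, so equality and hashing are independent of construction
    order. Use :meth:`of` to build canonically.
    """

    side_a: frozenset[str]
    side_b: frozenset[str]

    @classmethod
    def of(cls, side: Iterable[str], taxa: Iterable[str]) -> "Split":
        side = frozenset(side)
        taxa = frozenset(taxa)
        if not side or side == taxa:
            raise ValueError("both sides of a split must be nonempty")
        if not side <= taxa:
            raise ValueError("split side is not a subset of the taxon set")
        other = taxa - side
        if min(side) <= min(other):
            return cls(side, other)
        return cls(other, side)

    def __post_init__(self) -> None:
        if not self.side_a or not self.side_b:
            raise ValueError("both sides of a split must be nonempty")
        if self.side_a & self.side_b:
            raise ValueError("split sides must be disjoint")
        if min(self.side_a) > min(self.side_b):
            raise ValueError("split is not canonically oriented; use Split.of")

    @property
    def taxa(self) -> frozenset[str]:
        return self.side_a | self.side_b

    @property
    def size(self) -> int:
        """Size of the smaller side."""
        return min(len(self.side_a), len(self.side_b))

    def separates(self, x: str, y: str) -> bool:
        return (x in self.side_a) != (y in self.side_a)

    def __str__(self) -> str:
        a = ",".join(sorted(self.side_a))
        b = ",".join(sorted(self.side_b))
        return f"{{{a}}}|{{{b}}}"


def is_trivial(s: Split) -> bool:
    """True iff one side of the split is a single taxon."""
    return s.size == 1


@dataclass
class SplitSystem:
    """A weighted set of splits over a common taxon set.

    The semantics of the weights depend on the producing algorithm
    (jackknife support, isolation index, least-squares edge length,
    quartet index); they are carried but never compared during
    evaluation.
    """

    taxa: tuple[str, ...]
    weights: dict[Split, float] = field(default_factory=dict)
    circular_ordering: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.taxa = tuple(self.taxa)
        tset = frozenset(self.taxa)
        if len(tset) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        for s, w in self.weights.items():
            if s.taxa != tset:
                raise ValueError(f"split {s} is not over the system's taxon set")
            if w < 0:
                raise ValueError(f"negative weight for split {s}")

    @property
    def splits(self) -> frozenset[Split]:
        return frozenset(self.weights)

    def weight(self, s: Split) -> float:
        return self.weights[s]

    def nontrivial(self) -> frozenset[Split]:
        return frozenset(s for s in self.weights if not is_trivial(s))

    def add(self, s: Split, w: float) -> None:
        if s.taxa != frozenset(self.taxa):
            raise ValueError(f"split {s} is not over the system's taxon set")
        if w < 0:
            raise ValueError("split weights must be nonnegative")
        if s in self.weights:
            raise ValueError(f"duplicate split {s}")
        self.weights[s] = w

    def __len__(self) -> int:
        return len(self.weights)

    def __iter__(self) -> Iterator[Split]:
        return iter(self.weights)


def are_compatible(s1: Split, s2: Split) -> bool:
    """Pairwise compatibility: one of the four side intersections is empty."""
    if s1.taxa != s2.taxa:
        raise ValueError("splits are over different taxon sets")
    return (
        not (s1.side_a & s2.side_a)
        or not (s1.side_a & s2.side_b)
        or not (s1.side_b & s2.side_a)
        or not (s1.side_b & s2.side_b)
    )


def is_compatible(ss: SplitSystem) -> bool:
    """True iff all splits are pairwise compatible (tree-representable)."""
    return all(
        are_compatible(s1, s2) for s1, s2 in itertools.combinations(ss.splits, 2)
    )


def _masks(ss: SplitSystem) -> tuple[dict[str, int], list[tuple[int, int]]]:
    bit = {t: 1 << i for i, t in enumerate(ss.taxa)}
    pairs = []
    for s in ss.weights:
        a = sum(bit[t] for t in s.side_a)
        b = sum(bit[t] for t in s.side_b)
        pairs.append((a, b))
    return bit, pairs


def is_weakly_compatible(ss: SplitSystem) -> bool:
    """Bandelt-Dress weak compatibility of the whole system.

    For every triple of splits and every choice of sides (A1, A2, A3),
    at least one of A1&A2&A3, A1&B2&B3, B1&A2&B3, B1&B2&A3 must be
    empty. Vacuously true for fewer than three splits.
    """
    _, masks = _masks(ss)
    for (a1, b1), (a2, b2), (a3, b3) in itertools.combinations(masks, 3):
        for x1, y1 in ((a1, b1), (b1, a1)):
            for x2, y2 in ((a2, b2), (b2, a2)):
                for x3, y3 in ((a3, b3), (b3, a3)):
                    if (
                        (x1 & x2 & x3)
                        and (x1 & y2 & y3)
                        and (y1 & x2 & y3)
                        and (y1 & y2 & x3)
                    ):
                        return False
    return True


def _arcs_of_ordering(ordering: Sequence[str]) -> set[frozenset[str]]:
    n = len(ordering)
    arcs: set[frozenset[str]] = set()
    doubled = list(ordering) + list(ordering)
    for start in range(n):
        for length in range(1, n):
            arcs.add(frozenset(doubled[start : start + length]))
    return arcs


def fits_ordering(ss: SplitSystem, ordering: Sequence[str]) -> bool:
    """True iff every split of the system is an arc of the cyclic ordering."""
    if frozenset(ordering) != frozenset(ss.taxa):
        raise ValueError("ordering does not cover the taxon set")
    arcs = _arcs_of_ordering(ordering)
    return all(s.side_a in arcs for s in ss.weights)


_CIRCULAR_SEARCH_GUARD = 10


def is_circular(
    ss: SplitSystem, ordering: Sequence[str] | None = None
) -> bool:
    """Whether the system is circular (all splits arcs of one cyclic order).

    A candidate ordering (e.g. the one produced by Neighbor-Net, stored
    in ``circular_ordering``) is tested directly; otherwise all cyclic
    orderings are searched, which is only feasible for small taxon sets
    (guarded at 10 taxa).
    """
    if ordering is None:
        ordering = ss.circular_ordering
    if ordering is not None:
        return fits_ordering(ss, ordering)
    taxa = sorted(ss.taxa)
    if len(taxa) > _CIRCULAR_SEARCH_GUARD:
        raise ValueError(
            f"exhaustive circular-ordering search guarded at "
            f"{_CIRCULAR_SEARCH_GUARD} taxa; supply a candidate ordering"
        )
    if len(taxa) <= 3:
        return True
    first, rest = taxa[0], taxa[1:]
    for perm in itertools.permutations(rest):
        if perm[0] > perm[-1]:
            continue  # each cycle once (reflection symmetry)
        if fits_ordering(ss, (first, *perm)):
            return True
    return False


# ---------------------------------------------------------------------------
# Trees <-> splits.


def _leaf_labels(tree: dendropy.Tree) -> list[str]:
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError("tree has duplicate leaf labels")
    return labels


def splits_from_tree(
    tree: dendropy.Tree, topology_only: bool = False
) -> SplitSystem:
    """All splits induced by the edges of a (possibly rooted) tree.

    The tree is interpreted as unrooted: a rooted binary tree's two
    root-adjacent edges induce one split whose weight is the sum of
    their branch lengths. Edge weights default to 1 when no branch
    length is present (or when ``topology_only`` is set). A binary
    unrooted tree on n leaves yields exactly n-3 nontrivial splits.
    """
    labels = _leaf_labels(tree)
    taxa = frozenset(labels)
    ss = SplitSystem(tuple(sorted(labels)))
    acc: dict[Split, float] = {}
    below: dict[dendropy.Node, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
        else:
            below[node] = frozenset().union(*(below[c] for c in node.child_nodes()))
        if node.parent_node is None:
            continue
        side = below[node]
        if not side or side == taxa:
            continue
        s = Split.of(side, taxa)
        if topology_only:
            w = 1.0
        else:
            w = node.edge.length if node.edge.length is not None else 1.0
        acc[s] = acc.get(s, 0.0) + w
    for s, w in acc.items():
        ss.add(s, w)
    return ss


# ---------------------------------------------------------------------------
# Evaluation.


@dataclass(frozen=True)
class EvaluationResult:
    """Nontrivial-split agreement between a network and a true tree.

    ``sensitivity_degenerate`` / ``ppv_degenerate`` flag the conventions
    used when the true tree has no nontrivial splits (tp+fn = 0) or the
    network has none (tp+fp = 0); both ratios are then reported as 1.0.
    """

    tp: int
    fn: int
    fp: int
    sensitivity: float
    ppv: float
    sensitivity_degenerate: bool = False
    ppv_degenerate: bool = False


def evaluate(
    network: SplitSystem, true_tree: dendropy.Tree | SplitSystem
) -> EvaluationResult:
    """Compare a network's nontrivial splits with a true tree's, weight-blind."""
    if isinstance(true_tree, SplitSystem):
        true_system = true_tree
    else:
        true_system = splits_from_tree(true_tree, topology_only=True)
    if frozenset(network.taxa) != frozenset(true_system.taxa):
        raise ValueError("network and true tree are over different taxon sets")
    net = network.nontrivial()
    ref = true_system.nontrivial()
    tp = len(net & ref)
    fn = len(ref - net)
    fp = len(net - ref)
    sens_degen = (tp + fn) == 0
    ppv_degen = (tp + fp) == 0
    sensitivity = 1.0 if sens_degen else tp / (tp + fn)
    ppv = 1.0 if ppv_degen else tp / (tp + fp)
    return EvaluationResult(tp, fn, fp, sensitivity, ppv, sens_degen, ppv_degen)
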