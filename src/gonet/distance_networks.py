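"""Split networks from distance matrices: split decomposition and Neighbor-Net.

Split decomposition (Bandelt-Dress) keeps every split A|B whose
*isolation index*

    alpha(A|B) = 1/2 * min over i,i' in A and j,j' in B of
        max(d(i,j)+d(i',j'), d(i,j')+d(i',j), d(i,i')+d(j,j'))
        - d(i,i') - d(j,j')

is strictly positive, weighted by alpha. The resulting system is always
weakly compatible. The d-splits of a subset are hereditary, which
licenses the standard incremental (taxon-by-taxon) construction; an
exhaustive enumeration over all bipartitions is kept as the small-n
oracle.

Neighbor-Net first builds a circular ordering of the taxa by NJ-style
agglomeration (clusters of one or two linked nodes; three-node paths are
reduced to two with fixed 2/3-1/3 averaging formulas), then estimates
weights for all n(n-1)/2 arc splits of the ordering by non-negative
least squares against the input distances. Splits with weight zero are
dropped; every positive-weight split is kept (no further filtering).
The output is always circular with respect to the produced ordering.

On additive (tree) metrics both methods recover exactly the tree's
splits with branch lengths as weights.
"""

from __future__ import annotations

import itertools
from typing import Sequence

import numpy as np
from scipy.optimize import nnls

from .distances import DistanceMatrix
from .splits import Split, SplitSystem

__all__ = [
    "isolation_index",
    "split_decomposition",
    "split_decomposition_exhaustive",
    "neighbor_net",
    "neighbor_net_ordering",
]


# ---------------------------------------------------------------------------
# Split decomposition.


def isolation_index(
    dm: DistanceMatrix, side_a: Sequence[str], side_b: Sequence[str]
) -> float:
    """Bandelt-Dress isolation index of the split side_a | side_b.

    The minimum runs over ordered pairs with repetition, so singleton
    sides are handled by the same formula (for the 2-taxon system
    {i}|{j} it reduces to d(i,j)).
    """
    idx = {t: i for i, t in enumerate(dm.taxa)}
    d = np.asarray(dm.values, dtype=float)
    a = [idx[t] for t in side_a]
    b = [idx[t] for t in side_b]
    best = np.inf
    for i, i2 in itertools.combinations_with_replacement(a, 2):
        for j, j2 in itertools.combinations_with_replacement(b, 2):
            base = d[i, i2] + d[j, j2]
            v = max(d[i, j] + d[i2, j2], d[i, j2] + d[i2, j], base) - base
            if v < best:
                best = v
                if best <= 0:
                    return 0.5 * best
    return 0.5 * best


def _validated(dm: DistanceMatrix) -> DistanceMatrix:
    if len(dm) < 2:
        raise ValueError("need at least 2 taxa")
    return dm


def split_decomposition(dm: DistanceMatrix) -> SplitSystem:
    """All d-splits (isolation index > 0) of the metric, built incrementally.

    Taxa are introduced one at a time; every d-split of the enlarged set
    restricts to a d-split of the smaller one (or to the new trivial
    split), so only extensions of the current splits plus the new
    trivial split need checking at each step.
    """
    _validated(dm)
    taxa = list(dm.taxa)
    current: dict[frozenset[str], float] = {
        frozenset([taxa[0]]): isolation_index(dm, [taxa[0]], [taxa[1]])
    }
    subset = taxa[:2]
    for x in taxa[2:]:
        nxt: dict[frozenset[str], float] = {}
        candidates: set[frozenset[str]] = {frozenset([x])}
        for side in current:
            candidates.add(side)
            candidates.add(side | {x})
        subset.append(x)
        sset = frozenset(subset)
        for side in candidates:
            other = sset - side
            if not side or not other:
                continue
            alpha = isolation_index(dm, sorted(side), sorted(other))
            if alpha > 0:
                nxt[side] = alpha
        current = nxt
    ss = SplitSystem(tuple(sorted(taxa)))
    for side, alpha in current.items():
        ss.add(Split.of(side, taxa), alpha)
    return ss


def split_decomposition_exhaustive(dm: DistanceMatrix, guard: int = 10) -> SplitSystem:
    """Oracle: enumerate every bipartition and keep those with alpha > 0."""
    _validated(dm)
    taxa = list(dm.taxa)
    if len(taxa) > guard:
        raise ValueError(f"exhaustive enumeration guarded at {guard} taxa")
    first, rest = taxa[0], taxa[1:]
    ss = SplitSystem(tuple(sorted(taxa)))
    for r in range(0, len(rest)):
        for combo in itertools.combinations(rest, r):
            side = frozenset([first, *combo])
            other = frozenset(taxa) - side
            if not other:
                continue
            alpha = isolation_index(dm, sorted(side), sorted(other))
            if alpha > 0:
                ss.add(Split.of(side, taxa), alpha)
    return ss


# ---------------------------------------------------------------------------
# Neighbor-Net.


def neighbor_net_ordering(dm: DistanceMatrix) -> tuple[str, ...]:
    """Circular taxon ordering from the Neighbor-Net agglomeration.

    Clusters hold one or two *linked* nodes (a path fragment of the
    final cycle). Cluster pairs are chosen by the NJ Q criterion on
    cluster-averaged distances; node pairs within the chosen clusters by
    the same criterion over the nodes of the two clusters plus the
    remaining clusters as units. Each selection links the two nodes;
    paths longer than two nodes are reduced with the standard averaging
    formulas

        d(u,z) = (2 d(a,z) + d(b,z)) / 3
        d(v,z) = (2 d(c,z) + d(b,z)) / 3
        d(u,v) = (d(a,b) + d(a,c) + d(b,c)) / 3

    for a path a-b-c replaced by u-v, and expanded again (in reverse)
    once only a short path remains. Ties break toward the lowest
    creation-order indices.
    """
    n = len(dm)
    if n <= 3:
        return tuple(dm.taxa)
    cap = 3 * n + 4
    d = np.zeros((cap, cap))
    d[:n, :n] = np.asarray(dm.values, dtype=float)
    clusters: list[list[int]] = [[i] for i in range(n)]
    expansions: list[tuple[int, int, int, int, int]] = []
    nxt = n

    def cluster_dist(ca: list[int], cb: list[int]) -> float:
        return float(np.mean([d[x, y] for x in ca for y in cb]))

    while True:
        m = len(clusters)
        if m < 2 or sum(len(c) for c in clusters) <= 3:
            break
        dc = np.zeros((m, m))
        for i in range(m):
            for j in range(i + 1, m):
                dc[i, j] = dc[j, i] = cluster_dist(clusters[i], clusters[j])
        r = dc.sum(axis=1)
        best, best_q = None, np.inf
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * dc[i, j] - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q, best = q, (i, j)
        ia, ib = best
        ca, cb = clusters[ia], clusters[ib]

        if len(ca) == 1 and len(cb) == 1:
            x, y = ca[0], cb[0]
        else:
            pool = ca + cb
            others = [clusters[k] for k in range(m) if k not in (ia, ib)]
            mhat = len(pool) + len(others)
            rr = {}
            for z in pool:
                rr[z] = sum(cluster_dist([z], c) for c in others) + sum(
                    d[z, w] for w in pool if w != z
                )
            best, best_q = None, np.inf
            for x_ in ca:
                for y_ in cb:
                    q = (mhat - 2) * d[x_, y_] - rr[x_] - rr[y_]
                    if q < best_q - 1e-12:
                        best_q, best = q, (x_, y_)
            x, y = best

        path_a = ca if ca[-1] == x else list(reversed(ca))
        path_b = cb if cb[0] == y else list(reversed(cb))
        path = path_a + path_b
        while len(path) > 2:
            a, b, c = path[0], path[1], path[2]
            u, v = nxt, nxt + 1
            nxt += 2
            for z in range(nxt - 2):
                d[u, z] = d[z, u] = (2.0 * d[a, z] + d[b, z]) / 3.0
                d[v, z] = d[z, v] = (2.0 * d[c, z] + d[b, z]) / 3.0
            d[u, v] = d[v, u] = (d[a, b] + d[a, c] + d[b, c]) / 3.0
            expansions.append((u, v, a, b, c))
            path = [u, v] + path[3:]
        clusters[ia] = path
        del clusters[ib]

    cycle = [node for cl in clusters for node in cl]
    for u, v, a, b, c in reversed(expansions):
        i = cycle.index(u)
        j = cycle.index(v)
        k = len(cycle)
        if (i + 1) % k == j:
            cycle = cycle[: i + 1] + [b] + cycle[j:]
            cycle[i] = a
            cycle[i + 2] = c
        elif (j + 1) % k == i:
            cycle = cycle[: j + 1] + [b] + cycle[i:]
            cycle[j] = c
            cycle[j + 2] = a
        else:  # pragma: no cover - adjacency is maintained by construction
            raise AssertionError("reduced pair not adjacent in cycle")
    assert sorted(cycle) == list(range(n))
    return tuple(dm.taxa[i] for i in cycle)


def _arc_splits(ordering: Sequence[str]) -> list[frozenset[str]]:
    n = len(ordering)
    sides = []
    for p in range(1, n):
        for q in range(p, n):
            sides.append(frozenset(ordering[p : q + 1]))
    return sides


def neighbor_net(dm: DistanceMatrix) -> SplitSystem:
    """Neighbor-Net split network of a distance matrix.

    For fewer than 4 taxa only trivial splits can exist; they are still
    weighted by the least-squares fit. The returned system carries its
    circular ordering in ``circular_ordering``.
    """
    _validated(dm)
    ordering = neighbor_net_ordering(dm)
    taxa = list(dm.taxa)
    idx = {t: i for i, t in enumerate(taxa)}
    sides = _arc_splits(ordering)
    pairs = list(itertools.combinations(range(len(taxa)), 2))
    a_mat = np.zeros((len(pairs), len(sides)))
    for col, side in enumerate(sides):
        mask = np.zeros(len(taxa), dtype=bool)
        for t in side:
            mask[idx[t]] = True
        for row, (i, j) in enumerate(pairs):
            if mask[i] != mask[j]:
                a_mat[row, col] = 1.0
    dvec = np.array([dm.values[i, j] for i, j in pairs], dtype=float)
    weights, _ = nnls(a_mat, dvec)
    # Weights at the level of NNLS round-off are numerical zeros, not
    # low-weight splits; everything above that is kept (no filtering).
    tol = 1e-9 * max(1.0, float(dvec.max(initial=0.0)))
    ss = SplitSystem(tuple(sorted(taxa)), circular_ordering=ordering)
    for side, w in zip(sides, weights):
        if w > tol:
            ss.add(Split.of(side, taxa), float(w))
    return ss
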