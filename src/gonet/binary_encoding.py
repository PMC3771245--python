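"""Binary adjacency encoding of gene orders and the parsimony-splits network.

The binary encoding (BE) turns a set of permutations into a 0/1 matrix:
one row per genome, one column per unordered gene pair {N, M} (N < M) in
each of its four relative orientations -- (+N +M), (+M +N), (+N -M) and
(-N +M) -- giving 2n(n-1) columns for n genes. An entry is 1 iff the two
genes are adjacent in that genome with those directions.

Reading an adjacency left-to-right, the ordered signed pair (a, b) and
its reverse-complement (-b, -a) describe the same physical junction, so
each adjacency is canonicalized by putting the gene with the smaller
absolute label first (flipping both order and signs when needed); then
exactly one of the four columns fires per adjacency, and a genome and
its full reversal encode identically. A linear m-gene genome therefore
has exactly m-1 ones per row.

The parsimony-splits method turns such binary characters into a weakly
compatible split system: for a quartet {i,j,k,l} let c(ij|kl) be the
number of columns with x_i = x_j != x_k = x_l, and

    beta(ij|kl) = c(ij|kl) - max(c(ik|jl), c(il|jk)).

A split A|B is a p-split iff beta(ij|kl) > 0 (strict dominance) for
*every* quartet with i,j in A and k,l in B; its weight is the minimal
beta. P-splits are hereditary under taxon deletion, so the system is
built incrementally; exhaustive enumeration over all bipartitions is
the small-n oracle. Trivial splits have no defining quartets and are
returned unconditionally with a degenerate pair-count weight.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .genomes import GenomeSet

__all__ = [
    "BinaryEncoding",
    "encode",
    "canonical_adjacency",
    "parsimony_splits",
    "parsimony_splits_exhaustive",
]

from .splits import Split, SplitSystem

# Orientation classes for a pair N < M, in canonical form (sign_N*N, sign_M*M):
# (+N,+M); (-N,-M) which is (+M,+N) read backwards; (+N,-M); (-N,+M).
_CLASSES = ((1, 1), (-1, -1), (1, -1), (-1, 1))


def canonical_adjacency(a: int, b: int) -> tuple[int, int]:
    """Canonical form of the ordered signed adjacency (a, b).

    (a, b) and (-b, -a) are the two readings of one junction; the
    canonical form puts the smaller absolute label first.
    """
    if abs(a) < abs(b):
        return (a, b)
    return (-b, -a)


@dataclass(frozen=True)
class BinaryEncoding:
    """Rows = taxa, columns = oriented gene pairs, entries = adjacency flags."""

    taxa: tuple[str, ...]
    columns: tuple[tuple[int, int], ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.taxa), len(self.columns)):
            raise ValueError("matrix shape does not match taxa/columns")

    @property
    def n_genes(self) -> int:
        return len({abs(x) for col in self.columns for x in col})

    def drop_empty_columns(self) -> "BinaryEncoding":
        """Copy without all-zero columns (they carry no information)."""
        keep = np.nonzero(self.matrix.any(axis=0))[0]
        return BinaryEncoding(
            self.taxa,
            tuple(self.columns[i] for i in keep),
            self.matrix[:, keep],
        )


def encode(gs: GenomeSet) -> BinaryEncoding:
    """Binary adjacency encoding of a genome set (2n(n-1) columns)."""
    genes = sorted(gs.gene_universe)
    columns: list[tuple[int, int]] = []
    col_index: dict[tuple[int, int], int] = {}
    for n_lab, m_lab in itertools.combinations(genes, 2):
        for sn, sm in _CLASSES:
            col = (sn * n_lab, sm * m_lab)
            col_index[col] = len(columns)
            columns.append(col)
    mat = np.zeros((len(gs), len(columns)), dtype=np.uint8)
    for row, g in enumerate(gs):
        for a, b in zip(g.genes, g.genes[1:]):
            mat[row, col_index[canonical_adjacency(a, b)]] = 1
    return BinaryEncoding(gs.names, tuple(columns), mat)


# ---------------------------------------------------------------------------
# Parsimony splits.


class _QuartetCounts:
    """Cached c(ij|kl) pattern counts over the informative columns."""

    def __init__(self, matrix: np.ndarray):
        m = np.asarray(matrix, dtype=bool)
        informative = m.any(axis=0) & ~m.all(axis=0)  # constant columns count 0
        self._m = m[:, informative]
        self._cache: dict[tuple[int, int, int, int], int] = {}

    def c(self, i: int, j: int, k: int, l: int) -> int:
        """Columns with x_i = x_j != x_k = x_l."""
        key = (i, j, k, l) if (i, j) <= (k, l) else (k, l, i, j)
        got = self._cache.get(key)
        if got is None:
            m = self._m
            got = int(
                np.count_nonzero((m[i] == m[j]) & (m[k] == m[l]) & (m[i] != m[k]))
            )
            self._cache[key] = got
        return got

    def beta(self, i: int, j: int, k: int, l: int) -> int:
        return self.c(i, j, k, l) - max(self.c(i, k, j, l), self.c(i, l, j, k))


def _split_index(counts: _QuartetCounts, side_a: list[int], side_b: list[int]) -> int:
    """min beta over all quartets; <= 0 means not a p-split."""
    best = None
    for i, j in itertools.combinations(side_a, 2):
        for k, l in itertools.combinations(side_b, 2):
            b = counts.beta(i, j, k, l)
            if b <= 0:
                return b
            if best is None or b < best:
                best = b
    return best if best is not None else 0


def _trivial_weight(counts: _QuartetCounts, i: int, others: list[int]) -> int:
    """Degenerate pair index for the trivial split {i} | rest."""
    best = None
    for k, l in itertools.combinations_with_replacement(others, 2):
        m = counts._m
        v = int(np.count_nonzero((m[k] == m[l]) & (m[i] != m[k])))
        if best is None or v < best:
            best = v
    return best or 0


def _with_trivial(
    ss: SplitSystem, counts: _QuartetCounts, taxa: list[str]
) -> SplitSystem:
    n = len(taxa)
    for i, t in enumerate(taxa):
        others = [k for k in range(n) if k != i]
        ss.add(Split.of([t], taxa), float(_trivial_weight(counts, i, others)))
    return ss


def parsimony_splits(be: BinaryEncoding) -> SplitSystem:
    """Parsimony-splits network of a binary encoding, built incrementally.

    With fewer than 4 taxa no quartet exists and only trivial splits are
    returned. Nontrivial p-splits carry their (integer, >= 1) minimal
    quartet index as weight.
    """
    taxa = list(be.taxa)
    n = len(taxa)
    counts = _QuartetCounts(be.matrix)
    ss = SplitSystem(tuple(sorted(taxa)))
    if n < 4:
        return _with_trivial(ss, counts, taxa)

    # Incremental construction over taxon indices 0..n-1. The current
    # p-splits of the prefix are extended by the new taxon on either
    # side; new nontrivial splits can also arise from the prefix's
    # trivial splits ({y} -> {x, y}).
    current: set[frozenset[int]] = set()
    for size in range(4, n + 1):
        x = size - 1
        prefix = list(range(size))
        candidates: set[frozenset[int]] = set()
        for side in current:
            candidates.add(side)
            candidates.add(side | {x})
        for y in range(x):
            candidates.add(frozenset({x, y}))
        current = set()
        for side in candidates:
            other = [t for t in prefix if t not in side]
            if len(side) < 2 or len(other) < 2:
                continue
            if _split_index(counts, sorted(side), other) > 0:
                current.add(side)
    for side in current:
        other = [t for t in range(n) if t not in side]
        w = _split_index(counts, sorted(side), other)
        ss.add(Split.of([taxa[i] for i in side], taxa), float(w))
    return _with_trivial(ss, counts, taxa)


def parsimony_splits_exhaustive(be: BinaryEncoding, guard: int = 10) -> SplitSystem:
    """Oracle: test every bipartition against the quartet condition."""
    taxa = list(be.taxa)
    n = len(taxa)
    if n > guard:
        raise ValueError(f"exhaustive enumeration guarded at {guard} taxa")
    counts = _QuartetCounts(be.matrix)
    ss = SplitSystem(tuple(sorted(taxa)))
    if n < 4:
        return _with_trivial(ss, counts, taxa)
    rest = list(range(1, n))
    for r in range(1, n - 2):
        for combo in itertools.combinations(rest, r):
            side = [0, *combo]
            other = [t for t in range(n) if t not in side]
            if len(other) < 2:
                continue
            w = _split_index(counts, side, other)
            if w > 0:
                ss.add(Split.of([taxa[i] for i in side], taxa), float(w))
    return _with_trivial(ss, counts, taxa)
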