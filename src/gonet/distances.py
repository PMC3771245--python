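"""Exact signed inversion (reversal) distance and distance matrices.

The minimum number of inversions transforming one signed permutation of n
genes into another is computed exactly from the breakpoint graph by the
Hannenhalli-Pevzner formula

    d = (n + 1) - c + h + f

where ``c`` is the number of alternating cycles, ``h`` the number of
hurdles (unoriented components that do not separate other unoriented
components on the circle of graph positions), and ``f`` is 1 when the
permutation is a fortress (an odd number of hurdles, all of them
super-hurdles).

A breadth-first-search oracle over the inversion move graph is provided
for small gene counts; it is deliberately independent of the breakpoint
graph machinery and arbitrates its correctness in tests.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.sparse.csgraph import connected_components

from .genomes import GenomeSet, SignedPermutation

__all__ = [
    "BreakpointGraph",
    "DistanceMatrix",
    "inversion_distance",
    "bfs_distance_oracle",
    "bfs_distance_map",
    "distance_matrix",
    "read_phylip",
    "write_phylip",
]


@dataclass(frozen=True)
class BreakpointGraph:
    """Cycle/hurdle/fortress decomposition of a permutation vs the identity."""

    n: int
    cycles: int
    hurdles: int
    fortress: bool

    @property
    def extended_size(self) -> int:
        return 2 * self.n + 2

    @property
    def distance(self) -> int:
        return (self.n + 1) - self.cycles + self.hurdles + int(self.fortress)


def _relative_permutation(a: SignedPermutation, b: SignedPermutation) -> tuple[int, ...]:
    """Relabel ``a`` in the coordinate frame where ``b`` is the identity."""
    if a.universe != b.universe:
        raise ValueError(
            f"gene universes differ between {a.name!r} and {b.name!r}"
        )
    image = {}
    for pos, g in enumerate(b.genes, start=1):
        image[abs(g)] = pos if g > 0 else -pos
    return tuple(
        image[abs(g)] if g > 0 else -image[abs(g)] for g in a.genes
    )


def breakpoint_graph(rel: tuple[int, ...]) -> BreakpointGraph:
    """Breakpoint-graph statistics of a signed permutation vs the identity.

    ``rel`` must be a signed permutation of 1..n. Each gene g is doubled
    into endpoints (2g-1, 2g), framed by 0 and 2n+1. Black edges pair
    consecutive positions (2k, 2k+1); gray edges pair values (2i, 2i+1).
    """
    n = len(rel)
    size = 2 * n + 2
    seq = np.empty(size, dtype=np.int64)
    seq[0] = 0
    seq[-1] = size - 1
    for k, g in enumerate(rel):
        if g > 0:
            seq[2 * k + 1] = 2 * g - 1
            seq[2 * k + 2] = 2 * g
        else:
            seq[2 * k + 1] = -2 * g
            seq[2 * k + 2] = -2 * g - 1
    pos = np.empty(size, dtype=np.int64)
    pos[seq] = np.arange(size)

    # Alternating cycles: from a position, the black partner is pos^1,
    # the gray partner of a value is value^1.
    visited = bytearray(size)
    cycles = 0
    pos_list = pos.tolist()
    seq_list = seq.tolist()
    for start in range(size):
        if visited[start]:
            continue
        cycles += 1
        p = start
        while not visited[p]:
            visited[p] = 1
            q = p ^ 1            # black edge
            visited[q] = 1
            p = pos_list[seq_list[q] ^ 1]   # gray edge

    # Gray edge i = (values 2i, 2i+1), i = 0..n.
    ev = pos[0:size:2]
    od = pos[1:size:2]
    left = np.minimum(ev, od)
    right = np.maximum(ev, od)
    oriented = ((ev + od) % 2) == 0
    trivial = (right == left + 1) & (left % 2 == 0)  # adjacency 2-cycles

    if bool(np.all(oriented | trivial)):
        # No unoriented breakpoint edge at all: no hurdles possible.
        return BreakpointGraph(n, cycles, 0, False)

    # Components of the interleaving (crossing) graph of gray edges.
    cross = (
        (left[:, None] < left[None, :])
        & (left[None, :] < right[:, None])
        & (right[:, None] < right[None, :])
    )
    cross = cross | cross.T
    ncomp, labels = connected_components(cross, directed=False)

    comps: list[np.ndarray] = []
    for comp in range(ncomp):
        members = np.nonzero(labels == comp)[0]
        if bool(np.any(oriented[members])):
            continue
        if len(members) == 1 and bool(trivial[members[0]]):
            continue
        positions = np.sort(
            np.concatenate([left[members], right[members]])
        )
        comps.append(positions)

    hurdles_idx = _hurdle_indices(comps)
    h = len(hurdles_idx)
    fortress = False
    if h >= 3 and h % 2 == 1:
        fortress = all(_is_super_hurdle(comps, i, hurdles_idx) for i in hurdles_idx)
    return BreakpointGraph(n, cycles, h, fortress)


def _hurdle_indices(comps: list[np.ndarray]) -> set[int]:
    """Hurdles among unoriented components given their sorted position sets.

    Component extents are laminar (nested or disjoint), so each other
    component lies either wholly outside the extent (one circular arc,
    since position 0 and 2n+1 are adjacent on the circle) or inside one
    gap between consecutive positions. A component is a hurdle iff all
    other unoriented components occupy a single such arc.
    """
    hurdles: set[int] = set()
    for i, u in enumerate(comps):
        lo, hi = int(u[0]), int(u[-1])
        buckets: set[int] = set()
        for j, w in enumerate(comps):
            if j == i:
                continue
            wl = int(w[0])
            if wl < lo or wl > hi:
                buckets.add(-1)
            else:
                buckets.add(int(np.searchsorted(u, wl)))
            if len(buckets) > 1:
                break
        if len(buckets) <= 1:
            hurdles.add(i)
    return hurdles


def _is_super_hurdle(
    comps: list[np.ndarray], i: int, hurdles_idx: set[int]
) -> bool:
    """A hurdle is *super* if deleting it promotes a non-hurdle to a hurdle."""
    rest = [c for j, c in enumerate(comps) if j != i]
    old_nonhurdles = [j for j in range(len(comps)) if j != i and j not in hurdles_idx]
    new_hurdles = _hurdle_indices(rest)
    remap = [j for j in range(len(comps)) if j != i]
    return any(remap[k] in old_nonhurdles for k in new_hurdles)


def inversion_distance(a: SignedPermutation, b: SignedPermutation) -> int:
    """Exact minimum number of inversions transforming ``a`` into ``b``."""
    return breakpoint_graph(_relative_permutation(a, b)).distance


# ---------------------------------------------------------------------------
# Independent BFS oracle over the inversion move graph (small n only).

_BFS_MAX_GENES = 8


def _neighbors(state: tuple[int, ...]) -> list[tuple[int, ...]]:
    n = len(state)
    out = []
    for i in range(n):
        for j in range(i, n):
            out.append(
                state[:i]
                + tuple(-x for x in reversed(state[i : j + 1]))
                + state[j + 1 :]
            )
    return out


def bfs_distance_map(
    a: SignedPermutation, max_genes: int = _BFS_MAX_GENES
) -> dict[tuple[int, ...], int]:
    """Distances from ``a`` to every reachable signed permutation, by BFS.

    Exhausts the full state space of 2^n * n! signed permutations, so it
    is guarded to small gene counts.
    """
    if len(a) > max_genes:
        raise ValueError(
            f"BFS oracle limited to {max_genes} genes, got {len(a)}"
        )
    start = a.genes
    dist: dict[tuple[int, ...], int] = {start: 0}
    frontier = deque([start])
    while frontier:
        s = frontier.popleft()
        d = dist[s] + 1
        for t in _neighbors(s):
            if t not in dist:
                dist[t] = d
                frontier.append(t)
    return dist


def bfs_distance_oracle(
    a: SignedPermutation, b: SignedPermutation, max_genes: int = _BFS_MAX_GENES
) -> int:
    """Shortest inversion path length from ``a`` to ``b`` by exhaustive BFS."""
    if a.universe != b.universe:
        raise ValueError("gene universes differ")
    if len(a) > max_genes:
        raise ValueError(
            f"BFS oracle limited to {max_genes} genes, got {len(a)}"
        )
    target = b.genes
    start = a.genes
    if start == target:
        return 0
    dist: dict[tuple[int, ...], int] = {start: 0}
    frontier = deque([start])
    while frontier:
        s = frontier.popleft()
        d = dist[s] + 1
        for t in _neighbors(s):
            if t == target:
                return d
            if t not in dist:
                dist[t] = d
                frontier.append(t)
    raise AssertionError("inversion move graph is connected; unreachable")


# ---------------------------------------------------------------------------
# Distance matrices.


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative distance matrix with taxon labels."""

    taxa: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "taxa", tuple(self.taxa))
        v = np.asarray(self.values)
        if v.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxon count")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distances must be nonnegative")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.taxa)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.taxa.index(pair[0])
        j = self.taxa.index(pair[1])
        return self.values[i, j]


def distance_matrix(gs: GenomeSet) -> DistanceMatrix:
    """All pairwise exact inversion distances of a genome set.

    Pairs are independent, so the computation is safe to parallelize; at
    desk scale a serial loop over unordered pairs suffices.
    """
    m = len(gs)
    d = np.zeros((m, m), dtype=np.int64)
    for i in range(m):
        for j in range(i + 1, m):
            d[i, j] = d[j, i] = inversion_distance(gs[i], gs[j])
    n = len(gs.gene_universe)
    if np.any(d > n + 1):
        raise AssertionError("inversion distance exceeded theoretical maximum")
    return DistanceMatrix(gs.names, d)


def write_phylip(dm: DistanceMatrix, path: str | Path) -> None:
    """Write a PHYLIP square distance matrix (taxon count, then rows)."""
    path = Path(path)
    lines = [f"{len(dm)}"]
    is_int = np.issubdtype(dm.values.dtype, np.integer)
    for name, row in zip(dm.taxa, dm.values):
        vals = " ".join(
            str(int(x)) if is_int else format(float(x), ".6f") for x in row
        )
        lines.append(f"{name}  {vals}")
    path.write_text("\n".join(lines) + "\n")


def read_phylip(path: str | Path) -> DistanceMatrix:
    """Read a PHYLIP square distance matrix as written by :func:`write_phylip`."""
    tokens = Path(path).read_text().split("\n")
    tokens = [t for t in tokens if t.strip() and not t.lstrip().startswith("#")]
    if not tokens:
        raise ValueError(f"{path}: empty distance file")
    ntax = int(tokens[0].split()[0])
    taxa: list[str] = []
    rows: list[list[float]] = []
    for line in tokens[1 : 1 + ntax]:
        parts = line.split()
        taxa.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    if len(taxa) != ntax:
        raise ValueError(f"{path}: expected {ntax} rows, found {len(taxa)}")
    arr = np.array(rows)
    if np.allclose(arr, np.round(arr)):
        arr = arr.astype(np.int64)
    return DistanceMatrix(tuple(taxa), arr)
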