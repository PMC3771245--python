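"""Tree I/O (Newick, via dendropy) and deterministic neighbor joining.

Neighbor joining is the built-in tree estimator for jackknife
replicates. It is implemented here rather than delegated so that ties
in the Q criterion are broken deterministically (lowest-index pair
wins), which makes whole pipelines reproducible bit-for-bit; jackknifed
integer inversion distances tie frequently.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

from .distances import DistanceMatrix

__all__ = ["read_tree", "read_trees", "write_trees", "nj_tree"]


def read_tree(source: str | Path) -> dendropy.Tree:
    """Read a single Newick tree from a file path or a literal string."""
    text = Path(source).read_text() if Path(str(source)).exists() else str(source)
    lines = [
        ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")
    ]
    return dendropy.Tree.get(data="\n".join(lines), schema="newick")


def read_trees(path: str | Path) -> list[dendropy.Tree]:
    """Read a multi-tree Newick file (one tree per line, '#' comments)."""
    trees: list[dendropy.Tree] = []
    tns = dendropy.TaxonNamespace()
    for ln in Path(path).read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        trees.append(
            dendropy.Tree.get(data=ln, schema="newick", taxon_namespace=tns)
        )
    if not trees:
        raise ValueError(f"{path}: no trees found")
    return trees


def write_trees(
    trees: Sequence[dendropy.Tree], path: str | Path, header: str | None = None
) -> None:
    """Write trees as one Newick string per line."""
    lines: list[str] = []
    if header:
        lines.extend(f"# {h}" for h in header.splitlines())
    for t in trees:
        lines.append(
            t.as_string(schema="newick", suppress_rooting=True).strip()
        )
    Path(path).write_text("\n".join(lines) + "\n")


def nj_tree(dm: DistanceMatrix, collapse_zero_internal: bool = True) -> dendropy.Tree:
    """Neighbor-joining tree from a distance matrix.

    Standard Saitou-Nei agglomeration with the Studier-Keppler Q
    criterion. Ties are broken toward the lexicographically lowest pair
    of node indices (in order of node creation), negative branch
    lengths are clamped to zero, and the returned tree is unrooted.

    By default, internal edges whose *estimated* length is non-positive
    are contracted, so edges carrying no distance signal yield
    multifurcations instead of an arbitrary (tie-broken) resolution;
    pass ``collapse_zero_internal=False`` for the strictly binary tree.
    """
    m0 = len(dm)
    if m0 < 3:
        raise ValueError(f"neighbor joining requires >= 3 taxa, got {m0}")
    cap = 2 * m0
    d = np.zeros((cap, cap))
    d[:m0, :m0] = np.asarray(dm.values, dtype=float)

    tns = dendropy.TaxonNamespace(list(dm.taxa))
    nodes: list[dendropy.Node] = []
    for label in dm.taxa:
        node = dendropy.Node()
        node.taxon = tns.get_taxon(label)
        nodes.append(node)

    active = list(range(m0))
    nxt = m0
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        best_q = np.inf
        for ai in range(m):
            for aj in range(ai + 1, m):
                q = (m - 2) * sub[ai, aj] - r[ai] - r[aj]
                if q < best_q - 1e-12:
                    best_q = q
                    best = (ai, aj)
        ai, aj = best
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        parent = dendropy.Node()
        for child, length in ((nodes[i], li), (nodes[j], lj)):
            parent.add_child(child)
            child.edge.length = max(0.0, float(length))
            child.estimated_length = float(length)
        nodes.append(parent)
        u = nxt
        nxt += 1
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (d[i, k] + d[j, k] - dij)
            d[u, k] = d[k, u] = duk
        active = [k for k in active if k not in (i, j)]
        active.append(u)

    center = dendropy.Node()
    (i, j, k) = active
    vi = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    vj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    vk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    for idx, length in ((i, vi), (j, vj), (k, vk)):
        center.add_child(nodes[idx])
        nodes[idx].edge.length = max(0.0, float(length))
        nodes[idx].estimated_length = float(length)

    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = center
    tree.is_rooted = False
    if collapse_zero_internal:
        _collapse_unsupported_edges(tree)
    return tree


def _collapse_unsupported_edges(tree: dendropy.Tree) -> None:
    """Contract internal edges whose NJ length estimate is <= 0."""
    changed = True
    while changed:
        changed = False
        for node in list(tree.postorder_internal_node_iter()):
            if node.parent_node is None:
                continue
            if getattr(node, "estimated_length", 1.0) <= 0.0:
                parent = node.parent_node
                for child in list(node.child_nodes()):
                    node.remove_child(child)
                    parent.add_child(child)
                parent.remove_child(node)
                changed = True
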