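"""Gene-order jackknife resampling and replicate tree sets.

Each replicate removes the *same* randomly chosen subset of genes from
every genome (40% by default), preserving the order and signs of the
remaining genes, then estimates a tree. The built-in estimator is
neighbor joining on exact inversion distances; externally produced
multi-tree Newick files can be used instead (see
:func:`gonet.trees.read_trees`), so any gene-order tree program can be
plugged in upstream of the consensus network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np

from .distances import distance_matrix
from .genomes import GenomeSet, SignedPermutation
from .trees import nj_tree

__all__ = ["JackknifeConfig", "jackknife_resample", "jackknife_trees"]


@dataclass(frozen=True)
class JackknifeConfig:
    """Jackknife parameters.

    removal_fraction: fraction of genes removed per replicate (default
        0.40); the removal count is floor(fraction * n) for determinism.
    replicates: number of replicate trees (default 100).
    seed: master seed; replicate r draws from a stream seeded seed + r,
        so replicates are individually reproducible.
    """

    removal_fraction: float = 0.40
    replicates: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.removal_fraction < 1.0):
            raise ValueError("removal_fraction must be in (0, 1)")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def jackknife_resample(
    gs: GenomeSet, cfg: JackknifeConfig, replicate_index: int
) -> GenomeSet:
    """One jackknife replicate: drop a shared random gene subset everywhere."""
    rng = np.random.default_rng(cfg.seed + replicate_index)
    universe = sorted(gs.gene_universe)
    n = len(universe)
    k = math.floor(cfg.removal_fraction * n)
    if n - k < 2:
        raise ValueError(
            f"jackknife would retain {n - k} genes; at least 2 are required"
        )
    removed = set(rng.choice(universe, size=k, replace=False).tolist())
    reduced = tuple(
        SignedPermutation(
            g.name, tuple(x for x in g.genes if abs(x) not in removed)
        )
        for g in gs
    )
    return GenomeSet(reduced)


def jackknife_trees(gs: GenomeSet, cfg: JackknifeConfig) -> list[dendropy.Tree]:
    """Replicate neighbor-joining trees from jackknifed inversion distances."""
    if len(gs) < 3:
        raise ValueError("jackknife trees require at least 3 genomes")
    trees = []
    for r in range(cfg.replicates):
        sample = jackknife_resample(gs, cfg, r)
        trees.append(nj_tree(distance_matrix(sample)))
    return trees
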