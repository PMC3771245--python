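"""Shared fixtures: random genomes, additive tree metrics, tiny datasets."""

from __future__ import annotations

import random

import dendropy
import numpy as np
import pytest

from gonet import DistanceMatrix, GenomeSet, SignedPermutation


def random_signed_permutation(
    n: int, rng: np.random.Generator, name: str = "x"
) -> SignedPermutation:
    vals = rng.permutation(np.arange(1, n + 1)) * rng.choice([1, -1], size=n)
    return SignedPermutation(name, tuple(int(v) for v in vals))


def random_genome_set(
    n_taxa: int, n_genes: int, rng: np.random.Generator
) -> GenomeSet:
    return GenomeSet(
        tuple(
            random_signed_permutation(n_genes, rng, name=f"g{i}")
            for i in range(n_taxa)
        )
    )


def random_tree_metric(
    n: int, rng: random.Random
) -> tuple[DistanceMatrix, dendropy.Tree]:
    """Random binary tree with dyadic branch lengths and its path metric.

    Branch lengths are multiples of 1/64 in [7/64, 2], so every path sum
    is exactly representable in binary floating point and the metric is
    exactly additive — splits at the alpha > 0 / weight > 0 boundary are
    then decided exactly, not by rounding noise.
    """
    taxa = [f"t{i}" for i in range(n)]
    tns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n,
        taxon_namespace=tns,
        rng=rng,
    )
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node is not None:
            edge.length = rng.randrange(7, 129) / 64.0
    pdm = tree.phylogenetic_distance_matrix()
    d = np.zeros((n, n))
    for i, t1 in enumerate(tns):
        for j, t2 in enumerate(tns):
            if i < j:
                d[i, j] = d[j, i] = pdm.distance(t1, t2)
    return DistanceMatrix(tuple(t.label for t in tns), d), tree


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230828)


@pytest.fixture
def pyrng() -> random.Random:
    return random.Random(20230828)


@pytest.fixture
def small_genomes() -> GenomeSet:
    """Four 5-gene genomes, a couple of inversions apart."""
    return GenomeSet(
        (
            SignedPermutation("A", (1, 2, 3, 4, 5)),
            SignedPermutation("B", (1, -3, -2, 4, 5)),
            SignedPermutation("C", (1, -3, -2, -5, -4)),
            SignedPermutation("D", (5, 4, 3, 2, 1)),
        )
    )
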