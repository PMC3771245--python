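"""Exact inversion distance vs the BFS oracle, metric axioms, PHYLIP I/O."""

import itertools

import numpy as np
import pytest

from gonet import (
    DistanceMatrix,
    GenomeSet,
    SignedPermutation,
    bfs_distance_map,
    bfs_distance_oracle,
    distance_matrix,
    identity_permutation,
    inversion_distance,
    read_phylip,
    write_phylip,
)
from gonet.distances import breakpoint_graph

from .conftest import random_genome_set, random_signed_permutation


def all_signed_permutations(n):
    for perm in itertools.permutations(range(1, n + 1)):
        for signs in itertools.product((1, -1), repeat=n):
            yield tuple(s * g for s, g in zip(signs, perm))


class TestInversionDistanceExamples:
    def test_identity_is_zero(self):
        p = SignedPermutation("a", (1, 2, 3))
        assert inversion_distance(p, p) == 0

    def test_single_gene_flip_is_one(self):
        a = SignedPermutation("a", (1, 2, 3))
        b = SignedPermutation("b", (1, -2, 3))
        assert inversion_distance(a, b) == 1

    def test_whole_reversal_is_one(self):
        a = SignedPermutation("a", (1, 2, 3))
        b = SignedPermutation("b", (-3, -2, -1))
        assert inversion_distance(a, b) == 1

    def test_all_positive_descending_needs_three(self):
        # (3,2,1) vs identity: all breakpoint-graph components unoriented,
        # one hurdle; value confirmed by the BFS oracle.
        a = SignedPermutation("a", (3, 1, 2))
        b = identity_permutation(3)
        assert inversion_distance(a, b) == bfs_distance_oracle(a, b)
        c = SignedPermutation("c", (3, 2, 1))
        assert inversion_distance(c, b) == bfs_distance_oracle(c, b) == 3

    def test_mismatched_universes_raise(self):
        with pytest.raises(ValueError):
            inversion_distance(
                SignedPermutation("a", (1, 2)), SignedPermutation("b", (1, 3))
            )

    def test_symmetric_under_argument_swap(self, rng):
        for _ in range(20):
            a = random_signed_permutation(12, rng, "a")
            b = random_signed_permutation(12, rng, "b")
            assert inversion_distance(a, b) == inversion_distance(b, a)


class TestBreakpointGraph:
    def test_identity_has_max_cycles(self):
        bg = breakpoint_graph(tuple(range(1, 8)))
        assert bg.cycles == 8
        assert bg.distance == 0
        assert bg.hurdles == 0 and not bg.fortress

    def test_cycle_count_below_max_for_nonidentity(self, rng):
        for _ in range(20):
            p = random_signed_permutation(10, rng).genes
            bg = breakpoint_graph(p)
            assert 1 <= bg.cycles <= 11
            assert (bg.cycles == 11) == (p == tuple(range(1, 11)))

    def test_hurdle_free_implies_no_fortress(self, rng):
        for _ in range(50):
            bg = breakpoint_graph(random_signed_permutation(8, rng).genes)
            if bg.hurdles == 0:
                assert not bg.fortress


class TestAgainstBfsOracle:
    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    def test_exhaustive_small(self, n):
        ident = identity_permutation(n)
        table = bfs_distance_map(ident)
        for genes in all_signed_permutations(n):
            hp = inversion_distance(SignedPermutation("x", genes), ident)
            assert hp == table[genes], genes

    def test_random_pairs_n6(self, rng):
        src = random_signed_permutation(6, rng, "src")
        table = bfs_distance_map(src)
        keys = sorted(table)
        for idx in rng.choice(len(keys), size=60, replace=False):
            genes = keys[int(idx)]
            assert inversion_distance(SignedPermutation("x", genes), src) == table[genes]

    def test_oracle_guard(self):
        a = identity_permutation(9)
        with pytest.raises(ValueError):
            bfs_distance_oracle(a, a)

    def test_oracle_examples(self):
        a = SignedPermutation("a", (1, 2, 3, 4))
        assert bfs_distance_oracle(a, a) == 0
        b = SignedPermutation("b", (1, -3, -2, 4))
        assert bfs_distance_oracle(a, b) == 1


class TestMetricProperties:
    def test_triangle_inequality_sampled(self, rng):
        for _ in range(15):
            a = random_signed_permutation(10, rng, "a")
            b = random_signed_permutation(10, rng, "b")
            c = random_signed_permutation(10, rng, "c")
            dab = inversion_distance(a, b)
            dbc = inversion_distance(b, c)
            dac = inversion_distance(a, c)
            assert dac <= dab + dbc

    def test_distance_bounded_by_applied_inversions(self, rng):
        # applying k inversions can never move further than k
        for _ in range(20):
            genes = list(identity_permutation(15).genes)
            k = int(rng.integers(1, 8))
            for _ in range(k):
                i, j = sorted(rng.integers(0, 15, size=2))
                genes[i : j + 1] = [-g for g in reversed(genes[i : j + 1])]
            d = inversion_distance(
                SignedPermutation("x", tuple(genes)), identity_permutation(15)
            )
            assert 0 <= d <= k


class TestDistanceMatrix:
    def test_identical_genomes_zero_matrix(self):
        gs = GenomeSet(
            (SignedPermutation("A", (1, 2, 3)), SignedPermutation("B", (1, 2, 3)))
        )
        dm = distance_matrix(gs)
        assert dm.values.sum() == 0

    def test_symmetric_zero_diagonal(self, rng):
        dm = distance_matrix(random_genome_set(8, 20, rng))
        assert np.array_equal(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0)
        assert np.all(dm.values <= 21)

    def test_bounded_by_twice_scenario_length(self, rng):
        # genomes k inversions from a common ancestor are <= 2k apart
        n, k = 30, 4
        genomes = []
        for t in range(4):
            genes = list(range(1, n + 1))
            for _ in range(k):
                i, j = sorted(rng.integers(0, n, size=2))
                genes[i : j + 1] = [-g for g in reversed(genes[i : j + 1])]
            genomes.append(SignedPermutation(f"g{t}", tuple(genes)))
        dm = distance_matrix(GenomeSet(tuple(genomes)))
        assert np.all(dm.values <= 2 * k)

    def test_rejects_asymmetric(self):
        with pytest.raises(ValueError):
            DistanceMatrix(("a", "b"), np.array([[0, 1], [2, 0]]))

    def test_phylip_roundtrip(self, tmp_path, rng):
        dm = distance_matrix(random_genome_set(5, 12, rng))
        f = tmp_path / "d.phy"
        write_phylip(dm, f)
        back = read_phylip(f)
        assert back.taxa == dm.taxa
        assert np.array_equal(back.values, dm.values)
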