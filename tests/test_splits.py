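"""Split model, structure predicates, tree conversion, and evaluation."""

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gonet import (
    Split,
    SplitSystem,
    are_compatible,
    evaluate,
    is_circular,
    is_compatible,
    is_trivial,
    is_weakly_compatible,
    splits_from_tree,
)
from gonet.splits import fits_ordering

TAXA4 = ("A", "B", "C", "D")


def sp(side, taxa=TAXA4):
    return Split.of(side, taxa)


def system(taxa, *sides):
    ss = SplitSystem(tuple(taxa))
    for s in sides:
        ss.add(Split.of(s, taxa), 1.0)
    return ss


class TestSplit:
    def test_canonical_equality(self):
        assert sp({"A", "B"}) == sp({"C", "D"})
        assert hash(sp({"A", "B"})) == hash(sp({"C", "D"}))

    def test_rejects_empty_side(self):
        with pytest.raises(ValueError):
            Split.of(set(), TAXA4)
        with pytest.raises(ValueError):
            Split.of(set(TAXA4), TAXA4)

    @settings(max_examples=50, deadline=None)
    @given(data=st.data())
    def test_orientation_independent_of_construction(self, data):
        n = data.draw(st.integers(2, 8))
        taxa = tuple(f"x{i}" for i in range(n))
        side = data.draw(
            st.sets(st.sampled_from(taxa), min_size=1, max_size=n - 1)
        )
        other = set(taxa) - side
        assert Split.of(side, taxa) == Split.of(other, taxa)

    def test_trivial(self):
        assert is_trivial(sp({"A"}))
        assert not is_trivial(sp({"A", "B"}))
        assert is_trivial(Split.of({"A"}, ("A", "B")))


class TestCompatibility:
    def test_trivial_compatible_with_everything(self):
        assert are_compatible(sp({"A", "B"}), sp({"A"}))

    def test_conflicting_quartet_splits(self):
        assert not are_compatible(sp({"A", "B"}), sp({"A", "C"}))

    def test_self_compatible(self):
        s = sp({"A", "B"})
        assert are_compatible(s, s)

    def test_taxon_set_mismatch_raises(self):
        with pytest.raises(ValueError):
            are_compatible(sp({"A", "B"}), Split.of({"A"}, ("A", "B", "C")))


class TestWeakCompatibility:
    def test_compatible_system_is_weakly_compatible(self):
        taxa = tuple("ABCDEF")
        ss = system(taxa, {"A", "B"}, {"A", "B", "C"}, {"E", "F"})
        assert is_compatible(ss)
        assert is_weakly_compatible(ss)

    def test_empty_system_vacuous(self):
        assert is_weakly_compatible(SplitSystem(TAXA4))

    def test_all_three_quartet_splits_not_weakly_compatible(self):
        # {AB|CD, AC|BD, AD|BC} violates the triple condition
        ss = system(TAXA4, {"A", "B"}, {"A", "C"}, {"A", "D"})
        assert not is_weakly_compatible(ss)

    def test_two_incompatible_splits_still_weakly_compatible(self):
        ss = system(TAXA4, {"A", "B"}, {"A", "C"})
        assert is_weakly_compatible(ss)


class TestCircularity:
    def test_single_quartet_split_orderings(self):
        ss = system(TAXA4, {"A", "C"})
        assert not fits_ordering(ss, ("A", "B", "C", "D"))
        assert fits_ordering(ss, ("A", "C", "B", "D"))
        assert is_circular(ss)

    def test_tree_splits_are_circular(self, pyrng):
        from .conftest import random_tree_metric

        for _ in range(5):
            _, tree = random_tree_metric(7, pyrng)
            assert is_circular(splits_from_tree(tree))

    def test_guard_raises_without_candidate(self):
        taxa = tuple(f"x{i:02d}" for i in range(12))
        ss = SplitSystem(taxa)
        ss.add(Split.of(taxa[:6], taxa), 1.0)
        with pytest.raises(ValueError):
            is_circular(ss)

    def test_candidate_ordering_bypasses_guard(self):
        taxa = tuple(f"x{i:02d}" for i in range(12))
        ss = SplitSystem(taxa)
        ss.add(Split.of(taxa[:6], taxa), 1.0)
        assert is_circular(ss, ordering=taxa)


class TestSplitsFromTree:
    def test_quartet_newick(self):
        tree = dendropy.Tree.get(data="((A,B),(C,D));", schema="newick")
        ss = splits_from_tree(tree)
        assert ss.nontrivial() == {sp({"A", "B"})}

    def test_star_tree_has_no_nontrivial_splits(self):
        tree = dendropy.Tree.get(data="(A,B,C,D,E);", schema="newick")
        assert splits_from_tree(tree).nontrivial() == frozenset()

    def test_binary_tree_split_count_and_compatibility(self, pyrng):
        from .conftest import random_tree_metric

        for _ in range(5):
            _, tree = random_tree_metric(10, pyrng)
            ss = splits_from_tree(tree)
            assert len(ss.nontrivial()) == 10 - 3
            assert is_compatible(ss)
            assert is_weakly_compatible(ss)

    def test_weights_are_branch_lengths(self):
        tree = dendropy.Tree.get(
            data="((A:1,B:2):0.5,(C:1,D:4):0.25);", schema="newick"
        )
        ss = splits_from_tree(tree)
        # the two root-adjacent half-edges fuse into one unrooted edge
        assert ss.weight(sp({"A", "B"})) == pytest.approx(0.75)
        assert ss.weight(sp({"A"})) == pytest.approx(1.0)

    def test_agrees_with_dendropy_bipartitions(self, pyrng):
        from .conftest import random_tree_metric

        _, tree = random_tree_metric(8, pyrng)
        ss = splits_from_tree(tree, topology_only=True)
        tree.encode_bipartitions()
        tns = tree.taxon_namespace
        dendropy_splits = set()
        for bp in tree.bipartition_encoding:
            mask = bp.leafset_bitmask
            side = frozenset(
                t.label for i, t in enumerate(tns) if mask & (1 << i)
            )
            if 0 < len(side) < len(tns):
                dendropy_splits.add(Split.of(side, [t.label for t in tns]))
        assert ss.splits <= dendropy_splits


class TestEvaluate:
    def tree(self, newick):
        return dendropy.Tree.get(data=newick, schema="newick")

    def test_perfect_agreement(self):
        t = self.tree("((A,B),(C,D),E);")
        res = evaluate(splits_from_tree(t), t)
        assert (res.tp, res.fn, res.fp) == (2, 0, 0)
        assert res.sensitivity == 1.0 and res.ppv == 1.0

    def test_extra_network_split(self):
        t = self.tree("((A,B),C,(D,E));")
        taxa = ("A", "B", "C", "D", "E")
        net = system(taxa, {"A", "B"}, {"D", "E"}, {"A", "C"})
        res = evaluate(net, t)
        assert (res.tp, res.fn, res.fp) == (2, 0, 1)
        assert res.sensitivity == 1.0
        assert res.ppv == pytest.approx(2 / 3)

    def test_missing_tree_split(self):
        t = self.tree("((A,B),(C,D),(E,F));")
        taxa = tuple("ABCDEF")
        net = system(taxa, {"A", "B"})
        res = evaluate(net, t)
        assert (res.tp, res.fn, res.fp) == (1, 2, 0)
        assert res.sensitivity == pytest.approx(1 / 3)
        assert res.ppv == 1.0

    def test_weights_ignored(self):
        t = self.tree("((A,B),(C,D),E);")
        taxa = ("A", "B", "C", "D", "E")
        net = SplitSystem(taxa)
        net.add(Split.of({"A", "B"}, taxa), 1e-9)
        net.add(Split.of({"C", "D"}, taxa), 1e-9)
        res = evaluate(net, t)
        assert res.tp == 2 and res.sensitivity == 1.0

    def test_degenerate_star_tree_flagged(self):
        t = self.tree("(A,B,C,D);")
        net = SplitSystem(TAXA4)
        res = evaluate(net, t)
        assert res.sensitivity == 1.0 and res.sensitivity_degenerate
        assert res.ppv == 1.0 and res.ppv_degenerate

    def test_antisymmetry_of_fn_fp(self):
        taxa = tuple("ABCDEF")
        s1 = system(taxa, {"A", "B"}, {"A", "B", "C"})
        s2 = system(taxa, {"A", "B"}, {"E", "F"})
        r12 = evaluate(s1, s2)
        r21 = evaluate(s2, s1)
        assert (r12.fn, r12.fp) == (r21.fp, r21.fn)
        assert r12.tp == r21.tp

    def test_taxon_mismatch_raises(self):
        t = self.tree("((A,B),(C,D));")
        with pytest.raises(ValueError):
            evaluate(SplitSystem(("A", "B", "C", "E")), t)
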