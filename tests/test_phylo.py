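import numpy as np
import pytest

from armscan.phylo import (DistanceMatrix, PhyloTree, _family_patristic,
                           bootstrap_support, neighbor_joining, p_distance,
                           partition_classes)
from armscan.seqio import AlignmentBlock

from oracles import random_additive_tree


def leaf_patristic(tree: PhyloTree):
    leaves = sorted(tree.leaf_names)
    fams, mat = _family_patristic(tree, {l: l for l in tree.leaf_names})
    order = [fams.index(l) for l in leaves]
    return leaves, mat[np.ix_(order, order)]


def test_p_distance_basics():
    aln = AlignmentBlock(rows=[("a", "AAAA"), ("b", "AAAT"), ("c", "AAAA")])
    dm = p_distance(aln, min_comparable=1)
    i, j = dm.ids.index("a"), dm.ids.index("b")
    assert dm.values[i, j] == pytest.approx(0.25)
    assert dm.values[i, dm.ids.index("c")] == 0.0


def test_p_distance_pairwise_deletion():
    aln = AlignmentBlock(rows=[("a", "AA-A"), ("b", "AATA")])
    dm = p_distance(aln, min_comparable=1)
    assert dm.values[0, 1] == 0.0
    assert dm.comparable[0, 1] == 3


def test_p_distance_all_gap_pair_is_error():
    aln = AlignmentBlock(rows=[("a", "AA--"), ("b", "--TT")])
    with pytest.raises(ValueError, match="no comparable"):
        p_distance(aln, min_comparable=1)


def test_p_distance_low_overlap_flagged_missing():
    aln = AlignmentBlock(rows=[("a", "AAA-"), ("b", "--AT"), ("c", "AAAT")])
    dm = p_distance(aln, min_comparable=2)
    assert np.isnan(dm.values[0, 1])  # a/b share one column only


def test_three_taxon_closed_form():
    dm = DistanceMatrix(
        ("A", "B", "C"),
        np.array([[0.0, 2.0, 4.0], [2.0, 0.0, 4.0], [4.0, 4.0, 0.0]]),
    )
    tree = neighbor_joining(dm)
    lengths = {ch.name: ch.length for ch in tree.root.children}
    assert lengths == {"A": pytest.approx(1.0), "B": pytest.approx(1.0),
                      "C": pytest.approx(3.0)}


def test_nj_requires_three_taxa():
    dm = DistanceMatrix(("A", "B"), np.array([[0.0, 1.0], [1.0, 0.0]]))
    with pytest.raises(ValueError, match="at least 3"):
        neighbor_joining(dm)


def test_nj_exact_on_additive_matrices(rng):
    for _ in range(30):
        n = int(rng.integers(4, 13))
        labels, dist, bips = random_additive_tree(rng, n)
        tree = neighbor_joining(DistanceMatrix(tuple(labels), dist))
        assert set(tree.bipartitions()) == bips
        leaves, patristic = leaf_patristic(tree)
        assert leaves == labels
        assert np.abs(patristic - dist).max() < 1e-9


def test_nj_invariant_to_taxon_order(rng):
    labels, dist, bips = random_additive_tree(rng, 8)
    perm = rng.permutation(8)
    tree1 = neighbor_joining(DistanceMatrix(tuple(labels), dist))
    tree2 = neighbor_joining(
        DistanceMatrix(tuple(labels[i] for i in perm), dist[np.ix_(perm, perm)])
    )
    assert set(tree1.bipartitions()) == set(tree2.bipartitions())
    _, p1 = leaf_patristic(tree1)
    _, p2 = leaf_patristic(tree2)
    assert np.allclose(p1, p2, atol=1e-9)


def test_nj_agrees_with_independent_implementation(rng):
    """Cross-check topology against scikit-bio's neighbor joining."""
    import skbio

    labels, dist, bips = random_additive_tree(rng, 9)
    ours = neighbor_joining(DistanceMatrix(tuple(labels), dist))
    theirs = skbio.tree.nj(skbio.DistanceMatrix(dist, ids=labels))
    anchor = min(labels)
    their_bips = set()
    for node in theirs.non_tips():
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = frozenset(labels) - side
        if 1 < len(side) < len(labels) - 1:
            their_bips.add(side)
    assert set(ours.bipartitions()) == their_bips


def _two_clade_alignment(cols=40, rng=None):
    rng = rng or np.random.default_rng(0)
    a = "".join(rng.choice(list("ACDEFGHIK"), size=cols))
    b = "".join(rng.choice(list("LMNPQRSTV"), size=cols))
    def noisy(base):
        chars = list(base)
        for i in range(0, cols, 7):
            chars[i] = "W" if chars[i] != "W" else "Y"
        return "".join(chars)
    return AlignmentBlock(
        rows=[("a1", a), ("a2", noisy(a)), ("b1", b), ("b2", noisy(b))]
    )


def test_bootstrap_single_replicate_supports_are_binary():
    aln = _two_clade_alignment()
    tree = bootstrap_support(aln, B=1, seed=3)
    supports = [n.support for n in tree.bipartitions().values()]
    assert supports and all(s in (0.0, 100.0) for s in supports)


def test_bootstrap_deterministic_under_seed():
    aln = _two_clade_alignment()
    t1 = bootstrap_support(aln, B=20, seed=9)
    t2 = bootstrap_support(aln, B=20, seed=9)
    s1 = {k: v.support for k, v in t1.bipartitions().items()}
    s2 = {k: v.support for k, v in t2.bipartitions().items()}
    assert s1 == s2


def test_bootstrap_strong_signal_full_support_survives_column_shuffle(rng):
    aln = _two_clade_alignment(cols=60)
    perm = rng.permutation(60)
    shuffled = AlignmentBlock(
        rows=[(rid, "".join(s[i] for i in perm)) for rid, s in aln.rows]
    )
    for a in (aln, shuffled):
        tree = bootstrap_support(a, B=50, seed=4)
        clade = frozenset({"b1", "b2"})
        assert tree.bipartitions()[clade].support == 100.0


def test_partition_two_separated_families():
    aln = _two_clade_alignment()
    tree = bootstrap_support(aln, B=20, seed=5)
    part = partition_classes(
        tree, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}, k_cut=70
    )
    assert part.groups() == [frozenset({"A"}), frozenset({"B"})]
    assert all(p == 1.0 for p in part.purity.values())


def test_partition_collapses_when_k_cut_exceeds_supports():
    aln = _two_clade_alignment()
    tree = bootstrap_support(aln, B=20, seed=5)
    part = partition_classes(
        tree, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}, k_cut=101
    )
    assert part.groups() == [frozenset({"A", "B"})]
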