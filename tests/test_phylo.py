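"""MSA, p-distances, neighbor joining, midpoint rooting and MRCA taxonomy
propagation."""

import dendropy
import numpy as np
import pytest

from crasskit.phylo import (distance_matrix, midpoint_root,
                            neighbor_joining, parse_reference_labels,
                            progressive_msa, propagate_taxonomy,
                            TaxonomyAssignment)
from crasskit.records import ProteinRecord


def leaf_depths(tree):
    out = {}
    for lf in tree.leaf_node_iter():
        d, n = 0.0, lf
        while n.parent_node is not None:
            d += n.edge.length or 0.0
            n = n.parent_node
        out[lf.taxon.label] = d
    return out


def path_distances(tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.distance(taxa[i], taxa[j])
    return [t.label for t in taxa], d


def random_additive_tree(rng, n):
    """Random binary tree with exponential branch lengths; returns its
    newick and the labels."""
    nodes = [f"t{i}" for i in range(n)]
    lengths = {}
    frags = {lab: lab for lab in nodes}
    active = nodes[:]
    k = 0
    while len(active) > 2:
        i, j = sorted(rng.choice(len(active), 2, replace=False))
        a, b = active[j], active[i]       # pop larger index first
        la, lb = rng.exponential(1.0, 2) + 0.05
        new = f"n{k}"; k += 1
        frags[new] = f"({frags[a]}:{la:.6f},{frags[b]}:{lb:.6f})"
        active.remove(a); active.remove(b); active.append(new)
    la, lb = rng.exponential(1.0, 2) + 0.05
    newick = f"({frags[active[0]]}:{la:.6f},{frags[active[1]]}:{lb:.6f});"
    return newick, nodes


# ---------------------------------------------------------------------------
# MSA


def test_msa_identical_sequences_no_gaps():
    ids, rows = progressive_msa([ProteinRecord(id="a", seq="MKVLW"),
                                 ProteinRecord(id="b", seq="MKVLW")])
    assert rows == ["MKVLW", "MKVLW"]


def test_msa_single_gap_at_deletion():
    ids, rows = progressive_msa([ProteinRecord(id="a", seq="ACDEFG"),
                                 ProteinRecord(id="b", seq="ACEFG")])
    assert rows[0] == "ACDEFG"
    assert rows[1] == "AC-EFG"


def test_msa_width_at_least_longest_input(rng):
    AA = "ACDEFGHIKLMNPQRSTVWY"
    prots = [ProteinRecord(id=f"p{i}", seq="".join(
        AA[j] for j in rng.integers(0, 20, int(rng.integers(20, 40)))))
        for i in range(5)]
    ids, rows = progressive_msa(prots)
    width = len(rows[0])
    assert all(len(r) == width for r in rows)
    assert width >= max(len(p.seq) for p in prots)


def test_msa_needs_two_sequences():
    with pytest.raises(ValueError):
        progressive_msa([ProteinRecord(id="a", seq="MKV")])


# ---------------------------------------------------------------------------
# distances


def test_distance_matrix_examples():
    d = distance_matrix(["AAAAAAAAAA", "AAABBBAAAA"])
    assert d[0, 1] == pytest.approx(0.3)
    d2 = distance_matrix(["AA-A", "AABA"])
    assert d2[0, 1] == pytest.approx(0.0)     # gap column excluded


def test_distance_matrix_symmetric_zero_diagonal(rng):
    rows = ["".join(rng.choice(list("ACDE-"), 30)) for _ in range(5)]
    try:
        d = distance_matrix(rows)
    except ValueError:
        return    # all-gap overlap pair: error is the specified behavior
    assert np.allclose(d, d.T)
    assert np.allclose(np.diag(d), 0.0)


def test_distance_matrix_no_comparable_positions():
    with pytest.raises(ValueError):
        distance_matrix(["A-", "-A"])


# ---------------------------------------------------------------------------
# neighbor joining


def test_nj_three_taxa_closed_form():
    d = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], float)
    t = neighbor_joining(d, ["A", "B", "C"])
    labels, got = path_distances(t)
    assert np.allclose(got, d)
    # star branch lengths: x_A = (dAB + dAC - dBC)/2 = 1
    depths = {lf.taxon.label: lf.edge.length
              for lf in t.leaf_node_iter()}
    assert depths["A"] == pytest.approx(1.0)
    assert depths["B"] == pytest.approx(3.0)
    assert depths["C"] == pytest.approx(5.0)


def test_nj_recovers_four_taxon_additive_tree():
    # ((A:1,B:2):1,(C:3,D:4):1)
    labels = list("ABCD")
    d = np.array([[0, 3, 6, 7], [3, 0, 7, 8],
                  [6, 7, 0, 7], [7, 8, 7, 0]], float)
    t = neighbor_joining(d, labels)
    got_labels, got = path_distances(t)
    assert got_labels == labels
    assert np.allclose(got, d, atol=1e-9)
    # topology AB|CD: the split must separate {A,B} from {C,D}
    t.encode_bipartitions()
    splits = {frozenset(lf.taxon.label for lf in e.head_node.leaf_iter())
              for e in t.preorder_edge_iter() if e.head_node.child_nodes()}
    assert frozenset("AB") in splits or frozenset("CD") in splits


def test_nj_exact_on_random_additive_trees(rng):
    for _ in range(10):
        n = int(rng.integers(4, 11))
        newick, labels = random_additive_tree(rng, n)
        src = dendropy.Tree.get(data=newick, schema="newick")
        _, d_true = path_distances(src)
        t = neighbor_joining(d_true, sorted(labels))
        _, d_got = path_distances(t)
        assert np.allclose(d_got, d_true, atol=1e-9)


def test_nj_rejects_bad_input():
    with pytest.raises(ValueError):
        neighbor_joining(np.array([[0, 1], [1, 0]]), ["a", "b"])
    d = np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0]], float)
    with pytest.raises(ValueError):
        neighbor_joining(d, list("abc"))


def test_nj_agrees_with_skbio(rng):
    """Cross-check against an independent implementation."""
    skbio = pytest.importorskip("skbio")
    from skbio import DistanceMatrix
    from skbio.tree import nj as skbio_nj
    newick, labels = random_additive_tree(rng, 7)
    src = dendropy.Tree.get(data=newick, schema="newick")
    got_labels, d = path_distances(src)
    ours = neighbor_joining(d, got_labels)
    theirs = skbio_nj(DistanceMatrix(d, got_labels))
    _, d_ours = path_distances(ours)
    d_theirs = np.zeros_like(d)
    for i, a in enumerate(got_labels):
        for j, b in enumerate(got_labels):
            if i != j:
                d_theirs[i, j] = theirs.find(a).distance(theirs.find(b))
    assert np.allclose(d_ours, d_theirs, atol=1e-6)


# ---------------------------------------------------------------------------
# midpoint rooting


def test_midpoint_two_leaves():
    t = dendropy.Tree.get(data="(A:3,B:7);", schema="newick")
    r = midpoint_root(t)
    depths = leaf_depths(r)
    assert depths["A"] == pytest.approx(5.0)
    assert depths["B"] == pytest.approx(5.0)


def oracle_min_max_depth(tree):
    """Minimum achievable max root-leaf depth over every point on every
    edge = half the tree diameter."""
    _, d = path_distances(tree)
    return d.max() / 2.0


def test_midpoint_minimizes_max_depth_exhaustive(rng):
    for _ in range(10):
        n = int(rng.integers(3, 9))
        newick, labels = random_additive_tree(rng, n)
        t = dendropy.Tree.get(data=newick, schema="newick")
        target = oracle_min_max_depth(t)
        r = midpoint_root(t)
        depths = leaf_depths(r)
        assert max(depths.values()) == pytest.approx(target, abs=1e-9)


def test_midpoint_preserves_path_distances(rng):
    newick, labels = random_additive_tree(rng, 6)
    t = dendropy.Tree.get(data=newick, schema="newick")
    _, before = path_distances(t)
    r = midpoint_root(t)
    _, after = path_distances(r)
    assert np.allclose(before, after, atol=1e-9)


def test_midpoint_matches_dendropy(rng):
    newick, _ = random_additive_tree(rng, 8)
    t = dendropy.Tree.get(data=newick, schema="newick")
    ours = midpoint_root(t)
    theirs = dendropy.Tree.get(data=newick, schema="newick")
    theirs.reroot_at_midpoint(update_bipartitions=False)
    d_ours = leaf_depths(ours)
    d_theirs = leaf_depths(theirs)
    for k in d_ours:
        assert d_ours[k] == pytest.approx(d_theirs[k], abs=1e-9)


# ---------------------------------------------------------------------------
# taxonomy propagation


def test_propagation_toy_tree():
    t = dendropy.Tree.get(
        data="(((h1|alpha:1,(h2|alpha:1,p1:1):1):1,"
             "(h3|beta:1,h4|beta:1):1):1,p2:9);",
        schema="newick", preserve_underscores=True)
    got = {a.leaf_id: a.family for a in propagate_taxonomy(t)}
    assert got["p1"] == "alpha"
    assert got["p2"] == "unclassified"      # outside every labeled MRCA
    assert got["h3|beta"] == "beta"


def test_propagation_nested_labels_smallest_clade_wins():
    # delta clade nested inside the broader alpha MRCA
    t = dendropy.Tree.get(
        data="((h1|alpha:1,((h2|delta:1,(p1:1,h3|delta:1):1):1,"
             "h4|alpha:1):1):1,out:9);",
        schema="newick", preserve_underscores=True)
    got = {a.leaf_id: a.family for a in propagate_taxonomy(t)}
    assert got["p1"] == "delta"
    assert got["h4|alpha"] == "alpha"


def test_reference_leaves_keep_their_own_label(rng):
    newick, labels = random_additive_tree(rng, 8)
    # label two disjoint cherries
    t = dendropy.Tree.get(data=newick, schema="newick")
    leaves = [lf.taxon.label for lf in t.leaf_node_iter()]
    ref = {leaves[0]: "alpha", leaves[1]: "beta"}
    got = {a.leaf_id: a.family
           for a in propagate_taxonomy(t, reference=ref)}
    for leaf, fam in ref.items():
        assert got[leaf] == fam


def test_propagation_missing_family_errors():
    t = dendropy.Tree.get(data="(a:1,b:1);", schema="newick")
    with pytest.raises(ValueError):
        propagate_taxonomy(t, reference={"a": "alpha"},
                           families=["alpha", "beta"])


def test_planted_family_recovery_on_random_fixture_trees(rng):
    """Random trees with monophyletic reference families plus unlabeled
    query leaves inside each family clade: propagation must recover every
    planted query family."""
    for rep in range(20):
        parts = []
        truth = {}
        ref = {}
        for fam in ("alpha", "beta", "delta", "zeta"):
            refs, queries = [], []
            for i in range(3):
                lab = f"h_{fam}{i}|{fam}"
                ref[lab] = fam
                refs.append(lab)
            for i in range(2):
                lab = f"q_{fam}{i}"
                truth[lab] = fam
                queries.append(lab)
            # interleave so every query sits inside the reference MRCA
            members = [refs[0], queries[0], refs[1], queries[1], refs[2]]
            frag = members[0] + ":0.1"
            for m in members[1:]:
                frag = f"({frag},{m}:0.1):0.1"
            parts.append(frag)
        newick = f"(({parts[0]},{parts[1]}):1.0,({parts[2]},{parts[3]}):1.0);"
        t = dendropy.Tree.get(data=newick, schema="newick",
                              preserve_underscores=True)
        got = {a.leaf_id: a.family for a in propagate_taxonomy(t, ref)}
        for q, fam in truth.items():
            assert got[q] == fam
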