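"""Progressive MSA, p-distance, neighbor joining."""

import dendropy
import numpy as np
import pytest

from hervarch import (
    DistanceMatrix,
    neighbor_joining,
    p_distance,
    progressive_msa,
    tree_from_sequences,
)
from hervarch.phylo import MultipleAlignment, PhyloTree, TreeNode

from conftest import mutate, random_dna


def test_identical_sequences_align_without_gaps():
    msa = progressive_msa({"a": "ACGTACGT", "b": "ACGTACGT"})
    assert msa.rows[0] == msa.rows[1] == "ACGTACGT"


def test_single_gap_alignment():
    msa = progressive_msa({"x": "ACGT", "y": "ACT"})
    assert msa.n_columns == 4
    gapped = dict(zip(msa.labels, msa.rows))
    assert gapped["x"] == "ACGT"
    assert gapped["y"].count("-") == 1
    matched = sum(
        a == b for a, b in zip(gapped["x"], gapped["y"]) if a != "-" and b != "-"
    )
    assert matched == 3


def test_msa_rows_reproduce_inputs():
    rng = np.random.default_rng(0)
    template = random_dna(rng, 400)
    seqs = {f"s{i}": mutate(rng, template, 0.02) for i in range(5)}
    msa = progressive_msa(seqs)
    for name, seq in seqs.items():
        assert msa.ungapped(name) == seq


def test_low_divergence_group_stays_similar():
    rng = np.random.default_rng(1)
    template = random_dna(rng, 500)
    seqs = {f"s{i}": mutate(rng, template, 0.02) for i in range(5)}
    dm = p_distance(progressive_msa(seqs))
    off_diag = dm.values[~np.eye(5, dtype=bool)]
    assert off_diag.max() <= 0.05  # pairwise identity >= 0.95


def test_msa_input_validation():
    with pytest.raises(ValueError):
        progressive_msa({"a": "ACGT"})
    with pytest.raises(ValueError):
        progressive_msa({"a": "ACGT", "b": "ACQT"})
    with pytest.raises(ValueError):
        progressive_msa({"a": "MKL", "b": "MKV"}, alphabet="dna")


def test_p_distance_examples():
    msa = MultipleAlignment(("a", "b"), ("ACGTACGTAC", "ACGTACGTAC"))
    assert p_distance(msa).get("a", "b") == 0.0
    msa2 = MultipleAlignment(("a", "b"), ("ACGTACGTAC", "TCGTTCGTTC"))
    assert p_distance(msa2).get("a", "b") == pytest.approx(0.3)


def test_p_distance_ignores_gapped_columns():
    msa = MultipleAlignment(("a", "b"), ("AC-TA", "ACGTT"))
    # comparable columns: A,C,T,A vs A,C,T,T -> 1/4
    assert p_distance(msa).get("a", "b") == pytest.approx(0.25)


def test_p_distance_matches_quadratic_oracle():
    rng = np.random.default_rng(2)
    labels = tuple(f"s{i}" for i in range(6))
    rows = []
    for _ in labels:
        rows.append(
            "".join(rng.choice(list("ACGT-"), p=[0.22, 0.22, 0.22, 0.22, 0.12], size=80))
        )
    msa = MultipleAlignment(labels, tuple(rows))
    dm = p_distance(msa)
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i == j:
                continue
            comp = [
                (x, y) for x, y in zip(rows[i], rows[j]) if x != "-" and y != "-"
            ]
            expected = sum(x != y for x, y in comp) / len(comp)
            assert dm.values[i, j] == pytest.approx(expected)


def test_p_distance_is_metric_on_gapfree_alignments():
    rng = np.random.default_rng(3)
    labels = tuple(f"s{i}" for i in range(5))
    rows = tuple("".join(rng.choice(list("ACGT"), size=60)) for _ in labels)
    dm = p_distance(MultipleAlignment(labels, rows))
    v = dm.values
    assert np.allclose(v, v.T)
    for i in range(5):
        for j in range(5):
            for k in range(5):
                assert v[i, j] <= v[i, k] + v[k, j] + 1e-12


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def random_additive_tree(rng, labels):
    """A random binary tree with random branch lengths; returns (tree,
    leaf-to-leaf path-length matrix) — the additive-matrix oracle."""
    nodes = [TreeNode(name=l) for l in labels]
    lengths = {}
    counter = [0]
    edges = []
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        bi, bj = rng.uniform(0.05, 1.0, size=2)
        parent = TreeNode(children=((nodes[i], bi), (nodes[j], bj)))
        edges.append((parent, nodes[i], bi))
        edges.append((parent, nodes[j], bj))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = nodes[0]

    # leaf-to-leaf distances by DFS
    def paths(node, acc, out):
        if node.is_leaf:
            out[node.name] = acc
        for child, bl in node.children:
            paths(child, acc + bl, out)

    # distance(i,j) = depth_i + depth_j - 2*depth(lca); easier: recompute per leaf
    def dist_from(leaf_root):
        # BFS over undirected adjacency
        adj = {}

        def build(node):
            for child, bl in node.children:
                adj.setdefault(id(node), []).append((child, bl))
                adj.setdefault(id(child), []).append((node, bl))
                build(child)

        build(root)
        by_id = {}

        def collect(node):
            by_id[id(node)] = node
            for child, _ in node.children:
                collect(child)

        collect(root)
        start = next(n for n in by_id.values() if n.is_leaf and n.name == leaf_root)
        dist = {id(start): 0.0}
        stack = [start]
        while stack:
            cur = stack.pop()
            for nxt, bl in adj.get(id(cur), []):
                if id(nxt) not in dist:
                    dist[id(nxt)] = dist[id(cur)] + bl
                    stack.append(nxt)
        return {
            n.name: dist[id(n)] for n in by_id.values() if n.is_leaf
        }

    n = len(labels)
    values = np.zeros((n, n))
    for i, a in enumerate(labels):
        da = dist_from(a)
        for j, b in enumerate(labels):
            values[i, j] = da[b]
    np.fill_diagonal(values, 0.0)
    values = (values + values.T) / 2
    return root, DistanceMatrix(tuple(labels), values)


def rf_distance(newick_a, newick_b):
    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=tns)
    t2 = dendropy.Tree.get(data=newick_b, schema="newick", taxon_namespace=tns)
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(t1, t2)


def tree_newick(root):
    return PhyloTree(root).to_newick()


def test_three_taxon_closed_form():
    labels = ("A", "B", "C")
    v = np.array([[0, 0.4, 0.6], [0.4, 0, 0.8], [0.6, 0.8, 0]])
    tree = neighbor_joining(DistanceMatrix(labels, v))
    bl = {child.name: l for child, l in tree.root.children}
    assert bl["A"] == pytest.approx((0.4 + 0.6 - 0.8) / 2)
    assert bl["B"] == pytest.approx((0.4 + 0.8 - 0.6) / 2)
    assert bl["C"] == pytest.approx((0.6 + 0.8 - 0.4) / 2)


def test_four_taxon_additive_recovery():
    """On an additive 4-taxon matrix NJ recovers topology and branch lengths."""
    # tree: ((A:0.2,B:0.3):0.15,C:0.4,D:0.7)
    labels = ("A", "B", "C", "D")
    d = {
        ("A", "B"): 0.5,
        ("A", "C"): 0.2 + 0.15 + 0.4,
        ("A", "D"): 0.2 + 0.15 + 0.7,
        ("B", "C"): 0.3 + 0.15 + 0.4,
        ("B", "D"): 0.3 + 0.15 + 0.7,
        ("C", "D"): 1.1,
    }
    v = np.zeros((4, 4))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j:
                v[i, j] = d[tuple(sorted((a, b)))]
    tree = neighbor_joining(DistanceMatrix(labels, v))
    expected = "((A:0.2,B:0.3):0.15,C:0.4,D:0.7);"
    assert rf_distance(tree.to_newick(), expected) == 0
    # every edge length exact
    lengths = []

    def collect(node):
        for child, bl in node.children:
            lengths.append(round(bl, 10))
            collect(child)

    collect(tree.root)
    assert sorted(lengths) == pytest.approx([0.15, 0.2, 0.3, 0.4, 0.7])


def test_nj_consistency_on_random_additive_matrices():
    """NJ reproduces the generating topology for 50 random 6-leaf trees."""
    rng = np.random.default_rng(7)
    labels = [f"T{i}" for i in range(6)]
    for _ in range(50):
        true_root, dm = random_additive_tree(rng, labels)
        tree = neighbor_joining(dm)
        assert rf_distance(tree.to_newick(), tree_newick(true_root)) == 0


def test_nj_invariant_under_label_permutation():
    rng = np.random.default_rng(8)
    labels = [f"T{i}" for i in range(6)]
    _, dm = random_additive_tree(rng, labels)
    perm = list(rng.permutation(6))
    labels_p = tuple(dm.labels[i] for i in perm)
    values_p = dm.values[np.ix_(perm, perm)]
    t1 = neighbor_joining(dm)
    t2 = neighbor_joining(DistanceMatrix(labels_p, values_p))
    assert rf_distance(t1.to_newick(), t2.to_newick()) == 0


def test_outgroup_rooting():
    rng = np.random.default_rng(9)
    _, dm = random_additive_tree(rng, [f"T{i}" for i in range(5)])
    tree = neighbor_joining(dm, outgroup="T3")
    names = [
        child.name for child, _ in tree.root.children if child.is_leaf
    ]
    assert "T3" in names
    with pytest.raises(ValueError, match="outgroup"):
        neighbor_joining(dm, outgroup="missing")


def test_nj_needs_three_taxa():
    with pytest.raises(ValueError):
        neighbor_joining(DistanceMatrix(("a", "b"), np.array([[0, 1.0], [1.0, 0]])))


def test_template_groups_cluster_together():
    """Sequences simulated from two templates: NJ keeps each template's
    descendants together (the similarity-grouping claim, on synthetic data)."""
    rng = np.random.default_rng(10)
    ta = random_dna(rng, 400)
    tb = mutate(rng, ta, 0.25)  # a distant relative
    seqs = {}
    for i in range(3):
        seqs[f"A{i}"] = mutate(rng, ta, 0.02)
        seqs[f"B{i}"] = mutate(rng, tb, 0.02)
    tree, dm, _ = tree_from_sequences(seqs, alphabet="nt")
    # the A leaves form a clade on one side: check via bipartition in dendropy
    t = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
    a_taxa = {f"A{i}" for i in range(3)}
    clades = []
    for node in t.preorder_node_iter():
        leaves = {l.taxon.label for l in node.leaf_iter()}
        clades.append(leaves)
    assert a_taxa in clades or ({f"B{i}" for i in range(3)}) in clades
    # and within-group distances are smaller than between-group
    within = max(dm.get("A0", "A1"), dm.get("B0", "B1"))
    between = dm.get("A0", "B0")
    assert within < between
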