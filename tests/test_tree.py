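"""p-distances, neighbor joining, clade enumeration and Newick I/O."""

import io

import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.tree import TreeNode

from sstea.msa import ALPHABET, AlignedRecord, TMAlignment
from sstea.tree import (
    Subfamily,
    build_nj_tree,
    p_distance_matrix,
    read_newick,
    subfamilies_containing,
    write_newick,
)


def _rec(rid, seq, species="sp"):
    return AlignedRecord(rid, species, seq)


def test_p_distance_identity_and_single_mismatch():
    base = "A" * 171
    one_off = "C" + "A" * 170
    dm = p_distance_matrix(TMAlignment([_rec("a", base), _rec("b", base), _rec("c", one_off)]))
    assert dm["a", "b"] == 0.0
    assert dm["a", "c"] == pytest.approx(1 / 171)


def test_p_distance_matches_brute_force_recount():
    rng = np.random.default_rng(2)
    seqs = ["".join(ALPHABET[a] for a in rng.integers(20, size=171)) for _ in range(6)]
    aln = TMAlignment([_rec(f"r{i}", s) for i, s in enumerate(seqs)])
    dm = p_distance_matrix(aln)
    for i in range(6):
        for j in range(6):
            expected = sum(x != y for x, y in zip(seqs[i], seqs[j])) / 171
            assert dm[f"r{i}", f"r{j}"] == pytest.approx(expected)


def test_p_distance_ambiguity_matches_only_itself():
    a = "X" + "A" * 170
    b = "X" + "A" * 170
    c = "C" + "A" * 170
    dm = p_distance_matrix(TMAlignment([_rec("a", a), _rec("b", b), _rec("c", c)]))
    assert dm["a", "b"] == 0.0
    assert dm["a", "c"] == pytest.approx(1 / 171)


def _splits(tree):
    """Non-trivial leaf bipartitions of an (un)rooted tree, as frozensets."""
    leaves = frozenset(t.name for t in tree.tips())
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(leaves) - 1:
            out.add(min(side, other := leaves - side, key=sorted))
    return out


def _random_additive(rng, n_taxa):
    """A random binary tree with known branch lengths and its path-distance matrix."""
    nodes = [TreeNode(name=f"t{i}") for i in range(n_taxa)]
    for node in nodes:
        node.length = float(rng.uniform(0.1, 1.0))
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = TreeNode(children=[nodes[i], nodes[j]])
        parent.length = float(rng.uniform(0.1, 1.0))
        rest = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes = rest + [parent]
    root = TreeNode(children=nodes)
    ids = [f"t{i}" for i in range(n_taxa)]
    dm = root.tip_tip_distances(endpoints=ids)
    return root, DistanceMatrix(dm.data, ids)


@pytest.mark.parametrize("n_taxa", [4, 5, 6, 8])
def test_nj_recovers_generating_topology_from_additive_matrix(n_taxa):
    rng = np.random.default_rng(n_taxa)
    for _ in range(10):
        true_tree, dm = _random_additive(rng, n_taxa)
        recovered = build_nj_tree(dm)
        assert _splits(recovered) == _splits(true_tree)


def test_nj_three_taxa_closed_form_branch_lengths():
    # three-point formulas: x = (dab + dac - dbc) / 2, etc.
    d = {"ab": 0.6, "ac": 0.8, "bc": 0.9}
    dm = DistanceMatrix(
        [[0, d["ab"], d["ac"]], [d["ab"], 0, d["bc"]], [d["ac"], 0.9, 0]],
        ["a", "b", "c"],
    )
    tree = build_nj_tree(dm)
    tip_dist = tree.tip_tip_distances(endpoints=["a", "b", "c"])
    assert tip_dist["a", "b"] == pytest.approx(0.6)
    assert tip_dist["a", "c"] == pytest.approx(0.8)
    assert tip_dist["b", "c"] == pytest.approx(0.9)


def test_nj_requires_three_taxa():
    dm = DistanceMatrix([[0, 0.1], [0.1, 0]], ["a", "b"])
    with pytest.raises(ValueError):
        build_nj_tree(dm)


def test_midpoint_root_separates_two_planted_clusters():
    rng = np.random.default_rng(5)
    anc1 = rng.integers(20, size=171)
    anc2 = rng.integers(20, size=171)
    recs = []
    for k, anc in enumerate((anc1, anc2)):
        for i in range(5):
            row = anc.copy()
            flip = rng.choice(171, size=4, replace=False)
            row[flip] = rng.integers(20, size=4)
            recs.append(_rec(f"c{k}_{i}", "".join(ALPHABET[a] for a in row)))
    tree = build_nj_tree(p_distance_matrix(TMAlignment(recs)))
    sides = [frozenset(t.name for t in child.tips()) for child in tree.children]
    cluster0 = frozenset(f"c0_{i}" for i in range(5))
    assert cluster0 in sides or (frozenset(r.id for r in recs) - cluster0) in sides


def _chain_tree():
    """Nested clades of sizes 2, 4, 8, 16 around leaf L0."""
    newick = io.StringIO(
        "((((L0:1,L1:1):1,(L2:1,L3:1):1):1,(L4:1,L5:1,L6:1,L7:1):1):1,"
        "(L8:1,L9:1,L10:1,L11:1,L12:1,L13:1,L14:1,L15:1):1):1;"
    )
    return TreeNode.read(newick, format="newick")


def test_subfamilies_containing_applies_size_window():
    tree = _chain_tree()
    subs = subfamilies_containing(tree, "L0", min_size=3, max_size=10)
    assert [s.size for s in subs] == [4, 8]
    for s in subs:
        assert "L0" in s.members


def test_subfamilies_exclude_whole_tree_clade():
    tree = _chain_tree()
    subs = subfamilies_containing(tree, "L0", min_size=1, max_size=100)
    assert all(s.size < 16 for s in subs)
    assert [s.size for s in subs] == sorted(s.size for s in subs)


def test_subfamilies_empty_window_and_unknown_leaf():
    tree = _chain_tree()
    assert subfamilies_containing(tree, "L0", min_size=9, max_size=10) == []
    with pytest.raises(KeyError):
        subfamilies_containing(tree, "NOPE")


def test_subfamily_size_must_match_members():
    with pytest.raises(ValueError):
        Subfamily(frozenset({"a", "b"}), 3)


def test_newick_roundtrip(tmp_path):
    path = tmp_path / "t.nwk"
    path.write_text("(A:1,(B:1,C:1):1);\n")
    tree = read_newick(path)
    assert sorted(t.name for t in tree.tips()) == ["A", "B", "C"]
    out = tmp_path / "o.nwk"
    write_newick(tree, out)
    assert _splits(read_newick(out)) == _splits(tree)
    assert read_newick(out).find("B").length == 1.0


def test_malformed_newick_raises(tmp_path):
    path = tmp_path / "bad.nwk"
    path.write_text("((A:1,(B:1;")
    with pytest.raises(Exception):
        read_newick(path)
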