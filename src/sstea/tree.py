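"""Subfamily tree machinery: p-distances, neighbor joining, clade queries.

The receptor database is organized as a hierarchical tree built by neighbor
joining from the pairwise p-distance matrix of the 171 TM columns.  A
*subfamily* is the set of sequences under one node; scoring considers every
subfamily containing the query receptor whose size lies in a window (default
50-300 sequences) large enough for evolutionary signal yet small enough to
keep ligand pressure homogeneous.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from .bw import N_TM_COLUMNS
from .msa import TMAlignment

__all__ = [
    "Subfamily",
    "p_distance_matrix",
    "build_nj_tree",
    "subfamilies_containing",
    "read_newick",
    "write_newick",
]


@dataclass(frozen=True)
class Subfamily:
    """One scoring-eligible branch of the tree."""

    members: frozenset[str]
    size: int
    node: TreeNode | None = None

    def __post_init__(self) -> None:
        if self.size != len(self.members):
            raise ValueError("subfamily size disagrees with member set")


def p_distance_matrix(aln: TMAlignment) -> DistanceMatrix:
    """Pairwise fraction of mismatching TM columns (p-distance).

    Ambiguity symbols count as a mismatch against everything except an
    identical symbol.
    """
    if len(aln) < 2:
        raise ValueError("need at least 2 records for a distance matrix")
    mat = aln.matrix
    n = len(aln)
    d = np.zeros((n, n))
    # chunk the row-by-row broadcast to bound memory on large alignments
    step = max(1, 2**24 // (n * N_TM_COLUMNS))
    for i0 in range(0, n, step):
        block = (mat[i0 : i0 + step, None, :] != mat[None, :, :]).sum(axis=2)
        d[i0 : i0 + step] = block / N_TM_COLUMNS
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=aln.ids)


def build_nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining, midpoint-rooted.

    NJ yields an unrooted tree; midpoint rooting makes "the branches
    containing a receptor" well defined for the subfamily window query.
    Deterministic for a fixed input order.
    """
    if dm.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    tree = nj(dm)
    rooted = tree.root_at_midpoint()
    _annotate_counts(rooted)
    return rooted


def _annotate_counts(tree: TreeNode) -> None:
    """Cache the leaf count of every node in ``node.leaf_count``."""
    for node in tree.postorder():
        if node.is_tip():
            node.leaf_count = 1
        else:
            node.leaf_count = sum(c.leaf_count for c in node.children)


def subfamilies_containing(
    tree: TreeNode,
    receptor_id: str,
    min_size: int = 50,
    max_size: int = 300,
) -> list[Subfamily]:
    """Ancestor clades of ``receptor_id`` within the subfamily size window.

    Returned smallest-first; clades covering the whole tree are excluded so the
    out-set (everything else) is never empty and the outside entropy is always
    defined.
    """
    try:
        leaf = tree.find(receptor_id)
    except Exception as exc:  # skbio raises MissingNodeError
        raise KeyError(f"receptor {receptor_id!r} is not a leaf of the tree") from exc
    if not leaf.is_tip():
        raise KeyError(f"{receptor_id!r} names an internal node, not a leaf")

    total = sum(1 for _ in tree.tips())
    out: list[Subfamily] = []
    node = leaf
    while node is not None:
        count = getattr(node, "leaf_count", None)
        if count is None:
            count = sum(1 for _ in node.tips()) if not node.is_tip() else 1
        if min_size <= count <= max_size and count < total:
            members = frozenset(
                t.name for t in (node.tips() if not node.is_tip() else [node])
            )
            out.append(Subfamily(members, count, node))
        node = node.parent
    out.sort(key=lambda s: s.size)
    return out


def read_newick(path: str | Path) -> TreeNode:
    tree = TreeNode.read(str(path), format="newick")
    _annotate_counts(tree)
    return tree


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")
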