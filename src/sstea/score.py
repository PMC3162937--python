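"""ss-TEA scoring: per-position inside/outside entropies and residue ranking.

The working hypothesis: a ligand-binding residue is conserved *within* a
receptor subfamily (low inside entropy E_in) but variable *across* the rest of
the family (high outside entropy E_out), whereas structurally required
residues are conserved everywhere and background positions are variable
everywhere.  Each TM position therefore maps to a point in the (E_in, E_out)
plane; its score is the Euclidean distance, after normalizing both axes by
ln 20, to the corner of perfect inside conservation and maximal outside
variability.  Scores are evaluated on every tree branch holding 50-300
sequences around the query receptor and aggregated; residues are ranked
ascending, rank 1 being the most binding-like.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import entropy as _shannon
from skbio.tree import TreeNode

from .bw import BWPosition, N_TM_COLUMNS, TM_POSITIONS, parse_bw
from .msa import ALPHABET, SYMBOL_CODE, TMAlignment
from .tree import Subfamily, subfamilies_containing

__all__ = [
    "EntropyPair",
    "ResidueScoreTable",
    "MAX_ENTROPY",
    "column_entropy",
    "two_entropy",
    "combined_score",
    "aggregate_branches",
    "score_receptor",
    "score_with_subfamilies",
]

N_AA = len(ALPHABET)
#: Entropy of a uniform 20-letter column, the normalization constant (nats).
MAX_ENTROPY = math.log(N_AA)


@dataclass(frozen=True)
class EntropyPair:
    """Inside/outside Shannon entropies of one column for one subfamily."""

    position: BWPosition
    e_in: float
    e_out: float
    n_in: int
    n_out: int


def column_entropy(column: Iterable[str] | str) -> float:
    """Shannon entropy (nats) of a column over the 20 standard amino acids.

    ``H = -sum_a p_a ln p_a`` with ``p_a`` the frequency of residue type ``a``
    among the countable symbols.  Ambiguity codes are excluded from the counts;
    a column with no countable symbol has no defined entropy.
    """
    counts = np.zeros(N_AA)
    for sym in column:
        code = SYMBOL_CODE.get(sym)
        if code is None:
            raise ValueError(f"invalid amino-acid symbol: {sym!r}")
        if code < N_AA:
            counts[code] += 1
    n = counts.sum()
    if n == 0:
        raise ValueError("column entropy undefined: no countable symbols")
    return float(_shannon(counts))


def _counts_by_column(mat: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """(20, n_cols) standard-residue counts over a row subset."""
    sub = mat[rows]
    ncols = sub.shape[1]
    flat = sub + np.arange(ncols, dtype=np.int64) * 32  # codes < 32
    counts = np.bincount(flat.ravel(), minlength=32 * ncols).reshape(ncols, 32)
    return counts[:, :N_AA].T.astype(float)


def _entropy_per_column(counts: np.ndarray) -> np.ndarray:
    """Columnwise Shannon entropy (nats) from a (20, n_cols) count table."""
    n = counts.sum(axis=0)
    if (n == 0).any():
        raise ValueError("column entropy undefined: no countable symbols")
    p = counts / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return -terms.sum(axis=0)


def two_entropy(
    aln: TMAlignment, subfamily: Subfamily, position: BWPosition
) -> EntropyPair:
    """E_in on subfamily members and E_out on everything else, one position."""
    inside = set(subfamily.members)
    missing = inside - set(aln.ids)
    if missing:
        raise KeyError(f"subfamily members absent from alignment: {sorted(missing)[:3]}")
    outside = [rid for rid in aln.ids if rid not in inside]
    if not outside:
        raise ValueError("empty out-set: subfamily covers the whole alignment")
    col = aln.column(position)
    idx = {rid: i for i, rid in enumerate(aln.ids)}
    col_in = "".join(col[idx[r]] for r in inside)
    col_out = "".join(col[idx[r]] for r in outside)
    return EntropyPair(
        position,
        column_entropy(col_in),
        column_entropy(col_out),
        len(inside),
        len(outside),
    )


def combined_score(
    e: EntropyPair | tuple[float, float],
    corner: tuple[float, float] = (0.0, MAX_ENTROPY),
) -> float:
    """Distance of the (E_in, E_out) point to the binding-like corner.

    Entropies are normalized by ln 20 to [0, 1]; the default corner is perfect
    conservation inside (E_in = 0) and maximal variability outside
    (E_out = ln 20), so ``s = sqrt(e_in_hat^2 + (1 - e_out_hat)^2)`` ranges
    over [0, sqrt(2)] and *lower is more binding-like*.
    """
    if isinstance(e, EntropyPair):
        e_in, e_out = e.e_in, e.e_out
    else:
        e_in, e_out = e
    cx, cy = corner[0] / MAX_ENTROPY, corner[1] / MAX_ENTROPY
    return math.hypot(e_in / MAX_ENTROPY - cx, e_out / MAX_ENTROPY - cy)


Aggregate = Literal["min", "size_weighted_mean"]


def aggregate_branches(
    branch_scores: Mapping[int, float], aggregate: Aggregate = "min"
) -> float:
    """Final per-position score S from the per-branch scores.

    ``min`` (default): a residue is binding-like if *any* well-sized subfamily
    conserves it.  ``size_weighted_mean``: ``S = sum_j j * s_j / sum_j j`` with
    ``j`` the branch size.
    """
    if not branch_scores:
        raise ValueError(
            "no eligible subfamily branch; relax the size window "
            "(min_size/max_size) for this receptor"
        )
    if aggregate == "min":
        return min(branch_scores.values())
    if aggregate == "size_weighted_mean":
        tot = sum(branch_scores)
        return sum(j * s for j, s in branch_scores.items()) / tot
    raise ValueError(f"unknown aggregate mode: {aggregate!r}")


@dataclass
class ResidueScoreTable:
    """Per-position ss-TEA result for one query receptor.

    ``table`` has one row per TM position (all 171) with columns ``position``,
    per-branch ``e_in_<j>``/``e_out_<j>``/``s_<j>``, ``score`` (final S) and
    ``rank`` (1 = most binding-like; ties broken by BW position order).
    """

    receptor_id: str
    subfamily_sizes: list[int]
    table: pd.DataFrame
    aggregate: str = "min"
    corner: str = "theoretical"
    metadata: dict = field(default_factory=dict)

    def ranking(self) -> list[BWPosition]:
        """Positions ordered rank 1 first."""
        ordered = self.table.sort_values("rank")["position"]
        return [parse_bw(p) for p in ordered]

    def rank_of(self, position: BWPosition) -> int:
        row = self.table[self.table["position"] == str(position)]
        return int(row["rank"].iloc[0])

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# receptor={self.receptor_id} aggregate={self.aggregate} "
                     f"corner={self.corner} "
                     f"branches={','.join(map(str, self.subfamily_sizes))}\n")
            self.table.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ResidueScoreTable":
        with open(path) as fh:
            header = fh.readline()
            df = pd.read_csv(fh, sep="\t", dtype={"position": str})
        meta = dict(
            item.split("=", 1) for item in header.lstrip("#").split() if "=" in item
        )
        sizes = [int(x) for x in meta.get("branches", "").split(",") if x]
        return cls(
            meta.get("receptor", ""), sizes, df,
            meta.get("aggregate", "min"), meta.get("corner", "theoretical"),
        )


def score_with_subfamilies(
    aln: TMAlignment,
    subfamilies: Sequence[Subfamily],
    receptor_id: str,
    aggregate: Aggregate = "min",
    corner: Literal["theoretical", "empirical"] = "theoretical",
) -> ResidueScoreTable:
    """Score all 171 positions against an explicit list of subfamilies.

    This is the scoring core; :func:`score_receptor` derives the subfamily
    list from a tree and delegates here.
    """
    if receptor_id not in aln:
        raise KeyError(f"receptor {receptor_id!r} not in alignment")
    if not subfamilies:
        raise ValueError(
            "no eligible subfamily branch; relax the size window "
            "(min_size/max_size) for this receptor"
        )
    mat = aln.matrix
    all_rows = np.arange(len(aln), dtype=np.intp)
    total_counts = _counts_by_column(mat, all_rows)

    branch_cols: dict[int, dict[str, np.ndarray]] = {}
    for sf in subfamilies:
        if receptor_id not in sf.members:
            raise ValueError(f"subfamily of size {sf.size} lacks {receptor_id!r}")
        rows_in = aln.row_indices(sorted(sf.members))
        counts_in = _counts_by_column(mat, rows_in)
        counts_out = total_counts - counts_in
        e_in = _entropy_per_column(counts_in)
        e_out = _entropy_per_column(counts_out)
        if corner == "empirical":
            cx = (e_in.min(), e_out.max())
        else:
            cx = (0.0, MAX_ENTROPY)
        s = np.hypot(
            (e_in - cx[0]) / MAX_ENTROPY, (e_out - cx[1]) / MAX_ENTROPY
        )
        branch_cols[sf.size] = {"e_in": e_in, "e_out": e_out, "s": s}

    sizes = sorted(branch_cols)
    s_matrix = np.vstack([branch_cols[j]["s"] for j in sizes])
    if aggregate == "min":
        final = s_matrix.min(axis=0)
    elif aggregate == "size_weighted_mean":
        w = np.asarray(sizes, dtype=float)
        final = (w[:, None] * s_matrix).sum(axis=0) / w.sum()
    else:
        raise ValueError(f"unknown aggregate mode: {aggregate!r}")

    # ranks ascending in S; ties resolved by BW position order (stable sort
    # over positions already in BW order)
    order = np.argsort(final, kind="stable")
    ranks = np.empty(N_TM_COLUMNS, dtype=int)
    ranks[order] = np.arange(1, N_TM_COLUMNS + 1)

    data: dict[str, object] = {"position": [str(p) for p in TM_POSITIONS]}
    for j in sizes:
        data[f"e_in_{j}"] = branch_cols[j]["e_in"]
        data[f"e_out_{j}"] = branch_cols[j]["e_out"]
        data[f"s_{j}"] = branch_cols[j]["s"]
    data["score"] = final
    data["rank"] = ranks
    return ResidueScoreTable(
        receptor_id, sizes, pd.DataFrame(data), aggregate, corner
    )


def score_receptor(
    aln: TMAlignment,
    tree: TreeNode,
    receptor_id: str,
    min_size: int = 50,
    max_size: int = 300,
    aggregate: Aggregate = "min",
    corner: Literal["theoretical", "empirical"] = "theoretical",
) -> ResidueScoreTable:
    """Rank all TM positions of one receptor by subfamily-specific conservation."""
    subfamilies = subfamilies_containing(tree, receptor_id, min_size, max_size)
    if not subfamilies:
        raise ValueError(
            f"no subfamily of size {min_size}..{max_size} contains "
            f"{receptor_id!r}; relax the size window"
        )
    return score_with_subfamilies(aln, subfamilies, receptor_id, aggregate, corner)
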