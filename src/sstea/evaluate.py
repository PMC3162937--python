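"""pROC AUC performance measure, reference sets and benchmark baselines.

Ranking quality is measured by the area under the ROC curve drawn with a
logarithmic false-positive axis (pROC AUC), which rewards recovering true
ligand-binding residues *early*:

    AUC = (1/n) * sum_i log10(1 / beta_i)

where ``beta_i`` is the fraction of false positives ranked above the i-th true
residue.  ``beta_i`` is clamped below at ``1/n_false`` so a top-ranked true
residue among 100 false ones contributes exactly 2.0; a uniformly random
ranking scores 1/ln 10 ~= 0.434 on average.

The packaged reference set holds literature-curated ligand-binding positions
of 10 class A receptors (47 memberships over 22 distinct BW positions), used
both as ground truth and to build the "theoretically optimal" generic baseline
ranking.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .bw import BWPosition, TM_POSITIONS, parse_bw
from .score import ResidueScoreTable

__all__ = [
    "ProcResult",
    "ReferenceSet",
    "load_reference_sets",
    "proc_auc",
    "theoretical_optimal_ranking",
    "top_rank_transform",
    "evaluate_receptor",
    "read_ranking_tsv",
    "write_ranking_tsv",
]


@dataclass(frozen=True)
class ProcResult:
    """pROC AUC with the per-true-residue false-positive fractions."""

    auc: float
    n_true: int
    n_false: int
    betas: tuple[float, ...]


@dataclass(frozen=True)
class ReferenceSet:
    """Receptor -> set of ligand-binding BW positions."""

    sets: Mapping[str, frozenset[BWPosition]]

    @property
    def receptors(self) -> list[str]:
        return list(self.sets)

    def __getitem__(self, receptor: str) -> frozenset[BWPosition]:
        return self.sets[receptor]

    def __contains__(self, receptor: str) -> bool:
        return receptor in self.sets

    def all_positions(self) -> frozenset[BWPosition]:
        out: set[BWPosition] = set()
        for s in self.sets.values():
            out |= s
        return frozenset(out)

    def total_memberships(self) -> int:
        return sum(len(s) for s in self.sets.values())

    def usage_counts(self) -> dict[BWPosition, int]:
        """How many receptors use each position for ligand binding."""
        counts: dict[BWPosition, int] = {}
        for s in self.sets.values():
            for p in s:
                counts[p] = counts.get(p, 0) + 1
        return counts


def load_reference_sets(path: str | Path | None = None) -> ReferenceSet:
    """Load the packaged mutagenesis-curated reference sets (or a user TSV).

    The TSV has columns ``receptor`` and ``position`` (BW label), one row per
    membership.
    """
    if path is None:
        src = resources.files("sstea").joinpath("data/table1_reference_sets.tsv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p, sep="\t", dtype={"position": str})
    else:
        df = pd.read_csv(path, sep="\t", dtype={"position": str})
    sets: dict[str, set[BWPosition]] = {}
    for _, row in df.iterrows():
        sets.setdefault(str(row["receptor"]), set()).add(parse_bw(str(row["position"])))
    return ReferenceSet({r: frozenset(s) for r, s in sets.items()})


def proc_auc(
    ranking: Sequence[BWPosition], true_set: Iterable[BWPosition]
) -> ProcResult:
    """Semi-logarithmic ROC AUC of a ranking against a true-position set.

    ``ranking`` is rank 1 first.  ``beta_i`` counts only false positives
    strictly above the i-th true positive (other true positives do not count),
    and is clamped below at ``1/n_false`` so the measure stays finite when a
    true residue outranks every false one.
    """
    true_set = set(true_set)
    if not true_set:
        raise ValueError("true set must be non-empty")
    missing = true_set - set(ranking)
    if missing:
        raise ValueError(f"true positions absent from ranking: {sorted(map(str, missing))}")
    n_true = len(true_set)
    n_false = len(ranking) - n_true
    if n_false == 0:
        raise ValueError("ranking holds no false positives")
    betas = []
    fp_above = 0
    for pos in ranking:
        if pos in true_set:
            betas.append(max(fp_above / n_false, 1.0 / n_false))
        else:
            fp_above += 1
    auc = float(np.mean([np.log10(1.0 / b) for b in betas]))
    return ProcResult(auc, n_true, n_false, tuple(betas))


def theoretical_optimal_ranking(
    refsets: ReferenceSet, universe: Sequence[BWPosition] | None = None
) -> list[BWPosition]:
    """Generic baseline: positions ordered by how many receptors use them.

    The reference positions come first, by descending receptor-usage count
    (ties broken by BW position order — an arbitrary choice that can shift
    per-receptor values slightly), followed by the remaining TM positions in
    BW order.
    """
    if not refsets.sets:
        raise ValueError("need at least one receptor reference set")
    universe = list(universe) if universe is not None else list(TM_POSITIONS)
    counts = refsets.usage_counts()
    ref_sorted = sorted(counts, key=lambda p: (-counts[p], p))
    rest = [p for p in universe if p not in counts]
    return ref_sorted + rest


def top_rank_transform(
    ranking: Sequence[BWPosition], prioritized: Iterable[BWPosition]
) -> list[BWPosition]:
    """Stable partition: prioritized positions first, relative order kept."""
    prioritized = set(prioritized)
    missing = prioritized - set(ranking)
    if missing:
        raise ValueError(f"prioritized positions absent from ranking: {sorted(map(str, missing))}")
    top = [p for p in ranking if p in prioritized]
    rest = [p for p in ranking if p not in prioritized]
    return top + rest


def evaluate_receptor(
    scores: ResidueScoreTable | Sequence[BWPosition],
    refsets: ReferenceSet,
    receptor_id: str | None = None,
    top_ranked: bool = False,
) -> ProcResult:
    """pROC AUC of a receptor's residue ranking against its reference set.

    ``scores`` may be a :class:`~sstea.score.ResidueScoreTable` or any
    ready-made ranking (e.g. read from an external method's TSV) — rankings
    are interchangeable.  With ``top_ranked=True`` the union of all reference
    positions (the 22-position pocket knowledge) is stably promoted ahead of
    everything else first.
    """
    if isinstance(scores, ResidueScoreTable):
        receptor = receptor_id or scores.receptor_id
        ranking = scores.ranking()
    else:
        if receptor_id is None:
            raise ValueError("receptor_id is required for a bare ranking")
        receptor = receptor_id
        ranking = list(scores)
    if receptor not in refsets:
        raise KeyError(f"receptor {receptor!r} has no reference set")
    if top_ranked:
        ranking = top_rank_transform(ranking, refsets.all_positions())
    return proc_auc(ranking, refsets[receptor])


def read_ranking_tsv(path: str | Path) -> list[BWPosition]:
    """Read an exchange ranking: TSV with columns ``rank`` and ``position``."""
    df = pd.read_csv(path, sep="\t", dtype={"position": str}).sort_values("rank")
    return [parse_bw(str(p)) for p in df["position"]]


def write_ranking_tsv(ranking: Sequence[BWPosition], path: str | Path) -> None:
    pd.DataFrame(
        {"rank": range(1, len(ranking) + 1), "position": [str(p) for p in ranking]}
    ).to_csv(path, sep="\t", index=False)
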