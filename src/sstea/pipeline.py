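"""Gap-free TM alignment pipeline: placement, order repair and filtering.

Each candidate sequence is scanned independently with the seven helix
profiles.  When the seven best placements are not in helix order, the
highest-scoring strictly increasing, non-overlapping subset of hits is kept as
anchors and every inconsistent helix is realigned constrained to the interval
between its nearest anchors.  Records failing more than 4 of 7 helix
thresholds are discarded; a few genuine receptor families (e.g. the
prostanoids) show weak helix patterns for up to 4 helices, which fixes the
discard threshold.  Near-duplicate records of one species and records from
sparsely sequenced species are removed afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .msa import AlignedRecord, HelixMeta, SequenceRecord, TMAlignment
from .profiles import CalibratedThresholds, HelixHit, HelixProfile, gapfree_align

__all__ = [
    "AlignmentFailure",
    "align_sequence",
    "align_records",
    "filter_failing",
    "dedup_species",
    "filter_species",
    "run_alignment_pipeline",
]

HELICES = (1, 2, 3, 4, 5, 6, 7)


class AlignmentFailure(Exception):
    """No gap-free placement exists for some helix of a record."""


def _consistent(hits: dict[int, HelixHit], lengths: dict[int, int]) -> bool:
    """Offsets strictly increasing and windows non-overlapping in helix order."""
    for h in HELICES[:-1]:
        if hits[h].offset + lengths[h] > hits[h + 1].offset:
            return False
    return True


def _best_anchor_subset(
    hits: dict[int, HelixHit], lengths: dict[int, int], seq_len: int
) -> list[int]:
    """Highest-total-score subset of helices whose hits are in consistent order.

    Weighted longest-increasing-subsequence over the 7 hits, with the extra
    constraint that the gaps around the anchors leave enough room to realign
    every excluded helix gap-free in between; at least one helix is always
    admissible on its own for sequences long enough to hold all 7 windows.
    """

    def room_before(h: int) -> bool:
        return hits[h].offset >= sum(lengths[g] for g in HELICES if g < h)

    def room_after(h: int) -> bool:
        tail = seq_len - (hits[h].offset + lengths[h])
        return tail >= sum(lengths[g] for g in HELICES if g > h)

    def room_between(g: int, h: int) -> bool:
        gap = hits[h].offset - (hits[g].offset + lengths[g])
        return gap >= sum(lengths[k] for k in HELICES if g < k < h)

    best_score: dict[int, float] = {}
    prev: dict[int, int | None] = {}
    for h in HELICES:
        if not (room_before(h) and room_after(h)):
            continue
        best_score[h] = hits[h].score
        prev[h] = None
        for g in HELICES[: h - 1]:
            if g in best_score and room_between(g, h):
                cand = best_score[g] + hits[h].score
                if cand > best_score[h]:
                    best_score[h] = cand
                    prev[h] = g
    if not best_score:
        return []
    end = max(best_score, key=best_score.__getitem__)
    chain: list[int] = []
    node: int | None = end
    while node is not None:
        chain.append(node)
        node = prev[node]
    return chain[::-1]


def align_sequence(
    profiles: dict[int, HelixProfile],
    seq: SequenceRecord,
    thresholds: CalibratedThresholds,
) -> tuple[AlignedRecord, list[HelixMeta]]:
    """Place all 7 helix windows gap-free, repairing out-of-order placements.

    Raises :class:`AlignmentFailure` when some helix cannot be placed even
    after constraining to the interval between its consistent neighbors.
    """
    lengths = {h: profiles[h].length for h in HELICES}
    total = sum(lengths.values())
    if len(seq.sequence) < total:
        raise AlignmentFailure(
            f"{seq.id}: sequence of length {len(seq.sequence)} cannot hold "
            f"{total} TM residues"
        )

    hits = {h: gapfree_align(profiles[h], seq) for h in HELICES}

    if not _consistent(hits, lengths):
        anchors = _best_anchor_subset(hits, lengths, len(seq.sequence))
        if not anchors:
            raise AlignmentFailure(
                f"{seq.id}: no helix hit admits a consistent gap-free layout"
            )
        anchor_set = set(anchors)
        placed: dict[int, HelixHit] = {h: hits[h] for h in anchor_set}
        for h in HELICES:
            if h in anchor_set:
                continue
            left = [g for g in anchor_set if g < h]
            right = [g for g in anchor_set if g > h]
            # lower bound: end of the nearest placed helix to the left
            lo = 0
            for g in range(1, h):
                if g in placed:
                    lo = max(lo, placed[g].offset + lengths[g])
            if right:
                nxt = min(right)
                # reserve room for not-yet-placed helices between h and nxt
                reserved = sum(lengths[g] for g in range(h + 1, nxt) if g not in placed)
                hi = hits[nxt].offset - reserved
            else:
                reserved = sum(lengths[g] for g in range(h + 1, 8) if g not in placed)
                hi = len(seq.sequence) - reserved
            try:
                placed[h] = gapfree_align(profiles[h], seq, search_range=(lo, hi))
            except ValueError as exc:
                raise AlignmentFailure(f"{seq.id}: {exc}") from exc
        hits = placed

    assert _consistent(hits, lengths)
    metas = [
        HelixMeta(h, hits[h].offset, hits[h].score,
                  thresholds.passes(h, hits[h].score))
        for h in HELICES
    ]
    tm = "".join(
        seq.sequence[hits[h].offset : hits[h].offset + lengths[h]] for h in HELICES
    )
    return AlignedRecord(seq.id, seq.species, tm, seq.source), metas


def align_records(
    profiles: dict[int, HelixProfile],
    records: list[SequenceRecord],
    thresholds: CalibratedThresholds,
) -> tuple[TMAlignment, list[tuple[str, str]]]:
    """Align every record; returns the alignment and (id, reason) rejections."""
    aln = TMAlignment([])
    rejected: list[tuple[str, str]] = []
    for rec in records:
        try:
            row, metas = align_sequence(profiles, rec, thresholds)
        except AlignmentFailure as exc:
            rejected.append((rec.id, str(exc)))
            continue
        aln.add_record(row, metas)
    return aln, rejected


def filter_failing(aln: TMAlignment, max_failed_helices: int = 4) -> TMAlignment:
    """Drop records failing the profile threshold for > ``max_failed_helices``."""
    keep = []
    for rec in aln:
        metas = aln.helix_meta.get(rec.id)
        if metas is None:
            raise ValueError(f"record {rec.id} has no helix metadata")
        failed = sum(not m.passed for m in metas)
        if failed <= max_failed_helices:
            keep.append(rec.id)
    return aln.subset(keep)


def dedup_species(aln: TMAlignment, max_diff: int = 10) -> TMAlignment:
    """Collapse per-species near-duplicates (< ``max_diff`` mismatching columns).

    Same-species records differing at fewer than ``max_diff`` aligned TM
    positions are grouped transitively; the lexicographically smallest id of
    each group is kept.  Identical sequences in different species are never
    collapsed.
    """
    by_species: dict[str, list[int]] = {}
    for i, rec in enumerate(aln):
        by_species.setdefault(rec.species, []).append(i)

    mat = aln.matrix
    ids = aln.ids
    keep: list[str] = []
    for rows in by_species.values():
        parent = {i: i for i in rows}

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        sub = mat[rows]
        # pairwise Hamming distances within one species
        diffs = (sub[:, None, :] != sub[None, :, :]).sum(axis=2)
        for a in range(len(rows)):
            for b in range(a + 1, len(rows)):
                if diffs[a, b] < max_diff:
                    ra, rb = find(rows[a]), find(rows[b])
                    if ra != rb:
                        parent[rb] = ra
        groups: dict[int, list[str]] = {}
        for i in rows:
            groups.setdefault(find(i), []).append(ids[i])
        keep.extend(min(members) for members in groups.values())

    order = {rid: i for i, rid in enumerate(ids)}
    return aln.subset(sorted(keep, key=order.__getitem__))


def filter_species(aln: TMAlignment, min_count: int = 100) -> TMAlignment:
    """Keep only records of species with at least ``min_count`` sequences.

    Guards against bias from incompletely sequenced genomes.
    """
    counts: dict[str, int] = {}
    for sp in aln.species:
        counts[sp] = counts.get(sp, 0) + 1
    keep = [r.id for r in aln if counts[r.species] >= min_count]
    return aln.subset(keep)


@dataclass
class PipelineResult:
    alignment: TMAlignment
    rejected: list[tuple[str, str]]
    n_aligned: int
    n_after_quality: int
    n_after_dedup: int
    n_after_species: int


def run_alignment_pipeline(
    profiles: dict[int, HelixProfile],
    records: list[SequenceRecord],
    thresholds: CalibratedThresholds,
    max_failed_helices: int = 4,
    dedup_diff: int = 10,
    species_min: int = 100,
) -> PipelineResult:
    """Full candidate-to-database pipeline: align, quality-filter, dedup, species-filter."""
    aln, rejected = align_records(profiles, records, thresholds)
    n_aligned = len(aln)
    aln = filter_failing(aln, max_failed_helices)
    n_quality = len(aln)
    aln = dedup_species(aln, dedup_diff)
    n_dedup = len(aln)
    aln = filter_species(aln, species_min)
    return PipelineResult(aln, rejected, n_aligned, n_quality, n_dedup, len(aln))
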