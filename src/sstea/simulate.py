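"""Synthetic multi-subfamily MSAs and helix-bearing sequences for testing.

The generator emulates the statistical structure the two-entropy score
assumes: *binding* columns conserved within one subfamily (probability ``c``)
but background-distributed outside it, *structural* columns conserved across
every record, and i.i.d. *background* columns everywhere else.  A separate
generator plants in-order helix windows inside longer sequences (with random
linkers) next to composition-matched shuffled decoys, to exercise the
alignment, calibration and order-repair machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .bw import BWPosition, HELIX_SLICES, N_TM_COLUMNS, POSITION_INDEX, parse_bw
from .msa import ALPHABET, AlignedRecord, SequenceRecord, TMAlignment
from .profiles import HelixProfile

__all__ = [
    "SyntheticSpec",
    "TruthTable",
    "default_spec",
    "generate_msa",
    "generate_helix_sequences",
    "conserved_seed_alignment",
]

N_AA = len(ALPHABET)

#: Uniform null over the 20 standard residues.
UNIFORM_BACKGROUND = np.full(N_AA, 1.0 / N_AA)

#: Swissprot-like amino-acid frequencies (order ACDEFGHIKLMNPQRSTVWY) for a
#: more realistic background preset.
SWISSPROT_BACKGROUND = np.array(
    [0.0825, 0.0137, 0.0546, 0.0672, 0.0386, 0.0707, 0.0227, 0.0591, 0.0580,
     0.0965, 0.0241, 0.0406, 0.0474, 0.0393, 0.0553, 0.0664, 0.0535, 0.0686,
     0.0110, 0.0292]
)
SWISSPROT_BACKGROUND /= SWISSPROT_BACKGROUND.sum()

_DEFAULT_SPECIES = (
    "homo_sapiens", "mus_musculus", "rattus_norvegicus",
    "canis_lupus", "bos_taurus", "gallus_gallus",
)

# Binding columns of the focal subfamily: known pocket positions.
_DEFAULT_BINDING = ("3.28", "3.32", "5.42", "6.55", "7.39")
# Structural columns: the x.50 anchors and similarly family-wide motifs.
_DEFAULT_STRUCTURAL = (
    "1.50", "2.50", "3.49", "3.50", "4.50", "5.50", "6.48", "6.50", "7.49", "7.50",
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions of one synthetic MSA.

    ``binding_positions[k]`` are the columns conserved specifically within
    subfamily ``k``; they must be disjoint from the structural columns.
    ``relatedness`` optionally mixes a per-subfamily ancestral letter into the
    background columns (probability of drawing the ancestral letter), giving
    subfamilies the overall sequence similarity real ortholog clusters have;
    the default 0 keeps background columns i.i.d.
    """

    sizes: tuple[int, ...] = (60,) * 10
    binding_positions: tuple[tuple[BWPosition, ...], ...] = (
        tuple(parse_bw(p) for p in _DEFAULT_BINDING),
    ) + ((),) * 9
    structural_positions: tuple[BWPosition, ...] = tuple(
        parse_bw(p) for p in _DEFAULT_STRUCTURAL
    )
    conservation: float = 0.95
    structural_conservation: float = 0.95
    background: tuple[float, ...] = tuple(float(x) for x in UNIFORM_BACKGROUND)
    relatedness: float = 0.0
    species: tuple[str, ...] = _DEFAULT_SPECIES
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.binding_positions) != len(self.sizes):
            raise ValueError("need one binding-position set per subfamily")
        if any(n < 2 for n in self.sizes):
            raise ValueError("subfamily sizes must be at least 2")
        if not 0 < self.conservation <= 1:
            raise ValueError("conservation must be in (0, 1]")
        structural = set(self.structural_positions)
        for k, planted in enumerate(self.binding_positions):
            overlap = structural & set(planted)
            if overlap:
                raise ValueError(
                    f"subfamily {k}: binding and structural sets overlap: "
                    f"{sorted(map(str, overlap))}"
                )

    @property
    def n_subfamilies(self) -> int:
        return len(self.sizes)

    @property
    def n_records(self) -> int:
        return sum(self.sizes)


def default_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """The canonical test conditions: 10 subfamilies of 60 (600 records), the
    focal subfamily carrying 5 planted binding columns, 10 structural columns,
    conservation 0.95, uniform background."""
    return SyntheticSpec(seed=seed, **overrides)


@dataclass(frozen=True)
class TruthTable:
    """Planted structure of a synthetic MSA."""

    record_subfamily: dict[str, int]
    position_role: dict[BWPosition, str]  # "binding:<k>" | "structural" | "background"

    def subfamily_members(self, k: int) -> frozenset[str]:
        return frozenset(r for r, sf in self.record_subfamily.items() if sf == k)

    def binding_positions(self, k: int) -> frozenset[BWPosition]:
        tag = f"binding:{k}"
        return frozenset(p for p, role in self.position_role.items() if role == tag)


def _draw_with_conserved(
    rng: np.random.Generator,
    n: int,
    letter: int,
    conservation: float,
    background: np.ndarray,
) -> np.ndarray:
    """n draws: the conserved letter w.p. ``conservation``, else background."""
    out = rng.choice(N_AA, size=n, p=background)
    conserved = rng.random(n) < conservation
    out[conserved] = letter
    return out


def generate_msa(spec: SyntheticSpec) -> tuple[TMAlignment, TruthTable]:
    """Generate a gap-free 171-column MSA with the planted structure of ``spec``.

    Deterministic per ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    bg = np.asarray(spec.background, dtype=float)
    bg = bg / bg.sum()
    n_total = spec.n_records

    mat = np.empty((n_total, N_TM_COLUMNS), dtype=np.int64)
    # background columns: i.i.d. background for everyone (optionally mixed
    # with a per-subfamily ancestral letter when relatedness > 0)
    for j in range(N_TM_COLUMNS):
        mat[:, j] = rng.choice(N_AA, size=n_total, p=bg)

    starts = np.concatenate([[0], np.cumsum(spec.sizes)])
    role: dict[BWPosition, str] = {p: "background" for p in POSITION_INDEX}

    if spec.relatedness > 0:
        for k, size in enumerate(spec.sizes):
            anc = rng.choice(N_AA, size=N_TM_COLUMNS, p=bg)
            rows = slice(starts[k], starts[k + 1])
            take = rng.random((size, N_TM_COLUMNS)) < spec.relatedness
            mat[rows] = np.where(take, anc[None, :], mat[rows])

    # structural columns: one letter conserved across ALL records
    for p in spec.structural_positions:
        j = POSITION_INDEX[p]
        letter = int(rng.integers(N_AA))
        mat[:, j] = _draw_with_conserved(
            rng, n_total, letter, spec.structural_conservation, bg
        )
        role[p] = "structural"

    # binding columns: subfamily-specific letter conserved inside only
    for k, planted in enumerate(spec.binding_positions):
        rows = slice(starts[k], starts[k + 1])
        for p in planted:
            j = POSITION_INDEX[p]
            letter = int(rng.integers(N_AA))
            mat[rows, j] = _draw_with_conserved(
                rng, spec.sizes[k], letter, spec.conservation, bg
            )
            role[p] = f"binding:{k}"

    records = []
    record_subfamily: dict[str, int] = {}
    for k, size in enumerate(spec.sizes):
        for i in range(size):
            rid = f"SF{k:02d}_R{i:03d}"
            species = spec.species[i % len(spec.species)]
            seq = "".join(ALPHABET[a] for a in mat[starts[k] + i])
            records.append(AlignedRecord(rid, species, seq, source="synthetic"))
            record_subfamily[rid] = k
    return TMAlignment(records), TruthTable(record_subfamily, role)


def conserved_seed_alignment(
    n: int = 40, mutation_rate: float = 0.2, seed: int = 0
) -> TMAlignment:
    """A conserved synthetic family standing in for a curated seed alignment.

    One random ancestral 171-residue sequence; each record mutates every
    column independently to a uniform letter with probability
    ``mutation_rate``.  Synthetic: emulates the per-column conservation of a
    hand-curated TM seed, not real GPCR sequences.
    """
    rng = np.random.default_rng(seed)
    ancestor = rng.integers(N_AA, size=N_TM_COLUMNS)
    records = []
    for i in range(n):
        mutate = rng.random(N_TM_COLUMNS) < mutation_rate
        row = np.where(mutate, rng.integers(N_AA, size=N_TM_COLUMNS), ancestor)
        seq = "".join(ALPHABET[a] for a in row)
        records.append(
            AlignedRecord(f"SEED_{i:03d}", "homo_sapiens", seq, source="synthetic")
        )
    return TMAlignment(records)


@dataclass(frozen=True)
class HelixSequenceTruth:
    """Ground truth of :func:`generate_helix_sequences`."""

    offsets: dict[str, tuple[int, ...]]  # planted records: 7 helix starts
    decoys: frozenset[str]


def generate_helix_sequences(
    profiles: dict[int, HelixProfile],
    n_planted: int = 10,
    n_decoys: int = 10,
    linker_range: tuple[int, int] = (5, 30),
    identity: float = 0.9,
    seed: int = 0,
) -> tuple[list[SequenceRecord], HelixSequenceTruth]:
    """Sequences with in-order planted helix windows plus shuffled decoys.

    Planted records embed, for each helix, a window drawn from the profile
    consensus (each column keeps the consensus letter with probability
    ``identity``, else uniform) separated by uniform-random linkers whose
    lengths are drawn from ``linker_range`` (inclusive; termini included).
    Decoys are per-record residue-frequency-matched shuffles of planted-style
    sequences.
    """
    if n_planted < 0 or n_decoys < 0 or n_planted + n_decoys < 1:
        raise ValueError("need at least one record")
    rng = np.random.default_rng(seed)
    lo, hi = linker_range
    consensus = {h: profiles[h].consensus() for h in sorted(profiles)}

    def planted_sequence() -> tuple[str, tuple[int, ...]]:
        parts: list[str] = []
        offsets: list[int] = []
        pos = 0
        for h in sorted(consensus):
            linker_len = int(rng.integers(lo, hi + 1))
            linker = "".join(ALPHABET[a] for a in rng.integers(N_AA, size=linker_len))
            parts.append(linker)
            pos += linker_len
            offsets.append(pos)
            cons = consensus[h]
            keep = rng.random(len(cons)) < identity
            window = "".join(
                c if k else ALPHABET[int(rng.integers(N_AA))]
                for c, k in zip(cons, keep)
            )
            parts.append(window)
            pos += len(window)
        tail_len = int(rng.integers(lo, hi + 1))
        parts.append("".join(ALPHABET[a] for a in rng.integers(N_AA, size=tail_len)))
        return "".join(parts), tuple(offsets)

    records: list[SequenceRecord] = []
    offsets: dict[str, tuple[int, ...]] = {}
    for i in range(n_planted):
        seq, offs = planted_sequence()
        rid = f"PLANT_{i:03d}"
        records.append(SequenceRecord(rid, "homo_sapiens", seq, "synthetic"))
        offsets[rid] = offs
    decoys: set[str] = set()
    for i in range(n_decoys):
        seq, _ = planted_sequence()
        arr = np.array(list(seq))
        rng.shuffle(arr)
        rid = f"DECOY_{i:03d}"
        records.append(SequenceRecord(rid, "homo_sapiens", "".join(arr), "synthetic"))
        decoys.add(rid)
    return records, HelixSequenceTruth(offsets, frozenset(decoys))
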