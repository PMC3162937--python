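"""Gap-free TM alignment container and FASTA / metadata I/O.

A :class:`TMAlignment` holds one aligned record per receptor sequence: the
concatenation of the seven helix windows, 171 residues, no gaps.  Records carry
a species tag parsed from the FASTA header (``id|species`` dialect) because the
database-stage filters are keyed on per-species sequence counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .bw import BWPosition, N_TM_COLUMNS, POSITION_INDEX

__all__ = [
    "ALPHABET",
    "AMBIGUITY",
    "SequenceRecord",
    "AlignedRecord",
    "TMAlignment",
    "read_tm_fasta",
    "write_tm_fasta",
    "read_protein_fasta",
    "write_helix_metadata",
    "read_helix_metadata",
]

#: The 20 standard amino acids; the fixed alphabet of every entropy count.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
#: Ambiguity / non-standard codes tolerated in records but excluded from counts.
AMBIGUITY = "XBZJU"
_VALID = set(ALPHABET) | set(AMBIGUITY)

#: Integer code of each symbol; ambiguity codes map to 20.. and are masked out
#: of the 20-letter count tables downstream.
SYMBOL_CODE: dict[str, int] = {a: i for i, a in enumerate(ALPHABET)}
SYMBOL_CODE.update({a: 20 + i for i, a in enumerate(AMBIGUITY)})

_CODE_LUT = np.full(128, -1, dtype=np.int8)
for _a, _c in SYMBOL_CODE.items():
    _CODE_LUT[ord(_a)] = _c
del _a, _c


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a protein string as int8 codes (0..19 standard, 20+ ambiguity)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE_LUT[arr]
    if (codes < 0).any():
        bad = sorted({seq[i] for i in np.nonzero(codes < 0)[0]})
        raise ValueError(f"invalid amino-acid symbol(s): {bad}")
    return codes


@dataclass(frozen=True)
class SequenceRecord:
    """An unaligned candidate protein sequence with provenance."""

    id: str
    species: str
    sequence: str
    source: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("empty record id")
        bad = set(self.sequence) - _VALID
        if bad:
            raise ValueError(f"record {self.id}: invalid symbols {sorted(bad)}")

    @property
    def has_ambiguity(self) -> bool:
        return any(c in AMBIGUITY for c in self.sequence)


@dataclass(frozen=True)
class AlignedRecord:
    """One gap-free row of the TM alignment: exactly 171 residues.

    ``source`` is a provenance tag; it is not part of record identity.
    """

    id: str
    species: str
    seq: str
    source: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if len(self.seq) != N_TM_COLUMNS:
            raise ValueError(
                f"record {self.id}: aligned TM sequence must have "
                f"{N_TM_COLUMNS} residues, got {len(self.seq)}"
            )
        bad = set(self.seq) - _VALID
        if bad:
            raise ValueError(
                f"record {self.id}: invalid symbols {sorted(bad)} "
                "(gaps are not permitted inside helix windows)"
            )


@dataclass
class HelixMeta:
    """Per-record placement of one helix window in the full-length sequence."""

    helix: int
    offset: int
    score: float
    passed: bool


class TMAlignment:
    """Gap-free multiple sequence alignment of the 171 TM columns.

    Column extraction is total: every record maps every
    :class:`~sstea.bw.BWPosition` to exactly one amino-acid symbol.
    Optional per-record per-helix metadata records where each helix window was
    found in the source sequence and whether it passed its profile threshold.
    """

    def __init__(
        self,
        records: Sequence[AlignedRecord],
        helix_meta: Mapping[str, Sequence[HelixMeta]] | None = None,
    ) -> None:
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record ids: {dup}")
        self._records: list[AlignedRecord] = list(records)
        self._index: dict[str, int] = {r.id: i for i, r in enumerate(records)}
        self.helix_meta: dict[str, list[HelixMeta]] = (
            {k: list(v) for k, v in helix_meta.items()} if helix_meta else {}
        )
        self._matrix: np.ndarray | None = None

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[AlignedRecord]:
        return iter(self._records)

    def __getitem__(self, rid: str) -> AlignedRecord:
        return self._records[self._index[rid]]

    def __contains__(self, rid: str) -> bool:
        return rid in self._index

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TMAlignment):
            return NotImplemented
        return self._records == other._records

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self._records]

    @property
    def species(self) -> list[str]:
        return [r.species for r in self._records]

    @property
    def matrix(self) -> np.ndarray:
        """(n_records, 171) int8 code matrix; ambiguity codes are >= 20."""
        if self._matrix is None:
            self._matrix = np.vstack([encode_sequence(r.seq) for r in self._records])
        return self._matrix

    def row_indices(self, rids: Iterable[str]) -> np.ndarray:
        return np.asarray([self._index[r] for r in rids], dtype=np.intp)

    def column(self, position: BWPosition) -> str:
        """All symbols of one alignment column, in record order."""
        j = POSITION_INDEX[position]
        return "".join(r.seq[j] for r in self._records)

    def subset(self, rids: Iterable[str]) -> "TMAlignment":
        keep = list(rids)
        recs = [self[rid] for rid in keep]
        meta = {rid: self.helix_meta[rid] for rid in keep if rid in self.helix_meta}
        return TMAlignment(recs, meta)

    def add_record(self, rec: AlignedRecord, meta: Sequence[HelixMeta] | None = None) -> None:
        if rec.id in self._index:
            raise ValueError(f"duplicate record id: {rec.id}")
        self._index[rec.id] = len(self._records)
        self._records.append(rec)
        if meta is not None:
            self.helix_meta[rec.id] = list(meta)
        self._matrix = None


# -- FASTA I/O --------------------------------------------------------------


def _parse_header(header: str) -> tuple[str, str]:
    """Split an ``id|species`` FASTA header; species may be empty."""
    if "|" in header:
        rid, species = header.split("|", 1)
    else:
        rid, species = header, ""
    rid = rid.strip()
    if not rid:
        raise ValueError(f"unparseable FASTA header: {header!r}")
    return rid, species.strip()


def read_tm_fasta(path: str | Path) -> TMAlignment:
    """Read an aligned TM FASTA (one 171-residue record per receptor)."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        rid, species = _parse_header(rec.description)
        records.append(AlignedRecord(rid, species, str(rec.seq).upper()))
    return TMAlignment(records)


def write_tm_fasta(aln: TMAlignment, path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(r.seq), id=f"{r.id}|{r.species}", description="")
        for r in aln
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_protein_fasta(path: str | Path, source: str = "") -> list[SequenceRecord]:
    """Read unaligned candidate protein sequences (``id|species`` headers)."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        rid, species = _parse_header(rec.description)
        out.append(SequenceRecord(rid, species, str(rec.seq).upper(), source))
    return out


# -- per-helix metadata sidecar ---------------------------------------------


def write_helix_metadata(aln: TMAlignment, path: str | Path) -> None:
    """TSV sidecar with columns id, helix, offset, score, pass."""
    rows = [
        {"id": rid, "helix": m.helix, "offset": m.offset,
         "score": m.score, "pass": int(m.passed)}
        for rid, metas in aln.helix_meta.items()
        for m in metas
    ]
    pd.DataFrame(rows, columns=["id", "helix", "offset", "score", "pass"]).to_csv(
        path, sep="\t", index=False
    )


def read_helix_metadata(path: str | Path) -> dict[str, list[HelixMeta]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[HelixMeta]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["id"]), []).append(
            HelixMeta(int(row["helix"]), int(row["offset"]),
                      float(row["score"]), bool(row["pass"]))
        )
    return out
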