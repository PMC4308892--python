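"""Sequence I/O: FASTA reading/writing, alphabet canonicalization, dedup.

The internal canonical alphabet is DNA (``T``); conversion to RNA happens
only at the duplex/feature boundary. FASTA parsing and writing are delegated
to Biopython.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_CHARS = frozenset("ACGTUN")

_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a canonical-DNA sequence."""
    return seq.translate(_DNA_COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    return seq.replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.replace("U", "T")


@dataclass(frozen=True)
class SmallRNARecord:
    """One candidate small-RNA (or reference) sequence.

    ``sequence`` is stored upper-cased in whichever alphabet the reading
    policy selected (canonical DNA by default).
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def has_ambiguous(self) -> bool:
        """True if the record contains N; such records are excluded from
        feature extraction but kept in their library."""
        return "N" in self.sequence

    def as_rna(self) -> "SmallRNARecord":
        return replace(self, sequence=to_rna(self.sequence))

    def as_dna(self) -> "SmallRNARecord":
        return replace(self, sequence=to_dna(self.sequence))


@dataclass
class SequenceLibrary:
    """Ordered collection of records with unique ids."""

    records: list[SmallRNARecord] = field(default_factory=list)
    source_tag: str = ""
    n_rejected: int = 0

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate record ids in library {self.source_tag!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SmallRNARecord]:
        return iter(self.records)

    def __getitem__(self, key: int | str) -> SmallRNARecord:
        if isinstance(key, str):
            for r in self.records:
                if r.id == key:
                    return r
            raise KeyError(key)
        return self.records[key]

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]


AlphabetPolicy = Literal["dna", "rna", "auto"]


def read_fasta(path: str | Path, alphabet_policy: AlphabetPolicy = "dna") -> SequenceLibrary:
    """Read a FASTA file into a :class:`SequenceLibrary`.

    Records with characters outside ``{A,C,G,T,U,N}`` are rejected with a
    warning; the rejected count is reported on the library. ``alphabet_policy``
    controls canonicalization: ``dna`` maps U->T (the internal canonical
    form), ``rna`` maps T->U, ``auto`` is an alias for ``dna``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records: list[SmallRNARecord] = []
    n_rejected = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not set(seq) <= VALID_CHARS:
            bad = sorted(set(seq) - VALID_CHARS)
            warnings.warn(
                f"record {rec.id!r} rejected: invalid characters {bad}",
                stacklevel=2,
            )
            n_rejected += 1
            continue
        if alphabet_policy == "rna":
            seq = to_rna(seq)
        else:  # dna and auto both canonicalize to DNA
            seq = to_dna(seq)
        records.append(SmallRNARecord(id=rec.id, sequence=seq, description=rec.description))
    if n_rejected:
        warnings.warn(f"{n_rejected} record(s) rejected while reading {path}", stacklevel=2)
    return SequenceLibrary(records=records, source_tag=str(path), n_rejected=n_rejected)


def write_fasta(lib: SequenceLibrary | Iterable[SmallRNARecord], path: str | Path) -> Path:
    """Write records as 60-column-wrapped FASTA. Returns the path written."""
    path = Path(path)
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description or "")
        for r in lib
    ]
    with open(path, "w") as fh:
        SeqIO.write(seqrecs, fh, "fasta")
    return path


def dedupe(
    lib: SequenceLibrary,
    near_duplicates: bool = False,
    max_hamming: int = 2,
) -> SequenceLibrary:
    """Remove redundant records; first occurrence wins.

    Default mode removes exact sequence duplicates. ``near_duplicates=True``
    additionally drops records within ``max_hamming`` substitutions of an
    already-retained record of equal length.
    """
    seen: set[str] = set()
    by_length: dict[int, list[str]] = {}
    kept: list[SmallRNARecord] = []
    for rec in lib:
        if rec.sequence in seen:
            continue
        if near_duplicates:
            close = any(
                _hamming_leq(rec.sequence, other, max_hamming)
                for other in by_length.get(rec.length, ())
            )
            if close:
                continue
        seen.add(rec.sequence)
        by_length.setdefault(rec.length, []).append(rec.sequence)
        kept.append(rec)
    return SequenceLibrary(records=kept, source_tag=lib.source_tag, n_rejected=lib.n_rejected)


def _hamming_leq(a: str, b: str, k: int) -> bool:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > k:
                return False
    return True


#: Column order of the predictions TSV written by the pipeline.
PREDICTION_COLUMNS = (
    "read_id",
    "sequence",
    "length",
    "count",
    "target_id",
    "mismatches",
    "duplex_query",
    "duplex_target",
    "svm_score",
    "label",
)
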