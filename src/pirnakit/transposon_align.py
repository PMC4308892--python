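"""Mismatch-limited (substitutions only) alignment of short queries against
a transposon library.

Uses pigeonhole seeding: a query searched at up to ``k`` mismatches is split
into ``k+1`` disjoint seeds; any qualifying placement must contain at least
one exact seed. Queries too short to carry ``k+1`` seeds of the index's seed
length fall back to a vectorized full scan, so the hit set is always exactly
the brute-force Hamming hit set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np

from .io_formats import SequenceLibrary, SmallRNARecord, reverse_complement

Strand = Literal["+", "-"]

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


@dataclass(frozen=True, order=True)
class TransposonHit:
    """A placement of a query on a target's forward strand.

    ``offset`` is 0-based; the matched span is ``[offset, offset + length)``.
    Reverse-strand hits mean the reverse complement of the query matches the
    target forward sequence over that span.
    """

    target_id: str
    offset: int
    strand: str
    mismatches: int
    query_id: str
    length: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")


class TargetIndex:
    """Exact-seed lookup table over a target library."""

    def __init__(self, targets: SequenceLibrary, seed_length: int):
        if seed_length < 4:
            raise ValueError("seed_length must be >= 4")
        self.seed_length = seed_length
        self.targets = targets
        self.target_seqs: dict[str, str] = {}
        self._encoded: dict[str, np.ndarray] = {}
        self.seeds: dict[str, list[tuple[str, int]]] = {}
        for rec in targets:
            if rec.length < seed_length:
                warnings.warn(
                    f"target {rec.id!r} shorter than seed length {seed_length}; skipped",
                    stacklevel=2,
                )
                continue
            seq = rec.sequence
            self.target_seqs[rec.id] = seq
            self._encoded[rec.id] = _encode(seq)
            for pos in range(len(seq) - seed_length + 1):
                kmer = seq[pos : pos + seed_length]
                self.seeds.setdefault(kmer, []).append((rec.id, pos))

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        """Exact occurrences of a seed-length k-mer as (target_id, position)."""
        if len(kmer) != self.seed_length:
            raise ValueError(f"lookup k-mer must have length {self.seed_length}")
        return self.seeds.get(kmer, [])


def build_index(targets: SequenceLibrary, seed_length: int = 8) -> TargetIndex:
    return TargetIndex(targets, seed_length)


def _hamming(a: str, b: str, limit: int) -> int:
    """Hamming distance with early abort above ``limit`` (returns limit+1)."""
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return mm
    return mm


def _scan_orientation(
    seq: str, index: TargetIndex, max_mismatches: int
) -> list[tuple[str, int, int]]:
    """All (target_id, offset, mismatches) placements of ``seq`` at
    Hamming distance <= max_mismatches, one fixed orientation."""
    L = len(seq)
    n_seeds = max_mismatches + 1
    out: list[tuple[str, int, int]] = []
    if L >= n_seeds * index.seed_length:
        sl = index.seed_length
        candidates: set[tuple[str, int]] = set()
        for i in range(n_seeds):
            start = i * sl
            for tid, pos in index.lookup(seq[start : start + sl]):
                off = pos - start
                if off >= 0 and off + L <= len(index.target_seqs[tid]):
                    candidates.add((tid, off))
        for tid, off in candidates:
            mm = _hamming(seq, index.target_seqs[tid][off : off + L], max_mismatches)
            if mm <= max_mismatches:
                out.append((tid, off, mm))
    else:
        q = _encode(seq)
        for tid, enc in index._encoded.items():
            if len(enc) < L:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(enc, L)
            mms = (windows != q).sum(axis=1)
            for off in np.nonzero(mms <= max_mismatches)[0]:
                out.append((tid, int(off), int(mms[off])))
    return out


def align(
    query: SmallRNARecord,
    index: TargetIndex,
    max_mismatches: int = 3,
    strands: Literal["both", "forward", "reverse"] = "both",
) -> list[TransposonHit]:
    """All placements of the query with Hamming distance <= max_mismatches.

    Substitutions only, no indels. Reverse-strand hits compare the reverse
    complement of the query against the target forward sequence. Queries
    containing N yield no hits. Hits are sorted by
    (target_id, offset, strand) for reproducibility.
    """
    if query.has_ambiguous:
        warnings.warn(f"query {query.id!r} contains N; no hits reported", stacklevel=2)
        return []
    hits: list[TransposonHit] = []
    L = query.length
    if strands in ("both", "forward"):
        for tid, off, mm in _scan_orientation(query.sequence, index, max_mismatches):
            hits.append(TransposonHit(tid, off, "+", mm, query.id, L))
    if strands in ("both", "reverse"):
        rc = reverse_complement(query.sequence)
        for tid, off, mm in _scan_orientation(rc, index, max_mismatches):
            hits.append(TransposonHit(tid, off, "-", mm, query.id, L))
    hits.sort(key=lambda h: (h.target_id, h.offset, h.strand))
    return hits


def partition_mappable(
    queries: SequenceLibrary,
    index: TargetIndex,
    max_mismatches: int = 3,
    strands: Literal["both", "forward", "reverse"] = "both",
) -> tuple[SequenceLibrary, SequenceLibrary]:
    """Split queries into (mappable, unmappable) by >=1 hit."""
    mappable, unmappable = [], []
    for rec in queries:
        if align(rec, index, max_mismatches, strands):
            mappable.append(rec)
        else:
            unmappable.append(rec)
    return (
        SequenceLibrary(mappable, source_tag=queries.source_tag + ":mappable"),
        SequenceLibrary(unmappable, source_tag=queries.source_tag + ":unmappable"),
    )


def hits_to_bed(hits: Iterable[TransposonHit], path: str | Path | None = None) -> str:
    """Render hits as BED6 (target as chrom, mismatches as score)."""
    lines = [
        "\t".join(
            (h.target_id, str(h.offset), str(h.offset + h.length), h.query_id,
             str(h.mismatches), h.strand)
        )
        for h in hits
    ]
    text = "\n".join(lines) + ("\n" if lines else "")
    if path is not None:
        Path(path).write_text(text)
    return text
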