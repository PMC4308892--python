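"""Structure-sequence triplet-element features.

Each width-3 window on the query contributes one count to the element named
by the window's pairing pattern (over ``(`` / ``.``) plus the identity of
the middle nucleotide, giving 8 x 4 = 32 elements. Also provides per-element
F-value discrimination ranking between two labeled classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .duplex import DuplexStructure
from .io_formats import SmallRNARecord, to_rna

#: The 8 pairing-state compositions of three adjacent query nucleotides,
#: in canonical order.
PATTERNS: tuple[str, ...] = ("(((", "((.", "(..", "(.(", ".((", ".(.", "..(", "...")

#: Middle-nucleotide alphabet (RNA).
NUCLEOTIDES: str = "ACGU"


def triplet_alphabet() -> list[str]:
    """The 32 element names in canonical order (patterns x A,C,G,U)."""
    return [p + n for p in PATTERNS for n in NUCLEOTIDES]


_ALPHABET = triplet_alphabet()
_ELEMENT_INDEX = {name: i for i, name in enumerate(_ALPHABET)}


@dataclass(frozen=True)
class TripletVector:
    """32 element frequencies in canonical order."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (32,):
            raise ValueError(f"TripletVector requires 32 values, got shape {v.shape}")
        object.__setattr__(self, "values", v)

    def __getitem__(self, element: str) -> float:
        return float(self.values[_ELEMENT_INDEX[element]])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(_ALPHABET, map(float, self.values)))


def extract(
    structure: DuplexStructure | str,
    query: SmallRNARecord,
    normalize: bool = True,
) -> TripletVector:
    """Triplet-element frequencies for a query given its duplex structure.

    Slides a width-3 window over the query; the window count is L-2. Only
    the query-side pattern and the query sequence matter; the target side of
    the structure is ignored.
    """
    qs = structure.query_struct if isinstance(structure, DuplexStructure) else structure
    seq = to_rna(query.sequence)
    L = len(seq)
    if L < 3:
        raise ValueError("sequence too short for triplet extraction (need >= 3 nt)")
    if len(qs) != L:
        raise ValueError("structure length must equal query length")
    if "N" in seq:
        raise ValueError("sequences containing N are excluded from feature extraction")
    counts = np.zeros(32)
    for i in range(L - 2):
        element = qs[i : i + 3] + seq[i + 1]
        counts[_ELEMENT_INDEX[element]] += 1
    if normalize:
        counts /= L - 2
    return TripletVector(counts)


def feature_matrix(vectors: Iterable[TripletVector]) -> np.ndarray:
    return np.vstack([v.values for v in vectors])


@dataclass(frozen=True)
class FeatureDiscrimination:
    element: str
    f_value: float
    mu_pos: float
    mu_neg: float
    sd_pos: float
    sd_neg: float


def f_values(
    pos: Sequence[TripletVector] | np.ndarray,
    neg: Sequence[TripletVector] | np.ndarray,
) -> list[FeatureDiscrimination]:
    """Rank the 32 elements by F = |mu+ - mu-| / (sd+ + sd-), descending.

    Standard deviations are population (divide by n). A zero denominator
    gives F = 0 when the class means agree and +inf (ranked first) when they
    differ. Ties are broken by canonical element order.
    """
    P = pos if isinstance(pos, np.ndarray) else feature_matrix(pos)
    N = neg if isinstance(neg, np.ndarray) else feature_matrix(neg)
    if P.size == 0 or N.size == 0:
        raise ValueError("both classes must be nonempty")
    mu_p, mu_n = P.mean(axis=0), N.mean(axis=0)
    sd_p, sd_n = P.std(axis=0, ddof=0), N.std(axis=0, ddof=0)
    out = []
    for k, element in enumerate(_ALPHABET):
        denom = sd_p[k] + sd_n[k]
        diff = abs(mu_p[k] - mu_n[k])
        # np.std of a constant column returns ~1e-16, not 0
        if denom <= 1e-12:
            denom = 0.0
        if denom > 0:
            f = diff / denom
        else:
            f = 0.0 if diff == 0 else math.inf
        out.append(
            FeatureDiscrimination(
                element=element,
                f_value=float(f),
                mu_pos=float(mu_p[k]),
                mu_neg=float(mu_n[k]),
                sd_pos=float(sd_p[k]),
                sd_neg=float(sd_n[k]),
            )
        )
    # stable sort preserves canonical order among ties
    out.sort(key=lambda d: -d.f_value)
    return out


def matrix_to_tsv(matrix: np.ndarray, ids: Sequence[str] | None = None) -> str:
    """Dense TSV rendering with the 32-element header."""
    header = "id\t" + "\t".join(_ALPHABET) if ids is not None else "\t".join(_ALPHABET)
    lines = [header]
    for i, row in enumerate(np.atleast_2d(matrix)):
        cells = [f"{x:.6g}" for x in row]
        if ids is not None:
            cells.insert(0, ids[i])
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"
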