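"""Deterministic toy-data generators: transposon libraries, planted
transposon-derived reads, ncRNA pools for negative sampling, and labeled
32-dim feature sets with tunable class separation.

All generators are byte-reproducible from their seed.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

from .classifier import LabeledDataset
from .io_formats import SequenceLibrary, SmallRNARecord, reverse_complement, write_fasta
from .triplet_features import triplet_alphabet

_BASES = np.array(list("ACGT"))

DEFAULT_CLASSES: tuple[str, ...] = ("SINE", "LINE", "LTR", "DNA")

#: Default read-length distribution for planted positives (24-30 nt peak).
DEFAULT_LENGTH_DIST: dict[int, float] = {
    24: 0.08, 25: 0.15, 26: 0.25, 27: 0.22, 28: 0.15, 29: 0.10, 30: 0.05,
}

# Feature-level class separation mimics the observed pattern: fully-paired
# triplets enriched in positives, two-paired-one-unpaired in negatives.
_POS_BOOST_ELEMENTS = ("(((A", "(((C", "(((G", "(((U")
_NEG_BOOST_ELEMENTS = (
    "((.A", "((.C", "((.G", "((.U", ".((A", ".((C", ".((G", ".((U",
)
_DIRICHLET_BASE = 4.0
DEFAULT_SEPARATION = 6.0


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def make_transposons(
    n: int,
    length: int,
    classes: Sequence[str] = DEFAULT_CLASSES,
    seed: int = 0,
) -> SequenceLibrary:
    """n uniform-composition random targets, class labels round-robin."""
    if n <= 0 or length <= 0:
        raise ValueError("n and length must be positive")
    rng = np.random.default_rng(seed)
    records = [
        SmallRNARecord(
            id=f"te_{i:04d}",
            sequence=_random_seq(rng, length),
            description=f"te_{i:04d} class={classes[i % len(classes)]}",
        )
        for i in range(n)
    ]
    return SequenceLibrary(records, source_tag="synthetic-transposons")


def plant_positive_reads(
    transposons: SequenceLibrary,
    n: int,
    length_dist: dict[int, float] | None = None,
    mismatch_rate: float = 0.0,
    five_prime_u_bias: float = 0.0,
    seed: int = 0,
) -> SequenceLibrary:
    """Reads cut from transposons (either strand) with <= 3 substitutions.

    ``mismatch_rate`` is the per-slot probability for up to three planted
    substitutions; a 5'-U edit, when applied, consumes one slot so every
    read stays mappable at <= 3 mismatches.
    """
    if len(transposons) == 0:
        raise ValueError("transposon library is empty")
    dist = length_dist or DEFAULT_LENGTH_DIST
    lengths = np.array(sorted(dist))
    probs = np.array([dist[k] for k in lengths], dtype=float)
    probs /= probs.sum()
    if lengths.max() > max(r.length for r in transposons):
        raise ValueError("requested read length exceeds every target length")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        read_len = int(rng.choice(lengths, p=probs))
        while True:
            te = transposons[int(rng.integers(len(transposons)))]
            if te.length >= read_len:
                break
        start = int(rng.integers(te.length - read_len + 1))
        seq = te.sequence[start : start + read_len]
        if rng.random() < 0.5:
            seq = reverse_complement(seq)
        budget = 3
        bases = list(seq)
        if five_prime_u_bias > 0 and rng.random() < five_prime_u_bias:
            if bases[0] != "T":
                bases[0] = "T"
                budget -= 1
        n_extra = int(rng.binomial(budget, mismatch_rate)) if mismatch_rate > 0 else 0
        if n_extra:
            positions = rng.choice(np.arange(1, read_len), size=n_extra, replace=False)
            for p in positions:
                alternatives = [b for b in "ACGT" if b != bases[p]]
                bases[p] = alternatives[int(rng.integers(3))]
        records.append(SmallRNARecord(id=f"pos_{i:05d}", sequence="".join(bases)))
    return SequenceLibrary(records, source_tag="synthetic-positives")


def make_ncrna_pool(
    transposons: SequenceLibrary,
    n: int = 50,
    length_range: tuple[int, int] = (150, 400),
    te_insert_prob: float = 0.7,
    seed: int = 0,
) -> SequenceLibrary:
    """Random 'ncRNA' sequences, most carrying an embedded transposon
    fragment so that 20-30 nt subfragments can pass a mappability filter."""
    if len(transposons) == 0:
        raise ValueError("transposon library is empty")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = list(_random_seq(rng, length))
        if rng.random() < te_insert_prob:
            te = transposons[int(rng.integers(len(transposons)))]
            ins_len = int(rng.integers(40, min(90, te.length, length) + 1))
            te_start = int(rng.integers(te.length - ins_len + 1))
            frag = te.sequence[te_start : te_start + ins_len]
            at = int(rng.integers(length - ins_len + 1))
            seq[at : at + ins_len] = list(frag)
        records.append(SmallRNARecord(id=f"ncrna_{i:05d}", sequence="".join(seq)))
    return SequenceLibrary(records, source_tag="synthetic-ncrna-pool")


def make_labeled_features(
    n_pos: int,
    n_neg: int,
    separation: float = DEFAULT_SEPARATION,
    seed: int = 0,
) -> LabeledDataset:
    """Dirichlet-distributed 32-dim frequency rows whose class mean profiles
    differ by ``separation`` along the boosted elements; rows sum to 1.
    At separation 0 the classes are exchangeable."""
    if separation < 0:
        raise ValueError("separation must be >= 0")
    rng = np.random.default_rng(seed)
    names = triplet_alphabet()
    idx = {name: k for k, name in enumerate(names)}
    alpha_pos = np.full(32, _DIRICHLET_BASE)
    alpha_neg = np.full(32, _DIRICHLET_BASE)
    for el in _POS_BOOST_ELEMENTS:
        alpha_pos[idx[el]] += separation
    for el in _NEG_BOOST_ELEMENTS:
        alpha_neg[idx[el]] += separation / 2.0
    X = np.vstack(
        [rng.dirichlet(alpha_pos, size=n_pos), rng.dirichlet(alpha_neg, size=n_neg)]
    )
    y = np.concatenate([np.ones(n_pos, int), -np.ones(n_neg, int)])
    ids = [f"pos_{i:05d}" for i in range(n_pos)] + [f"neg_{i:05d}" for i in range(n_neg)]
    return LabeledDataset(X, y, ids)


def write_fixture_set(
    out_dir: str | Path,
    seed: int = 42,
    n_transposons: int = 20,
    transposon_length: int = 500,
    n_positives: int = 150,
    n_pool: int = 60,
) -> dict[str, Path]:
    """Write transposons.fa, positives.fa, pool.fa and classes.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    transposons = make_transposons(n_transposons, transposon_length, seed=seed)
    positives = plant_positive_reads(
        transposons, n_positives, mismatch_rate=0.15, five_prime_u_bias=0.8,
        seed=seed + 1,
    )
    pool = make_ncrna_pool(transposons, n=n_pool, seed=seed + 2)
    paths = {
        "transposons": write_fasta(transposons, out / "transposons.fa"),
        "positives": write_fasta(positives, out / "positives.fa"),
        "pool": write_fasta(pool, out / "pool.fa"),
    }
    class_lines = [
        f"{rec.id}\t{rec.description.split('class=')[1].split()[0]}"
        for rec in transposons
    ]
    classes_path = out / "classes.tsv"
    classes_path.write_text("\n".join(class_lines) + "\n")
    paths["classes"] = classes_path
    return paths
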