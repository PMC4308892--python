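"""Pseudo-piRNA negative-set construction.

Double randomization (random pool sequence, then a random 20-30 nt
fragment), followed by exclusion of known positives, a transposon
mappability filter, exact-sequence deduplication, and bin-exact matching of
the positive length distribution via largest-remainder quotas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_formats import SequenceLibrary, SmallRNARecord
from .transposon_align import TargetIndex, align

MIN_LEN, MAX_LEN = 20, 30


@dataclass
class LengthDistribution:
    """Normalized length histogram with support in [20, 30] nt."""

    probabilities: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.probabilities.values())
        if total <= 0:
            raise ValueError("length distribution must have positive mass")
        self.probabilities = {
            k: v / total for k, v in sorted(self.probabilities.items()) if v > 0
        }
        bad = [k for k in self.probabilities if not MIN_LEN <= k <= MAX_LEN]
        if bad:
            raise ValueError(f"length distribution support outside [20, 30]: {bad}")

    def quotas(self, n: int) -> dict[int, int]:
        """Integer per-length quotas summing to n (largest-remainder rounding)."""
        raw = {k: p * n for k, p in self.probabilities.items()}
        base = {k: int(v) for k, v in raw.items()}
        short = n - sum(base.values())
        # distribute the remainder to the largest fractional parts; ties by length
        order = sorted(raw, key=lambda k: (-(raw[k] - base[k]), k))
        for k in order[:short]:
            base[k] += 1
        return base


def length_distribution(lib: SequenceLibrary) -> LengthDistribution:
    """Empirical length distribution of a library, restricted to 20-30 nt."""
    if len(lib) == 0:
        raise ValueError("cannot compute a length distribution of an empty library")
    counts: dict[int, int] = {}
    n_outside = 0
    for rec in lib:
        if MIN_LEN <= rec.length <= MAX_LEN:
            counts[rec.length] = counts.get(rec.length, 0) + 1
        else:
            n_outside += 1
    if n_outside:
        warnings.warn(
            f"{n_outside} record(s) outside [20, 30] nt ignored in length distribution",
            stacklevel=2,
        )
    if not counts:
        raise ValueError("no records within [20, 30] nt")
    return LengthDistribution({k: float(v) for k, v in counts.items()})


def generate_pseudo(
    pool: SequenceLibrary,
    exclusions: SequenceLibrary,
    index: TargetIndex,
    n: int,
    target_dist: LengthDistribution,
    max_mismatches: int = 3,
    seed: int = 0,
    max_attempts: int | None = None,
) -> SequenceLibrary:
    """Sample up to ``n`` pseudo sequences reproducibly from ``seed``.

    Fragments identical to an exclusion sequence are discarded; surviving
    fragments must map to the transposon index with <= max_mismatches and
    are deduplicated by exact sequence. Per-length output counts follow
    ``target_dist`` quotas exactly where fillable; unfillable bins trigger a
    warning and a smaller library.
    """
    excluded = set(exclusions.sequences())
    usable = [r.sequence for r in pool if r.length >= MIN_LEN and r.sequence not in excluded]
    if not usable:
        raise ValueError("pool is empty after exclusion removal")
    rng = np.random.default_rng(seed)
    quotas = target_dist.quotas(n)
    remaining = dict(quotas)
    if max_attempts is None:
        max_attempts = max(200 * n, 20_000)
    seen: set[str] = set()
    kept: list[SmallRNARecord] = []
    attempts = 0
    while attempts < max_attempts and any(v > 0 for v in remaining.values()):
        attempts += 1
        src = usable[rng.integers(len(usable))]
        frag_len = int(rng.integers(MIN_LEN, MAX_LEN + 1))
        if len(src) < frag_len:
            continue
        start = int(rng.integers(len(src) - frag_len + 1))
        frag = src[start : start + frag_len]
        if remaining.get(frag_len, 0) <= 0:
            continue
        if frag in seen or frag in excluded or "N" in frag:
            continue
        seen.add(frag)
        rec = SmallRNARecord(id=f"pseudo_{len(kept):06d}", sequence=frag)
        if not align(rec, index, max_mismatches=max_mismatches):
            continue
        kept.append(rec)
        remaining[frag_len] -= 1
    unfilled = {k: v for k, v in remaining.items() if v > 0}
    if unfilled:
        warnings.warn(
            f"could not fill length quotas {unfilled}; returning {len(kept)} of {n}",
            stacklevel=2,
        )
    if not kept:
        warnings.warn("no pool fragment passed the mappability filter", stacklevel=2)
    return SequenceLibrary(kept, source_tag="pseudo")
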