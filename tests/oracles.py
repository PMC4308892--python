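"""Independent brute-force oracles used to check the package's fast paths.

These deliberately avoid the implementation's algorithms: the alignment
oracle is a full-window Hamming scan, the duplex oracle is an exhaustive
enumeration of antiparallel non-crossing matchings, and the feature oracle
is direct window counting.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def brute_force_hits(
    query: str, targets: dict[str, str], max_mismatches: int, strands: str = "both"
) -> set[tuple[str, int, str, int]]:
    """All (target_id, offset, strand, mismatches) placements by full scan."""
    out = set()
    orientations = []
    if strands in ("both", "forward"):
        orientations.append((query, "+"))
    if strands in ("both", "reverse"):
        orientations.append((revcomp(query), "-"))
    L = len(query)
    q_arrays = {s: np.frombuffer(seq.encode(), dtype=np.uint8) for seq, s in orientations}
    for tid, tseq in targets.items():
        if len(tseq) < L:
            continue
        t = np.frombuffer(tseq.encode(), dtype=np.uint8)
        windows = np.lib.stride_tricks.sliding_window_view(t, L)
        for (seq, strand) in orientations:
            mms = (windows != q_arrays[strand]).sum(axis=1)
            for off in np.nonzero(mms <= max_mismatches)[0]:
                out.add((tid, int(off), strand, int(mms[off])))
    return out


# same scoring constants as the implementation's contract
_PAIRS = {("G", "C"): 3, ("C", "G"): 3, ("A", "U"): 2, ("U", "A"): 2,
          ("G", "U"): 1, ("U", "G"): 1}


def exhaustive_duplex(q: str, w: str) -> tuple[float, set[int]]:
    """Enumerate every antiparallel non-crossing WC/wobble matching of RNA
    strings q and w; return (max score, set of pair counts achieving it).

    A matching is a set of pairs (i, j) where the i's increase while the
    j's strictly decrease; score = sum of pair scores + 1 per stacked pair
    ((i, j) and (i+1, j-1) both present).
    """
    n, m = len(q), len(w)
    best = {"score": 0.0, "counts": {0}}

    def rec(start_i: int, max_j: int, prev: tuple[int, int] | None,
            score: float, npairs: int) -> None:
        if score > best["score"]:
            best["score"] = score
            best["counts"] = {npairs}
        elif score == best["score"]:
            best["counts"].add(npairs)
        for i in range(start_i, n):
            for j in range(max_j):
                s = _PAIRS.get((q[i], w[j]))
                if s is None:
                    continue
                bonus = 1 if prev is not None and i == prev[0] + 1 and j == prev[1] - 1 else 0
                rec(i + 1, j, (i, j), score + s + bonus, npairs + 1)

    rec(0, m, None, 0.0, 0)
    return best["score"], best["counts"]


def score_pairing(q: str, w: str, pairs) -> float:
    """Independent rescoring of a concrete pair list (validity checked)."""
    pairs = sorted(pairs)
    score = 0.0
    prev = None
    for i, j in pairs:
        assert (q[i], w[j]) in _PAIRS, f"invalid pair {q[i]}-{w[j]}"
        if prev is not None:
            assert i > prev[0] and j < prev[1], "crossing or parallel pairs"
        score += _PAIRS[(q[i], w[j])]
        if prev is not None and i == prev[0] + 1 and j == prev[1] - 1:
            score += 1
        prev = (i, j)
    return score


def count_triplets(query_struct: str, rna_seq: str) -> dict[str, float]:
    """Window counts by direct iteration, normalized by window count."""
    L = len(rna_seq)
    counts: dict[str, float] = {}
    for i in range(L - 2):
        key = query_struct[i : i + 3] + rna_seq[i + 1]
        counts[key] = counts.get(key, 0) + 1
    return {k: v / (L - 2) for k, v in counts.items()}


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGU"))[rng.integers(0, 4, size=length)])
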