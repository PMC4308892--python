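"""Intermolecular RNA-RNA duplex prediction between a query and the
transcript-sense window it targets.

The engine is a deterministic dynamic program over non-crossing antiparallel
base pairings: Watson-Crick pairs score GC=3, AU=2, G.U wobble 1, with a +1
bonus for each stacked (adjacent) pair. Energy is the negative of the score
in arbitrary units; only its ordering is used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .io_formats import (
    SequenceLibrary,
    SmallRNARecord,
    reverse_complement,
    to_rna,
)
from .transposon_align import TransposonHit

PAIR_SCORES: dict[frozenset, float] = {
    frozenset(("G", "C")): 3.0,
    frozenset(("A", "U")): 2.0,
    frozenset(("G", "U")): 1.0,
}
STACK_BONUS = 1.0

_NEG_INF = float("-inf")


def pair_score(a: str, b: str, allow_wobble: bool = True) -> float:
    """Score of pairing nucleotides a and b (RNA alphabet); 0 if unpairable."""
    key = frozenset((a, b))
    score = PAIR_SCORES.get(key, 0.0)
    if not allow_wobble and key == frozenset(("G", "U")):
        return 0.0
    return score


@dataclass(frozen=True)
class DuplexStructure:
    """Dot-bracket description of a predicted query-target duplex.

    ``pairs`` holds 0-based (query_pos, target_pos) pairs; the duplex is
    antiparallel, so pairs are non-crossing with query positions increasing
    while target positions decrease.
    """

    query_struct: str
    target_struct: str
    energy: float
    pairs: tuple[tuple[int, int], ...]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def to_text(self, query: SmallRNARecord, window: SmallRNARecord) -> str:
        """Three-block serialization: query, window, energy."""
        return (
            f"{to_rna(query.sequence)}\n{self.query_struct}\n"
            f"{to_rna(window.sequence)}\n{self.target_struct}\n"
            f"energy\t{self.energy:.2f}\n"
        )


def target_window(
    hit: TransposonHit, targets: SequenceLibrary, flank: int = 0
) -> SmallRNARecord:
    """The transcript-sense RNA sequence the query would base-pair with.

    For a forward-strand hit the query matches the target span directly, so
    it pairs with the reverse complement of that span; for a reverse-strand
    hit the query already is the span's reverse complement and pairs with
    the span itself. Flanks are clipped at target ends.
    """
    target = targets[hit.target_id]
    lo = hit.offset - flank
    hi = hit.offset + hit.length + flank
    if hit.offset < 0 or hit.offset + hit.length > target.length:
        raise ValueError(
            f"hit {hit.query_id!r} out of bounds on target {hit.target_id!r}"
        )
    lo = max(lo, 0)
    hi = min(hi, target.length)
    span = target.sequence[lo:hi]
    if hit.strand == "+":
        window = reverse_complement(span)
    else:
        window = span
    return SmallRNARecord(
        id=f"{hit.target_id}:{lo}-{hi}({hit.strand})",
        sequence=to_rna(window),
    )


def predict_duplex(
    query: SmallRNARecord,
    window: SmallRNARecord,
    allow_wobble: bool = True,
) -> DuplexStructure:
    """Optimal non-crossing antiparallel duplex between query and window.

    Deterministic for fixed inputs: DP ties are broken by a fixed preference
    (pair > skip query base > skip window base).
    """
    q = to_rna(query.sequence)
    w = to_rna(window.sequence)
    if "N" in q or "N" in w:
        raise ValueError("sequences containing N cannot be folded into a duplex")
    if len(q) < 4 or len(w) < 4:
        raise ValueError("duplex prediction requires both sequences >= 4 nt")

    # Antiparallel pairing (i1<i2 => j1>j2) becomes a monotone matching
    # against the reversed window, with stacking on the DP diagonal.
    wr = w[::-1]
    n, m = len(q), len(wr)
    # dp[s][i][j]: best score over q[:i], wr[:j]; s=1 iff (i-1, j-1) paired.
    dp = [[[0.0] * (m + 1) for _ in range(n + 1)] for _ in range(2)]
    for j in range(m + 1):
        dp[1][0][j] = _NEG_INF
    for i in range(n + 1):
        dp[1][i][0] = _NEG_INF
    # choice[i][j]: 0=pair-from-unstacked, 1=pair-stacked, 2=skip q, 3=skip w
    choice = [[[-1] * (m + 1) for _ in range(n + 1)] for _ in range(2)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            ps = pair_score(q[i - 1], wr[j - 1], allow_wobble)
            # paired state
            best1, ch1 = _NEG_INF, -1
            if ps > 0:
                stacked = dp[1][i - 1][j - 1] + ps + STACK_BONUS
                fresh = dp[0][i - 1][j - 1] + ps
                if stacked >= fresh:
                    best1, ch1 = stacked, 1
                else:
                    best1, ch1 = fresh, 0
            dp[1][i][j] = best1
            choice[1][i][j] = ch1
            # unpaired state: drop one residue from either side
            skip_q = max(dp[0][i - 1][j], dp[1][i - 1][j])
            skip_w = max(dp[0][i][j - 1], dp[1][i][j - 1])
            if skip_q >= skip_w:
                dp[0][i][j] = skip_q
                choice[0][i][j] = 2
            else:
                dp[0][i][j] = skip_w
                choice[0][i][j] = 3

    s = 1 if dp[1][n][m] > dp[0][n][m] else 0
    score = dp[s][n][m]
    pairs: list[tuple[int, int]] = []
    i, j = n, m
    while i > 0 and j > 0:
        ch = choice[s][i][j]
        if s == 1:
            pairs.append((i - 1, m - j))  # back to original window coords
            s = ch  # 1 if previous diagonal cell was paired too
            i, j = i - 1, j - 1
        elif ch == 2:
            s = 1 if dp[1][i - 1][j] >= dp[0][i - 1][j] else 0
            i -= 1
        else:
            s = 1 if dp[1][i][j - 1] >= dp[0][i][j - 1] else 0
            j -= 1
    pairs.reverse()

    q_struct = ["."] * n
    t_struct = ["."] * len(w)
    for qi, tj in pairs:
        q_struct[qi] = "("
        t_struct[tj] = ")"
    return DuplexStructure(
        query_struct="".join(q_struct),
        target_struct="".join(t_struct),
        energy=-score,
        pairs=tuple(pairs),
    )


def best_duplex(
    query: SmallRNARecord,
    hits: list[TransposonHit],
    targets: SequenceLibrary,
    flank: int = 0,
    allow_wobble: bool = True,
) -> tuple[TransposonHit, DuplexStructure]:
    """Select the hit to fold against: fewest mismatches, then lowest duplex
    energy, then lexicographic (target_id, offset, strand) order."""
    if not hits:
        raise ValueError(f"query {query.id!r} is not transposon-associated (no hits)")
    scored = []
    for hit in hits:
        window = target_window(hit, targets, flank=flank)
        duplex = predict_duplex(query, window, allow_wobble=allow_wobble)
        scored.append(
            ((hit.mismatches, duplex.energy, hit.target_id, hit.offset, hit.strand),
             hit, duplex)
        )
    scored.sort(key=lambda t: t[0])
    _, hit, duplex = scored[0]
    return hit, duplex
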