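"""End-to-end prediction on small-RNA FASTA input and summary analyses."""

from __future__ import annotations

import warnings
from collections import Counter
from pathlib import Path

import pandas as pd

from .classifier import TrainedModel
from .duplex import best_duplex
from .io_formats import PREDICTION_COLUMNS, SequenceLibrary, dedupe, read_fasta
from .transposon_align import TargetIndex, TransposonHit, align, build_index
from .triplet_features import extract

UNMAPPABLE_LABEL = "not_transposon_associated"


def predict_pipeline(
    reads: str | Path | SequenceLibrary,
    transposons: str | Path | SequenceLibrary,
    model: TrainedModel,
    max_mismatches: int = 3,
    out: str | Path | None = None,
    seed_length: int = 8,
) -> pd.DataFrame:
    """Dedupe -> align -> best duplex -> triplet features -> SVM label.

    One output row per unique read; unmappable reads (and reads containing
    N) are kept with label ``not_transposon_associated``. ``count`` is the
    pre-dedup multiplicity of the read sequence.
    """
    read_lib = reads if isinstance(reads, SequenceLibrary) else read_fasta(reads)
    te_lib = (
        transposons
        if isinstance(transposons, SequenceLibrary)
        else read_fasta(transposons)
    )
    multiplicity = Counter(r.sequence for r in read_lib)
    unique = dedupe(read_lib)
    index = build_index(te_lib, seed_length=seed_length)
    rows = []
    for rec in unique:
        base = {
            "read_id": rec.id,
            "sequence": rec.sequence,
            "length": rec.length,
            "count": multiplicity[rec.sequence],
        }
        hits = [] if rec.has_ambiguous else align(rec, index, max_mismatches)
        if not hits or rec.length < 3:
            rows.append(
                base | {
                    "target_id": "NA", "mismatches": "NA",
                    "duplex_query": "NA", "duplex_target": "NA",
                    "svm_score": "NA", "label": UNMAPPABLE_LABEL,
                }
            )
            continue
        hit, duplex = best_duplex(rec, hits, te_lib)
        vector = extract(duplex, rec)
        labels, scores = model.predict(vector.values.reshape(1, -1))
        rows.append(
            base | {
                "target_id": hit.target_id,
                "mismatches": hit.mismatches,
                "duplex_query": duplex.query_struct,
                "duplex_target": duplex.target_struct,
                "svm_score": float(scores[0]),
                "label": int(labels[0]),
            }
        )
    frame = pd.DataFrame(rows, columns=list(PREDICTION_COLUMNS))
    if out is not None:
        frame.to_csv(out, sep="\t", index=False)
    return frame


def length_histogram(
    source: SequenceLibrary | pd.DataFrame,
    lo: int = 18,
    hi: int = 35,
    normalize: bool = False,
) -> dict[int, float]:
    """Per-length counts over [lo, hi]; lengths outside the range are still
    counted under their own key so totals are conserved."""
    if isinstance(source, pd.DataFrame):
        if len(source) == 0:
            raise ValueError("empty predictions")
        lengths = [int(x) for x in source["length"]]
    else:
        if len(source) == 0:
            raise ValueError("empty library")
        lengths = [r.length for r in source]
    counts: dict[int, float] = {k: 0 for k in range(lo, hi + 1)}
    for L in lengths:
        counts[L] = counts.get(L, 0) + 1
    if normalize:
        total = sum(counts.values())
        counts = {k: v / total for k, v in counts.items()}
    return counts


def target_class_percentages(
    hits: list[TransposonHit], class_map: dict[str, str]
) -> dict[str, float]:
    """Percentage of reads whose best hit falls in each transposon class.

    Each hit is assumed to be one read's selected best hit. Unknown targets
    count as 'other' with a warning. Percentages sum to 100.
    """
    if not hits:
        raise ValueError("no hits to summarize")
    tally: Counter[str] = Counter()
    n_unknown = 0
    for h in hits:
        cls = class_map.get(h.target_id)
        if cls is None:
            cls = "other"
            n_unknown += 1
        tally[cls] += 1
    if n_unknown:
        warnings.warn(
            f"{n_unknown} hit(s) on targets missing from the class map -> 'other'",
            stacklevel=2,
        )
    total = sum(tally.values())
    return {cls: 100.0 * n / total for cls, n in sorted(tally.items())}


def read_class_map(path: str | Path) -> dict[str, str]:
    """Sidecar TSV of target_id<TAB>class."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        tid, cls = line.split("\t")[:2]
        out[tid] = cls
    return out


def class_map_from_headers(lib: SequenceLibrary) -> dict[str, str]:
    """Parse ``class=NAME`` tokens from FASTA descriptions."""
    out: dict[str, str] = {}
    for rec in lib:
        if "class=" in rec.description:
            out[rec.id] = rec.description.split("class=")[1].split()[0]
    return out
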