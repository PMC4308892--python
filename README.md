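# pirnakit

Transposon-interaction-based classification of small RNAs (piRNA
prediction). Candidate reads are aligned to a transposon library with at
most three substitutions, the intermolecular RNA–RNA duplex against the
best hit is predicted, 32 structure–sequence triplet-element frequencies
are extracted from the duplex, and an RBF-kernel SVM separates real from
pseudo piRNAs. The package also ships the pseudo-piRNA negative-set
generator (double randomization + mappability filter + length matching),
the 7/2/1 stratified ten-fold cross-validation scheme with (C, γ) grid
search, Se/Sp/Pre/ACC evaluation, ROC/AUC, F-value feature ranking, and
deterministic synthetic-fixture generators.

## Layout

| module | role |
|---|---|
| `pirnakit.io_formats` | FASTA I/O (Biopython), alphabet canonicalization, dedup |
| `pirnakit.transposon_align` | pigeonhole-seeded, mismatch-limited alignment (substitutions only) |
| `pirnakit.duplex` | DP intermolecular duplex (dot-bracket, GC=3/AU=2/GU=1 + stacking) |
| `pirnakit.triplet_features` | 32 triplet elements, extraction, F-value ranking |
| `pirnakit.negative_generator` | pseudo-piRNA sampling with quota length matching |
| `pirnakit.classifier` | stratified partitions, grid search, SVM train/predict/evaluate/CV/ROC |
| `pirnakit.pipeline` | end-to-end prediction TSV, length histogram, target-class percentages |
| `pirnakit.synthetic_fixtures` | seed-reproducible toy transposons, reads, pools, labeled features |

## CLI

```sh
pirnakit make-fixtures --out-dir fixtures/ --seed 42
pirnakit generate-negatives --pool fixtures/pool.fa --exclude fixtures/positives.fa \
    --transposons fixtures/transposons.fa --n 100 \
    --match-lengths fixtures/positives.fa --seed 42 --out pseudo.fa
pirnakit train --pos fixtures/positives.fa --neg pseudo.fa \
    --transposons fixtures/transposons.fa --seed 42 \
    --out model.json --report cv_report.tsv
pirnakit predict --model model.json --reads fixtures/positives.fa \
    --transposons fixtures/transposons.fa --out predictions.tsv
pirnakit summarize --predictions predictions.tsv \
    --transposons fixtures/transposons.fa --lengths lengths.tsv
```

`train` accepts `--c-grid`/`--gamma-grid` as comma-separated values; the
default is the conventional exponential grid (C = 2⁻⁵…2¹⁵, γ = 2⁻¹⁵…2³,
steps of 2²), which is sizeable — pass a reduced grid for quick runs.

## Notes

- Internal canonical alphabet is DNA (T); RNA appears only at the
  duplex/feature boundary.
- The duplex engine is a self-contained deterministic DP over antiparallel
  non-crossing pairings; its optimality is cross-checked in the tests
  against exhaustive enumeration.
- All randomness flows from explicit seeds; same seed + inputs give
  byte-identical outputs end to end.
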