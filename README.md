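# zdnascan

Detection of potential Z-DNA-forming sequences in DNA. Every dinucleotide
step of an input sequence is scored with transition weights — alternating
purine/pyrimidine steps (GC/CG, GT/TG, AC/CA, AT/TA) score positively,
runs of AT/TA steps receive position-dependent adjustments (long runs favor
hairpins over Z-DNA and are penalized), and non-alternating "mismatch"
steps incur escalating penalties. Maximal-scoring contiguous regions are
then extracted and those at or above a threshold (default 50) are reported.

## Command line

```bash
zdnascan --fasta input.fa --output hits.csv
```

Input is multi-record FASTA, plain or gzip. Output is CSV with columns
`Sequence_name,Start,End,Z-DNA_Score,Sequence`; **Start/End are 0-based
nucleotide indices with an inclusive end** (also stated in a leading `#`
comment of every output file).

Useful flags (defaults in brackets):

- `--threshold` [50] — minimum region score to report
- `--gc-weight` [7], `--gt-weight` [1.25], `--ac-weight` [1.25],
  `--at-weight` [0.5] — per-step-class weights
- `--at-adjustments` [0.5,0.5,0.5,0,0,-5,-100] — adjustments added to the
  AT weight for the 1st, 2nd, ... step of a contiguous AT/TA run; the last
  element repeats for longer runs
- `--mismatch-start` [3], `--mismatch-delta` [3],
  `--mismatch-type` [linear] — penalty for the k-th step of a contiguous
  mismatch run: `start + (k-1)*delta` (linear) or `start*delta^(k-1)`
  (exponential)
- `--report-best` — when a record has no region passing the threshold,
  report its single best region anyway
- `--n-jobs N` — scan records in N worker processes (output bytes are
  identical regardless of N)
- `--plots` — also write a score-vs-length scatter and a score boxplot
- `--config FILE` — YAML/JSON scoring parameters; explicit CLI flags win

Exit codes: 0 success, 1 usage/config error, 2 input parse failure,
3 partial failure (some records skipped).

A second entry point writes deterministic repeat-motif FASTA fixtures for
testing:

```bash
zdnascan-fixtures --unit GC --copies 5 --flank 100 --flank-mode poly_a --seed 7 --out fixtures.fa
```

## Python API

```python
from zdnascan import ScoringParams, score_steps, max_scoring_subarray

params = ScoringParams()           # recommended defaults
steps = score_steps("GCGCGTGCATATGCGTG", params)
best = max_scoring_subarray(steps)  # (step_start, step_end, score)
```

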