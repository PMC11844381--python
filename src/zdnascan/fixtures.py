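"""Deterministic test-sequence generators and independent brute-force oracles.

The oracles deliberately share no code with :mod:`zdnascan.scoring` or
:mod:`zdnascan.detection`: ``oracle_score`` re-derives run positions with a
backward walk per step, and ``oracle_best_subarray`` enumerates every
contiguous span. Agreement between the two routes is therefore meaningful
evidence of correctness.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .records import SequenceRecord
from .scoring import ScoringParams

__all__ = [
    "MotifSpec",
    "generate_repeat",
    "generate_random_sequence",
    "write_fasta",
    "oracle_best_subarray",
    "oracle_score",
]

FLANK_MODES = ("random", "poly_a")


@dataclass(frozen=True)
class MotifSpec:
    """Recipe for a repeat motif with optional flanks.

    ``flank_mode='random'`` draws flanks uniformly over ACGT from ``seed``;
    ``'poly_a'`` gives homopolymer-A flanks (a Z-poor background useful for
    clean planted-motif recovery tests).
    """

    unit: str
    copies: int
    flank: int = 0
    flank_mode: str = "random"
    seed: int = 0
    record_id: str = ""

    def __post_init__(self) -> None:
        if self.copies < 1:
            raise ValueError("copies must be >= 1")
        if not self.unit:
            raise ValueError("unit must be non-empty")
        if self.flank < 0:
            raise ValueError("flank must be >= 0")
        if self.flank_mode not in FLANK_MODES:
            raise ValueError(f"flank_mode must be one of {FLANK_MODES}")


def generate_repeat(spec: MotifSpec) -> SequenceRecord:
    """Build the repeat sequence described by ``spec``; deterministic per seed."""
    core = spec.unit.upper() * spec.copies
    if spec.flank == 0:
        left = right = ""
    elif spec.flank_mode == "poly_a":
        left = right = "A" * spec.flank
    else:
        rng = np.random.default_rng(spec.seed)
        bases = np.array(list("ACGT"))
        left = "".join(rng.choice(bases, size=spec.flank))
        right = "".join(rng.choice(bases, size=spec.flank))
    record_id = spec.record_id or f"{spec.unit.upper()}x{spec.copies}"
    return SequenceRecord(record_id, left + core + right)


def generate_random_sequence(length: int, seed: int, record_id: str = "random") -> SequenceRecord:
    """Uniform ACGT sequence of the given length; deterministic per seed."""
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(np.array(list("ACGT")), size=length))
    return SequenceRecord(record_id, seq)


def write_fasta(records: Sequence[SequenceRecord], path: Union[str, Path], width: int = 70) -> None:
    """Emit records as a plain-text FASTA file (for end-to-end CLI tests)."""
    path = Path(path)
    with open(path, "w") as out:
        for rec in records:
            out.write(f">{rec.record_id}\n")
            for i in range(0, len(rec.sequence), width):
                out.write(rec.sequence[i : i + width] + "\n")


def oracle_best_subarray(
    scores: Sequence[float],
) -> Optional[tuple[int, int, float]]:
    """Exhaustive O(n^2) best contiguous span; ties broken by leftmost start,
    then longest span. None when empty or the best sum is <= 0."""
    n = len(scores)
    best: Optional[tuple[int, int, float]] = None
    for s in range(n):
        running = 0.0
        for e in range(s, n):
            running += scores[e]
            if best is None or running > best[2]:
                best = (s, e, running)
            elif running == best[2] and s == best[0] and e > best[1]:
                best = (s, e, running)
    if best is None or best[2] <= 0.0:
        return None
    return best


_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def _oracle_step_kind(a: str, b: str) -> str:
    if (a in _PURINES and b in _PYRIMIDINES) or (a in _PYRIMIDINES and b in _PURINES):
        return "".join(sorted((a, b)))  # AC, AT, CG or GT
    return "MM"


def oracle_score(sequence: str, params: Optional[ScoringParams] = None) -> float:
    """Total score of a sequence, re-derived character by character.

    For every step the position within its run is recounted from scratch by
    walking backwards, so no run-state is carried between steps.
    """
    if params is None:
        params = ScoringParams()
    seq = sequence.upper().replace("U", "T")
    total = 0.0
    for i in range(len(seq) - 1):
        kind = _oracle_step_kind(seq[i], seq[i + 1])
        if kind == "CG":
            total += params.gc_weight
        elif kind == "GT":
            total += params.gt_weight
        elif kind == "AC":
            total += params.ac_weight
        elif kind == "AT":
            k = 1
            j = i - 1
            while j >= 0 and _oracle_step_kind(seq[j], seq[j + 1]) == "AT":
                k += 1
                j -= 1
            adj = params.consecutive_at_adjustments
            total += params.at_weight + adj[k - 1 if k <= len(adj) else -1]
        else:
            k = 1
            j = i - 1
            while j >= 0 and _oracle_step_kind(seq[j], seq[j + 1]) == "MM":
                k += 1
                j -= 1
            if params.mismatch_penalty_type == "linear":
                total -= params.mismatch_penalty_start + (k - 1) * params.mismatch_penalty_delta
            else:
                total -= params.mismatch_penalty_start * params.mismatch_penalty_delta ** (k - 1)
    return total
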