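"""Per-dinucleotide-step scoring of DNA sequences.

Every adjacent base pair (a "step") is classified by whether it alternates
purine/pyrimidine and receives a weight; steps inside contiguous AT/TA runs
get position-dependent adjustments, and non-alternating ("mismatch") steps
get escalating penalties. The resulting score array is the substrate for
maximal-subarray region detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from math import isfinite
from typing import Sequence, Union

import numpy as np

from .records import SequenceRecord

__all__ = [
    "StepClass",
    "ScoringParams",
    "StepScoreArray",
    "classify_step",
    "mismatch_penalty",
    "at_run_adjustment",
    "score_steps",
]


class StepClass(Enum):
    """Category of a dinucleotide step."""

    GC = "GC"
    GT = "GT"
    AC = "AC"
    AT = "AT"
    MISMATCH = "MISMATCH"


# Ordered pairs for each alternating purine/pyrimidine class; anything else
# (purine->purine, pyrimidine->pyrimidine, or any non-ACGT character) is a
# mismatch.
_STEP_CLASS_OF_PAIR = {
    ("G", "C"): StepClass.GC,
    ("C", "G"): StepClass.GC,
    ("G", "T"): StepClass.GT,
    ("T", "G"): StepClass.GT,
    ("A", "C"): StepClass.AC,
    ("C", "A"): StepClass.AC,
    ("A", "T"): StepClass.AT,
    ("T", "A"): StepClass.AT,
}

_PENALTY_TYPES = ("linear", "exponential")


@dataclass(frozen=True)
class ScoringParams:
    """Weights, penalties and the reporting threshold.

    ``consecutive_at_adjustments[k-1]`` is ADDED to ``at_weight`` for the
    k-th AT/TA step of a contiguous AT/TA run; the final element applies to
    every later step of the run. Mismatch penalties are emitted as negative
    contributions: the k-th step of a contiguous mismatch run costs
    ``start + (k-1)*delta`` (linear) or ``start * delta**(k-1)``
    (exponential).
    """

    threshold: float = 50.0
    gc_weight: float = 7.0
    gt_weight: float = 1.25
    ac_weight: float = 1.25
    at_weight: float = 0.5
    consecutive_at_adjustments: tuple[float, ...] = (0.5, 0.5, 0.5, 0.0, 0.0, -5.0, -100.0)
    mismatch_penalty_start: float = 3.0
    mismatch_penalty_delta: float = 3.0
    mismatch_penalty_type: str = "linear"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "consecutive_at_adjustments", tuple(self.consecutive_at_adjustments)
        )
        for name in ("threshold", "gc_weight", "gt_weight", "ac_weight", "at_weight"):
            if not isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not self.consecutive_at_adjustments:
            raise ValueError("consecutive_at_adjustments must be non-empty")
        if any(not isfinite(v) for v in self.consecutive_at_adjustments):
            raise ValueError("consecutive_at_adjustments entries must be finite")
        if self.mismatch_penalty_start < 0:
            raise ValueError("mismatch_penalty_start must be >= 0")
        if self.mismatch_penalty_delta < 0:
            raise ValueError("mismatch_penalty_delta must be >= 0")
        if self.mismatch_penalty_type not in _PENALTY_TYPES:
            raise ValueError(
                f"mismatch_penalty_type must be one of {_PENALTY_TYPES}, "
                f"got {self.mismatch_penalty_type!r}"
            )
        if self.mismatch_penalty_type == "exponential" and self.mismatch_penalty_delta <= 1:
            raise ValueError("exponential penalty requires mismatch_penalty_delta > 1")


@dataclass(frozen=True)
class StepScoreArray:
    """Per-step scores for one record; length is sequence length minus one."""

    record_id: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.scores, dtype=np.float64)
        object.__setattr__(self, "scores", arr)

    def __len__(self) -> int:
        return len(self.scores)

    def total(self) -> float:
        return float(self.scores.sum()) if len(self.scores) else 0.0


def classify_step(base_a: str, base_b: str) -> StepClass:
    """Classify the ordered step ``base_a`` -> ``base_b``.

    Unknown characters fall through to MISMATCH.
    """
    return _STEP_CLASS_OF_PAIR.get((base_a, base_b), StepClass.MISMATCH)


def mismatch_penalty(k: int, params: ScoringParams) -> float:
    """Negative contribution of the k-th step in a contiguous mismatch run."""
    if k < 1:
        raise ValueError(f"run position must be >= 1, got {k}")
    if params.mismatch_penalty_type == "linear":
        return -(params.mismatch_penalty_start + (k - 1) * params.mismatch_penalty_delta)
    return -(params.mismatch_penalty_start * params.mismatch_penalty_delta ** (k - 1))


def at_run_adjustment(k: int, params: ScoringParams) -> float:
    """Adjustment added to ``at_weight`` for the k-th AT/TA step of a run.

    Past the end of the configured array, the last element keeps applying.
    """
    if k < 1:
        raise ValueError(f"run position must be >= 1, got {k}")
    adj = params.consecutive_at_adjustments
    return adj[min(k, len(adj)) - 1]


def score_steps(
    record: Union[SequenceRecord, str], params: ScoringParams | None = None
) -> StepScoreArray:
    """Score every dinucleotide step of a sequence.

    Run counters for AT/TA steps and for mismatch steps each reset whenever
    a step of any other class occurs. Sequences shorter than two bases give
    an empty array.
    """
    if params is None:
        params = ScoringParams()
    if isinstance(record, str):
        record = SequenceRecord("<anonymous>", record)
    seq = record.sequence
    n_steps = max(len(seq) - 1, 0)
    scores = np.empty(n_steps, dtype=np.float64)
    at_run = 0
    mm_run = 0
    for i in range(n_steps):
        cls = _STEP_CLASS_OF_PAIR.get((seq[i], seq[i + 1]), StepClass.MISMATCH)
        if cls is StepClass.GC:
            scores[i] = params.gc_weight
            at_run = mm_run = 0
        elif cls is StepClass.GT:
            scores[i] = params.gt_weight
            at_run = mm_run = 0
        elif cls is StepClass.AC:
            scores[i] = params.ac_weight
            at_run = mm_run = 0
        elif cls is StepClass.AT:
            at_run += 1
            mm_run = 0
            scores[i] = params.at_weight + at_run_adjustment(at_run, params)
        else:
            mm_run += 1
            at_run = 0
            scores[i] = mismatch_penalty(mm_run, params)
    return StepScoreArray(record.record_id, scores)
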