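"""Maximal-scoring region detection on step-score arrays.

Regions are contiguous spans of dinucleotide steps; a span of steps
[i, j] covers nucleotides [i, j+1], both ends 0-based inclusive. A region's
score is the plain sum of the precomputed step scores it spans — boundary
steps are not re-contextualized.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .scoring import ScoringParams, StepScoreArray

__all__ = [
    "ZDNAHit",
    "max_scoring_subarray",
    "find_candidate_regions",
    "steps_to_nucleotides",
]


@dataclass(frozen=True)
class ZDNAHit:
    """One reported region, 0-based inclusive nucleotide coordinates."""

    record_id: str
    start: int
    end: int
    score: float
    subsequence: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid hit span [{self.start}, {self.end}]")
        if len(self.subsequence) != self.end - self.start + 1:
            raise ValueError("subsequence length does not match coordinates")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def steps_to_nucleotides(step_start: int, step_end: int) -> tuple[int, int]:
    """Convert an inclusive step span to inclusive nucleotide coordinates."""
    if step_start > step_end:
        raise ValueError(f"reversed step span [{step_start}, {step_end}]")
    return step_start, step_end + 1


def max_scoring_subarray(
    scores: Sequence[float] | StepScoreArray,
) -> Optional[tuple[int, int, float]]:
    """Best-sum contiguous span of a score array, or None.

    Returns ``(step_start, step_end, sum)`` with both indices inclusive.
    Returns None when the array is empty or its maximum subarray sum is
    <= 0. Ties on sum are broken by leftmost start, then longest span.
    Linear time.
    """
    if isinstance(scores, StepScoreArray):
        scores = scores.scores
    best_sum = 0.0
    best: Optional[tuple[int, int]] = None
    cur = 0.0
    cur_start = 0
    for i, x in enumerate(scores):
        cur += x
        if cur > best_sum:
            best_sum = cur
            best = (cur_start, i)
        elif best is not None and cur == best_sum and cur_start == best[0] and i > best[1]:
            # same sum, same start, longer span
            best = (cur_start, i)
        if cur < 0.0:
            cur = 0.0
            cur_start = i + 1
    if best is None:
        return None
    return best[0], best[1], best_sum


def find_candidate_regions(
    scores: StepScoreArray,
    sequence: str,
    params: ScoringParams,
    report_best: bool = False,
) -> list[ZDNAHit]:
    """Extract threshold-passing regions from a step-score array.

    The array is partitioned into disjoint segments wherever the running sum
    of a left-to-right scan drops below zero; each segment contributes its
    own maximal subarray, and those with score >= threshold are returned
    sorted by start. When ``report_best`` is true and nothing passes the
    threshold, the single best subarray of the whole array is returned
    instead (if one with positive sum exists).
    """
    arr = scores.scores
    candidates: list[tuple[int, int, float]] = []
    seg_start = 0
    cur = 0.0
    for i, x in enumerate(arr):
        cur += x
        if cur < 0.0:
            _append_segment_best(arr, seg_start, i, candidates)
            seg_start = i + 1
            cur = 0.0
    _append_segment_best(arr, seg_start, len(arr) - 1, candidates)

    passing = [c for c in candidates if c[2] >= params.threshold]
    if not passing and report_best:
        best = max_scoring_subarray(arr)
        passing = [best] if best is not None else []

    hits = []
    for step_start, step_end, score in sorted(passing):
        start, end = steps_to_nucleotides(step_start, step_end)
        hits.append(
            ZDNAHit(
                record_id=scores.record_id,
                start=start,
                end=end,
                score=float(score),
                subsequence=sequence[start : end + 1],
            )
        )
    return hits


def _append_segment_best(
    arr: np.ndarray, seg_start: int, seg_end: int, out: list[tuple[int, int, float]]
) -> None:
    if seg_start > seg_end:
        return
    best = max_scoring_subarray(arr[seg_start : seg_end + 1])
    if best is not None:
        out.append((best[0] + seg_start, best[1] + seg_start, best[2]))
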