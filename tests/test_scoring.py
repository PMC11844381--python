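import logging

import numpy as np
import pytest

from zdnascan import (
    ScoringParams,
    SequenceRecord,
    StepClass,
    at_run_adjustment,
    classify_step,
    mismatch_penalty,
    normalize_sequence,
    score_steps,
)

from conftest import NATIVE


class TestClassifyStep:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("G", "C", StepClass.GC),
            ("C", "G", StepClass.GC),
            ("T", "G", StepClass.GT),
            ("G", "T", StepClass.GT),
            ("A", "C", StepClass.AC),
            ("C", "A", StepClass.AC),
            ("A", "T", StepClass.AT),
            ("T", "A", StepClass.AT),
            ("G", "A", StepClass.MISMATCH),
            ("A", "G", StepClass.MISMATCH),
            ("C", "T", StepClass.MISMATCH),
            ("G", "G", StepClass.MISMATCH),
            ("N", "G", StepClass.MISMATCH),
            ("X", "C", StepClass.MISMATCH),
        ],
    )
    def test_coverage(self, a, b, expected):
        assert classify_step(a, b) is expected

    def test_exhaustive_partition(self):
        # every ordered ACGT pair gets exactly one class, and the
        # alternating classes are exactly the purine<->pyrimidine pairs
        purines, pyrimidines = set("AG"), set("CT")
        for a in "ACGT":
            for b in "ACGT":
                cls = classify_step(a, b)
                alternating = (a in purines) != (b in purines)
                assert (cls is not StepClass.MISMATCH) == alternating


class TestMismatchPenalty:
    def test_first_mismatch(self, params):
        assert mismatch_penalty(1, params) == -3.0

    def test_linear_escalation(self, params):
        assert mismatch_penalty(2, params) == -6.0
        assert mismatch_penalty(3, params) == -9.0

    def test_exponential(self):
        p = ScoringParams(mismatch_penalty_type="exponential", mismatch_penalty_delta=2.0)
        assert mismatch_penalty(1, p) == -3.0
        assert mismatch_penalty(2, p) == -6.0
        assert mismatch_penalty(3, p) == -12.0

    def test_magnitude_nondecreasing(self, params):
        pens = [mismatch_penalty(k, params) for k in range(1, 20)]
        assert all(b <= a for a, b in zip(pens, pens[1:]))

    def test_invalid_k_rejected(self, params):
        with pytest.raises(ValueError):
            mismatch_penalty(0, params)


class TestAtRunAdjustment:
    @pytest.mark.parametrize(
        "k,expected",
        [(1, 0.5), (2, 0.5), (3, 0.5), (4, 0.0), (5, 0.0), (6, -5.0), (7, -100.0), (12, -100.0)],
    )
    def test_defaults(self, k, expected, params):
        assert at_run_adjustment(k, params) == expected

    def test_invalid_k_rejected(self, params):
        with pytest.raises(ValueError):
            at_run_adjustment(0, params)


class TestScoringParams:
    def test_defaults(self, params):
        assert params.threshold == 50
        assert params.gc_weight == 7
        assert params.gt_weight == params.ac_weight == 1.25
        assert params.at_weight == 0.5
        assert params.consecutive_at_adjustments == (0.5, 0.5, 0.5, 0.0, 0.0, -5.0, -100.0)
        assert params.mismatch_penalty_start == params.mismatch_penalty_delta == 3
        assert params.mismatch_penalty_type == "linear"

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"consecutive_at_adjustments": ()},
            {"mismatch_penalty_start": -1},
            {"mismatch_penalty_delta": -0.5},
            {"mismatch_penalty_type": "quadratic"},
            {"gc_weight": float("nan")},
            {"threshold": float("inf")},
            {"mismatch_penalty_type": "exponential", "mismatch_penalty_delta": 1.0},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ScoringParams(**kwargs)


class TestScoreSteps:
    def test_native_total(self, params):
        assert score_steps(NATIVE, params).total() == 45.5

    def test_gc_repeat(self, params):
        arr = score_steps("GCGC", params)
        assert arr.scores.tolist() == [7.0, 7.0, 7.0]
        assert arr.total() == 21.0

    def test_at_repeat_step_values(self, params):
        arr = score_steps("ATATATAT", params)
        assert arr.scores.tolist() == [1.0, 1.0, 1.0, 0.5, 0.5, -4.5, -99.5]

    def test_length_contract(self, params):
        for seq in ["", "A", "GC", "GCGT", "GCGCGTGACT"]:
            assert len(score_steps(seq, params)) == max(len(seq) - 1, 0)

    def test_mismatch_run_resets(self, params):
        # GG GG separated by an alternating step: both penalized as first-in-run
        arr = score_steps("GGCGG", params)
        assert arr.scores.tolist() == [-3.0, 7.0, 7.0, -3.0]

    def test_contiguous_mismatches_escalate(self, params):
        arr = score_steps("GGGG", params)
        assert arr.scores.tolist() == [-3.0, -6.0, -9.0]

    def test_at_run_resets_after_interruption(self, params):
        # two AT-class steps, interrupting AC/CG/GT steps, then a fresh AT run
        arr = score_steps("ATACGTA", params)
        assert arr.scores[0] == 1.0  # AT k=1
        assert arr.scores[-1] == 1.0  # TA k=1 after CG/GT interruption

    def test_mismatch_resets_at_counter(self, params):
        # AT run, then a mismatch run, then a fresh AT run restarting at k=1
        arr = score_steps("ATATGGATAT", params)
        assert arr.scores.tolist() == [1.0, 1.0, 1.0, 1.25, -3.0, -6.0, 1.0, 1.0, 1.0]

    def test_record_id_propagates(self, params):
        arr = score_steps(SequenceRecord("rec7", "GCGC"), params)
        assert arr.record_id == "rec7"

    def test_short_sequences_empty(self, params):
        assert len(score_steps("", params)) == 0
        assert len(score_steps("G", params)) == 0

    def test_non_acgt_scored_as_mismatch(self, params):
        arr = score_steps("GNNG", params)
        assert arr.scores.tolist() == [-3.0, -6.0, -9.0]


class TestNormalizeSequence:
    def test_case_and_uracil(self):
        assert normalize_sequence("gcgu") == "GCGT"

    def test_non_iupac_retained_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING):
            assert normalize_sequence("GC!G", "r1") == "GC!G"
        assert any("non-IUPAC" in r.message for r in caplog.records)

    def test_iupac_codes_silent(self, caplog):
        with caplog.at_level(logging.WARNING):
            normalize_sequence("ACGTNRYSWKMBDHV")
        assert not caplog.records
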