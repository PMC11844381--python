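"""Sequence records and input normalization."""

from __future__ import annotations

import logging
from dataclasses import dataclass

logger = logging.getLogger(__name__)

#: IUPAC nucleotide codes accepted without complaint (scored as mismatches
#: unless they form an alternating purine/pyrimidine step).
IUPAC_CODES = frozenset("ACGTURYSWKMBDHVN")


@dataclass(frozen=True)
class SequenceRecord:
    """One input sequence: identifier plus an uppercase DNA string."""

    record_id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


def normalize_sequence(raw: str, record_id: str = "?") -> str:
    """Uppercase a sequence and map U to T.

    Characters outside the IUPAC nucleotide alphabet are retained (they will
    score as mismatches) but trigger a warning so malformed inputs are
    visible in the log.
    """
    seq = raw.upper().replace("U", "T")
    bad = sorted(set(seq) - IUPAC_CODES)
    if bad:
        logger.warning(
            "record %s: %d non-IUPAC character(s) %s retained and scored as mismatches",
            record_id,
            sum(seq.count(c) for c in bad),
            "".join(bad),
        )
    return seq
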