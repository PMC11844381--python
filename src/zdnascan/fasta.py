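"""FASTA input, plain or gzip, with normalization and id de-duplication."""

from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import Iterator, TextIO, Union

from Bio.SeqIO.FastaIO import SimpleFastaParser

from .records import SequenceRecord, normalize_sequence

logger = logging.getLogger(__name__)

__all__ = ["FastaParseError", "read_fasta"]


class FastaParseError(ValueError):
    """Raised for structurally invalid FASTA input."""


def _open_text(path: Path) -> TextIO:
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: Union[str, Path]) -> Iterator[SequenceRecord]:
    """Yield normalized records from a FASTA file in file order.

    Multi-line sequences are joined and blank lines tolerated. Record ids
    are the header up to the first whitespace; duplicates within one file
    are suffixed ``_2``, ``_3``, ... in order of appearance.

    Raises FileNotFoundError for a missing path and FastaParseError (with
    the offending line number) when sequence data precedes the first
    header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")

    seen: dict[str, int] = {}
    n_records = 0
    with _open_text(path) as handle:
        _require_header_first(handle, path)
        handle.seek(0)
        for header, raw_seq in SimpleFastaParser(handle):
            record_id = header.split()[0] if header.split() else "unnamed"
            seen[record_id] = seen.get(record_id, 0) + 1
            if seen[record_id] > 1:
                record_id = f"{record_id}_{seen[record_id]}"
                logger.warning("duplicate record id in %s renamed to %s", path, record_id)
            n_records += 1
            yield SequenceRecord(record_id, normalize_sequence(raw_seq, record_id))
    if n_records == 0:
        logger.warning("no records found in %s", path)


def _require_header_first(handle: TextIO, path: Path) -> None:
    for line_no, line in enumerate(handle, start=1):
        if not line.strip():
            continue
        if line.startswith(">"):
            return
        raise FastaParseError(
            f"{path}:{line_no}: sequence data before first '>' header"
        )
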