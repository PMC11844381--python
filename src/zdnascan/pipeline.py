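"""FASTA-in / CSV-out scanning pipeline with optional parallelism and plots.

Output CSV columns: Sequence_name, Start, End, Z-DNA_Score, Sequence.
Start/End are 0-based, end-inclusive nucleotide indices (also stated in a
leading ``#`` comment of every CSV so files are self-describing). Output is
byte-identical regardless of worker count: records are scattered to workers
but hits are gathered and written in input order.
"""

from __future__ import annotations

import logging
import multiprocessing
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .detection import ZDNAHit, find_candidate_regions
from .fasta import read_fasta
from .records import SequenceRecord
from .scoring import ScoringParams, score_steps

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ScanResult", "run_scan", "scan_record", "write_csv", "plot_summary"]

CSV_HEADER = "Sequence_name,Start,End,Z-DNA_Score,Sequence"
CSV_COMMENT = "# Coordinates: Start and End are 0-based nucleotide indices, end-inclusive."


@dataclass
class RunConfig:
    """Everything one scan needs."""

    inputs: Sequence[Union[str, Path]]
    output: Union[str, Path]
    params: ScoringParams = field(default_factory=ScoringParams)
    report_best: bool = False
    n_jobs: int = 1
    plots: bool = False
    plot_prefix: Optional[Union[str, Path]] = None

    def __post_init__(self) -> None:
        if self.n_jobs < 1:
            raise ValueError("n_jobs must be >= 1")


@dataclass
class ScanResult:
    hits: list[ZDNAHit]
    n_records: int
    n_failed: int
    elapsed: float

    @property
    def exit_code(self) -> int:
        return 3 if self.n_failed else 0


def scan_record(
    record: SequenceRecord, params: ScoringParams, report_best: bool = False
) -> list[ZDNAHit]:
    """Score one record and extract its candidate regions."""
    if len(record) < 2:
        logger.info("record %s shorter than 2 nt, no steps to score", record.record_id)
        return []
    steps = score_steps(record, params)
    return find_candidate_regions(steps, record.sequence, params, report_best=report_best)


def _scan_task(args: tuple[SequenceRecord, ScoringParams, bool]) -> Optional[list[ZDNAHit]]:
    # Returns None on failure so a bad record cannot abort the whole pool.
    try:
        return scan_record(*args)
    except Exception:
        logger.exception("record %s failed to score, skipping", args[0].record_id)
        return None


def run_scan(config: RunConfig) -> ScanResult:
    """Scan every record of every input file and write the CSV.

    A record whose scan raises is logged and skipped; the result's
    exit_code is then 3 (partial failure).
    """
    t0 = time.monotonic()
    records: list[SequenceRecord] = []
    for path in config.inputs:
        records.extend(read_fasta(path))

    tasks = [(rec, config.params, config.report_best) for rec in records]
    per_record: list[Optional[list[ZDNAHit]]]
    if config.n_jobs > 1 and len(tasks) > 1:
        with multiprocessing.Pool(config.n_jobs) as pool:
            per_record = pool.map(_scan_task, tasks)
    else:
        per_record = [_scan_task(task) for task in tasks]

    hits: list[ZDNAHit] = []
    n_failed = 0
    for result in per_record:
        if result is None:
            n_failed += 1
        else:
            hits.extend(result)  # input order, then start (already sorted per record)

    write_csv(hits, config.output)
    if config.plots:
        prefix = config.plot_prefix or Path(config.output).with_suffix("")
        try:
            plot_summary(hits, prefix)
        except Exception:
            logger.warning("plotting failed; scan results are unaffected", exc_info=True)

    elapsed = time.monotonic() - t0
    logger.info(
        "scanned %d record(s): %d hit(s), %d failure(s), %.2fs elapsed",
        len(records),
        len(hits),
        n_failed,
        elapsed,
    )
    return ScanResult(hits=hits, n_records=len(records), n_failed=n_failed, elapsed=elapsed)


def format_score(score: float) -> str:
    """Minimal decimal rendering: 45.5, 63.75, 63."""
    return f"{score:.10g}"


def write_csv(hits: Iterable[ZDNAHit], path: Union[str, Path]) -> None:
    path = Path(path)
    with open(path, "w", newline="\n") as out:
        out.write(CSV_COMMENT + "\n")
        out.write(CSV_HEADER + "\n")
        for hit in hits:
            out.write(
                f"{hit.record_id},{hit.start},{hit.end},"
                f"{format_score(hit.score)},{hit.subsequence}\n"
            )


def plot_summary(hits: Sequence[ZDNAHit], output_prefix: Union[str, Path]) -> list[Path]:
    """Write a score-vs-length scatter and a score boxplot; returns the paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    prefix = Path(output_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    scatter_path = prefix.with_name(prefix.name + "_scatter.png")
    boxplot_path = prefix.with_name(prefix.name + "_boxplot.png")

    scores = [h.score for h in hits]
    lengths = [h.length for h in hits]

    fig, ax = plt.subplots(figsize=(6, 4))
    if hits:
        ax.scatter(lengths, scores, alpha=0.6)
    else:
        ax.annotate("no hits", xy=(0.5, 0.5), xycoords="axes fraction", ha="center")
    ax.set_xlabel("Region length (nt)")
    ax.set_ylabel("Z-DNA score")
    ax.set_title("Score vs length of detected regions")
    fig.tight_layout()
    fig.savefig(scatter_path)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4, 4))
    if hits:
        ax.boxplot(scores, tick_labels=["detected regions"])
    else:
        ax.annotate("no hits", xy=(0.5, 0.5), xycoords="axes fraction", ha="center")
    ax.set_ylabel("Z-DNA score")
    ax.set_title("Score distribution")
    fig.tight_layout()
    fig.savefig(boxplot_path)
    plt.close(fig)

    return [scatter_path, boxplot_path]
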