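"""Materialize scaffold sequences and account for unplaced target sequence.

Every scaffold is the concatenation of its runs' contig subsequences
(reverse-complemented for ``-`` runs) separated by ``N``-runs of the
estimated gap sizes.  All target bases not consumed by any run — whole
contigs without anchors, dropped single-anchor contigs, and leftover pieces
of cut contigs — are emitted once as unplaced records, so no input base is
ever lost or duplicated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

from .paths import ScaffoldPath
from .sketch import revcomp

logger = logging.getLogger(__name__)


@dataclass
class ScaffoldRecord:
    scaffold_id: str
    sequence: str
    # for placed records: the source ScaffoldPath; for unplaced: the
    # (contig, start, end) interval the record preserves
    source: object = None


def emit_scaffolds(
    paths: list[ScaffoldPath], target_seqs: dict[str, str]
) -> list[ScaffoldRecord]:
    """Concatenate oriented run subsequences with N-gaps, one per path."""
    records = []
    for sp in paths:
        parts = []
        for i, run in enumerate(sp.runs):
            if run.end > len(target_seqs[run.contig]):
                raise AssertionError(
                    f"run interval [{run.start},{run.end}) exceeds contig "
                    f"{run.contig} length (internal invariant breach)"
                )
            sub = target_seqs[run.contig][run.start : run.end]
            parts.append(revcomp(sub) if run.orientation == "-" else sub)
            if i < len(sp.gaps):
                parts.append("N" * sp.gaps[i])
        records.append(ScaffoldRecord(sp.scaffold_id, "".join(parts), source=sp))
    return records


def placed_intervals(paths: Iterable[ScaffoldPath]) -> dict[str, list[tuple[int, int]]]:
    """Per-contig sorted list of the intervals consumed by scaffold runs."""
    placed: dict[str, list[tuple[int, int]]] = {}
    for sp in paths:
        for run in sp.runs:
            placed.setdefault(run.contig, []).append((run.start, run.end))
    for intervals in placed.values():
        intervals.sort()
    return placed


def emit_unplaced(
    target_seqs: dict[str, str],
    placed: dict[str, list[tuple[int, int]]],
) -> list[ScaffoldRecord]:
    """Emit every target base not covered by a placed run, exactly once.

    Whole contigs keep the id ``unplaced_<contig>``; leftover pieces of cut
    contigs are named ``unplaced_<contig>_<start>_<end>`` (0-based
    half-open).
    """
    records = []
    for contig in target_seqs:
        length = len(target_seqs[contig])
        intervals = placed.get(contig, [])
        if not intervals:
            records.append(
                ScaffoldRecord(
                    f"unplaced_{contig}",
                    target_seqs[contig],
                    source=(contig, 0, length),
                )
            )
            continue
        cursor = 0
        for s, e in intervals:
            if s > cursor:
                records.append(
                    ScaffoldRecord(
                        f"unplaced_{contig}_{cursor}_{s}",
                        target_seqs[contig][cursor:s],
                        source=(contig, cursor, s),
                    )
                )
            cursor = max(cursor, e)
        if cursor < length:
            records.append(
                ScaffoldRecord(
                    f"unplaced_{contig}_{cursor}_{length}",
                    target_seqs[contig][cursor:length],
                    source=(contig, cursor, length),
                )
            )
    return records


def placement_report(
    target_seqs: dict[str, str],
    paths: list[ScaffoldPath],
    unplaced: list[ScaffoldRecord],
) -> dict:
    """Summary of how much of the target assembly was placed in scaffolds."""
    total = sum(len(s) for s in target_seqs.values())
    placed_bases = sum(run.end - run.start for sp in paths for run in sp.runs)
    unplaced_bases = sum(len(r.sequence) for r in unplaced)
    report = {
        "target_sequences": len(target_seqs),
        "target_bases": total,
        "scaffolds": len(paths),
        "placed_runs": sum(len(sp.runs) for sp in paths),
        "placed_bases": placed_bases,
        "unplaced_records": len(unplaced),
        "unplaced_bases": unplaced_bases,
        "fraction_placed": placed_bases / total if total else 0.0,
    }
    logger.info(
        "placed %d/%d bases (%.1f%%) in %d scaffolds",
        placed_bases,
        total,
        100.0 * report["fraction_placed"],
        len(paths),
    )
    return report


def report_tsv_text(report: dict) -> str:
    lines = ["metric\tvalue\n"]
    for key, value in report.items():
        if isinstance(value, float):
            lines.append(f"{key}\t{value:.6f}\n")
        else:
            lines.append(f"{key}\t{value}\n")
    return "".join(lines)
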