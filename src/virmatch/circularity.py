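"""Circular-scaffold classification from terminal repeats and read pairs.

A scaffold assembled from a circular template carries two hallmarks: the
assembler duplicates sequence across the origin, leaving a direct terminal
repeat, and sequencing fragments that straddled the origin leave read pairs
mapping near opposite ends of the linearised contig in junction-spanning
orientation.  A scaffold is called circular when all three criteria hold:

* length above 2 kb,
* a same-orientation terminal repeat of at least 35 bp,
* at least two junction-spanning read pairs, each mate within 500 bp of an end.

Coordinates are 0-based half-open throughout.  Reads are placed by exact
substring match on either strand (the synthetic default is error-free);
coordinate-sorted SAM alignments are accepted as an alternative evidence
source feeding the same windows.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .synthetic import revcomp

MIN_LENGTH_BP = 2_000  # strictly greater-than
MIN_TERMINAL_REPEAT = 35
MIN_SPANNING_PAIRS = 2
END_WINDOW = 500


@dataclass
class CircularityCall:
    contig_id: str
    length_bp: int
    terminal_repeat_len: int
    spanning_pairs: int
    verdict: str = field(init=False)
    failed_criteria: list[str] = field(init=False)

    def __post_init__(self) -> None:
        failed = []
        if self.length_bp <= MIN_LENGTH_BP:
            failed.append("length")
        if self.terminal_repeat_len < MIN_TERMINAL_REPEAT:
            failed.append("terminal_repeat")
        if self.spanning_pairs < MIN_SPANNING_PAIRS:
            failed.append("spanning_pairs")
        self.failed_criteria = failed
        self.verdict = "circular" if not failed else "not_circular"


def find_terminal_repeat(contig: str, min_len: int = MIN_TERMINAL_REPEAT,
                         max_scan: int = 1_000) -> int:
    """Length of the longest direct terminal repeat, 0 if below *min_len*.

    Looks for the longest exact prefix of the contig that equals a suffix in
    the same orientation; only repeats up to *max_scan* (and half the contig)
    are considered.  Chance repeats of >=35 bp are vanishingly rare in random
    sequence, so exact matching is a conservative stand-in for a significance
    test on end homology.
    """
    limit = min(max_scan, len(contig) // 2)
    for k in range(limit, min_len - 1, -1):
        if contig[:k] == contig[-k:]:
            return k
    return 0


def _place_read(read: str, contig: str) -> tuple[int, int, str] | None:
    """Exact placement (start, end, strand) or None if absent/ambiguous."""
    hits: list[tuple[int, int, str]] = []
    for strand, seq in (("+", read), ("-", revcomp(read))):
        start = contig.find(seq)
        while start != -1:
            hits.append((start, start + len(seq), strand))
            if len(hits) > 1:
                return None  # ambiguous: occurs more than once
            start = contig.find(seq, start + 1)
    return hits[0] if hits else None


def count_spanning_pairs(
    contig: str,
    read_pairs: Iterable[tuple[str, str]],
    end_window: int = END_WINDOW,
) -> int:
    """Count junction-spanning pairs: one mate wholly within *end_window* of
    the left end, the other within *end_window* of the right end, oriented
    towards the junction (forward mate at the right end, reverse at the left).

    Ambiguously placed reads (more than one exact occurrence) exclude their
    pair.  A mate starting more than *end_window* bases from its end does not
    count.
    """
    L = len(contig)
    n = 0
    for r1, r2 in read_pairs:
        p1 = _place_read(r1, contig)
        p2 = _place_read(r2, contig)
        if p1 is None or p2 is None:
            continue
        for left, right in ((p1, p2), (p2, p1)):
            if (
                left[1] <= end_window
                and right[0] >= L - end_window
                and left[2] == "-"
                and right[2] == "+"
            ):
                n += 1
                break
    return n


def spanning_pairs_from_sam(path: str | Path, contig_id: str, contig_len: int,
                            end_window: int = END_WINDOW) -> int:
    """Same junction windows, but evidence taken from SAM alignments."""
    import pysam

    by_name: dict[str, list[tuple[int, int, str]]] = {}
    with pysam.AlignmentFile(str(path), "r") as sam:
        for aln in sam:
            if aln.is_unmapped or aln.reference_name != contig_id:
                continue
            strand = "-" if aln.is_reverse else "+"
            by_name.setdefault(aln.query_name, []).append(
                (aln.reference_start, aln.reference_end, strand)
            )
    n = 0
    for placements in by_name.values():
        if len(placements) != 2:
            continue
        for left, right in (placements, placements[::-1]):
            if (
                left[1] <= end_window
                and right[0] >= contig_len - end_window
                and left[2] == "-"
                and right[2] == "+"
            ):
                n += 1
                break
    return n


def classify_circular(
    contig_id: str,
    contig: str,
    read_pairs: Iterable[tuple[str, str]],
    min_repeat: int = MIN_TERMINAL_REPEAT,
    end_window: int = END_WINDOW,
) -> CircularityCall:
    """Apply all three circularity criteria to one scaffold."""
    repeat = find_terminal_repeat(contig, min_len=min_repeat) if len(contig) >= 2 * min_repeat else 0
    pairs = count_spanning_pairs(contig, read_pairs, end_window=end_window)
    return CircularityCall(
        contig_id=contig_id,
        length_bp=len(contig),
        terminal_repeat_len=repeat,
        spanning_pairs=pairs,
    )


CALL_COLUMNS = ("contig_id", "length", "repeat_len", "spanning_pairs",
                "verdict", "failed_criteria")


def write_calls(calls: Sequence[CircularityCall], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(CALL_COLUMNS)
        for c in calls:
            w.writerow([c.contig_id, c.length_bp, c.terminal_repeat_len,
                        c.spanning_pairs, c.verdict, ";".join(c.failed_criteria)])
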