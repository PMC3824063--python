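"""Locus-level expression signals (RPM) and induced/repressed calls.

Expression at a miRNA locus is the sum of collapsed read counts
aligned there under stringent criteria (at most 3 alignments, at most
1 mismatch in the 17-nt seed), normalized per million total aligned
reads (RPM). Differential direction between conditions is the plain
signal ratio: above 1 induced, below 1 repressed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .align import AlignmentHit
from .readprep import CollapsedRead

Locus = tuple[str, int, int, str]  # chrom, start, end (half-open), strand


class ReadMap:
    """Genome-aligned reads indexed by (chromosome, strand) for counting."""

    def __init__(self, hits: Iterable[tuple[CollapsedRead, AlignmentHit]]):
        self._by_key: dict[tuple[str, str], list[tuple[int, int, int]]] = {}
        seen_reads: dict[str, int] = {}
        for read, hit in hits:
            self._by_key.setdefault((hit.ref_id, hit.strand), []).append(
                (hit.start, hit.end, read.count)
            )
            seen_reads[read.sequence] = read.count
        for lst in self._by_key.values():
            lst.sort()
        # each distinct read counts once toward the aligned total,
        # regardless of how many loci it maps to
        self.total_aligned = sum(seen_reads.values())

    def count_overlapping(
        self, chrom: str, start: int, end: int, strand: str, min_overlap_frac: float = 0.5
    ) -> int:
        """Sum counts of reads overlapping >= a fraction of their length."""
        total = 0
        for s, e, count in self._by_key.get((chrom, strand), []):
            if s >= end:
                break
            overlap = min(e, end) - max(s, start)
            if overlap > 0 and overlap >= min_overlap_frac * (e - s):
                total += count
        return total

    def count_within(self, chrom: str, start: int, end: int, strand: str) -> int:
        """Sum counts of reads lying fully inside the interval."""
        total = 0
        for s, e, count in self._by_key.get((chrom, strand), []):
            if s >= end:
                break
            if s >= start and e <= end:
                total += count
        return total


@dataclass
class ExpressionRecord:
    locus_id: str
    locus: Locus
    raw_count: int
    rpm: float
    sample: str


@dataclass
class DECall:
    locus_id: str
    rpm_treated: float
    rpm_control: float
    ratio: float | None
    direction: str  # induced | repressed | unchanged | undefined


def quantify(
    loci: Sequence[tuple[str, Locus]],
    read_map: ReadMap,
    total_aligned: int | None = None,
    sample: str = "",
    min_overlap_frac: float = 0.5,
) -> list[ExpressionRecord]:
    """RPM per locus from a stringent-alignment read map.

    ``loci`` is a sequence of (locus_id, (chrom, start, end, strand)).
    A read counts toward a locus when at least ``min_overlap_frac`` of
    it overlaps the locus on the same strand; multi-mapped reads
    contribute their full count at every locus they align to.
    """
    total = read_map.total_aligned if total_aligned is None else total_aligned
    if total == 0:
        raise ValueError("total aligned reads is zero; cannot normalize")
    out = []
    for locus_id, (chrom, start, end, strand) in loci:
        raw = read_map.count_overlapping(chrom, start, end, strand, min_overlap_frac)
        out.append(ExpressionRecord(locus_id, (chrom, start, end, strand), raw, raw / total * 1e6, sample))
    return out


def call_direction(treated: ExpressionRecord, control: ExpressionRecord) -> DECall:
    """Induced/repressed/unchanged by the treated/control signal ratio."""
    if control.rpm == 0:
        if treated.rpm == 0:
            return DECall(treated.locus_id, treated.rpm, control.rpm, None, "unchanged")
        return DECall(treated.locus_id, treated.rpm, control.rpm, None, "undefined")
    ratio = treated.rpm / control.rpm
    if ratio > 1:
        direction = "induced"
    elif ratio < 1:
        direction = "repressed"
    else:
        direction = "unchanged"
    return DECall(treated.locus_id, treated.rpm, control.rpm, ratio, direction)


def percent_control(treated: ExpressionRecord, control: ExpressionRecord) -> float:
    """Signal as a percentage of the control signal (100 x treated/control)."""
    if control.rpm == 0:
        raise ValueError("control signal is zero; percent control undefined")
    return 100.0 * treated.rpm / control.rpm
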