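"""Small-RNA read preparation: 3' trimming and collapsing to unique sequences.

Small-RNA libraries carry adapter sequence at the 3' end of every read
(mature miRNAs are ~18-22 nt, shorter than the sequenced read length).
Rather than adapter-matching, reads are blindly truncated to a fixed
length from the 3' end and then collapsed to the set of distinct
sequences, each carrying the number of identical raw reads in its FASTA
header (the ``>seq{i}_x{count}`` convention common in sRNA tools).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

_VALID_CHARS = frozenset("ACGTN")


@dataclass(frozen=True)
class RawRead:
    """A single sequencing read (DNA alphabet, N allowed)."""

    read_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CollapsedRead:
    """A unique trimmed sequence with its duplicate count."""

    sequence: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"count must be >= 1, got {self.count}")


@dataclass
class PrepConfig:
    """Trimming/collapsing parameters.

    trim_length
        Reads are truncated to their first ``trim_length`` bases (3' trim).
    drop_short
        Discard reads shorter than ``trim_length`` instead of padding.
    drop_with_N
        Discard reads whose retained prefix contains N.
    """

    trim_length: int = 20
    drop_short: bool = True
    drop_with_N: bool = True

    def __post_init__(self) -> None:
        if self.trim_length < 15:
            raise ValueError("trim_length must be >= 15")


def read_fastx(path: str | Path) -> Iterator[RawRead]:
    """Parse a FASTA or FASTQ file (gzip-transparent) into RawReads.

    The format is sniffed from the first non-blank character
    (``>`` FASTA, ``@`` FASTQ).
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        first = handle.read(1)
        while first and first.isspace():
            first = handle.read(1)
        handle.seek(0)
        if not first:
            return
        fmt = "fasta" if first == ">" else "fastq"
        for rec in SeqIO.parse(handle, fmt):
            yield RawRead(read_id=rec.id, sequence=str(rec.seq).upper())


def trim_reads(reads: Iterable[RawRead], cfg: PrepConfig | None = None) -> list[RawRead]:
    """Truncate reads to ``cfg.trim_length`` bases from the 5' end.

    Reads shorter than the trim length are dropped when ``drop_short``;
    reads with invalid characters are rejected per-read with a warning;
    reads whose retained prefix contains N are dropped when ``drop_with_N``.
    """
    cfg = cfg or PrepConfig()
    out: list[RawRead] = []
    n_short = n_bad = n_with_n = 0
    for read in reads:
        seq = read.sequence
        if not seq or not _VALID_CHARS.issuperset(seq):
            n_bad += 1
            logger.warning("rejecting read %s: invalid characters", read.read_id)
            continue
        if len(seq) < cfg.trim_length:
            if cfg.drop_short:
                n_short += 1
                continue
            # pad-free policy: keep as-is only when drop_short disabled
            out.append(read)
            continue
        trimmed = seq[: cfg.trim_length]
        if cfg.drop_with_N and "N" in trimmed:
            n_with_n += 1
            continue
        out.append(RawRead(read_id=read.read_id, sequence=trimmed))
    if n_short:
        logger.info("dropped %d reads shorter than %d nt", n_short, cfg.trim_length)
    if n_with_n:
        logger.info("dropped %d reads containing N", n_with_n)
    return out


def collapse_reads(reads: Iterable[RawRead]) -> list[CollapsedRead]:
    """Collapse identical sequences into (sequence, count) records.

    Output is deterministic: descending count, then lexicographic
    sequence. The counts sum to the number of input reads.
    """
    counts: dict[str, int] = {}
    for read in reads:
        counts[read.sequence] = counts.get(read.sequence, 0) + 1
    collapsed = [CollapsedRead(seq, n) for seq, n in counts.items()]
    collapsed.sort(key=lambda c: (-c.count, c.sequence))
    return collapsed


def write_collapsed_fasta(collapsed: Sequence[CollapsedRead], path: str | Path) -> None:
    """Write collapsed reads as FASTA with ``>seq{i}_x{count}`` headers."""
    with open(path, "w") as fh:
        for i, rec in enumerate(collapsed, start=1):
            fh.write(f">seq{i}_x{rec.count}\n{rec.sequence}\n")


def read_collapsed_fasta(path: str | Path) -> list[CollapsedRead]:
    """Read a collapsed FASTA written by :func:`write_collapsed_fasta`.

    The duplicate count is recovered from the ``_x{count}`` header suffix.
    """
    out: list[CollapsedRead] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if "_x" not in name:
            raise ValueError(f"header {name!r} lacks an _x<count> suffix")
        count = int(name.rsplit("_x", 1)[1])
        out.append(CollapsedRead(str(rec.seq).upper(), count))
    return out


def prepare(path: str | Path, cfg: PrepConfig | None = None) -> list[CollapsedRead]:
    """Convenience: parse, trim and collapse a FASTA/FASTQ file."""
    return collapse_reads(trim_reads(read_fastx(path), cfg))
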