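"""From positive classifications to a catalog of novel miRNA calls.

Positively classified precursors are post-filtered (assembly-junk
chromosomes out; insufficiently stable structures out: MFE must not
exceed -25 kcal/mol), converted to calls whose mature sequence is the
parent cluster sequence, and overlapping same-strand calls are merged
into single loci.
"""

from __future__ import annotations

import fnmatch
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .cluster import PrecursorCandidate


@dataclass
class CallFilterConfig:
    mfe_max: float = -25.0  # discard calls with MFE strictly greater than this
    excluded_chrom_patterns: tuple[str, ...] = ("chrUn*", "*_random")

    def __post_init__(self) -> None:
        if self.mfe_max >= 0:
            raise ValueError("mfe_max must be negative")


@dataclass
class NovelMiRNACall:
    chrom: str
    start: int
    end: int
    strand: str
    mature_sequence: str
    mfe: float
    vote_fraction: float
    cluster_total_count: int = 0
    source_candidates: list[str] = field(default_factory=list)

    def overlaps(self, other: "NovelMiRNACall") -> bool:
        return (
            self.chrom == other.chrom
            and self.strand == other.strand
            and self.start < other.end
            and other.start < self.end
        )


def _excluded_chrom(chrom: str, patterns: Sequence[str]) -> bool:
    return any(fnmatch.fnmatchcase(chrom, p) for p in patterns)


def postfilter(
    predicted: Iterable[tuple[PrecursorCandidate, float, float]],
    cfg: CallFilterConfig | None = None,
) -> list[NovelMiRNACall]:
    """Post-prediction discard rules applied to positive candidates.

    ``predicted`` yields (candidate, mfe, vote_fraction) triples.
    Candidates on excluded chromosomes (chrUn, *_random) or with MFE
    strictly greater than ``mfe_max`` are dropped; survivors become
    one call each, with the parent cluster sequence as the mature
    miRNA and the *cluster* interval as the call locus.
    """
    cfg = cfg or CallFilterConfig()
    calls: list[NovelMiRNACall] = []
    for cand, mfe, vote in predicted:
        if _excluded_chrom(cand.chrom, cfg.excluded_chrom_patterns):
            continue
        if mfe > cfg.mfe_max:
            continue
        cl = cand.source_cluster
        calls.append(
            NovelMiRNACall(
                chrom=cl.chrom,
                start=cl.start,
                end=cl.end,
                strand=cl.strand,
                mature_sequence=cl.sequence,
                mfe=mfe,
                vote_fraction=vote,
                cluster_total_count=cl.total_count,
                source_candidates=[cand.candidate_id],
            )
        )
    return calls


def merge_overlapping(calls: Sequence[NovelMiRNACall]) -> list[NovelMiRNACall]:
    """Merge same-strand overlapping calls into single loci.

    The merged call spans the union interval and keeps the best
    (lowest) MFE, the maximum vote fraction, and the mature sequence
    of the source cluster with the highest total count. Idempotent
    and order-invariant; no two output calls overlap on a strand.
    """
    ordered = sorted(calls, key=lambda c: (c.chrom, c.strand, c.start, c.end))
    out: list[NovelMiRNACall] = []
    for call in ordered:
        if out and out[-1].overlaps(call):
            prev = out[-1]
            if call.cluster_total_count > prev.cluster_total_count:
                mature, count = call.mature_sequence, call.cluster_total_count
            else:
                mature, count = prev.mature_sequence, prev.cluster_total_count
            out[-1] = replace(
                prev,
                start=min(prev.start, call.start),
                end=max(prev.end, call.end),
                mature_sequence=mature,
                cluster_total_count=count,
                mfe=min(prev.mfe, call.mfe),
                vote_fraction=max(prev.vote_fraction, call.vote_fraction),
                source_candidates=prev.source_candidates + call.source_candidates,
            )
        else:
            out.append(replace(call, source_candidates=list(call.source_candidates)))
    return out


def compare_conditions(
    calls_a: Sequence[NovelMiRNACall],
    calls_b: Sequence[NovelMiRNACall],
    exact: bool = False,
) -> tuple[list[NovelMiRNACall], list[NovelMiRNACall], list[tuple[NovelMiRNACall, NovelMiRNACall]]]:
    """Partition two call sets into (unique_A, unique_B, common).

    A locus is common when calls from both conditions overlap on the
    same strand (or coincide exactly with ``exact=True``). Counted on
    merged loci; the partition is exhaustive and disjoint.
    """
    a_merged = merge_overlapping(calls_a)
    b_merged = merge_overlapping(calls_b)

    def match(x: NovelMiRNACall, y: NovelMiRNACall) -> bool:
        if exact:
            return (x.chrom, x.start, x.end, x.strand) == (y.chrom, y.start, y.end, y.strand)
        return x.overlaps(y)

    common: list[tuple[NovelMiRNACall, NovelMiRNACall]] = []
    matched_b: set[int] = set()
    unique_a: list[NovelMiRNACall] = []
    for x in a_merged:
        hit = None
        for i, y in enumerate(b_merged):
            if i not in matched_b and match(x, y):
                hit = i
                break
        if hit is None:
            unique_a.append(x)
        else:
            matched_b.add(hit)
            common.append((x, b_merged[hit]))
    unique_b = [y for i, y in enumerate(b_merged) if i not in matched_b]
    return unique_a, unique_b, common


def write_bed(calls: Sequence[NovelMiRNACall], path) -> None:
    """BED6 catalog; score = 1000 x vote fraction."""
    with open(path, "w") as fh:
        for i, c in enumerate(calls, 1):
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\tnovel_{i}\t{int(round(1000 * c.vote_fraction))}\t{c.strand}\n"
            )


def write_catalog(calls: Sequence[NovelMiRNACall], fasta_path, tsv_path) -> None:
    with open(fasta_path, "w") as fa, open(tsv_path, "w") as tsv:
        tsv.write("name\tchrom\tstart\tend\tstrand\tmfe\tvote_fraction\tcount\tsources\n")
        for i, c in enumerate(calls, 1):
            name = f"novel_{i}"
            fa.write(f">{name} {c.chrom}:{c.start}-{c.end}:{c.strand}\n{c.mature_sequence}\n")
            tsv.write(
                f"{name}\t{c.chrom}\t{c.start}\t{c.end}\t{c.strand}\t{c.mfe:.2f}\t"
                f"{c.vote_fraction:.3f}\t{c.cluster_total_count}\t{','.join(c.source_candidates)}\n"
            )
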