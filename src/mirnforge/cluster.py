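"""Read clusters and candidate precursor windows.

Genome-aligned reads whose intervals overlap on the same strand are
grouped into clusters; each cluster's union interval is the putative
mature-miRNA locus. Because mature miRNAs are ~20-27 nt and reads are
uniformly trimmed, clusters whose span falls outside [20, 27] nt are
not miRNA-like and are discarded. Each surviving cluster is expanded
into several precursor windows (the cluster plus genomic flanks) so
that the mature sequence may sit on either arm of a ~110-nt hairpin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from ._seq import revcomp
from .align import AlignmentHit
from .readprep import CollapsedRead

logger = logging.getLogger(__name__)


class Genome:
    """A small in-memory genome: chromosome name -> sequence."""

    def __init__(self, sequences: Mapping[str, str]):
        self.sequences = {c: s.upper() for c, s in sequences.items()}

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        from Bio import SeqIO

        return cls({rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")})

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        if chrom not in self.sequences:
            raise KeyError(f"chromosome {chrom!r} not in genome")
        seq = self.sequences[chrom][start:end]
        return revcomp(seq) if strand == "-" else seq

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences


@dataclass
class ClusterConfig:
    min_span: int = 20
    max_span: int = 27
    min_test_count: int = 11  # raw-count floor applied to test clusters only
    window_flanks: tuple[tuple[int, int], ...] = ((70, 20), (45, 45), (20, 70))
    min_window: int = 60  # drop windows truncated below this at chromosome edges

    def __post_init__(self) -> None:
        if self.min_span > self.max_span:
            raise ValueError("min_span must be <= max_span")


@dataclass
class Cluster:
    chrom: str
    start: int
    end: int
    strand: str
    members: list[tuple[CollapsedRead, AlignmentHit]] = field(default_factory=list)

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def total_count(self) -> int:
        return sum(read.count for read, _ in self.members)

    @property
    def sequence(self) -> str:
        """Consensus locus sequence: the highest-count member read.

        Used as the mature sequence of a novel call ("parent cluster
        sequence"); ties break lexicographically for determinism.
        """
        best = min(self.members, key=lambda m: (-m[0].count, m[0].sequence))
        return best[0].sequence

    def key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.strand)


@dataclass
class PrecursorCandidate:
    chrom: str
    start: int
    end: int
    strand: str
    window_sequence: str
    cluster_offset: tuple[int, int]  # cluster interval in window coordinates
    source_cluster: Cluster
    label: str = "unlabeled"  # positive | negative | test | unlabeled
    flank: tuple[int, int] = (0, 0)

    @property
    def candidate_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.strand}:{self.flank[0]}_{self.flank[1]}"


def build_clusters(
    hits: Iterable[tuple[CollapsedRead, AlignmentHit]],
    cfg: ClusterConfig | None = None,
) -> list[Cluster]:
    """Group overlapping genome hits into strand-specific clusters.

    Clusters are maximal connected components of interval overlap per
    (chromosome, strand); those with a span outside
    [cfg.min_span, cfg.max_span] are discarded (logged). Output is
    sorted by (chrom, start, strand).
    """
    cfg = cfg or ClusterConfig()
    by_key: dict[tuple[str, str], list[tuple[CollapsedRead, AlignmentHit]]] = {}
    for read, hit in hits:
        by_key.setdefault((hit.ref_id, hit.strand), []).append((read, hit))

    clusters: list[Cluster] = []
    n_dropped = 0
    for (chrom, strand), pairs in by_key.items():
        pairs.sort(key=lambda p: (p[1].start, p[1].end, p[0].sequence))
        current: Cluster | None = None
        for read, hit in pairs:
            if current is not None and hit.start < current.end:
                current.end = max(current.end, hit.end)
                current.members.append((read, hit))
            else:
                if current is not None:
                    clusters.append(current)
                current = Cluster(chrom, hit.start, hit.end, strand, [(read, hit)])
        if current is not None:
            clusters.append(current)

    kept = []
    for c in clusters:
        if cfg.min_span <= c.span <= cfg.max_span:
            kept.append(c)
        else:
            n_dropped += 1
    if n_dropped:
        logger.info("discarded %d clusters with span outside [%d, %d]", n_dropped, cfg.min_span, cfg.max_span)
    kept.sort(key=lambda c: (c.chrom, c.start, c.strand))
    return kept


def filter_test_clusters(clusters: Sequence[Cluster], cfg: ClusterConfig | None = None) -> list[Cluster]:
    """Drop low-expression test clusters (raw count below the floor)."""
    cfg = cfg or ClusterConfig()
    return [c for c in clusters if c.total_count >= cfg.min_test_count]


def generate_precursors(
    cluster: Cluster,
    genome: Genome,
    cfg: ClusterConfig | None = None,
    label: str = "unlabeled",
) -> list[PrecursorCandidate]:
    """Expand one cluster into candidate precursor windows.

    One window per flank pair (upstream, downstream) in genomic
    coordinates; windows truncated at chromosome edges are dropped
    when shorter than ``cfg.min_window``. Window sequences are
    strand-oriented (reverse-complemented for minus-strand clusters),
    and ``cluster_offset`` places the cluster in window coordinates.
    """
    cfg = cfg or ClusterConfig()
    if cluster.chrom not in genome:
        raise KeyError(f"chromosome {cluster.chrom!r} not in genome")
    chrom_len = len(genome.sequences[cluster.chrom])
    out: list[PrecursorCandidate] = []
    for up, down in cfg.window_flanks:
        wstart = max(0, cluster.start - up)
        wend = min(chrom_len, cluster.end + down)
        if wend - wstart < cfg.min_window:
            continue
        seq = genome.fetch(cluster.chrom, wstart, wend, cluster.strand)
        if cluster.strand == "+":
            offset = (cluster.start - wstart, cluster.end - wstart)
        else:
            offset = (wend - cluster.end, wend - cluster.start)
        out.append(
            PrecursorCandidate(
                chrom=cluster.chrom,
                start=wstart,
                end=wend,
                strand=cluster.strand,
                window_sequence=seq,
                cluster_offset=offset,
                source_cluster=cluster,
                label=label,
                flank=(up, down),
            )
        )
    return out


def label_positive(
    candidate: PrecursorCandidate,
    known_mirna_loci: Iterable[tuple[str, int, int, str]],
) -> bool:
    """True iff the candidate overlaps a known miRNA locus, same strand.

    Positive-training candidates failing this check are discarded
    (discard rule 4, applied to the positive set only).
    """
    for chrom, start, end, strand in known_mirna_loci:
        if (
            chrom == candidate.chrom
            and strand == candidate.strand
            and candidate.start < end
            and start < candidate.end
        ):
            return True
    return False
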