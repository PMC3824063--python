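"""Tiered read alignment with seed-mismatch, best-stratum semantics.

Collapsed reads are aligned sequentially against annotation tiers
(mature miRNA -> mature-star -> unobserved mature-star -> hairpin ->
mRNA -> ncRNA families) and finally against the genome; a read is
claimed by the first tier where it produces a valid alignment, so only
reads matching no annotated RNA reach the genome ("test") set.

Alignment semantics mirror short-read seed alignment with best/strata
reporting: mismatches are counted within the first ``seed_length``
bases of the read (default 17) and capped at ``max_seed_mismatches``
(default 2); only hits in the best stratum (minimum seed mismatches)
are reported; a read whose best stratum exceeds ``max_alignments``
loci (default 6) is suppressed entirely as an ambiguous repetitive
mapper. Bases beyond the seed may mismatch freely. Both strands are
searched; N on either side is a mismatch.

The aligner is an exhaustive position scan vectorized with numpy —
exact by construction, and adequate for the desk-scale genomes this
package targets. A ``stringent`` parameter preset (3 alignments, 1
seed mismatch) is used for expression quantification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._seq import encode_read, encode_ref, revcomp
from .readprep import CollapsedRead

logger = logging.getLogger(__name__)

TIER_ORDER = (
    "mature",
    "star",
    "star_unobserved",
    "hairpin",
    "refseq_mrna",
    "rfam",
    "genome",
)


@dataclass
class AlignParams:
    """Seed/mismatch/multi-alignment policy.

    With ``stringent=True`` the preset used for expression signal
    calculation applies: at most 3 alignments and a single mismatched
    position within the 17-nt seed.
    """

    seed_length: int = 17
    max_seed_mismatches: int = 2
    max_alignments: int = 6
    stringent: bool = False

    def __post_init__(self) -> None:
        if self.stringent:
            self.max_alignments = 3
            self.max_seed_mismatches = 1
        if self.max_seed_mismatches < 0:
            raise ValueError("max_seed_mismatches must be >= 0")


@dataclass(frozen=True)
class AlignmentHit:
    read_sequence: str
    ref_id: str
    start: int  # 0-based
    end: int  # half-open; end - start == read length
    strand: str  # "+" or "-"
    seed_mismatches: int
    total_mismatches: int


class ReferenceTier:
    """A named set of reference sequences (one tier of the annotation).

    Encoded arrays and sliding-window views are cached per (record,
    read length), so aligning many same-length reads against the same
    tier costs one encoding pass.
    """

    def __init__(self, name: str, records: Mapping[str, str], both_strands: bool | None = None):
        self.name = name
        self.records = {rid: seq.upper() for rid, seq in records.items()}
        # transcript tiers are sense-strand references: a read from that
        # RNA matches the forward strand only; the genome is double-stranded
        self.both_strands = (name == "genome") if both_strands is None else both_strands
        self._encoded: dict[str, np.ndarray] = {}
        self._windows: dict[tuple[str, int], np.ndarray] = {}

    def __repr__(self) -> str:
        return f"ReferenceTier({self.name!r}, {len(self.records)} records)"

    def windows(self, rid: str, read_len: int) -> np.ndarray | None:
        key = (rid, read_len)
        if key not in self._windows:
            if rid not in self._encoded:
                self._encoded[rid] = encode_ref(self.records[rid])
            enc = self._encoded[rid]
            if len(enc) < read_len:
                self._windows[key] = None
            else:
                self._windows[key] = sliding_window_view(enc, read_len)
        return self._windows[key]


def tier_from_fasta(name: str, path) -> ReferenceTier:
    from Bio import SeqIO

    return ReferenceTier(
        name, {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    )


def _scan(
    read_seq: str, ref: ReferenceTier, params: AlignParams
) -> list[tuple[str, int, str, int, int]]:
    """All positions on both strands with seed mismatches within cap."""
    L = len(read_seq)
    fwd = encode_read(read_seq)
    rev = encode_read(revcomp(read_seq))
    s = params.seed_length
    cap = params.max_seed_mismatches
    out: list[tuple[str, int, str, int, int]] = []
    for rid in ref.records:
        win = ref.windows(rid, L)
        if win is None:
            continue
        # + strand: read seed is the window prefix
        neq = win != fwd
        seed_mm = neq[:, :s].sum(axis=1)
        ok = np.flatnonzero(seed_mm <= cap)
        if ok.size:
            tot = neq[ok].sum(axis=1)
            for idx, pos in enumerate(ok):
                out.append((rid, int(pos), "+", int(seed_mm[pos]), int(tot[idx])))
        if not ref.both_strands:
            continue
        # - strand: reverse-complemented read; its seed maps to the
        # window suffix (read 5' end sits at the window's 3' end)
        neq = win != rev
        seed_mm = neq[:, L - s :].sum(axis=1)
        ok = np.flatnonzero(seed_mm <= cap)
        if ok.size:
            tot = neq[ok].sum(axis=1)
            for idx, pos in enumerate(ok):
                out.append((rid, int(pos), "-", int(seed_mm[pos]), int(tot[idx])))
    return out


def align_read(
    read: CollapsedRead | str, ref: ReferenceTier, params: AlignParams | None = None
) -> list[AlignmentHit]:
    """Best-stratum alignments of one read against one tier.

    Returns hits with the minimum seed-mismatch count among all valid
    placements, sorted by (ref_id, start, strand); returns [] when the
    read does not align or when the best stratum holds more than
    ``max_alignments`` loci (multi-mapper suppression).
    """
    params = params or AlignParams()
    seq = read.sequence if isinstance(read, CollapsedRead) else read
    if len(seq) < params.seed_length:
        logger.warning("read shorter than seed length, rejected: %s", seq)
        return []
    return select_hits(seq, _scan(seq, ref, params), params)


def select_hits(
    seq: str, raw: list[tuple[str, int, str, int, int]], params: AlignParams
) -> list[AlignmentHit]:
    """Apply mismatch cap, best-stratum and multi-mapper rules to a scan.

    ``raw`` may come from a scan run with a looser mismatch cap, so
    one exhaustive scan can serve several parameter presets.
    """
    raw = [h for h in raw if h[3] <= params.max_seed_mismatches]
    if not raw:
        return []
    best = min(h[3] for h in raw)
    stratum = [h for h in raw if h[3] == best]
    if len(stratum) > params.max_alignments:
        logger.debug("read suppressed (%d best-stratum hits): %s", len(stratum), seq)
        return []
    stratum.sort(key=lambda h: (h[0], h[1], h[2]))
    L = len(seq)
    return [
        AlignmentHit(seq, rid, pos, pos + L, strand, mm, tot)
        for rid, pos, strand, mm, tot in stratum
    ]


def scan_read(
    read: CollapsedRead | str, ref: ReferenceTier, params: AlignParams | None = None
) -> list[tuple[str, int, str, int, int]]:
    """Exhaustive position scan (pre-selection): for hit caching."""
    params = params or AlignParams()
    seq = read.sequence if isinstance(read, CollapsedRead) else read
    if len(seq) < params.seed_length:
        return []
    return _scan(seq, ref, params)


class GenomeScanCache:
    """Caches exhaustive genome scans so several parameter presets
    (standard and stringent) can be applied without re-scanning."""

    def __init__(self, genome_tier: ReferenceTier, seed_length: int = 17, max_seed_mismatches: int = 2):
        self.tier = genome_tier
        self._scan_params = AlignParams(
            seed_length=seed_length, max_seed_mismatches=max_seed_mismatches
        )
        self._cache: dict[str, list[tuple[str, int, str, int, int]]] = {}

    def raw(self, seq: str) -> list[tuple[str, int, str, int, int]]:
        if seq not in self._cache:
            self._cache[seq] = _scan(seq, self.tier, self._scan_params)
        return self._cache[seq]

    def hits(self, read: CollapsedRead | str, params: AlignParams) -> list[AlignmentHit]:
        seq = read.sequence if isinstance(read, CollapsedRead) else read
        if len(seq) < params.seed_length:
            return []
        if params.max_seed_mismatches > self._scan_params.max_seed_mismatches:
            raise ValueError("cache was built with a tighter mismatch cap")
        return select_hits(seq, self.raw(seq), params)


@dataclass
class TierAssignment:
    """Outcome of sequential tier alignment for a read set."""

    assignments: dict[str, tuple[str, list[AlignmentHit]]] = field(default_factory=dict)
    unaligned: list[CollapsedRead] = field(default_factory=list)

    def reads_in_tier(self, tier_name: str) -> list[str]:
        return [
            seq for seq, (t, _) in self.assignments.items() if t == tier_name
        ]

    def tier_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, (t, _) in self.assignments.items():
            counts[t] = counts.get(t, 0) + 1
        counts["unaligned"] = len(self.unaligned)
        return counts


def assign_tiers(
    reads: Sequence[CollapsedRead],
    tiers: Sequence[ReferenceTier],
    params: AlignParams | None = None,
    genome_cache: GenomeScanCache | None = None,
) -> TierAssignment:
    """Assign each read to the first tier where it aligns.

    ``tiers`` must be ordered and end with the genome tier; reads
    aligning only there form the test set, reads aligning nowhere are
    reported unaligned. An optional :class:`GenomeScanCache` avoids
    re-scanning the genome for later parameter presets.
    """
    if not tiers:
        raise ValueError("empty tier list")
    params = params or AlignParams()
    result = TierAssignment()
    for read in reads:
        for tier in tiers:
            if genome_cache is not None and tier is genome_cache.tier:
                hits = genome_cache.hits(read, params)
            else:
                hits = align_read(read, tier, params)
            if hits:
                result.assignments[read.sequence] = (tier.name, hits)
                break
        else:
            result.unaligned.append(read)
    return result


def derive_unobserved_star(
    hairpin: str,
    mature_start_in_hairpin: int,
    mature_len: int,
    fold_engine: Callable[[str], "object"] | None = None,
) -> str:
    """Infer the unobserved star sequence opposite a mature miRNA.

    The hairpin is folded and the star is taken as the region pairing
    with the mature miRNA, shifted by the canonical 2-nt 3' overhang
    of a Dicer duplex. Returns "" when fewer than half the mature
    bases are paired (e.g. mature placed in the terminal loop).
    """
    s, e = mature_start_in_hairpin, mature_start_in_hairpin + mature_len
    if s < 0 or e > len(hairpin) or mature_len <= 0:
        raise ValueError("mature interval outside hairpin")
    if fold_engine is None:
        from .structure import fold as fold_engine  # default internal backend
    struct = fold_engine(hairpin)
    pt = struct.pair_table
    paired = [i for i in range(s, e) if pt[i] is not None]
    if len(paired) < mature_len / 2:
        return ""
    # nearest paired bases to the mature 5'/3' ends
    first, last = paired[0], paired[-1]
    a, b = pt[last], pt[first]
    if a > b:
        a, b = b, a
    star_start = max(0, a + 2)
    star_end = min(len(hairpin), b + 3)
    if star_end <= star_start:
        return ""
    return hairpin[star_start:star_end]


def stringent_params(base: AlignParams | None = None) -> AlignParams:
    """The stringent preset used for expression quantification."""
    base = base or AlignParams()
    return replace(base, stringent=True)
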