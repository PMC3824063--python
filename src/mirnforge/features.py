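"""The ten molecular features computed per filtered precursor candidate.

f1   paired nucleotide positions within the read cluster
f2   base pairs in the whole precursor structure
f3   cluster length (nt)
f4   expression (read counts) on the inferred mature-star interval
f5   total read (tag) count in the cluster
f6   minimum free energy of the precursor structure (kcal/mol)
f7   normalized energy: MFE / precursor length
f8   |unpaired positions on 5' arm - unpaired positions on 3' arm|
f9   conservation over the cluster (mean per-base score by default)
f10  unpaired positions in the overhang region (outside the
     outermost base pair)
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .cluster import PrecursorCandidate
from .quantify import ReadMap
from .structure import SecondaryStructure

FEATURE_COLUMNS = (
    "f1_pairs_in_cluster",
    "f2_pairs_in_precursor",
    "f3_cluster_length",
    "f4_star_expression",
    "f5_cluster_tag_count",
    "f6_mfe",
    "f7_norm_energy",
    "f8_arm_unpaired_diff",
    "f9_conservation",
    "f10_overhang_unpaired",
)


class ConservationTrack:
    """Per-base conservation scores from a bedGraph; 0.0 where absent."""

    def __init__(self, intervals: Iterable[tuple[str, int, int, float]] = ()):
        self._by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, score in intervals:
            self._by_chrom.setdefault(chrom, []).append((start, end, float(score)))
        for lst in self._by_chrom.values():
            lst.sort()

    @classmethod
    def from_bedgraph(cls, path) -> "ConservationTrack":
        def gen():
            with open(path) as fh:
                for line in fh:
                    line = line.strip()
                    if not line or line.startswith(("track", "#", "browser")):
                        continue
                    chrom, start, end, score = line.split()[:4]
                    yield chrom, int(start), int(end), float(score)

        return cls(gen())

    def mean(self, chrom: str, start: int, end: int) -> float:
        if end <= start:
            return 0.0
        return self.total(chrom, start, end) / (end - start)

    def total(self, chrom: str, start: int, end: int) -> float:
        acc = 0.0
        lst = self._by_chrom.get(chrom, [])
        idx = bisect.bisect_left(lst, (start,)) if lst else 0
        # step back once in case an interval starting earlier covers `start`
        if idx > 0:
            idx -= 1
        for s, e, score in lst[idx:]:
            if s >= end:
                break
            overlap = min(e, end) - max(s, start)
            if overlap > 0:
                acc += score * overlap
        return acc


@dataclass
class FeatureVector:
    f1_pairs_in_cluster: int
    f2_pairs_in_precursor: int
    f3_cluster_length: int
    f4_star_expression: int
    f5_cluster_tag_count: int
    f6_mfe: float
    f7_norm_energy: float
    f8_arm_unpaired_diff: int
    f9_conservation: float
    f10_overhang_unpaired: int

    def as_tuple(self) -> tuple:
        return tuple(getattr(self, c) for c in FEATURE_COLUMNS)


def star_interval_window(
    s: SecondaryStructure, cluster_offset: tuple[int, int], tolerance: int = 3
) -> Optional[tuple[int, int]]:
    """Inferred star interval (window coordinates), widened by a tolerance.

    The star is the region pairing with the cluster, shifted by the
    canonical 2-nt 3' overhang, then widened by +/- ``tolerance`` nt to
    absorb Drosha/Dicer processing heterogeneity. None when the
    cluster is essentially unpaired.
    """
    c0, c1 = cluster_offset
    pt = s.pair_table
    paired = [k for k in range(c0, c1) if pt[k] is not None]
    if len(paired) < (c1 - c0) / 2:
        return None
    a, b = pt[paired[-1]], pt[paired[0]]
    if a > b:
        a, b = b, a
    lo = max(0, a + 2 - tolerance)
    hi = min(len(s.sequence), b + 3 + tolerance)
    return (lo, hi) if hi > lo else None


def _window_to_genomic(candidate: PrecursorCandidate, w0: int, w1: int) -> tuple[int, int]:
    if candidate.strand == "+":
        return candidate.start + w0, candidate.start + w1
    return candidate.end - w1, candidate.end - w0


def compute_features(
    candidate: PrecursorCandidate,
    s: SecondaryStructure,
    reads: ReadMap | None = None,
    conservation: ConservationTrack | None = None,
    star_tolerance: int = 3,
    conservation_stat: str = "mean",
) -> FeatureVector:
    """All ten features for one structure-filtered candidate.

    ``reads`` is the genome-wide read map used for the star-expression
    feature (f4); ``conservation`` supplies f9 (defaults to 0.0 when
    no track is given). ``conservation_stat`` selects mean (default,
    span-independent) or sum over the cluster interval.
    """
    if s is None:
        raise ValueError("candidate has no folded structure")
    c0, c1 = candidate.cluster_offset
    pt = s.pair_table
    f1 = sum(1 for k in range(c0, c1) if pt[k] is not None)
    f2 = s.n_pairs
    cl = candidate.source_cluster
    f3 = cl.span

    f4 = 0
    if reads is not None:
        star_w = star_interval_window(s, (c0, c1), tolerance=star_tolerance)
        if star_w is not None:
            g0, g1 = _window_to_genomic(candidate, *star_w)
            f4 = reads.count_within(candidate.chrom, g0, g1, candidate.strand)

    f5 = cl.total_count
    f6 = s.mfe
    f7 = s.mfe / len(candidate.window_sequence)

    arms = s.stem_arms
    if arms is None:
        f8 = 0
    else:
        (a0, a1), (b0, b1) = arms
        un5 = sum(1 for k in range(a0, a1) if pt[k] is None)
        un3 = sum(1 for k in range(b0, b1) if pt[k] is None)
        f8 = abs(un5 - un3)

    if conservation is None:
        f9 = 0.0
    elif conservation_stat == "sum":
        f9 = conservation.total(cl.chrom, cl.start, cl.end)
    else:
        f9 = conservation.mean(cl.chrom, cl.start, cl.end)

    (o0, o1), (o2, o3) = s.overhangs
    f10 = (o1 - o0) + (o3 - o2)

    return FeatureVector(f1, f2, f3, f4, f5, f6, f7, f8, f9, f10)


def feature_matrix(
    rows: Sequence[tuple[str, FeatureVector, str]],
) -> pd.DataFrame:
    """Assemble (candidate_id, features, label) rows into a table.

    Columns are f1..f10 in declared order plus ``label``; the index is
    the candidate id. Duplicate ids are an error.
    """
    if not rows:
        return pd.DataFrame(columns=list(FEATURE_COLUMNS) + ["label"])
    ids = [r[0] for r in rows]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicated candidate ids in feature matrix")
    data = [fv.as_tuple() + (label,) for _, fv, label in rows]
    return pd.DataFrame(data, index=ids, columns=list(FEATURE_COLUMNS) + ["label"])
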