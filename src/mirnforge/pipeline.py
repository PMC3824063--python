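"""End-to-end discovery workflow: reads in, novel-miRNA catalog out.

One sample (lane) runs through: prep (trim/collapse) -> sequential
tier alignment -> training/test cluster construction -> precursor
windows -> folding and structure filters -> feature extraction ->
per-sample random-forest training -> test classification -> post
filters and merging -> stringent-alignment quantification. A second
condition reuses the same references; the pair is then compared for
common/unique loci and induced/repressed direction.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from . import novel_call as nc
from .align import (
    AlignParams,
    GenomeScanCache,
    ReferenceTier,
    TierAssignment,
    assign_tiers,
)
from .cluster import (
    Cluster,
    ClusterConfig,
    Genome,
    PrecursorCandidate,
    build_clusters,
    filter_test_clusters,
    generate_precursors,
    label_positive,
)
from .features import ConservationTrack, compute_features, feature_matrix
from .forest import ForestConfig, ForestModel, classify, importance, train
from .novel_call import CallFilterConfig, NovelMiRNACall
from .quantify import DECall, ExpressionRecord, ReadMap, call_direction, quantify
from .readprep import CollapsedRead, PrepConfig, RawRead, collapse_reads, trim_reads
from .structure import SecondaryStructure, StructureFilterConfig, fold, passes_structure_filters

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters, defaulting to the reference protocol."""

    prep: PrepConfig = field(default_factory=PrepConfig)
    align: AlignParams = field(default_factory=AlignParams)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    structure_filter: StructureFilterConfig = field(default_factory=StructureFilterConfig)
    forest: ForestConfig = field(default_factory=ForestConfig)
    call_filter: CallFilterConfig = field(default_factory=CallFilterConfig)
    fold_engine: str = "internal"
    star_tolerance: int = 3
    conservation_stat: str = "mean"
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in d:
                continue
            v = d[f.name]
            if dataclasses.is_dataclass(f.type) or f.name in (
                "prep", "align", "cluster", "structure_filter", "forest", "call_filter",
            ):
                sub = {
                    "prep": PrepConfig, "align": AlignParams, "cluster": ClusterConfig,
                    "structure_filter": StructureFilterConfig, "forest": ForestConfig,
                    "call_filter": CallFilterConfig,
                }[f.name]
                if f.name == "cluster" and "window_flanks" in v:
                    v = dict(v, window_flanks=tuple(tuple(p) for p in v["window_flanks"]))
                if f.name == "call_filter" and "excluded_chrom_patterns" in v:
                    v = dict(v, excluded_chrom_patterns=tuple(v["excluded_chrom_patterns"]))
                kwargs[f.name] = sub(**v)
            else:
                kwargs[f.name] = v
        return cls(**kwargs)


@dataclass
class DiscoveryResult:
    sample: str
    collapsed: list[CollapsedRead]
    assignment: TierAssignment
    clusters: dict[str, list[Cluster]]  # positive / negative / test
    candidates: dict[str, list[PrecursorCandidate]]  # post structure filter
    structures: dict[str, SecondaryStructure]  # candidate_id -> structure
    train_matrix: pd.DataFrame
    test_matrix: pd.DataFrame
    model: ForestModel
    feature_importance: pd.Series
    test_votes: pd.DataFrame
    calls: list[NovelMiRNACall]
    read_map: ReadMap  # standard-params genome read map
    stringent_map: ReadMap
    manifest: dict


def _genome_hits(
    reads: Sequence[CollapsedRead],
    cache: GenomeScanCache,
    params: AlignParams,
) -> list[tuple[CollapsedRead, "object"]]:
    return [(read, h) for read in reads for h in cache.hits(read, params)]


@dataclass
class SamplePrep:
    """Everything up to (and including) the feature tables for one sample."""

    sample: str
    collapsed: list[CollapsedRead]
    assignment: TierAssignment
    clusters: dict[str, list[Cluster]]
    candidates: dict[str, list[PrecursorCandidate]]
    structures: dict[str, SecondaryStructure]
    train_matrix: pd.DataFrame
    test_matrix: pd.DataFrame
    read_map: ReadMap
    stringent_map: ReadMap
    n_windows: dict[str, int]
    tier_counts: dict[str, int]


def prepare_sample(
    sample: str,
    raw_reads: Sequence[RawRead],
    tiers: Sequence[ReferenceTier],
    genome: Genome,
    known_mirna_loci: Sequence[tuple[str, int, int, str]],
    conservation: Optional[ConservationTrack] = None,
    cfg: Optional[PipelineConfig] = None,
) -> SamplePrep:
    """Prep, align, cluster, fold/filter and featurize one sample.

    ``tiers`` must be the annotation tiers in canonical order with the
    genome tier last; ``known_mirna_loci`` are strand-aware mature
    miRNA intervals used to vet the positive training set.
    """
    cfg = cfg or PipelineConfig()
    genome_tier = tiers[-1]
    if genome_tier.name != "genome":
        raise ValueError("last tier must be the genome")

    # 1. prep
    collapsed = collapse_reads(trim_reads(raw_reads, cfg.prep))
    logger.info("[%s] %d collapsed reads", sample, len(collapsed))

    # 2. sequential tier alignment (one exhaustive genome scan per read,
    # cached so the stringent preset below reuses it)
    cache = GenomeScanCache(
        genome_tier,
        seed_length=cfg.align.seed_length,
        max_seed_mismatches=max(cfg.align.max_seed_mismatches, 1),
    )
    assignment = assign_tiers(collapsed, tiers, cfg.align, genome_cache=cache)
    tier_counts = assignment.tier_counts()
    logger.info("[%s] tier counts: %s", sample, tier_counts)

    by_seq = {c.sequence: c for c in collapsed}

    def reads_of(tier_names: tuple[str, ...]) -> list[CollapsedRead]:
        return [
            by_seq[seq]
            for seq, (t, _) in assignment.assignments.items()
            if t in tier_names
        ]

    # 3. genomic projections: training reads are re-aligned to the genome
    pos_hits = _genome_hits(reads_of(("mature",)), cache, cfg.align)
    neg_hits = _genome_hits(reads_of(("refseq_mrna", "rfam")), cache, cfg.align)
    test_hits = _genome_hits(reads_of(("genome",)), cache, cfg.align)

    clusters = {
        "positive": build_clusters(pos_hits, cfg.cluster),
        "negative": build_clusters(neg_hits, cfg.cluster),
        "test": filter_test_clusters(build_clusters(test_hits, cfg.cluster), cfg.cluster),
    }

    # 4. genome-wide read maps (feature f4 + quantification)
    read_map = ReadMap(_genome_hits(collapsed, cache, cfg.align))
    stringent = AlignParams(seed_length=cfg.align.seed_length, stringent=True)
    stringent_map = ReadMap(_genome_hits(collapsed, cache, stringent))

    # 5. precursors, folding, structure filters, features
    structures: dict[str, SecondaryStructure] = {}
    candidates: dict[str, list[PrecursorCandidate]] = {}
    n_windows: dict[str, int] = {}
    for label in ("positive", "negative", "test"):
        kept: list[PrecursorCandidate] = []
        n_win = 0
        for cl in clusters[label]:
            for cand in generate_precursors(cl, genome, cfg.cluster, label=label):
                if label == "positive" and not label_positive(cand, known_mirna_loci):
                    continue
                n_win += 1
                s = fold(cand.window_sequence, engine=cfg.fold_engine)
                ok, _ = passes_structure_filters(cand.cluster_offset, s, cfg.structure_filter)
                if ok:
                    structures[cand.candidate_id] = s
                    kept.append(cand)
        candidates[label] = kept
        n_windows[label] = n_win

    def rows_for(label: str) -> list[tuple[str, object, str]]:
        rows = []
        for cand in candidates[label]:
            fv = compute_features(
                cand,
                structures[cand.candidate_id],
                reads=read_map,
                conservation=conservation,
                star_tolerance=cfg.star_tolerance,
                conservation_stat=cfg.conservation_stat,
            )
            rows.append((cand.candidate_id, fv, label))
        return rows

    train_matrix = feature_matrix(rows_for("positive") + rows_for("negative"))
    test_matrix = feature_matrix(rows_for("test"))
    return SamplePrep(
        sample=sample,
        collapsed=collapsed,
        assignment=assignment,
        clusters=clusters,
        candidates=candidates,
        structures=structures,
        train_matrix=train_matrix,
        test_matrix=test_matrix,
        read_map=read_map,
        stringent_map=stringent_map,
        n_windows=n_windows,
        tier_counts=tier_counts,
    )


def run_discovery(
    sample: str,
    raw_reads: Sequence[RawRead],
    tiers: Sequence[ReferenceTier],
    genome: Genome,
    known_mirna_loci: Sequence[tuple[str, int, int, str]],
    conservation: Optional[ConservationTrack] = None,
    cfg: Optional[PipelineConfig] = None,
) -> DiscoveryResult:
    """Run the full discovery workflow for one sample."""
    cfg = cfg or PipelineConfig()
    prep = prepare_sample(
        sample, raw_reads, tiers, genome, known_mirna_loci, conservation, cfg
    )
    candidates = prep.candidates
    structures = prep.structures
    train_matrix, test_matrix = prep.train_matrix, prep.test_matrix

    # 6. random forest (per sample)
    forest_cfg = dataclasses.replace(cfg.forest, rng_seed=cfg.seed)
    model = train(train_matrix, forest_cfg)
    feat_importance = importance(model)
    logger.info("[%s] OOB accuracy %.3f", sample, model.oob_accuracy)

    # 7. classify test candidates, post-filter, merge
    votes = classify(model, test_matrix)
    predicted = []
    for cand in candidates["test"]:
        row = votes.loc[cand.candidate_id]
        if row["predicted_label"] == "positive":
            predicted.append(
                (cand, structures[cand.candidate_id].mfe, float(row["vote_fraction"]))
            )
    calls = nc.merge_overlapping(nc.postfilter(predicted, cfg.call_filter))

    manifest = {
        "sample": sample,
        "n_raw_reads": len(raw_reads),
        "n_collapsed": len(prep.collapsed),
        "tier_counts": prep.tier_counts,
        "n_clusters": {k: len(v) for k, v in prep.clusters.items()},
        "n_windows": prep.n_windows,
        "n_candidates_post_structure": {k: len(v) for k, v in candidates.items()},
        "oob_accuracy": model.oob_accuracy,
        "confusion": dataclasses.asdict(model.confusion) if model.confusion else None,
        "n_predicted_positive": len(predicted),
        "n_calls": len(calls),
    }
    return DiscoveryResult(
        sample=sample,
        collapsed=prep.collapsed,
        assignment=prep.assignment,
        clusters=prep.clusters,
        candidates=candidates,
        structures=structures,
        train_matrix=train_matrix,
        test_matrix=test_matrix,
        model=model,
        feature_importance=feat_importance,
        test_votes=votes,
        calls=calls,
        read_map=prep.read_map,
        stringent_map=prep.stringent_map,
        manifest=manifest,
    )


@dataclass
class PairResult:
    control: DiscoveryResult
    treated: DiscoveryResult
    unique_control: list[NovelMiRNACall]
    unique_treated: list[NovelMiRNACall]
    common: list[tuple[NovelMiRNACall, NovelMiRNACall]]
    de_table: pd.DataFrame


def run_condition_pair(
    reads_by_condition: dict[str, Sequence[RawRead]],
    tiers: Sequence[ReferenceTier],
    genome: Genome,
    known_mirna_loci: Sequence[tuple[str, int, int, str]],
    conservation: Optional[ConservationTrack] = None,
    cfg: Optional[PipelineConfig] = None,
) -> PairResult:
    """Run both conditions and compare their novel-miRNA catalogs.

    ``reads_by_condition`` must have keys "control" and "treated".
    Expression direction is computed per union locus from the two
    stringent RPM signals (treated/control ratio).
    """
    cfg = cfg or PipelineConfig()
    results = {
        cond: run_discovery(
            cond, reads, tiers, genome, known_mirna_loci, conservation, cfg
        )
        for cond, reads in reads_by_condition.items()
    }
    control, treated = results["control"], results["treated"]
    uniq_c, uniq_t, common = nc.compare_conditions(control.calls, treated.calls)

    # union loci: merged novel calls across both conditions
    union = nc.merge_overlapping(control.calls + treated.calls)
    loci = [
        (f"locus_{i + 1}", (c.chrom, c.start, c.end, c.strand))
        for i, c in enumerate(union)
    ]
    expr_c = quantify(loci, control.stringent_map, sample="control")
    expr_t = quantify(loci, treated.stringent_map, sample="treated")
    de_rows = []
    for ec, et, (locus_id, locus) in zip(expr_c, expr_t, loci):
        call = call_direction(et, ec)
        de_rows.append(
            {
                "locus_id": locus_id,
                "chrom": locus[0],
                "start": locus[1],
                "end": locus[2],
                "strand": locus[3],
                "rpm_control": ec.rpm,
                "rpm_treated": et.rpm,
                "ratio": call.ratio,
                "direction": call.direction,
            }
        )
    de = pd.DataFrame(de_rows)
    return PairResult(control, treated, uniq_c, uniq_t, common, de)
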