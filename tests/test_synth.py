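"""The synthetic study: planted hairpins, simulated lanes, conservation
track and the expression-matrix generator."""

import dataclasses

import numpy as np
import pytest

from mirnforge.cluster import ClusterConfig, generate_precursors
from mirnforge.pipeline import PipelineConfig, run_discovery
from mirnforge.structure import fold, passes_structure_filters
from mirnforge.synth import (
    SyntheticSpec,
    make_conservation_track,
    plant_hairpins,
    simulate_expression_matrix,
    simulate_reads,
)


class TestPlantHairpins:
    def test_locus_census(self, dataset):
        spec = dataset.spec
        truth = dataset.truth
        assert len(truth.of_kind("known_mirna")) == spec.n_known_mirnas
        assert len(truth.of_kind("novel_mirna")) == spec.n_novel_mirnas
        assert len(truth.of_kind("decoy")) == spec.n_decoy_rnas
        assert len(truth.of_kind("trap")) == 1
        assert truth.of_kind("trap")[0].chrom == "chr1_random"

    def test_planted_sequences_sit_in_the_genome(self, dataset):
        for loc in dataset.truth.loci:
            assert (
                dataset.genome.fetch(loc.chrom, loc.mature_start, loc.mature_end, loc.strand)
                == loc.mature_seq
            )
            assert (
                dataset.genome.fetch(loc.chrom, loc.hairpin_start, loc.hairpin_end, loc.strand)
                == loc.hairpin_seq
            )

    def test_every_planted_locus_has_a_filter_passing_window(self, dataset):
        from mirnforge.cluster import Cluster

        cfg = ClusterConfig()
        for loc in dataset.truth.loci:
            if loc.strand == "+":
                c = Cluster(loc.chrom, loc.mature_start, loc.mature_end, "+", [])
            else:
                c = Cluster(loc.chrom, loc.mature_start, loc.mature_end, "-", [])
            passed = []
            for cand in generate_precursors(c, dataset.genome, cfg):
                s = fold(cand.window_sequence)
                ok, _ = passes_structure_filters(cand.cluster_offset, s)
                passed.append(ok)
            assert any(passed), loc.name

    def test_novel_loci_absent_from_annotation_tiers(self, dataset):
        tier_seqs = "".join(
            seq for t in dataset.tiers.values() for seq in t.records.values()
        )
        for loc in dataset.truth.of_kind("novel_mirna", "trap"):
            assert loc.mature_seq not in tier_seqs

    def test_loci_do_not_overlap(self, dataset):
        by_chrom = {}
        for loc in dataset.truth.loci:
            by_chrom.setdefault(loc.chrom, []).append((loc.hairpin_start, loc.hairpin_end))
        for intervals in by_chrom.values():
            intervals.sort()
            for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
                assert e1 <= s2

    def test_same_seed_is_byte_identical(self, tiny_spec):
        a = plant_hairpins(tiny_spec)
        b = plant_hairpins(tiny_spec)
        assert a.genome.sequences == b.genome.sequences
        for name in a.tiers:
            assert a.tiers[name].records == b.tiers[name].records

    def test_full_repression_marks_every_locus_down(self, tiny_spec):
        spec = dataclasses.replace(tiny_spec, repression_fraction=1.0)
        ds = plant_hairpins(spec)
        for loc in ds.truth.loci:
            assert loc.lam_treated < loc.lam_control


class TestSimulateReads:
    def test_realized_counts_near_poisson_mean(self, study):
        counts = study.counts.set_index("name")
        for loc in study.dataset.truth.loci:
            for cond, lam in (("control", loc.lam_control), ("treated", loc.lam_treated)):
                n = counts.loc[loc.name, f"count_{cond}"]
                assert abs(n - lam) <= 3 * np.sqrt(lam) + 1, (loc.name, cond)

    def test_reads_trim_to_planted_inserts(self, study):
        ds = study.dataset
        mature_prefixes = {l.mature_seq[:20] for l in ds.truth.loci} | {
            l.mature_seq[1:21] for l in ds.truth.loci
        } | {l.mature_seq[2:22] for l in ds.truth.loci}
        hit = sum(
            1 for r in study.reads["control"][:500] if r.sequence[:20] in mature_prefixes
        )
        assert hit > 300  # most reads come from planted mature arms

    def test_same_seed_reproduces_lanes(self, tiny_spec):
        ds = plant_hairpins(tiny_spec)
        r1, t1 = simulate_reads(ds)
        r2, t2 = simulate_reads(ds)
        assert [x.sequence for x in r1["control"]] == [x.sequence for x in r2["control"]]
        assert t1.equals(t2)

    def test_background_reads_alone_form_no_expressed_clusters(self, study):
        # at the default background depth, uniform reads never reach the
        # 11-count expression floor under the default cluster rules
        from mirnforge.align import ReferenceTier, align_read
        from mirnforge.cluster import build_clusters, filter_test_clusters
        from mirnforge.readprep import PrepConfig, collapse_reads, trim_reads

        bg = [r for r in study.reads["control"] if r.read_id.startswith("bg_")]
        assert bg
        collapsed = collapse_reads(trim_reads(bg, PrepConfig()))
        tier = ReferenceTier("genome", study.dataset.genome.sequences)
        hits = [(r, h) for r in collapsed for h in align_read(r, tier)]
        clusters = build_clusters(hits, ClusterConfig())
        assert filter_test_clusters(clusters) == []


class TestConservationTrack:
    def test_planted_mirna_loci_score_high(self, study):
        for loc in study.dataset.truth.of_kind("known_mirna", "novel_mirna", "trap"):
            assert study.conservation.mean(loc.chrom, loc.hairpin_start, loc.hairpin_end) >= 0.8

    def test_decoys_and_background_score_low(self, study):
        cons = study.conservation
        for loc in study.dataset.truth.of_kind("decoy"):
            assert cons.mean(loc.chrom, loc.hairpin_start, loc.hairpin_end) <= 0.2
        rng = np.random.default_rng(0)
        ds = study.dataset
        vals = []
        planted = [
            (l.chrom, l.hairpin_start, l.hairpin_end) for l in ds.truth.loci
        ]
        for _ in range(40):
            chrom = list(ds.genome.sequences)[int(rng.integers(4))]
            start = int(rng.integers(0, len(ds.genome.sequences[chrom]) - 100))
            if any(c == chrom and start < e and start + 100 > s for c, s, e in planted):
                continue
            vals.append(cons.mean(chrom, start, start + 100))
        assert np.mean(vals) <= 0.2


class TestNothingPlanted:
    def test_zero_novel_loci_yield_zero_calls(self, tiny_spec):
        spec = dataclasses.replace(tiny_spec, n_novel_mirnas=0)
        ds = plant_hairpins(spec)
        reads, _ = simulate_reads(ds)
        cons = make_conservation_track(ds)
        result = run_discovery(
            "control",
            reads["control"],
            ds.ordered_tiers(),
            ds.genome,
            ds.truth.known_mature_loci(),
            cons,
            PipelineConfig(seed=tiny_spec.seed),
        )
        assert result.calls == []


class TestExpressionMatrixGenerator:
    def test_shape_groups_and_planted_shift(self):
        raw, groups = simulate_expression_matrix(n_probes=100, n_de=10, effect=2.0, seed=0)
        assert raw.shape == (100, 6)
        assert groups == ["control"] * 3 + ["treated"] * 3
        assert (raw.to_numpy() > 0).all()
        log2 = np.log2(raw.to_numpy())
        de_shift = np.abs(log2[:10, 3:].mean(axis=1) - log2[:10, :3].mean(axis=1))
        null_shift = np.abs(log2[10:, 3:].mean(axis=1) - log2[10:, :3].mean(axis=1))
        assert de_shift.mean() > 5 * null_shift.mean()
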