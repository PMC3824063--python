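"""Seed-mismatch aligner semantics, tier assignment and star inference."""

import numpy as np
import pytest

from mirnforge._seq import revcomp
from mirnforge.align import (
    AlignParams,
    GenomeScanCache,
    ReferenceTier,
    align_read,
    assign_tiers,
    derive_unobserved_star,
)
from mirnforge.readprep import CollapsedRead
from mirnforge.structure import fold


def rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def brute_force_hits(read, records, params, both_strands=True):
    """Independent position scan: per-position character comparison with
    the same seed/stratum/cap rules, written without numpy windows."""
    L = len(read)
    s = params.seed_length
    raw = []
    for rid, ref in records.items():
        for strand in ("+", "-") if both_strands else ("+",):
            q = read if strand == "+" else revcomp(read)
            for pos in range(len(ref) - L + 1):
                win = ref[pos : pos + L]
                mm = [a != b or a == "N" or b == "N" for a, b in zip(win, q)]
                seed_mm = sum(mm[L - s :]) if strand == "-" else sum(mm[:s])
                if seed_mm <= params.max_seed_mismatches:
                    raw.append((rid, pos, strand, seed_mm, sum(mm)))
    if not raw:
        return []
    best = min(h[3] for h in raw)
    stratum = sorted([h for h in raw if h[3] == best])
    if len(stratum) > params.max_alignments:
        return []
    return stratum


class TestAlignRead:
    def test_unique_exact_match(self):
        rng = np.random.default_rng(0)
        genome = rand_seq(rng, 500)
        read = genome[100:120]
        tier = ReferenceTier("genome", {"chr1": genome})
        hits = align_read(read, tier)
        exact = [h for h in hits if h.seed_mismatches == 0]
        assert len(exact) == 1
        h = exact[0]
        assert (h.start, h.end, h.strand, h.total_mismatches) == (100, 120, "+", 0)

    def test_three_seed_mismatches_excluded(self):
        ref = "A" * 60
        read = "T" * 3 + "A" * 17  # 3 mismatches, all within the 17-nt seed
        tier = ReferenceTier("genome", {"chr1": ref})
        assert align_read(read, tier) == []

    def test_mismatches_beyond_seed_are_free(self):
        rng = np.random.default_rng(11)
        genome = rand_seq(rng, 200)
        locus = genome[50:70]
        # corrupt the 3 bases beyond the 17-nt seed
        read = locus[:17] + "".join(
            {"A": "C", "C": "A", "G": "T", "T": "G"}[b] for b in locus[17:]
        )
        tier = ReferenceTier("genome", {"chr1": genome})
        hits = [h for h in align_read(read, tier) if h.start == 50]
        assert hits and hits[0].seed_mismatches == 0
        assert hits[0].total_mismatches == 3

    def test_multimapper_suppressed_beyond_cap(self):
        rng = np.random.default_rng(1)
        unit = rand_seq(rng, 20)
        spacer = "A" * 30
        genome = spacer + (unit + spacer) * 8
        tier = ReferenceTier("genome", {"chr1": genome})
        # oracle: 8 identical loci exceed the 6-alignment cap -> suppressed
        params = AlignParams()
        assert brute_force_hits(unit, tier.records, params) == []
        assert align_read(unit, tier, params) == []
        # raising the cap re-admits all 8
        relaxed = AlignParams(max_alignments=8)
        assert len(align_read(unit, tier, relaxed)) == 8

    def test_best_stratum_excludes_worse_hits(self):
        rng = np.random.default_rng(2)
        unit = rand_seq(rng, 20)
        mutated = ("T" if unit[0] != "T" else "G") + unit[1:]
        genome = "A" * 30 + unit + "A" * 30 + mutated + "A" * 30
        tier = ReferenceTier("genome", {"chr1": genome})
        hits = align_read(unit, tier)
        assert [h.seed_mismatches for h in hits].count(0) == len(hits)

    def test_short_read_rejected(self):
        tier = ReferenceTier("genome", {"chr1": "A" * 50})
        assert align_read("ACGT", tier) == []

    def test_oracle_equivalence_on_random_genome(self):
        rng = np.random.default_rng(3)
        genome = rand_seq(rng, 3000)
        tier = ReferenceTier("genome", {"chr1": genome})
        params = AlignParams()
        for _ in range(25):
            if rng.random() < 0.6:
                pos = int(rng.integers(0, len(genome) - 20))
                read = list(genome[pos : pos + 20])
                for p in rng.choice(20, size=int(rng.integers(0, 4)), replace=False):
                    read[p] = "ACGT"[int(rng.integers(4))]
                read = "".join(read)
            else:
                read = rand_seq(rng, 20)
            got = [
                (h.ref_id, h.start, h.strand, h.seed_mismatches, h.total_mismatches)
                for h in align_read(read, tier, params)
            ]
            assert got == brute_force_hits(read, tier.records, params)

    def test_strand_symmetry(self):
        rng = np.random.default_rng(4)
        genome = rand_seq(rng, 800)
        tier = ReferenceTier("genome", {"chr1": genome})
        read = genome[200:220]
        fwd = align_read(read, tier)
        rev = align_read(revcomp(read), tier)
        flip = {"+": "-", "-": "+"}
        assert {(h.start, h.end, flip[h.strand]) for h in fwd} == {
            (h.start, h.end, h.strand) for h in rev
        }

    def test_transcript_tier_is_sense_strand_only(self):
        rng = np.random.default_rng(5)
        tx = rand_seq(rng, 40)
        tier = ReferenceTier("mature", {"t1": tx})
        antisense = revcomp(tx[5:25])
        assert align_read(antisense, tier) == []
        assert align_read(tx[5:25], tier) != []


class TestScanCache:
    def test_cache_matches_direct_alignment(self):
        rng = np.random.default_rng(6)
        genome = rand_seq(rng, 2000)
        tier = ReferenceTier("genome", {"chr1": genome})
        cache = GenomeScanCache(tier)
        std = AlignParams()
        stringent = AlignParams(stringent=True)
        for _ in range(10):
            pos = int(rng.integers(0, 1980))
            read = genome[pos : pos + 20]
            assert cache.hits(read, std) == align_read(read, tier, std)
            assert cache.hits(read, stringent) == align_read(read, tier, stringent)

    def test_cache_rejects_looser_params(self):
        tier = ReferenceTier("genome", {"chr1": "A" * 100})
        cache = GenomeScanCache(tier, max_seed_mismatches=1)
        with pytest.raises(ValueError):
            cache.hits("A" * 20, AlignParams(max_seed_mismatches=2))


class TestAssignTiers:
    def _toy(self):
        rng = np.random.default_rng(7)
        mature = {f"m{i}": rand_seq(rng, 22) for i in range(10)}
        rrna = {f"r{i}": rand_seq(rng, 60) for i in range(10)}
        genome_parts = [rand_seq(rng, 200)]
        intergenic = []
        for _ in range(10):
            seg = rand_seq(rng, 30)
            intergenic.append(seg[5:25])
            genome_parts += [seg, rand_seq(rng, 50)]
        # plant mature + rRNA genes in the genome too
        for seq in list(mature.values()) + list(rrna.values()):
            genome_parts += [seq, rand_seq(rng, 40)]
        genome = "".join(genome_parts)
        tiers = [
            ReferenceTier("mature", mature),
            ReferenceTier("rfam", rrna),
            ReferenceTier("genome", {"chr1": genome}),
        ]
        reads = (
            [CollapsedRead(s[:20], 1) for s in mature.values()]
            + [CollapsedRead(s[10:30], 1) for s in rrna.values()]
            + [CollapsedRead(s, 1) for s in intergenic]
        )
        return reads, tiers

    def test_planted_provenance_recovered(self):
        reads, tiers = self._toy()
        result = assign_tiers(reads, tiers)
        counts = result.tier_counts()
        assert (counts["mature"], counts["rfam"], counts["genome"]) == (10, 10, 10)
        assert counts["unaligned"] == 0

    def test_first_matching_tier_claims_the_read(self):
        reads, tiers = self._toy()
        result = assign_tiers(reads, tiers)
        # mature sequences are also in the genome, yet never reach it
        for read in reads[:10]:
            assert result.assignments[read.sequence][0] == "mature"

    def test_partition_property(self):
        reads, tiers = self._toy()
        result = assign_tiers(reads, tiers)
        assert len(result.assignments) + len(result.unaligned) == len(reads)

    def test_nowhere_aligning_read_reported_unaligned(self):
        _, tiers = self._toy()
        result = assign_tiers([CollapsedRead("GC" * 10, 1)], tiers)
        assert len(result.unaligned) == 1

    def test_empty_tier_list_is_an_error(self):
        with pytest.raises(ValueError):
            assign_tiers([CollapsedRead("A" * 20, 1)], [])


class TestDeriveStar:
    def test_perfect_inverted_repeat_gives_shifted_revcomp(self):
        rng = np.random.default_rng(8)
        mature = rand_seq(rng, 22)
        hairpin = mature + "AACA" * 2 + revcomp(mature)
        star = derive_unobserved_star(hairpin, 0, 22)
        # canonical 2-nt 3' overhang: the pairing partner shifted by 2,
        # clamped at the hairpin end
        expected = hairpin[len(mature) + 8 + 2 :]
        assert star == expected
        assert len(star) == 20

    def test_star_matches_pair_table_oracle(self):
        rng = np.random.default_rng(9)
        mature = rand_seq(rng, 22)
        hairpin = "AAC" + mature + "ACACACAC" + revcomp(mature) + "CCA"
        star = derive_unobserved_star(hairpin, 3, 22)
        pt = fold(hairpin).pair_table
        paired = [i for i in range(3, 25) if pt[i] is not None]
        lo, hi = pt[paired[-1]], pt[paired[0]]
        assert star == hairpin[lo + 2 : hi + 3]

    def test_mature_in_loop_returns_empty(self):
        stem = "G" * 15
        hairpin = stem + "A" * 12 + "C" * 15
        assert derive_unobserved_star(hairpin, 17, 8) == ""

    def test_mature_outside_hairpin_is_an_error(self):
        with pytest.raises(ValueError):
            derive_unobserved_star("ACGT" * 10, 30, 22)


class TestStringentPreset:
    def test_stringent_tightens_caps(self):
        p = AlignParams(stringent=True)
        assert p.max_alignments == 3
        assert p.max_seed_mismatches == 1

    def test_stringent_drops_two_mismatch_hits(self):
        rng = np.random.default_rng(10)
        genome = rand_seq(rng, 400)
        tier = ReferenceTier("genome", {"chr1": genome})
        read = list(genome[100:120])
        read[0] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[0]]
        read[5] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[5]]
        read = "".join(read)
        loose = [h for h in align_read(read, tier) if h.start == 100]
        assert loose and loose[0].seed_mismatches == 2
        strict_hits = align_read(read, tier, AlignParams(stringent=True))
        assert all(h.start != 100 or h.strand != "+" for h in strict_hits)
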