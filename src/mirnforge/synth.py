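"""Self-contained synthetic fixtures with planted ground truth.

The generator emulates the data a two-condition small-RNA-seq novel
miRNA study sees, at desk scale: a toy multi-chromosome genome with
planted miRNA hairpins (some annotated = "known", some unannotated =
"novel"), decoy structured RNAs assigned to the mRNA/ncRNA tiers,
two conditions of simulated collapsed reads in which most planted
loci are repressed in the treated sample, a conservation track that
scores planted miRNA loci high, and a synthetic probe-level
expression matrix for the microarray module. Every simulated read is
traceable to a planted locus or to background, so each pipeline stage
can be checked against a known answer.

Planted hairpins are built from a GC-biased mature 22-mer, a short
unstructured loop and an imperfect reverse complement (1-3 planted
mismatches), embedded between A/C-biased spacers so the precursor
window folds into a clean single stem; each construct is
rejection-sampled until at least one precursor window passes the
structure filters with a margin below the -25 kcal/mol call
threshold. One miRNA-like "trap" locus is planted on chr1_random:
it carries reads and conservation like a genuine novel miRNA and
must be eliminated by the chromosome post-filter, not by the
classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._seq import revcomp
from .align import ReferenceTier
from .cluster import Cluster, ClusterConfig, Genome, generate_precursors
from .features import ConservationTrack
from .readprep import RawRead
from .structure import StructureFilterConfig, can_pair, fold, passes_structure_filters

MATURE_LEN = 22
LOOP_LEN = 8
SPACER_LEN = 78
ADAPTER = "TGGAATTCTCGGGTGCCAAGG"  # appended 3' of the biological insert
_READ_OFFSETS = (0, 1, 2)  # 5' start wobble within the mature sequence
_OFFSET_PROBS = (0.6, 0.25, 0.15)


@dataclass
class SyntheticSpec:
    """Study conditions for the synthetic dataset."""

    genome_length: int = 200_000  # total over 4 chromosomes incl. chr1_random
    n_known_mirnas: int = 20
    n_novel_mirnas: int = 15
    n_decoy_rnas: int = 30
    reads_per_sample: int = 50_000
    repression_fraction: float = 0.8
    fold_range: tuple[float, float] = (2.0, 10.0)
    background_fraction: float = 0.05
    star_read_rate: float = 0.05
    seed: int = 0


@dataclass
class PlantedLocus:
    name: str
    kind: str  # known_mirna | novel_mirna | decoy | trap
    chrom: str
    strand: str
    hairpin_start: int = 0
    hairpin_end: int = 0
    mature_start: int = 0
    mature_end: int = 0
    star_start: int = 0
    star_end: int = 0
    mature_seq: str = ""
    star_seq: str = ""
    hairpin_seq: str = ""
    arm: str = "5p"
    tier: str = ""  # decoys only: refseq_mrna | rfam
    lam_control: float = 0.0
    lam_treated: float = 0.0
    direction: str = ""  # repressed | induced

    @property
    def mature_locus(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.mature_start, self.mature_end, self.strand)

    @property
    def hairpin_locus(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.hairpin_start, self.hairpin_end, self.strand)


@dataclass
class GroundTruth:
    loci: list[PlantedLocus] = field(default_factory=list)

    def of_kind(self, *kinds: str) -> list[PlantedLocus]:
        return [l for l in self.loci if l.kind in kinds]

    def known_mature_loci(self) -> list[tuple[str, int, int, str]]:
        return [l.mature_locus for l in self.of_kind("known_mirna")]

    def expected_table(self) -> pd.DataFrame:
        rows = [
            {
                "name": l.name,
                "kind": l.kind,
                "chrom": l.chrom,
                "mature_start": l.mature_start,
                "mature_end": l.mature_end,
                "strand": l.strand,
                "lam_control": l.lam_control,
                "lam_treated": l.lam_treated,
                "direction": l.direction,
            }
            for l in self.loci
        ]
        return pd.DataFrame(rows)


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    genome: Genome
    tiers: dict[str, ReferenceTier]
    truth: GroundTruth

    def ordered_tiers(self) -> list[ReferenceTier]:
        """Annotation tiers in canonical order, genome last."""
        order = ["mature", "star", "star_unobserved", "hairpin", "refseq_mrna", "rfam"]
        tiers = [self.tiers[n] for n in order]
        tiers.append(ReferenceTier("genome", self.genome.sequences))
        return tiers


def _random_seq(rng: np.random.Generator, n: int, probs=(0.25, 0.25, 0.25, 0.25)) -> str:
    return "".join(rng.choice(list("ACGT"), size=n, p=list(probs)))


def _spacer(rng: np.random.Generator, n: int = SPACER_LEN) -> str:
    # A/C-biased: poor self-pairing, so planted stems dominate the window fold
    return "".join(rng.choice(list("AC"), size=n))


def _mutate_star(rng: np.random.Generator, mature: str, star: str, n_mut: int) -> str:
    """Introduce n_mut non-pairing positions into the star arm."""
    star_l = list(star)
    positions = rng.choice(len(star_l), size=min(n_mut, len(star_l)), replace=False)
    for p in positions:
        partner = mature[len(mature) - 1 - p]
        choices = [b for b in "ACGT" if not can_pair(b, partner) and b != star_l[p]]
        if choices:
            star_l[p] = choices[rng.integers(len(choices))]
    return "".join(star_l)


def _build_hairpin(
    rng: np.random.Generator, n_mut: int, probs=(0.2, 0.3, 0.3, 0.2)
) -> tuple[str, str, str, str, int]:
    """Returns (hairpin, mature, star, arm, mature_offset_in_hairpin)."""
    mature = _random_seq(rng, MATURE_LEN, probs=probs)
    loop = _spacer(rng, LOOP_LEN)
    star = _mutate_star(rng, mature, revcomp(mature), n_mut)
    if rng.random() < 0.5:
        arm = "5p"
        hairpin = mature + loop + star
        offset = 0
    else:
        arm = "3p"
        hairpin = star + loop + mature
        offset = len(star) + LOOP_LEN
    return hairpin, mature, star, arm, offset


def _window_check(
    unit: str, mature_off: int, mfe_margin: float = -28.0
) -> bool:
    """True when >=1 precursor window of the planted unit passes filters.

    The cluster is taken as the mature interval widened by the read
    start wobble; windows follow the default flank set.
    """
    cfg = ClusterConfig()
    sf = StructureFilterConfig()
    c_start = mature_off
    c_end = mature_off + MATURE_LEN + max(_READ_OFFSETS) - 2  # span of wobbled 20-nt reads
    genome = Genome({"unit": unit})
    for cand in generate_precursors(
        Cluster("unit", c_start, c_end, "+", []), genome, cfg
    ):
        s = fold(cand.window_sequence)
        ok, _ = passes_structure_filters(cand.cluster_offset, s, sf)
        if ok and s.mfe <= mfe_margin:
            return True
    return False


def plant_hairpins(spec: SyntheticSpec) -> SyntheticDataset:
    """Build the genome, annotation tiers and ground truth.

    Deterministic given ``spec.seed``; raises if non-overlapping
    placement is impossible within ``genome_length``.
    """
    rng = np.random.default_rng(spec.seed)
    random_len = max(5_000, spec.genome_length // 10)
    regular_len = (spec.genome_length - random_len) // 3
    chrom_names = ["chr1", "chr2", "chr3"]

    # --- generate loci (sequence level, rejection-sampled) ---
    loci: list[PlantedLocus] = []

    def make_locus(name: str, kind: str, n_mut_lo: int, n_mut_hi: int, tier: str = "") -> PlantedLocus:
        # decoys are weaker hairpins: AU-rich stems with more mismatches,
        # just past the structure filters rather than comfortably stable
        if kind == "decoy":
            probs, margin = (0.35, 0.15, 0.15, 0.35), -20.0
        else:
            probs, margin = (0.2, 0.3, 0.3, 0.2), -28.0
        for _ in range(200):
            n_mut = int(rng.integers(n_mut_lo, n_mut_hi + 1))
            hairpin, mature, star, arm, m_off = _build_hairpin(rng, n_mut, probs)
            spacer_l, spacer_r = _spacer(rng), _spacer(rng)
            unit = spacer_l + hairpin + spacer_r
            if _window_check(unit, SPACER_LEN + m_off, mfe_margin=margin):
                strand = "+" if rng.random() < 0.7 else "-"
                loc = PlantedLocus(
                    name=name, kind=kind, chrom="", strand=strand,
                    mature_seq=mature, star_seq=star, hairpin_seq=hairpin,
                    arm=arm, tier=tier,
                )
                loc._unit = unit  # type: ignore[attr-defined]
                loc._m_off = SPACER_LEN + m_off  # type: ignore[attr-defined]
                return loc
        raise RuntimeError(f"could not construct a filter-passing hairpin for {name}")

    for i in range(spec.n_known_mirnas):
        loci.append(make_locus(f"known_{i + 1}", "known_mirna", 1, 2))
    for i in range(spec.n_novel_mirnas):
        loci.append(make_locus(f"novel_{i + 1}", "novel_mirna", 1, 2))
    for i in range(spec.n_decoy_rnas):
        tier = "refseq_mrna" if i % 2 == 0 else "rfam"
        loci.append(make_locus(f"decoy_{i + 1}", "decoy", 2, 3, tier=tier))
    trap = make_locus("trap_1", "trap", 1, 2)

    # --- place loci on chromosomes ---
    chrom_seqs: dict[str, str] = {}
    order = rng.permutation(len(loci))
    per_chrom: dict[str, list[PlantedLocus]] = {c: [] for c in chrom_names}
    for idx, loc in enumerate(order):
        per_chrom[chrom_names[idx % 3]].append(loci[loc])

    def place(chrom: str, assigned: list[PlantedLocus], target_len: int) -> str:
        parts: list[str] = []
        cursor = 0
        n = len(assigned)
        gap_budget = max(0, target_len - n * (2 * SPACER_LEN + 60) - 200)
        base_gap = gap_budget // (n + 1) if n else target_len
        for loc in assigned:
            gap = _random_seq(rng, max(50, int(base_gap * rng.uniform(0.6, 1.4))))
            parts.append(gap)
            cursor += len(gap)
            unit: str = loc._unit  # type: ignore[attr-defined]
            m_off: int = loc._m_off  # type: ignore[attr-defined]
            placed = unit if loc.strand == "+" else revcomp(unit)
            loc.chrom = chrom
            unit_start = cursor
            h_len = len(loc.hairpin_seq)
            if loc.strand == "+":
                loc.hairpin_start = unit_start + SPACER_LEN
                loc.hairpin_end = loc.hairpin_start + h_len
                loc.mature_start = unit_start + m_off
                loc.mature_end = loc.mature_start + MATURE_LEN
            else:
                u_len = len(unit)
                loc.hairpin_end = unit_start + u_len - SPACER_LEN
                loc.hairpin_start = loc.hairpin_end - h_len
                loc.mature_end = unit_start + u_len - m_off
                loc.mature_start = loc.mature_end - MATURE_LEN
            parts.append(placed)
            cursor += len(placed)
        if cursor < target_len:
            parts.append(_random_seq(rng, target_len - cursor))
        return "".join(parts)

    for chrom in chrom_names:
        chrom_seqs[chrom] = place(chrom, per_chrom[chrom], regular_len)
    chrom_seqs["chr1_random"] = place("chr1_random", [trap], random_len)
    loci.append(trap)

    genome = Genome(chrom_seqs)

    # --- expression plan ---
    # all locus classes share one intensity distribution: expression depth
    # carries no class signal, so classification must rest on structure,
    # star signal and conservation
    weights = [rng.uniform(200, 1200) for _ in loci]
    scale = (1 - spec.background_fraction) * spec.reads_per_sample / sum(weights)
    for loc, w in zip(loci, weights):
        loc.lam_control = w * scale
        fold_c = rng.uniform(*spec.fold_range)
        if rng.random() < spec.repression_fraction:
            loc.direction = "repressed"
            loc.lam_treated = loc.lam_control / fold_c
        else:
            loc.direction = "induced"
            loc.lam_treated = loc.lam_control * fold_c

    # --- annotation tiers ---
    known = [l for l in loci if l.kind == "known_mirna"]
    mature_tier = {f"{l.name}_mature": l.mature_seq for l in known}
    star_obs = {f"{l.name}_star": l.star_seq for i, l in enumerate(known) if i % 2 == 0}
    star_unobs = {f"{l.name}_star": l.star_seq for i, l in enumerate(known) if i % 2 == 1}
    hairpin_tier = {f"{l.name}_hairpin": l.hairpin_seq for l in known}
    refseq = {}
    rfam = {}
    for l in loci:
        if l.kind != "decoy":
            continue
        # decoy "transcript": hairpin with a little flanking context
        transcript = _spacer(rng, 15) + l.hairpin_seq
        rec = {f"{l.name}_tx": transcript}
        (refseq if l.tier == "refseq_mrna" else rfam).update(rec)

    tiers = {
        "mature": ReferenceTier("mature", mature_tier),
        "star": ReferenceTier("star", star_obs),
        "star_unobserved": ReferenceTier("star_unobserved", star_unobs),
        "hairpin": ReferenceTier("hairpin", hairpin_tier),
        "refseq_mrna": ReferenceTier("refseq_mrna", refseq),
        "rfam": ReferenceTier("rfam", rfam),
    }
    return SyntheticDataset(spec, genome, tiers, GroundTruth(loci))


def simulate_reads(
    dataset: SyntheticDataset, raw_length: int = 25
) -> tuple[dict[str, list[RawRead]], pd.DataFrame]:
    """Simulate the two read lanes (control, treated).

    Per-locus read counts are Poisson around the planned intensities;
    reads start at a wobbled offset within the mature (or star)
    sequence, are ``raw_length`` nt long with adapter fill at the 3'
    end, and background reads are drawn from uniform random genome
    positions with count 1. Returns ({condition: reads}, realized
    count table). Deterministic given the dataset's seed.
    """
    spec = dataset.spec
    rng = np.random.default_rng(spec.seed + 1)
    conditions = {"control": "lam_control", "treated": "lam_treated"}
    reads: dict[str, list[RawRead]] = {c: [] for c in conditions}
    rows = []

    def emit(cond: str, prefix: str, template: str, n: int) -> None:
        if n <= 0 or len(template) < 20 + max(_READ_OFFSETS):
            return
        offsets = rng.multinomial(n, _OFFSET_PROBS)
        k = 0
        for off, cnt in zip(_READ_OFFSETS, offsets):
            insert = template[off : off + 20]
            seq = (insert + ADAPTER)[:raw_length]
            for _ in range(cnt):
                k += 1
                reads[cond].append(RawRead(f"{prefix}_{cond}_{k}", seq))

    for loc in dataset.truth.loci:
        realized = {}
        for cond, lam_attr in conditions.items():
            lam = getattr(loc, lam_attr)
            n = int(rng.poisson(lam))
            realized[cond] = n
            emit(cond, loc.name, loc.mature_seq, n)
            if loc.kind != "decoy":
                # only genuine miRNA loci shed star-strand reads; decoy
                # RNAs are not processed as Dicer duplexes
                n_star = int(rng.poisson(spec.star_read_rate * lam))
                emit(cond, loc.name + "_star", loc.star_seq, n_star)
        rows.append(
            {
                "name": loc.name,
                "kind": loc.kind,
                "direction": loc.direction,
                "count_control": realized["control"],
                "count_treated": realized["treated"],
            }
        )

    n_bg = int(spec.background_fraction * spec.reads_per_sample)
    chroms = list(dataset.genome.sequences)
    lengths = np.array([len(dataset.genome.sequences[c]) for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    for cond in conditions:
        for i in range(n_bg):
            ci = rng.choice(len(chroms), p=probs)
            chrom = chroms[ci]
            pos = int(rng.integers(0, len(dataset.genome.sequences[chrom]) - raw_length))
            strand = "+" if rng.random() < 0.5 else "-"
            seq = dataset.genome.fetch(chrom, pos, pos + raw_length, strand)
            reads[cond].append(RawRead(f"bg_{cond}_{i + 1}", seq))

    for cond in conditions:
        rng.shuffle(reads[cond])  # lanes are unordered
    return reads, pd.DataFrame(rows)


def make_conservation_track(dataset: SyntheticDataset) -> ConservationTrack:
    """Conservation scores: planted miRNA loci high, everything else low."""
    rng = np.random.default_rng(dataset.spec.seed + 2)
    intervals: list[tuple[str, int, int, float]] = []
    for loc in dataset.truth.loci:
        if loc.kind in ("known_mirna", "novel_mirna", "trap"):
            score = rng.uniform(0.8, 1.0)
        else:
            score = rng.uniform(0.0, 0.2)
        intervals.append((loc.chrom, loc.hairpin_start, loc.hairpin_end, round(score, 3)))
    # sparse low-score background intervals
    chroms = list(dataset.genome.sequences)
    for _ in range(50):
        chrom = chroms[rng.integers(len(chroms))]
        clen = len(dataset.genome.sequences[chrom])
        start = int(rng.integers(0, max(1, clen - 200)))
        intervals.append((chrom, start, start + 200, round(rng.uniform(0.0, 0.2), 3)))
    return ConservationTrack(intervals)


def write_bedgraph(track: ConservationTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track._by_chrom):
            for start, end, score in track._by_chrom[chrom]:
                fh.write(f"{chrom}\t{start}\t{end}\t{score}\n")


def write_fastq(reads: Sequence[RawRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def write_genome_fasta(genome: Genome, path) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_tier_fastas(dataset: SyntheticDataset, out_dir) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, tier in dataset.tiers.items():
        with open(out / f"{name}.fa", "w") as fh:
            for rid, seq in tier.records.items():
                fh.write(f">{rid}\n{seq}\n")


def simulate_expression_matrix(
    n_probes: int = 500,
    n_per_group: int = 3,
    n_de: int = 50,
    effect: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Synthetic probe x sample intensity matrix for the array module.

    ``n_de`` probes receive a +/-``effect`` log2 shift in the treated
    group; the rest are null. Returns (linear-scale intensities,
    group labels); probes are named p1..pN, DE probes first.
    """
    rng = np.random.default_rng(seed)
    base = rng.normal(8.0, 1.0, size=n_probes)
    log2 = np.tile(base[:, None], (1, 2 * n_per_group)) + rng.normal(
        0.0, 0.25, size=(n_probes, 2 * n_per_group)
    )
    signs = rng.choice([-1.0, 1.0], size=n_de)
    log2[:n_de, n_per_group:] += signs[:, None] * effect
    cols = [f"control_{i + 1}" for i in range(n_per_group)] + [
        f"treated_{i + 1}" for i in range(n_per_group)
    ]
    groups = ["control"] * n_per_group + ["treated"] * n_per_group
    df = pd.DataFrame(2.0 ** log2, index=[f"p{i + 1}" for i in range(n_probes)], columns=cols)
    return df, groups
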