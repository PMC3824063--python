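# Methods

This note documents the models and procedures `mirnforge` implements,
the parameters that matter, the synthetic study the tests run on, and
the choices made where the design was genuinely open. Nothing here
states a result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Alignment model

Reads are uniform-length (20 nt after trimming), so alignment is
ungapped, full-length placement. Mismatches are counted within the
first `seed_length = 17` bases of the read and capped at
`max_seed_mismatches = 2`; the trailing bases beyond the seed may
mismatch freely. Only hits in the best stratum (minimum seed
mismatches over all valid placements) are reported, and a read whose
best stratum exceeds `max_alignments = 6` placements is suppressed
entirely — retaining an arbitrary subset of a repetitive mapper's
hits would bias downstream cluster counts. A *stringent* preset
(≤ 3 placements, ≤ 1 seed mismatch) is used for expression
quantification. `N` counts as a mismatch on either side.

The aligner itself is an exhaustive per-position scan (vectorized
with numpy), exact by construction and adequate for the ≤ 1 Mb
genomes this package targets; the test suite checks it hit-for-hit
against an independently written per-character scan on a 50-kb
genome. An external-aligner adapter can be substituted behind the
same `AlignmentHit` contract for larger genomes.

Two strandedness rules: the genome is searched on both strands;
transcript tiers (mature, star, hairpin, mRNA, ncRNA families) are
searched sense-strand only, since a read deriving from those RNAs
matches their forward sequence. Without this distinction, star-strand
reads are claimed antisense by the mature tier and the star tiers
never see a read.

Tier order is fixed: mature → star → star-unobserved → hairpin →
mRNA → ncRNA families → genome, each read removed from the pool at
the first tier that accepts it. Identical seed/stratum/cap semantics
apply at every tier.

## Cluster and precursor construction

Clusters are maximal connected components of interval overlap among
genome hits per (chromosome, strand); touching-but-not-overlapping
intervals do not merge. Since member reads are uniformly 20 nt, the
20–27 nt miRNA-length constraint is read as a constraint on the
cluster's union span; clusters outside it are discarded (logged), and
test-set clusters additionally need a raw count ≥ 11. Training
clusters are genomic projections: reads claimed by the mature tier
(positive) or mRNA/ncRNA tiers (negative) are re-aligned to the
genome with the standard parameters, because all ten features are
defined on genomic windows. Positive candidates must additionally
overlap a known miRNA locus on the same strand.

Each cluster expands into one window per flank pair — default
(70, 20), (45, 45), (20, 70) in genomic coordinates — so that a
~110–115 nt window can host the mature sequence on either arm or
centered. Windows truncated below 60 nt at chromosome edges are
dropped. Minus-strand windows are reverse-complemented and the
cluster offset recomputed in window coordinates.

## Secondary-structure model

The internal folding engine is a Zuker-style dynamic program over a
deliberately small nearest-neighbor energy model:

* pair strengths GC = 1.7, AU = 1.1, GU = 0.6 kcal/mol; a stacked
  pair contributes −(strength(outer) + strength(inner));
* hairpin loops: 5.0 + 0.25·(size − 3), minimum size 3;
* bulge/interior loops: 3.0 + 0.3·size, total unpaired capped at 30;
* multiloops: 3.4 + 0.4 per branch (closing pair included) + 0.1 per
  unpaired base;
* exterior bases free; lonely pairs allowed; MFE of an unpairable
  sequence is 0.0.

The model's *definition* is the loop-decomposition scoring function
`score_structure`; the DP is verified in the tests by exhaustively
enumerating all structures of random sequences up to 25 nt and
minimizing that same scoring function — the oracle shares the energy
definition but not the minimization path. The DP tables are filled by
a numba-compiled kernel (O(n²·(L² + n)) with interior-loop cap L=30),
and the traceback reconstructs one MFE structure deterministically.
Energies are on a plausible kcal/mol scale but are not ViennaRNA's
Turner energies; for parity with published MFE values the RNAfold
adapter (`engine="vienna"`) can be used, and the −25 kcal/mol call
threshold applies to whichever backend is active.

Structure filters, in order: (1) exactly one terminal loop
(single-stem hairpin); (2) ≥ 19 base *pairs* in the window;
(3) ≥ 11 paired *positions* within the cluster interval — a 20–27 nt
cluster lying on one arm cannot contain 11 full pairs, so the
cluster-level rule must count paired nucleotides; (4, positive
training only) overlap with a known miRNA locus.

## Features

f1 paired positions in the cluster; f2 pairs in the precursor;
f3 cluster span (nt); f4 star expression; f5 cluster tag count;
f6 MFE (kcal/mol); f7 MFE / window length; f8 |unpaired on 5' arm −
unpaired on 3' arm|; f9 conservation; f10 unpaired positions outside
the outermost pair.

The star interval for f4 is derived from the fold: the region pairing
with the cluster, shifted by the canonical 2-nt 3' overhang of a
Dicer duplex, widened by ±3 nt for processing heterogeneity, and
counted as reads falling fully inside it. The read pool for f4 (and
for quantification) is a genome-wide map built by re-aligning *all*
collapsed reads to the genome — star reads claimed by annotation
tiers would otherwise be invisible to the feature.

f9 is the mean per-base conservation over the cluster from a
bedGraph-style track (sum selectable); "conservation of the locus" is
the reading consistent with its role as the top-ranked feature, the
alternative reading (read expression within conserved regions) being
redundant with f5. Absent a track, f9 is 0.0. f8 uses the absolute
difference; the signed value carries no extra information for a
symmetric classifier and is not fed to the model.

## Random-forest protocol

1000 trees; each tree's bag is ⌊0.66·n⌋ training rows drawn *without*
replacement, and each tree sees exactly 3 of the 10 features, fixed
for the whole tree (a per-split mtry=3 variant is available via
`ForestConfig(per_split=True)`). Trees are sklearn
`DecisionTreeClassifier`s grown to purity with Gini splits — the
conventional default; the bagging geometry, OOB aggregation and
importance computation are implemented here because they differ from
the standard bootstrap forest. For each training row, votes aggregate
only over trees whose bag excluded it; a candidate is positive iff
its positive-vote fraction strictly exceeds 0.5 (ties negative —
conservative for discovery). Importance permutes one feature among
each tree's OOB rows and reports the mean decrease in per-tree OOB
accuracy. All sampling is integer-indexed from one seeded generator,
so results are reproducible across platforms. Models are trained per
condition (control and treated separately).

## Novel calls and quantification

Positive candidates are discarded on chrUn\*/\*_random chromosomes or
when MFE > −25.0 kcal/mol (−25.0 itself passes). A call's locus and
mature sequence come from the parent cluster (highest-count member
read; lexicographic tie-break). Overlapping same-strand calls merge
into union loci keeping the best MFE, the maximum vote fraction, and
the mature sequence of the strongest cluster — a cluster's several
surviving windows necessarily collapse into one call. Cross-condition
"common" loci are same-strand overlaps of merged loci (exact
coordinate matching via flag).

RPM = raw count / total stringent-aligned reads × 10⁶, where a read
counts at a locus when ≥ 50% of it overlaps on the same strand, a
multi-mapped read contributes its full count at each of its ≤ 3 loci
(fractional weighting available), but counts once toward the total.
Direction: ratio > 1 induced, < 1 repressed, = 1 unchanged; a locus
with zero control signal is reported "undefined" and excluded from
ratio tables. No dispersion model is fitted: the design this serves
has one lane per condition.

## Microarray module

Raw intensities are log2-transformed, quantile-normalized (columns
forced to the mean sorted vector), and multi-row probes summarized by
median polish (≤ 10 alternating median sweeps, tolerance 1e-6; the
probe summary is overall + column effects). The statistic is
SNR = (mean_t − mean_c)/(sd_t + sd_c) with sample SDs floored at
max(0.01, floor_frac·|mean|); the tiny absolute floor only matters
when replicates are identical. The null is built by relabeling
samples n_perm = 10,000 times, pooling SNR values across probes
("sample/probe permutations"; per-probe nulls via
`pool_probes=False`, exact enumeration of all relabelings via
`exhaustive=True`). Random-mode p-values use the +1 pseudocount
estimator; exhaustive mode reports exact frequencies (the identity
labeling keeps p > 0). Significance: two-sided p ≤ 0.01 and
|linear fold change| ≥ 1.2, where FC = 2^Δlog2, sign-folded so the
absolute threshold reads the same in both directions.

## The synthetic study

Defaults: a 200-kb genome over chr1–chr3 plus a 20-kb `chr1_random`;
20 known miRNA hairpins (present in the annotation tiers and the
genome), 15 novel hairpins (genome only), 30 decoy RNAs (mRNA/ncRNA
tiers and genome), and one *trap* locus on `chr1_random` that looks
exactly like a novel miRNA — reads, strong hairpin, high conservation
— and must be eliminated by the chromosome post-filter, not by the
classifier. 50,000 reads per condition; 80% of loci repressed in the
treated lane by a fold drawn from (2, 10), the rest induced; 5%
uniform background reads from random genome positions; star-strand
reads at 5% of each miRNA locus's depth (decoys emit none — they are
not Dicer substrates). All locus classes draw expected depth from one
shared distribution (uniform 200–1200 expected reads) so that
expression level carries no class signal and classification must rest
on structure, star signal and conservation.

Hairpins are a GC-biased random 22-mer mature, an 8-nt A/C loop, and
an imperfect reverse complement (1–2 planted mismatches for miRNA
classes, 2–3 AU-rich for decoys), embedded between 78-nt A/C-biased
spacers and rejection-sampled until at least one precursor window
passes the structure filters with MFE ≤ −28 (miRNA classes; −20 for
decoys) — so true novel calls clear the −25 threshold with margin.
Reads start at a 0/+1/+2 wobble within the mature sequence
(probabilities 0.6/0.25/0.15), giving 22-nt clusters, and are emitted
as 25-nt raw reads with adapter fill to exercise trimming. Counts are
Poisson around the planned intensities; conservation scores are
0.8–1.0 over planted miRNA hairpins and 0.0–0.2 elsewhere.

What the generator does *not* emulate — and hence what passing tests
do not show about real data: sequencing errors beyond end wobble,
non-uniform read-length distributions, isomiR 5' heterogeneity beyond
+2, RNA editing, repeat-driven multi-mapping structure, realistic
genome composition (real flanks fold less cleanly than A/C spacers,
so real windows fail the single-stem rule more often), cross-mapping
between paralogous miRNA families, and thermodynamically calibrated
MFE values. Near-palindromic planted hairpins do reproduce one real
phenomenon: reads from one strand also align antisense on the other,
producing "shadow" calls at the same locus on the opposite strand —
the end-to-end metrics therefore score recovery on the same strand
but count a call as false only if it overlaps no planted hairpin on
either strand.

Problem sizes in the shipped tests and acceptance script (a 200-kb
genome with ~66 loci and 50k reads per lane, 50-kb oracle genomes,
200 training rows per class for the classifier simulation) were
chosen as the smallest scales at which every stage still has
non-trivial work — multi-mappers, filtered clusters, both strands,
tier fall-through — while a full run stays in the minutes range on
one CPU.

## Numerical and degenerate-input choices

Floating-point energies are compared with 1e-6 tolerance in the
traceback (all model constants have ≤ 2 decimals, so ties are exact).
Deterministic orderings everywhere: collapsed reads by (−count,
sequence); hits by (ref, start, strand); clusters by (chrom, start,
strand). Empty inputs return empty outputs (trim, collapse, classify,
merge); hard errors are reserved for contract violations
(single-class training, zero aligned total, missing chromosome,
unbalanced dot-bracket, non-positive intensities). Config defaults
equal the reference protocol throughout (trim 20; seed 17/2 mm/6
alignments; stringent 3/1; cluster span 20–27 and count ≥ 11; ≥ 19
and ≥ 11 pairing rules; 1000 trees / 0.66 bag / 3 features; MFE ≤
−25; p ≤ 0.01; |FC| ≥ 1.2; 10,000 permutations), and every stage
seeds from one `PipelineConfig.seed`.

## Known limitations

* The internal energy model is intentionally simple; its MFE values
  are comparable within a run but not to published Turner-model
  energies. Use the RNAfold backend when absolute energies matter.
* The exhaustive aligner scales as genome × reads; it is a reference
  implementation for desk-scale genomes, not a bowtie replacement.
* "Unobserved star" derivation assumes the canonical 2-nt 3' overhang
  and ≥ 50% mature pairing; non-canonical Drosha/Dicer products are
  out of scope.
* One lane per condition means the induced/repressed call is a point
  ratio with no significance attached; the microarray module, which
  has replicates, is where inference happens.
* The trap-locus construction covers chrUn/\*_random exclusion but
  not other assembly artifacts (alt haplotypes, decoy contigs).
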