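# Methods

## Model and procedure

`dualref` targets somatic single-nucleotide variants in an individual with
a highly heterozygous diploid genome, sequenced with paired short reads
from two tissues (a "mutant" and a "control" sample, called reciprocally)
and assembled into both a pseudo-haploid and a phased diploid reference.

**Read assignment.** Every read is aligned to both references; the record
pair is compared by alignment score (BWA convention: +1 per match, −4 per
mismatch, so an ungapped read of length L with m mismatches scores
L − 5m), then by MAPQ, and a full tie goes to the diploid assembly.
Rationale: a het site inside a read is a −5 swing against the haploid
reference, so haplotype-distinct spans sort to the diploid assembly by
score; haplotype-identical spans have two equally good diploid placements
(MAPQ 0) and sort to the haploid assembly by MAPQ; reads from sequence
present only in one haplotype map on only one side. Assignment is per
read (per mate), not per fragment; mates may split. Only primary
alignments are compared; clipped reads and duplicate-flagged reads are
removed from both outputs after the decision is logged. A MAPQ of 255
("unavailable") loses ties to any numeric MAPQ.

**Pileup counting.** A bam-readcount-style engine counts, per position,
per-allele read support with forward/reverse splits, mean base quality and
the mean per-read mismatch fraction (NM divided by aligned length, M/=/X
only). A read whose deletion spans the position, or whose insertion is
anchored at it (insertions belong to the base on their left), contributes
indel evidence and no base. Overlapping mates count twice (bam-readcount's
default); duplicates never count. The mismatch fraction deliberately does
*not* subtract the candidate variant base: the differential filter below
absorbs the variant's own 1/read_len ≤ 0.01 contribution for reads of
≥ 100 bp.

**Somatic calling.** The control sample is counted leniently (MAPQ ≥ 0,
BQ ≥ 0) so that *any* alternate evidence, however weak, disqualifies a
position — minimising false negatives on the control side. Control
positions require depth ≥ 20× in diploid mode or > 40× (≥ 41) in haploid
mode, no indel evidence, and zero non-reference bases (configurable
`max_control_alt`, default 0). The mutant sample is counted stringently
(MAPQ ≥ 10, BQ ≥ 30); a candidate becomes a call iff, in order: its
position is control-licensed; depth ≤ 70× (diploid) / ≤ 120× (haploid);
no indel evidence; exactly two observed alleles (reference plus one
alternate — sites with no reference reads are rejected, their mismatch
mean being undefined); ≥ 3 alternate reads with at least one on each
strand; reference-read mean mismatch ≤ 0.01; and alternate-minus-reference
mean mismatch ≤ 0.01. Coverage caps are applied to post-threshold depth.
Inequalities follow the printed thresholds literally: "≥ 20×" is
inclusive, "> 40×" strict, "≤ 70×/≤ 120×" inclusive.

**Merging.** Haploid- and diploid-mode calls are united on shared
coordinates. For synthetic genomes the haplotypes are length-collinear, so
the coordinate map is the identity onto the two haplotype contigs, minus
divergent blocks (hapB-only sequence with no haploid image). Same site +
same alternate collapse with dual provenance; same site + different
alternates are both kept and flagged as conflicting; unmappable diploid
calls keep diploid coordinates. A flank-based map builder (unique exact
matching of ±100 bp context) covers non-synthetic inputs.

**Effective sites** — the rate denominator — count control-sample
diploid-mode positions with depth strictly above 20×.

**Mismap classification.** For a diploid-placed read, the window is its
footprint ±2 kb (clipped at contig ends), aligned to the haploid assembly
by a pluggable aligner contract (query, targets → best local footprint +
score). Footprints spanning < 4 kb (strictly: 3,999 bp undefined, 4,000 bp
defined) yield `undefined`; otherwise the verdict is `proper` iff the
read's direct haploid start position lies inside the footprint, `improper`
otherwise — including the case of a confidently anchored window whose read
has no direct haploid alignment at all. Two aligners are provided: exact
substring search (used in tests, exact for windows drawn verbatim from the
searched assembly) and an edlib infix aligner that tolerates the het
mismatch load of real windows and rejects alignments above 25% divergence
(so half-divergent windows go `undefined` rather than being force-fitted).
Multi-target ties resolve to the first-best target; how the original
analysis resolved equally good placements is unknown, and the contract
makes the policy replaceable.

**Germline cross-check.** Short-read germline variants enter the check iff
depth ∈ [0.5, 2] × sample mean (inclusive), VAF ≥ 0.3 and FILTER=PASS; a
variant is "reproduced" iff ≥ 5 long reads support the alternate allele.
The result reports the not-reproduced fraction stratified by VAF bin.

**Layer model and rates.** If leaf/embryo-shared mutations (which must
derive from L2) have median VAF v, then L2 contributes 2v of sample DNA,
L1+L3 contribute 1 − 2v, and L1 < L3 bounds L1 at half that remainder —
so with v = 0.3: L2 = 60%, L1 < 20%, L1-fixed VAF < 0.1. The median is
used (mean available as an option). Transmissible (L2-consistent) calls
are those with VAF ≥ 0.2 (haploid mode) or ≥ 0.4 (diploid mode, where
per-contig coverage halves and VAF doubles). Rates: raw = n /
effective_sites; annual = raw / age; generational = annual ×
generation_time — a lower bound, since mutations postdating the sampled
branch are mostly invisible. Values are reported in scientific notation
at 2 significant digits by default (1 for the headline comparisons).
Spectra fold purine-reference substitutions onto the pyrimidine strand
into the six classes C>A…T>G, reported also in both-strand notation
(C>T ≡ C:G>T:A).

## The synthetic data generator

The generator reproduces the *structure* of the study system, not its
full complexity:

* **Genome**: uniform random sequence; het SNVs drawn per-base at
  `het_rate` (default 0.016, the kmer-based genome-wide estimate for the
  oak the method was built on); divergent blocks replace hapB with
  unrelated same-length sequence (modelling the ~9% of reads mappable only
  to the diploid assembly, while keeping coordinates collinear). One
  1 Mb-scale chromosome suffices for every test; defaults `n_chrom=1`.
* **Somatic implants**: fixed in one layer (default DNA fractions L1 18%,
  L2 60%, L3 22%) on one haplotype; expected VAF =
  `layer_fraction × cell_fraction / 2`. Positions avoid het sites,
  divergent blocks, chromosome ends (one read length) and one another (at
  least one read length apart — two implants inside one read would give
  carrier reads NM = 2 and trip the mismatch-delta filter, an artefact of
  desk-scale implant density that real genomes, with mutations orders of
  magnitude sparser, cannot produce).
* **Reads**: 150 bp pairs, insert 400 ± 60 bp (the study's read length and
  insert geometry are not published; these are ordinary modern short-read
  values), fragments uniform, haplotype fair-coin, layer drawn by DNA
  fraction; substitution errors only, at `error_rate` (default 0.1%),
  with Q20 at error positions and Q38 elsewhere so the BQ ≥ 30 filter has
  sub-threshold bases to act on. Indel errors and clipped reads are not
  simulated; dedicated fixtures inject them where the filters need
  positive cases.
* **Truth alignments**: ungapped, unclipped, placed at the true position;
  AS/NM computed by direct sequence comparison; MAPQ 60 unless the span is
  haplotype-identical in diploid mode (then 0); hapB reads overlapping a
  divergent block are unmapped in haploid mode. Identical seeds give
  byte-identical FASTQ/SAM.

What passing tests therefore do **not** show: robustness to real aligner
behaviour (soft clipping, gapped alignment, MAPQ shades between 0 and 60),
indel errors, clustered heterozygosity, GC-coverage bias, or PCR
duplicates. The generator's role is to make the *logic* of every stage
falsifiable against known truth, not to certify performance on real data.

## Numerical and design choices

* Per-site depth of uniform random fragments is Poisson; coverage checks
  use Poisson intervals around the target depth rather than fixed bands.
* Thresholds are exact integer/float comparisons at the printed values;
  boundary tests pin each one (19/20, 40/41, 70/71, 120/121, 2/3, 29/30,
  9/10, 0.01/0.011, 4/5, 0.5×/2×, 0.3, 3999/4000).
* All randomness flows through `numpy.random.default_rng`; compound runs
  derive child seeds (< 2³¹) from one integer via `SeedSequence`.
* Truth emission declares a read unmapped when it derives from hapB inside
  a divergent block; everything else maps (the mismatch load of het sites
  never approaches an aligner's score floor at 1.6% heterozygosity).
* Reciprocal mutant/control calling cannot overlap by construction: each
  direction requires the other sample to be confidently reference.

## Problem sizes

Tests and the acceptance script run on one CPU in a few minutes using
100–200 kb chromosomes at 60× (1 Mb for the genome-wide het-count and
effective-sites checks): coverage statistics per site are independent of
chromosome length, so these sizes measure the same per-site behaviour as a
full genome while keeping every run seedable and fast.

## Known limitations

* The caller's sensitivity dead band is structural: sites whose ±150 bp
  neighbourhood is het-poor send most reads to the haploid reference, can
  leave the diploid contig below the 20× control floor, and may also miss
  the > 40× haploid control floor at 60× total depth — under uniform 1.6%
  heterozygosity this affects roughly one implant in ten. On real
  (clustered-het) genomes the two modes partition the genome less evenly.
* Strand-support filtering stochastically drops true variants with few
  alternate reads (all-one-strand probability 2 × 0.5ⁿ).
* The manual inspection step of the original workflow (retaining a subset
  of calls after visual review) is not algorithmically specified and is
  not reproduced; call counts here correspond to the pre-inspection stage.
* False-negative-rate modelling, realistic indel/SV simulation, and
  invoking external aligners inside tests are out of scope.
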