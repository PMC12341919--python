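# dualref

Somatic SNV detection in highly heterozygous genomes using **two**
references at once: a pseudo-haploid assembly and a (partially) phased
diploid assembly of the same individual.

## The problem

In long-lived plants, most somatic mutations are confined to one clonally
segregated meristem layer (L1 epidermis, L2 photosynthetic/germ tissue, L3
ground tissue), so even a mutation *fixed* in a layer appears in
whole-leaf sequencing at a low variant allele frequency — about
`layer_dna_fraction / 2`, since it also sits on only one haplotype.
Detecting such variants is squeezed from both sides by the reference
choice:

* against a **haploid** assembly, reads from the divergent haplotype pick
  up het sites as mismatches (BWA: +1 match / −4 mismatch) and can mismap,
  inflating false positives and hiding regions absent from the assembly;
* against a **diploid** assembly, haplotype-identical regions give MAPQ 0
  and coverage is halved, hiding exactly the low-frequency variants of
  interest.

`dualref` implements the dual-reference strategy: align to both, then
assign each read to one reference by the hierarchy **higher alignment
score → higher MAPQ → diploid default**, drop clipped reads, and call
somatic SNVs in each mode with a control-masked stringent filter cascade
before merging the two call sets on shared coordinates:

* control sample counted leniently (MAPQ ≥ 0, BQ ≥ 0); control positions
  require depth ≥ 20× (diploid mode) or > 40× (haploid mode), no indels,
  zero non-reference bases;
* mutant sample counted stringently (MAPQ ≥ 10, BQ ≥ 30); calls require
  depth ≤ 70× / ≤ 120×, a biallelic site without indels, ≥ 3 alternate
  reads on both strands, reference-read mean mismatch ≤ 0.01 and an
  alt−ref mismatch difference ≤ 0.01.

On top of the caller sit a flank-window mismap classifier
(proper/improper/undefined by whether a read's direct haploid placement
falls inside the ≥ 4 kb haploid footprint of its ±2 kb diploid context), a
short-read vs HiFi germline cross-check, and the meristem-layer VAF model
that turns shared-SNV VAFs into layer DNA fractions, transmissibility
thresholds (VAF ≥ 0.2 haploid / ≥ 0.4 diploid), and per-site, annual and
generational mutation rates.

Everything is exercisable without external data: the `simulate` module
generates diploid genomes (~1.6% heterozygosity, haplotype-divergent
blocks), layer-structured somatic implants, paired short reads with
errors, and deterministic truth alignments carrying BWA-convention AS/NM
tags and a unique-60/ambiguous-0 MAPQ model.

## Worked example

```bash
python examples/05_layer_model_and_rates.py
```

```
L2 fraction 60%  L1+L3 40%  L1 VAF bound 0.10
L2-consistent calls: 2/3 (thresholds: hap >=0.2, dip >=0.4)
raw rate          6e-08 per bp
annual rate       2.5e-10 per bp per year
generational rate 1.3e-08 per bp per generation
spectrum: {'C:G>A:T': 1, 'C:G>T:A': 2}
```

A median shared-SNV VAF of 0.3 means the mutant (L2) cell lineage holds
60% of the sample DNA, leaving ≤ 20% for L1 and hence a VAF ceiling of 0.1
for L1-fixed mutations; 77 transmissible mutations over 1.3 Gb of
effective sites in a 234-year-old tree give ≈ 6 × 10⁻⁸ mutations per site,
≈ 2.5 × 10⁻¹⁰ per site per year, and ≈ 1.3 × 10⁻⁸ per site per 50-year
generation.

The other examples walk the pipeline end to end on synthetic data:

```bash
python examples/03_somatic_calling.py
```

```
haploid : control positions    4546  calls 1
diploid : control positions  252539  calls 14
merged calls: 15  implants recovered: 15/20
effective sites (diploid control > 20x): 253,134
  chr1_hapA:2372 A>C  VAF 0.59  alt 19 (10F/9R)
  ...
```

Diploid-mode VAFs sit near 0.6 because the haplotype contig carrying an
L2 mutation holds only that haplotype's reads — the basis of the doubled
(0.4) diploid-mode transmissibility threshold.

A thin CLI mirrors the library (`dualref simulate / assign / pileup /
call / merge / mismap / rate / spectrum`); run `dualref --help`.

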