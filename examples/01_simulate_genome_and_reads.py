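"""Simulate a heterozygous diploid genome with layer-structured somatic
mutations and paired short reads, and inspect the implanted truth.

The genome carries ~1.6% SNV heterozygosity plus one divergent block where
hapB has no counterpart in the haploid assembly.  Somatic SNVs are fixed in
one meristem layer on one haplotype, so an L2 mutation (60% of leaf DNA) is
expected at a whole-sample VAF of 0.3.
"""

from dualref import (
    implant_somatic_mutations,
    simulate_diploid_genome,
    simulate_reads,
)

genome = simulate_diploid_genome(
    chrom_len=100_000, het_rate=0.016, divergent_spec=[5_000], seed=1
)
print(f"genome: {len(genome.het_variants)} het SNVs, blocks {genome.divergent_blocks}")

implants = implant_somatic_mutations(genome, n_per_layer={"L2": 5, "L1": 2}, seed=2)
truth = simulate_reads(genome, implants, depth=60, error_rate=0.001, seed=3)
print(f"reads: {truth.n_fragments} fragments ({2 * truth.n_fragments} mates) at 60x")

for imp in implants:
    counts = truth.raw_allele_counts(imp.chrom, imp.pos0)
    depth = sum(counts.values())
    vaf = counts.get(imp.alt_allele, 0) / depth
    print(
        f"  {imp.layer} {imp.chrom}:{imp.pos0 + 1} {imp.ref_allele}>{imp.alt_allele} "
        f"hap{imp.haplotype}  expected VAF {imp.expected_vaf:.2f}  observed {vaf:.2f}"
    )
# Observed VAFs scatter binomially around the layer expectation: ~0.3 for
# L2 (transmissible candidates), ~0.09 for L1 (below the 0.1 bound).
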