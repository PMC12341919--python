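"""Assign each read to the haploid or the diploid reference.

Reads spanning a het site score higher on their own haplotype contig
(each het is a -5 swing under BWA's +1/-4 scoring), so they go to the
diploid assembly; reads from haplotype-identical spans have MAPQ 0 there
and go to the haploid assembly; divergent-block hapB reads only map to the
diploid assembly at all.
"""

from collections import Counter

from dualref import partition_alignments, simulate_diploid_genome, simulate_reads
from dualref.simulate import emit_truth_alignments

genome = simulate_diploid_genome(chrom_len=100_000, het_rate=0.016, divergent_spec=[5_000], seed=1)
truth = simulate_reads(genome, [], depth=30, seed=2)
hap = emit_truth_alignments(truth, "haploid")
dip = emit_truth_alignments(truth, "diploid")

res = partition_alignments(hap, dip)
print(f"haploid set {len(res.haploid)}  diploid set {len(res.diploid)}  excluded {len(res.excluded)}")
reasons = Counter((d.assigned_to, d.reason) for d in res.decisions)
for (side, reason), n in sorted(reasons.items()):
    print(f"  {side:8s} {reason:16s} {n}")
# 'mapq' decisions are haplotype-identical spans rescued for the haploid
# reference; 'score' decisions are hapB reads pulled to the diploid
# assembly; 'only_mapped_one' are divergent-block reads with no haploid home.
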