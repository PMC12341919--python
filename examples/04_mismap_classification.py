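"""Flank-based mismap detection: is a read's direct haploid placement where
its diploid-assembly context says it should be?

Each diploid-placed read defines a window (footprint +/- 2 kb) that is
aligned to the haploid assembly; the read is 'proper' if its direct haploid
position falls inside the window's haploid footprint, 'improper' otherwise,
and 'undefined' when the footprint spans under 4 kb.  Here we also plant a
fake 50 kb displacement to show the improper verdict firing.
"""

from collections import Counter
from dataclasses import replace

from dualref import ExactSubstringAligner, classify_read_mapping
from dualref import simulate_diploid_genome, simulate_reads
from dualref.simulate import emit_truth_alignments

genome = simulate_diploid_genome(chrom_len=100_000, het_rate=0.0, seed=21)
truth = simulate_reads(genome, [], depth=4, error_rate=0.0, seed=22)
dip = emit_truth_alignments(truth, "diploid")
hap = {r.key: r for r in emit_truth_alignments(truth, "haploid")}
aligner = ExactSubstringAligner()

verdicts = Counter()
for r in dip[:400]:
    v = classify_read_mapping(r, genome.diploid_refs(), hap[r.key], genome.haploid_refs(), aligner)
    verdicts[v.verdict] += 1
print("clean data:", dict(verdicts))

r = next(x for x in dip if 20_000 < x.pos0 < 30_000)
displaced = replace(hap[r.key], pos0=hap[r.key].pos0 + 50_000)
v = classify_read_mapping(r, genome.diploid_refs(), displaced, genome.haploid_refs(), aligner)
print(f"planted 50 kb displacement -> {v.verdict}; expected {v.expected_interval}, observed {v.observed_position}")
# On paralogy-free data every full-length window is proper ('undefined'
# only near contig ends where the window is clipped below 4 kb).
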