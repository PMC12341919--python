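"""Run the full dual-reference somatic caller on a mutant/control pair.

The mutant sample carries 20 L2-fixed implants; the control has none.
The control is counted leniently (MAPQ>=0, BQ>=0) to build the
control-position mask, the mutant stringently (MAPQ>=10, BQ>=30), and the
filter cascade (coverage caps, biallelic, >=3 alt reads on both strands,
mismatch-profile filters) runs in both reference modes before merging.
"""

from dualref.pipeline import recovered_implants, run_synthetic_experiment

res = run_synthetic_experiment(
    seed=11, chrom_len=150_000, n_per_layer={"L2": 20}, depth=60
)
for mode in ("haploid", "diploid"):
    mr = res.by_mode[mode]
    print(f"{mode:8s}: control positions {len(mr.control_set):7d}  calls {len(mr.calls)}")
rec = recovered_implants(res)
print(f"merged calls: {len(res.merged)}  implants recovered: {sum(rec.values())}/{len(rec)}")
print(f"effective sites (diploid control > 20x): {res.effective_sites():,}")
for c in res.by_mode["diploid"].calls[:5]:
    print(f"  {c.ref_name}:{c.pos1} {c.ref_allele}>{c.alt_allele}  VAF {c.vaf:.2f}  alt {c.alt_count} ({c.alt_fwd}F/{c.alt_rev}R)")
# Diploid-mode VAFs sit near 0.6 (the implant haplotype carries the
# mutation in the 60% L2 fraction and the contig holds only that
# haplotype's reads); a few implants in het-poor spans lack diploid
# control coverage and are picked up, if at all, by the haploid mode.
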