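"""Generator correctness: genome drawing, implants, reads, truth alignments."""

import numpy as np
import pysam
import pytest
from scipy import stats

from dualref import samio
from dualref.core import DEFAULT_SCORING, seq_to_array
from dualref.simulate import (
    DEFAULT_LAYER_FRACTIONS,
    emit_truth_alignments,
    implant_somatic_mutations,
    reference_lengths,
    simulate_diploid_genome,
    simulate_reads,
)


class TestDiploidGenome:
    def test_zero_het_rate_gives_identical_haplotypes(self):
        g = simulate_diploid_genome(chrom_len=20_000, het_rate=0.0, seed=1)
        assert np.array_equal(g.hapA["chr1"], g.hapB["chr1"])
        assert g.het_variants == [] and g.divergent_blocks == []

    def test_het_count_within_binomial_interval(self):
        # central 99.9% binomial interval for n=1e6, p=0.016
        g = simulate_diploid_genome(chrom_len=1_000_000, het_rate=0.016, seed=2)
        lo, hi = stats.binom.ppf([0.0005, 0.9995], 1_000_000, 0.016)
        assert lo <= len(g.het_variants) <= hi

    def test_haplotypes_differ_exactly_at_recorded_sites(self):
        g = simulate_diploid_genome(chrom_len=20_000, het_rate=0.01, divergent_spec=[1000], seed=3)
        diff = np.nonzero(g.hapA["chr1"] != g.hapB["chr1"])[0]
        allowed = {v.pos0 for v in g.het_variants}
        for _, s, e in g.divergent_blocks:
            allowed |= set(range(s, e))
        assert set(diff) <= allowed
        # het records must all be true differences
        for v in g.het_variants:
            assert g.hapA[v.chrom][v.pos0] != g.hapB[v.chrom][v.pos0]

    def test_oversized_divergent_blocks_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            simulate_diploid_genome(chrom_len=10_000, divergent_spec=[6000, 6000], seed=1)

    @pytest.mark.parametrize("bad", [-0.01, 0.06])
    def test_het_rate_validated(self, bad):
        with pytest.raises(ValueError):
            simulate_diploid_genome(chrom_len=20_000, het_rate=bad, seed=1)


@pytest.fixture(scope="module")
def genome():
    return simulate_diploid_genome(chrom_len=50_000, het_rate=0.016, seed=4)


class TestImplants:

    def test_expected_vaf_formula(self, genome):
        imps = implant_somatic_mutations(genome, n_per_layer=5, cell_fraction=1.0, seed=1)
        by_layer = {i.layer: i.expected_vaf for i in imps}
        # L2 fixed in a 60% layer -> VAF 0.3; L1 (18%) -> 0.09, below 0.1
        assert by_layer["L2"] == pytest.approx(0.3)
        assert by_layer["L1"] == pytest.approx(0.09) and by_layer["L1"] < 0.1
        assert by_layer["L3"] == pytest.approx(0.11)

    def test_zero_implants_leaves_genome_untouched(self, genome):
        before = genome.hapA["chr1"].copy()
        assert implant_somatic_mutations(genome, n_per_layer=0, seed=1) == []
        assert np.array_equal(genome.hapA["chr1"], before)

    def test_positions_avoid_het_sites_blocks_and_each_other(self):
        g = simulate_diploid_genome(chrom_len=50_000, het_rate=0.016, divergent_spec=[3000], seed=5)
        imps = implant_somatic_mutations(g, n_per_layer=10, seed=2, min_distance=150)
        het = {v.pos0 for v in g.het_variants}
        pos = sorted(i.pos0 for i in imps)
        assert not (set(pos) & het)
        assert all(not g.in_divergent_block("chr1", p) for p in pos)
        assert min(b - a for a, b in zip(pos, pos[1:])) >= 150

    def test_too_many_implants_rejected(self, genome):
        with pytest.raises(ValueError):
            implant_somatic_mutations(genome, n_per_layer=10_000, seed=1)

    def test_ref_allele_matches_haplotype(self, genome):
        for imp in implant_somatic_mutations(genome, n_per_layer=5, seed=3):
            hap = genome.hapA if imp.haplotype == "A" else genome.hapB
            assert chr(hap[imp.chrom][imp.pos0]) == imp.ref_allele
            assert imp.alt_allele != imp.ref_allele


class TestReads:
    def test_error_free_reads_are_exact_substrings(self):
        g = simulate_diploid_genome(chrom_len=20_000, het_rate=0.016, seed=6)
        truth = simulate_reads(g, [], depth=10, error_rate=0.0, seed=1)
        b = truth.batches["chr1"]
        for i in range(0, b.n, 37):
            hap = g.hapA["chr1"] if b.hap[i] == 0 else g.hapB["chr1"]
            s1 = b.mate_starts(1, truth.read_len)[i]
            s2 = b.mate_starts(2, truth.read_len)[i]
            assert np.array_equal(b.r1[i], hap[s1 : s1 + truth.read_len])
            assert np.array_equal(b.r2[i], hap[s2 : s2 + truth.read_len])

    def test_mean_depth_matches_requested_coverage(self):
        g = simulate_diploid_genome(chrom_len=100_000, het_rate=0.0, seed=7)
        truth = simulate_reads(g, [], depth=60, seed=2)
        cov = np.zeros(100_000)
        b = truth.batches["chr1"]
        for mate in (1, 2):
            st = b.mate_starts(mate, truth.read_len)
            np.add.at(cov, st, 1)
            np.add.at(cov, st + truth.read_len, -1)
        mean_depth = np.cumsum(cov)[:-1].mean()
        assert abs(mean_depth - 60) / 60 < 0.05

    def test_observed_vaf_within_binomial_interval(self):
        g = simulate_diploid_genome(chrom_len=100_000, het_rate=0.016, seed=8)
        imps = implant_somatic_mutations(g, n_per_layer={"L2": 10}, seed=3)
        truth = simulate_reads(g, imps, depth=100, seed=4)
        for imp in imps:
            counts = truth.raw_allele_counts(imp.chrom, imp.pos0)
            depth = sum(counts.values())
            alt = counts.get(imp.alt_allele, 0)
            lo, hi = stats.binom.ppf([0.005, 0.995], depth, imp.expected_vaf)
            assert lo <= alt <= hi

    def test_mean_vaf_bias_small_over_many_implants(self):
        # >=50 implants at depth 100: mean(observed - expected VAF) within 0.02
        g = simulate_diploid_genome(chrom_len=200_000, het_rate=0.016, seed=9)
        imps = implant_somatic_mutations(
            g, n_per_layer={"L1": 17, "L2": 17, "L3": 16}, seed=5
        )
        truth = simulate_reads(g, imps, depth=100, seed=6)
        deltas = []
        for imp in imps:
            counts = truth.raw_allele_counts(imp.chrom, imp.pos0)
            depth = sum(counts.values())
            deltas.append(counts.get(imp.alt_allele, 0) / depth - imp.expected_vaf)
        assert abs(np.mean(deltas)) <= 0.02

    def test_error_positions_get_low_quality(self):
        g = simulate_diploid_genome(chrom_len=20_000, het_rate=0.0, seed=10)
        truth = simulate_reads(g, [], depth=20, error_rate=0.01, seed=7)
        b = truth.batches["chr1"]
        ref = g.hapA["chr1"]
        s1 = b.mate_starts(1, truth.read_len)
        for i in range(0, b.n, 11):
            mism = b.r1[i] != ref[s1[i] : s1[i] + truth.read_len]
            assert np.all(b.q1[i][mism] == 20)
            assert np.all(b.q1[i][~mism] == 38)

    def test_parameter_validation(self):
        g = simulate_diploid_genome(chrom_len=20_000, seed=1)
        with pytest.raises(ValueError):
            simulate_reads(g, [], depth=0)
        with pytest.raises(ValueError):
            simulate_reads(g, [], read_len=500, insert_mean=400)


@pytest.fixture(scope="module")
def setup():
    g = simulate_diploid_genome(chrom_len=30_000, het_rate=0.016, divergent_spec=[2000], seed=11)
    imps = implant_somatic_mutations(g, n_per_layer={"L2": 3}, seed=8)
    truth = simulate_reads(g, imps, depth=15, error_rate=0.002, seed=9)
    return g, truth


class TestTruthAlignments:

    @pytest.mark.parametrize("mode", ["haploid", "diploid"])
    def test_record_conservation(self, setup, mode):
        g, truth = setup
        recs = emit_truth_alignments(truth, mode)
        assert len(recs) == 2 * truth.n_fragments

    def test_alignment_score_examples(self):
        # 100 bp with one mismatch scores 95; a perfect read scores 100
        assert DEFAULT_SCORING.alignment_score(99, 1) == 95
        assert DEFAULT_SCORING.alignment_score(100, 0) == 100

    @pytest.mark.parametrize("mode", ["haploid", "diploid"])
    def test_scores_match_brute_force_rescoring(self, setup, tmp_path, mode):
        """AS/NM of every emitted record equal an independent re-scoring of
        SEQ against the reference FASTA, going through the written SAM."""
        g, truth = setup
        recs = emit_truth_alignments(truth, mode)
        sam = tmp_path / f"{mode}.sam"
        samio.write_sam(sam, recs, reference_lengths(g, mode))
        refs = g.haploid_refs() if mode == "haploid" else g.diploid_refs()
        n_checked = 0
        with pysam.AlignmentFile(str(sam)) as fh:
            for seg in fh:
                if seg.is_unmapped:
                    continue
                ref = refs[seg.reference_name]
                sub = ref[seg.reference_start : seg.reference_end]
                read = seq_to_array(seg.query_sequence)
                mism = int((read != sub).sum())
                assert seg.get_tag("NM") == mism
                assert seg.get_tag("AS") == len(read) - 5 * mism
                n_checked += 1
        assert n_checked > 1000

    def test_divergent_block_hapB_reads_unmapped_in_haploid_mode(self, setup):
        g, truth = setup
        (chrom, s, e) = g.divergent_blocks[0]
        recs = {(r.read_id, r.mate_index): r for r in emit_truth_alignments(truth, "haploid")}
        b = truth.batches[chrom]
        rl = truth.read_len
        n_blocked = 0
        for mate in (1, 2):
            st = b.mate_starts(mate, rl)
            for i in range(b.n):
                overlaps = st[i] < e and st[i] + rl > s
                r = recs[(truth.read_id(chrom, i), mate)]
                if b.hap[i] == 1 and overlaps:
                    assert not r.is_mapped
                    n_blocked += 1
                else:
                    assert r.is_mapped
        assert n_blocked > 0

    def test_diploid_mapq_reflects_haplotype_distinguishability(self, setup):
        g, truth = setup
        het_cum = np.concatenate([[0], np.cumsum(g.het_mask("chr1"))])
        blk_cum = np.concatenate([[0], np.cumsum(g.block_mask("chr1"))])
        rl = truth.read_len
        seen = {0: 0, 60: 0}
        for r in emit_truth_alignments(truth, "diploid"):
            s = r.pos0
            distinct = (het_cum[s + rl] - het_cum[s] > 0) or (blk_cum[s + rl] - blk_cum[s] > 0)
            assert r.mapq == (60 if distinct else 0)
            seen[r.mapq] += 1
        assert seen[0] > 0 and seen[60] > 0

    def test_byte_identical_outputs_for_identical_seeds(self, tmp_path):
        def build(tag):
            g = simulate_diploid_genome(chrom_len=10_000, het_rate=0.016, seed=42)
            imps = implant_somatic_mutations(g, n_per_layer={"L2": 2}, seed=43)
            truth = simulate_reads(g, imps, depth=8, seed=44)
            r1, r2 = tmp_path / f"{tag}.R1.fq", tmp_path / f"{tag}.R2.fq"
            truth.write_fastq(r1, r2)
            sam = tmp_path / f"{tag}.sam"
            samio.write_sam(sam, emit_truth_alignments(truth, "diploid"), reference_lengths(g, "diploid"))
            return r1.read_bytes(), r2.read_bytes(), sam.read_bytes()
        assert build("a") == build("b")

    def test_read_origins_cover_every_read_once(self):
        g = simulate_diploid_genome(chrom_len=10_000, het_rate=0.01, seed=12)
        truth = simulate_reads(g, [], depth=5, seed=10)
        origins = truth.read_origins
        ids = [r.read_id for r in emit_truth_alignments(truth, "haploid")]
        assert len(origins) == truth.n_fragments
        assert set(ids) == set(origins)
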