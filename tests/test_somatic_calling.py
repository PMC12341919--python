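"""Control masking, the stringent filter cascade, merging and effective sites."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dualref.pileup_counts import (
    LENIENT,
    STRINGENT,
    AlleleStats,
    CountThresholds,
    PileupSite,
)
from dualref.somatic_calling import (
    ControlPositionSet,
    CoordMap,
    ModeConfig,
    SomaticCall,
    build_control_positions,
    call_somatic_candidates,
    compute_effective_sites,
    evaluate_candidate,
    merge_call_sets,
)


def site(
    pos1=100,
    ref="C",
    ref_count=40,
    alt=None,
    alt_count=0,
    alt_fwd=None,
    indels=0,
    ref_mm=0.0,
    alt_mm=0.0,
    thresholds=STRINGENT,
    ref_name="chr1",
    extra=None,
):
    """Compact PileupSite builder for filter fixtures."""
    alleles = {}
    if ref_count:
        alleles[ref] = AlleleStats(ref_count, ref_count, 0, 38.0 * ref_count, ref_mm * ref_count)
    if alt_count:
        fwd = alt_fwd if alt_fwd is not None else max(1, alt_count // 2)
        alleles[alt] = AlleleStats(alt_count, fwd, alt_count - fwd, 35.0 * alt_count, alt_mm * alt_count)
    if extra:
        for b, n in extra.items():
            alleles[b] = AlleleStats(n, n, 0, 35.0 * n, 0.0)
    depth = sum(a.count for a in alleles.values())
    return PileupSite(ref_name, pos1, ref, depth, alleles, indels, thresholds)


def control_all(*positions, mode="diploid"):
    return ControlPositionSet(mode, {("chr1", p) for p in positions})


class TestControlPositions:
    CFG_D = ModeConfig.diploid()
    CFG_H = ModeConfig.haploid()

    @pytest.mark.parametrize(
        "cfg,depth,included",
        [
            (CFG_D, 19, False),  # diploid needs >= 20x
            (CFG_D, 20, True),
            (CFG_D, 25, True),
            (CFG_H, 40, False),  # haploid needs > 40x
            (CFG_H, 41, True),
        ],
    )
    def test_depth_boundaries(self, cfg, depth, included):
        s = site(ref_count=depth, thresholds=LENIENT)
        got = build_control_positions([s], cfg)
        assert (("chr1", 100) in got) is included

    def test_any_alt_observation_disqualifies(self):
        s = site(ref_count=49, alt="T", alt_count=1, thresholds=LENIENT)
        assert len(build_control_positions([s], self.CFG_D)) == 0

    def test_indel_evidence_disqualifies(self):
        s = site(ref_count=50, indels=1, thresholds=LENIENT)
        assert len(build_control_positions([s], self.CFG_D)) == 0

    def test_non_lenient_pileups_rejected(self):
        with pytest.raises(ValueError, match="leniently"):
            build_control_positions([site(ref_count=50, thresholds=STRINGENT)], self.CFG_D)

    def test_bed_round_trip(self, tmp_path):
        cps = control_all(5, 6, 7, 20)
        path = tmp_path / "ctl.bed"
        cps.to_bed(path)
        assert path.read_text() == "chr1\t4\t7\nchr1\t19\t20\n"


class TestFilterCascade:
    CFG = ModeConfig.diploid()

    def _run(self, s, control=None):
        control = control if control is not None else control_all(s.pos1)
        return evaluate_candidate(s, control, self.CFG)

    def test_clean_candidate_is_called(self):
        call, trace = self._run(site(ref_count=57, alt="T", alt_count=3, alt_fwd=2, alt_mm=1 / 150))
        assert call is not None
        assert call.alt_allele == "T" and call.alt_count == 3
        assert call.vaf == pytest.approx(3 / 60)
        assert trace[-1] == "mismatch_delta"

    def test_not_in_control_set(self):
        call, trace = self._run(site(), control_all(999))
        assert call is None and trace == []

    @pytest.mark.parametrize("alt_count,called", [(2, False), (3, True)])
    def test_min_alt_reads_boundary(self, alt_count, called):
        call, _ = self._run(site(ref_count=40, alt="T", alt_count=alt_count, alt_fwd=1, alt_mm=1 / 150))
        assert (call is not None) is called

    def test_single_strand_support_rejected(self):
        call, trace = self._run(site(ref_count=40, alt="T", alt_count=5, alt_fwd=5, alt_mm=1 / 150))
        assert call is None and trace[-1] == "min_alt_reads"
        call, _ = self._run(site(ref_count=40, alt="T", alt_count=5, alt_fwd=0, alt_mm=1 / 150))
        assert call is None

    @pytest.mark.parametrize(
        "cfg,depth_ref,called",
        [
            (ModeConfig.diploid(), 67, True),    # total 70 <= 70
            (ModeConfig.diploid(), 68, False),   # total 71 > 70
            (ModeConfig.haploid(), 117, True),   # total 120 <= 120
            (ModeConfig.haploid(), 118, False),  # total 121 > 120
        ],
    )
    def test_mutant_coverage_cap(self, cfg, depth_ref, called):
        s = site(ref_count=depth_ref, alt="T", alt_count=3, alt_fwd=2, alt_mm=1 / 150)
        call, _ = evaluate_candidate(s, ControlPositionSet(cfg.mode, {("chr1", 100)}), cfg)
        assert (call is not None) is called

    def test_triallelic_site_rejected(self):
        s = site(ref_count=50, alt="T", alt_count=4, alt_fwd=2, extra={"G": 1})
        call, trace = self._run(s)
        assert call is None and trace[-1] == "no_indel"

    def test_site_without_ref_reads_rejected(self):
        s = site(ref_count=0, alt="T", alt_count=10, alt_fwd=5)
        call, trace = self._run(s)
        assert call is None and trace[-1] == "no_indel"

    def test_indel_evidence_rejected(self):
        call, trace = self._run(site(ref_count=50, alt="T", alt_count=3, alt_fwd=2, indels=1))
        assert call is None and trace[-1] == "max_coverage"

    @pytest.mark.parametrize("ref_mm,called", [(0.01, True), (0.011, False)])
    def test_ref_mismatch_boundary(self, ref_mm, called):
        s = site(ref_count=50, alt="T", alt_count=3, alt_fwd=2, ref_mm=ref_mm, alt_mm=ref_mm)
        call, _ = self._run(s)
        assert (call is not None) is called

    @pytest.mark.parametrize("delta,called", [(0.01, True), (0.011, False)])
    def test_mismatch_delta_boundary(self, delta, called):
        s = site(ref_count=50, alt="T", alt_count=3, alt_fwd=2, ref_mm=0.0, alt_mm=delta)
        call, _ = self._run(s)
        assert (call is not None) is called

    def test_delta_absorbs_variant_base_for_150bp_reads(self):
        # alt reads carry their own variant as 1/150 = 0.0067 mismatch
        s = site(ref_count=50, alt="T", alt_count=5, alt_fwd=2, ref_mm=0.001, alt_mm=0.001 + 1 / 150)
        call, _ = self._run(s)
        assert call is not None

    @given(
        min_alt=st.integers(3, 6),
        max_cov=st.integers(40, 70),
        max_delta=st.floats(0.002, 0.01),
    )
    @settings(derandomize=True, max_examples=40)
    def test_tightening_thresholds_never_increases_calls(self, min_alt, max_cov, max_delta):
        sites = [
            site(pos1=p, ref_count=40 + p % 25, alt="T", alt_count=2 + p % 5,
                 alt_fwd=1 + p % 2, alt_mm=(p % 4) * 0.004)
            for p in range(1, 60)
        ]
        control = control_all(*range(1, 60))
        base = call_somatic_candidates(sites, control, ModeConfig.diploid())
        tight_cfg = ModeConfig(
            mode="diploid", control_min_cov=20, mutant_max_cov=max_cov,
            min_alt_reads=min_alt, max_mismatch_delta=max_delta,
        )
        tight = call_somatic_candidates(sites, control, tight_cfg)
        assert len(tight) <= len(base)
        assert {c.site for c in tight} <= {c.site for c in base}


def _call(chrom, pos1, alt="T", mode="haploid", ref="C"):
    return SomaticCall(chrom, pos1, ref, alt, 5, 3, 2, 50, 0.1, 0.0, 1 / 150, mode)


class TestMerge:
    CMAP = CoordMap(
        lambda s: [(f"{s[0]}_hapA", s[1]), (f"{s[0]}_hapB", s[1])],
        lambda s: (s[0][:-5], s[1]) if s[0][-5:] in ("_hapA", "_hapB") else None,
    )

    def test_disjoint_sets_union(self):
        # the upper branch contributed 173 calls and the lower 25; the union
        # of disjoint reciprocal call sets is their sum, 198
        hap = [_call("chr1", p) for p in range(1, 174)]
        dip = [_call("chr1_hapA", 10_000 + p) for p in range(1, 26)]
        merged = merge_call_sets(hap, dip, self.CMAP)
        assert len(merged) == 198

    def test_same_site_same_alt_collapses_with_provenance(self):
        hap = [_call("chr1", 500, mode="haploid")]
        dip = [_call("chr1_hapB", 500, mode="diploid")]
        merged = merge_call_sets(hap, dip, self.CMAP)
        assert len(merged) == 1
        assert merged[0].modes == {"haploid", "diploid"}
        assert merged[0].mappable and merged[0].anchor == ("chr1", 500)

    def test_conflicting_alts_kept_and_flagged(self):
        hap = [_call("chr1", 500, alt="T")]
        dip = [_call("chr1_hapA", 500, alt="G", mode="diploid")]
        merged = merge_call_sets(hap, dip, self.CMAP)
        assert len(merged) == 2 and all(m.conflict for m in merged)

    def test_unmappable_diploid_calls_keep_their_coordinates(self):
        cmap = CoordMap(lambda s: [], lambda s: None)
        merged = merge_call_sets([], [_call("chr1_hapB", 77, mode="diploid")], cmap)
        assert len(merged) == 1
        assert not merged[0].mappable and merged[0].anchor == ("chr1_hapB", 77)

    def test_idempotent_union(self):
        hap = [_call("chr1", 500)]
        merged = merge_call_sets(hap, [], self.CMAP)
        assert len(merged) == 1 and merged[0].modes == {"haploid"}


class TestEffectiveSites:
    def test_zero_track(self):
        assert compute_effective_sites(np.zeros(100)) == 0

    def test_strictly_above_threshold(self):
        assert compute_effective_sites(np.array([10, 21, 20, 25]), 20) == 2

    def test_uniform_coverage_counts_most_of_genome(self, recovery_result):
        n = recovery_result.effective_sites()
        # two 200 kb haplotype contigs at ~27x mean -> most positions pass
        assert n > 0.8 * 2 * 200_000


class TestOnSimulatedData:
    def test_symmetric_reciprocal_calling_is_disjoint(self, recovery_result):
        """Swapping mutant and control yields a call set disjoint from the
        forward direction (each direction requires the other sample to be
        confidently reference at the site)."""
        from dualref.pipeline import call_mode

        res = recovery_result
        fwd = res.by_mode["diploid"].calls
        rev = call_mode("diploid", res.control, res.mutant, res.genome).calls
        assert not ({c.site for c in fwd} & {c.site for c in rev})

    def test_every_call_reverifies_against_raw_pileups(self, recovery_result):
        """Brute-force re-verification of each emitted diploid-mode call
        from the pileup matrices, independent of the cascade code."""
        res = recovery_result
        cfg = res.by_mode["diploid"].config
        for call in res.by_mode["diploid"].calls:
            mat = res.by_mode["diploid"].mutant_matrices[call.ref_name]
            s = mat.site(call.pos1)
            ref, alt = call.ref_allele, call.alt_allele
            assert s.depth <= cfg.mutant_max_cov
            assert s.indel_evidence == 0
            observed = {b for b, a in s.alleles.items() if a.count > 0}
            assert observed == {ref, alt}
            assert s.alleles[alt].count >= 3
            assert s.alleles[alt].fwd >= 1 and s.alleles[alt].rev >= 1
            assert s.alleles[ref].mean_mismatch_fraction <= 0.01 + 1e-12
            assert (
                s.alleles[alt].mean_mismatch_fraction
                - s.alleles[ref].mean_mismatch_fraction
                <= 0.01 + 1e-12
            )
            cmat = res.by_mode["diploid"].control_matrices[call.ref_name]
            cs = cmat.site(call.pos1)
            assert cs.depth >= cfg.control_min_cov
            assert cs.nonref_count() == 0 and cs.indel_evidence == 0
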