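"""Control-masked stringent somatic SNV calling and haploid/diploid merging.

The caller is built around an asymmetric pair of samples: the *control*
sample is counted leniently (MAPQ >= 0, BQ >= 0) and defines the set of
control positions -- positions where the control is confidently
homozygous-reference (enough depth, no indel evidence, zero non-reference
bases).  Any alternate evidence in the control, however weak, disqualifies
the position; the lenient thresholds exist to minimise false negatives on
the control side.  The *mutant* sample is then counted stringently and a
candidate is emitted only if it survives the full filter cascade at a
control position.

Mode-specific coverage bounds follow the asymmetry of the two references:
against the diploid assembly coverage is split between haplotypes
(control >= 20x, mutant <= 70x); against the haploid assembly it is not
(control > 40x, mutant <= 120x).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Union

import numpy as np

from .pileup_counts import PileupMatrix, PileupSite
from . import samio

Site = tuple[str, int]  # (ref_name, pos1)


@dataclass(frozen=True)
class ModeConfig:
    mode: str
    control_min_cov: int
    mutant_max_cov: int
    mutant_min_mapq: int = 10
    mutant_min_bq: int = 30
    min_alt_reads: int = 3
    require_both_strands: bool = True
    max_ref_mismatch: float = 0.01
    max_mismatch_delta: float = 0.01
    max_control_alt: int = 0

    @classmethod
    def diploid(cls) -> "ModeConfig":
        """Diploid assembly as reference: control >= 20x, mutant <= 70x."""
        return cls(mode="diploid", control_min_cov=20, mutant_max_cov=70)

    @classmethod
    def haploid(cls) -> "ModeConfig":
        """Haploid assembly as reference: control > 40x (i.e. >= 41),
        mutant <= 120x."""
        return cls(mode="haploid", control_min_cov=41, mutant_max_cov=120)


@dataclass
class ControlPositionSet:
    mode: str
    positions: set[Site]

    def __contains__(self, site: Site) -> bool:
        return site in self.positions

    def __len__(self) -> int:
        return len(self.positions)

    def to_bed(self, path) -> None:
        """Serialise as sorted BED (0-based half-open), merging runs."""
        intervals = []
        for chrom in sorted({c for c, _ in self.positions}):
            pos = sorted(p - 1 for c, p in self.positions if c == chrom)
            start = prev = None
            for p in pos:
                if start is None:
                    start = prev = p
                elif p == prev + 1:
                    prev = p
                else:
                    intervals.append((chrom, start, prev + 1))
                    start = prev = p
            if start is not None:
                intervals.append((chrom, start, prev + 1))
        samio.write_bed(path, intervals)


@dataclass
class SomaticCall:
    ref_name: str
    pos1: int
    ref_allele: str
    alt_allele: str
    alt_count: int
    alt_fwd: int
    alt_rev: int
    depth: int
    vaf: float
    ref_mismatch_mean: float
    alt_mismatch_mean: float
    mode: str
    sample_label: str = ""
    filter_trace: list[str] = field(default_factory=list)

    @property
    def site(self) -> Site:
        return (self.ref_name, self.pos1)


Pileups = Union[PileupMatrix, Mapping[str, PileupMatrix], Iterable[PileupSite]]


def _as_matrices(pileups: Pileups) -> Optional[list[PileupMatrix]]:
    if isinstance(pileups, PileupMatrix):
        return [pileups]
    if isinstance(pileups, Mapping):
        return list(pileups.values())
    return None


def build_control_positions(control_pileups: Pileups, cfg: ModeConfig) -> ControlPositionSet:
    """Positions where the control sample is confidently homozygous-ref.

    Requires lenient counting (MAPQ >= 0, BQ >= 0): a position qualifies iff
    depth >= control_min_cov, it has no indel evidence, and at most
    ``max_control_alt`` (default zero) non-reference bases were observed.
    """
    out: set[Site] = set()
    mats = _as_matrices(control_pileups)
    if mats is not None:
        for mat in mats:
            _check_lenient(mat.thresholds)
            ok = (
                (mat.depth_track >= cfg.control_min_cov)
                & (mat.indel == 0)
                & (mat.nonref_track() <= cfg.max_control_alt)
            )
            for i in np.nonzero(ok)[0]:
                out.add((mat.ref_name, int(i) + 1))
    else:
        for site in control_pileups:
            _check_lenient(site.thresholds)
            if (
                site.depth >= cfg.control_min_cov
                and site.indel_evidence == 0
                and site.nonref_count() <= cfg.max_control_alt
            ):
                out.add((site.ref_name, site.pos1))
    return ControlPositionSet(cfg.mode, out)


def _check_lenient(thresholds) -> None:
    if thresholds.min_mapq != 0 or thresholds.min_bq != 0:
        raise ValueError(
            "control pileups must be counted leniently (MAPQ>=0, BQ>=0); "
            f"got {thresholds}"
        )


def evaluate_candidate(
    site: PileupSite, control: ControlPositionSet, cfg: ModeConfig
) -> tuple[Optional[SomaticCall], list[str]]:
    """Run the filter cascade on one pileup site.

    Returns ``(call, trace)``; the trace lists every test that passed, in
    order, so a returned call documents its own provenance and a ``None``
    records how far the site got.
    """
    trace: list[str] = []

    def ok(name: str) -> None:
        trace.append(name)

    if (site.ref_name, site.pos1) not in control:
        return None, trace
    ok("in_control")
    if site.depth > cfg.mutant_max_cov:
        return None, trace
    ok("max_coverage")
    if site.indel_evidence != 0:
        return None, trace
    ok("no_indel")
    observed = {b: a for b, a in site.alleles.items() if a.count > 0}
    ref = site.ref_base
    if ref not in observed or len(observed) != 2:
        return None, trace
    ok("biallelic")
    alt = next(b for b in observed if b != ref)
    alt_stats = observed[alt]
    if alt_stats.count < cfg.min_alt_reads:
        return None, trace
    ok("min_alt_reads")
    if cfg.require_both_strands and (alt_stats.fwd < 1 or alt_stats.rev < 1):
        return None, trace
    ok("both_strands")
    ref_mm = observed[ref].mean_mismatch_fraction
    alt_mm = alt_stats.mean_mismatch_fraction
    if ref_mm > cfg.max_ref_mismatch:
        return None, trace
    ok("ref_mismatch")
    if alt_mm - ref_mm > cfg.max_mismatch_delta:
        return None, trace
    ok("mismatch_delta")
    call = SomaticCall(
        ref_name=site.ref_name,
        pos1=site.pos1,
        ref_allele=ref,
        alt_allele=alt,
        alt_count=alt_stats.count,
        alt_fwd=alt_stats.fwd,
        alt_rev=alt_stats.rev,
        depth=site.depth,
        vaf=alt_stats.count / site.depth,
        ref_mismatch_mean=ref_mm,
        alt_mismatch_mean=alt_mm,
        mode=cfg.mode,
        filter_trace=trace.copy(),
    )
    return call, trace


def call_somatic_candidates(
    mutant_pileups: Pileups,
    control: ControlPositionSet,
    cfg: ModeConfig,
    sample_label: str = "",
) -> list[SomaticCall]:
    """Apply the stringent filter cascade to the mutant sample.

    Sites failing any filter are silently dropped; per-filter drop counts
    are retained on the returned list via :func:`filter_drop_counts` by
    callers that want them (the CLI logs them).
    """
    calls: list[SomaticCall] = []
    mats = _as_matrices(mutant_pileups)
    if mats is not None:
        sites: Iterable[PileupSite] = (
            mat.site(int(i) + 1)
            for mat in mats
            for i in np.nonzero(mat.nonref_track() > 0)[0]
        )
    else:
        sites = mutant_pileups
    for site in sites:
        if site.nonref_count() == 0:
            continue
        call, _trace = evaluate_candidate(site, control, cfg)
        if call is not None:
            call.sample_label = sample_label
            calls.append(call)
    calls.sort(key=lambda c: (c.ref_name, c.pos1))
    return calls


# ----------------------------------------------------------------- merge

class CoordMap:
    """Bidirectional mapping between haploid and diploid coordinates.

    For synthetic genomes the two haplotypes are length-collinear, so a
    haploid position maps to the same offset on both haplotype contigs,
    except inside divergent blocks where the hapB contig has no haploid
    counterpart.
    """

    def __init__(
        self,
        hap_to_dip_fn: Callable[[Site], list[Site]],
        dip_to_hap_fn: Callable[[Site], Optional[Site]],
    ):
        self._h2d = hap_to_dip_fn
        self._d2h = dip_to_hap_fn

    def hap_to_dip(self, site: Site) -> list[Site]:
        return self._h2d(site)

    def dip_to_hap(self, site: Site) -> Optional[Site]:
        return self._d2h(site)

    @classmethod
    def from_synthetic_genome(cls, genome) -> "CoordMap":
        blocks = genome.divergent_blocks

        def h2d(site: Site) -> list[Site]:
            chrom, pos1 = site
            out = [(f"{chrom}_hapA", pos1)]
            if not any(c == chrom and s < pos1 <= e for c, s, e in blocks):
                out.append((f"{chrom}_hapB", pos1))
            return out

        def d2h(site: Site) -> Optional[Site]:
            name, pos1 = site
            if name.endswith("_hapA"):
                return (name[:-5], pos1)
            if name.endswith("_hapB"):
                chrom = name[:-5]
                if any(c == chrom and s < pos1 <= e for c, s, e in blocks):
                    return None  # hapB-only sequence, absent from haploid
                return (chrom, pos1)
            return None

        return cls(h2d, d2h)


@dataclass
class MergedCall:
    """One genomic somatic SNV, possibly seen in both reference modes."""

    anchor: Site          # haploid coordinates when mappable
    mappable: bool        # False -> anchor is in diploid coordinates
    ref_allele: str
    alt_allele: str
    modes: set[str]
    records: list[SomaticCall]
    conflict: bool = False

    @property
    def vaf(self) -> float:
        return max(r.vaf for r in self.records)


def merge_call_sets(
    hap_calls: Iterable[SomaticCall],
    dip_calls: Iterable[SomaticCall],
    coord_map: CoordMap,
) -> list[MergedCall]:
    """Union of the two mode-specific call sets on shared coordinates.

    A haploid call and a diploid call at the same genomic site with the same
    alternate allele collapse into one record; the same site with different
    alternate alleles yields two records flagged as conflicting.  Diploid
    calls with no haploid counterpart (hapB-only sequence) keep their
    diploid coordinates.
    """
    grouped: dict[tuple[Site, bool], dict[str, MergedCall]] = {}
    for call in hap_calls:
        key = (call.site, True)
        _add_merge(grouped, key, call)
    for call in dip_calls:
        hap_site = coord_map.dip_to_hap(call.site)
        key = (hap_site, True) if hap_site is not None else (call.site, False)
        _add_merge(grouped, key, call)
    out: list[MergedCall] = []
    for (anchor, mappable), by_alt in grouped.items():
        conflict = len(by_alt) > 1
        for mc in by_alt.values():
            mc.conflict = conflict
            out.append(mc)
    out.sort(key=lambda m: (not m.mappable, m.anchor[0], m.anchor[1], m.alt_allele))
    return out


def _add_merge(grouped, key, call: SomaticCall) -> None:
    anchor, mappable = key
    by_alt = grouped.setdefault(key, {})
    mc = by_alt.get(call.alt_allele)
    if mc is None:
        by_alt[call.alt_allele] = MergedCall(
            anchor=anchor,
            mappable=mappable,
            ref_allele=call.ref_allele,
            alt_allele=call.alt_allele,
            modes={call.mode},
            records=[call],
        )
    else:
        mc.modes.add(call.mode)
        mc.records.append(call)


def compute_effective_sites(depth_track: np.ndarray, min_cov: int = 20) -> int:
    """Number of positions with depth strictly above ``min_cov`` ("above
    20x") -- the denominator of per-site mutation rates."""
    return int((np.asarray(depth_track) > min_cov).sum())


# ---------------------------------------------------- flank-based mapping

def build_coord_map_by_flanks(
    sites: Iterable[Site],
    hap_refs: Mapping[str, np.ndarray],
    dip_refs: Mapping[str, np.ndarray],
    flank: int = 100,
) -> dict[Site, list[Site]]:
    """Locate haploid sites in the diploid assembly by unique exact matching
    of their +/- ``flank`` bp context (the same flank trick used to carry
    previously validated variants between assemblies)."""
    out: dict[Site, list[Site]] = {}
    dip_bytes = {name: arr.tobytes() for name, arr in dip_refs.items()}
    for chrom, pos1 in sites:
        ref = hap_refs[chrom]
        s = max(0, pos1 - 1 - flank)
        window = ref[s : pos1 + flank].tobytes()
        offset = pos1 - 1 - s
        hits: list[Site] = []
        for name, target in dip_bytes.items():
            start = 0
            while True:
                i = target.find(window, start)
                if i < 0:
                    break
                hits.append((name, i + offset + 1))
                start = i + 1
        out[(chrom, pos1)] = hits
    return out


# ----------------------------------------------------------------- VCF

def write_calls_vcf(path, calls: Iterable[SomaticCall], ref_lengths: Mapping[str, int]) -> None:
    """Write calls as VCF 4.2 with per-call INFO annotations."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name in sorted(ref_lengths):
            fh.write(f"##contig=<ID={name},length={ref_lengths[name]}>\n")
        for tag, desc in [
            ("MODE", "Reference mode (haploid/diploid)"),
            ("ALTFWD", "Alt-supporting reads on forward strand"),
            ("ALTREV", "Alt-supporting reads on reverse strand"),
            ("REFMM", "Mean mismatch fraction of ref reads"),
            ("ALTMM", "Mean mismatch fraction of alt reads"),
            ("VAF", "Variant allele frequency"),
        ]:
            num_type = "1,Type=String" if tag == "MODE" else "1,Type=Float"
            fh.write(f'##INFO=<ID={tag},Number={num_type},Description="{desc}">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in sorted(calls, key=lambda c: (c.ref_name, c.pos1)):
            info = (
                f"MODE={c.mode};ALTFWD={c.alt_fwd};ALTREV={c.alt_rev};"
                f"REFMM={c.ref_mismatch_mean:.4f};ALTMM={c.alt_mismatch_mean:.4f};"
                f"VAF={c.vaf:.4f}"
            )
            fh.write(
                f"{c.ref_name}\t{c.pos1}\t.\t{c.ref_allele}\t{c.alt_allele}\t.\tPASS\t{info}\n"
            )


def write_calls_tsv(path, calls: Iterable[SomaticCall]) -> None:
    samio.write_tsv(
        path,
        [
            "chrom", "pos", "ref", "alt", "alt_count", "alt_fwd", "alt_rev",
            "depth", "vaf", "ref_mm", "alt_mm", "mode", "sample",
        ],
        (
            [
                c.ref_name, c.pos1, c.ref_allele, c.alt_allele, c.alt_count,
                c.alt_fwd, c.alt_rev, c.depth, f"{c.vaf:.4f}",
                f"{c.ref_mismatch_mean:.4f}", f"{c.alt_mismatch_mean:.4f}",
                c.mode, c.sample_label,
            ]
            for c in calls
        ),
    )
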