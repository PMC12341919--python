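"""End-to-end orchestration on synthetic data.

Wires the stages together the way the method prescribes: simulate a
diploid genome and two samples (mutant carries layer-structured implants,
control does not), emit truth alignments against both references, assign
each read to one reference, pile up the control leniently and the mutant
stringently in each mode, call somatic candidates against the
control-position mask, and merge the two mode-specific call sets on shared
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from . import simulate as sim
from .read_assignment import PartitionResult, partition_alignments
from .pileup_counts import LENIENT, CountThresholds, PileupMatrix, pileup_matrix
from .somatic_calling import (
    ControlPositionSet,
    CoordMap,
    MergedCall,
    ModeConfig,
    SomaticCall,
    build_control_positions,
    call_somatic_candidates,
    compute_effective_sites,
    merge_call_sets,
)

MODES = ("haploid", "diploid")


@dataclass
class SampleAlignments:
    """One sample's reads, assigned between the two references."""

    truth: sim.SimTruth
    partition: PartitionResult

    def assigned(self, mode: str):
        return self.partition.haploid if mode == "haploid" else self.partition.diploid


@dataclass
class ModeResult:
    mode: str
    config: ModeConfig
    control_set: ControlPositionSet
    calls: list[SomaticCall]
    control_matrices: dict[str, PileupMatrix]
    mutant_matrices: dict[str, PileupMatrix]


@dataclass
class ExperimentResult:
    genome: sim.DiploidGenome
    implants: list[sim.SomaticImplant]
    mutant: SampleAlignments
    control: SampleAlignments
    by_mode: dict[str, ModeResult]
    merged: list[MergedCall]
    coord_map: CoordMap

    def effective_sites(self, min_cov: int = 20) -> int:
        """Effective site count from the control sample's diploid-mode depth."""
        return sum(
            compute_effective_sites(mat.depth_track, min_cov)
            for mat in self.by_mode["diploid"].control_matrices.values()
        )


def align_and_assign(truth: sim.SimTruth) -> SampleAlignments:
    hap = sim.emit_truth_alignments(truth, "haploid")
    dip = sim.emit_truth_alignments(truth, "diploid")
    return SampleAlignments(truth, partition_alignments(hap, dip))


def _matrices(reads, refs: Mapping[str, np.ndarray], thresholds: CountThresholds):
    by_ref: dict[str, list] = {name: [] for name in refs}
    for r in reads:
        if r.ref_name in by_ref:
            by_ref[r.ref_name].append(r)
    return {
        name: pileup_matrix(rs, name, refs[name], thresholds)
        for name, rs in by_ref.items()
    }


def call_mode(
    mode: str,
    mutant: SampleAlignments,
    control: SampleAlignments,
    genome: sim.DiploidGenome,
    cfg: Optional[ModeConfig] = None,
    sample_label: str = "",
) -> ModeResult:
    """Run control masking + stringent calling for one reference mode."""
    if cfg is None:
        cfg = ModeConfig.haploid() if mode == "haploid" else ModeConfig.diploid()
    refs = genome.haploid_refs() if mode == "haploid" else genome.diploid_refs()
    stringent = CountThresholds(cfg.mutant_min_mapq, cfg.mutant_min_bq)
    control_mats = _matrices(control.assigned(mode), refs, LENIENT)
    mutant_mats = _matrices(mutant.assigned(mode), refs, stringent)
    control_set = build_control_positions(control_mats, cfg)
    calls = call_somatic_candidates(mutant_mats, control_set, cfg, sample_label)
    return ModeResult(mode, cfg, control_set, calls, control_mats, mutant_mats)


def run_synthetic_experiment(
    seed: int = 0,
    n_chrom: int = 1,
    chrom_len: int = 200_000,
    het_rate: float = 0.016,
    divergent_spec: Sequence[int] = (),
    layer_fractions: Mapping[str, float] = sim.DEFAULT_LAYER_FRACTIONS,
    n_per_layer: int | Mapping[str, int] = 0,
    cell_fraction: float = 1.0,
    depth: float = 60.0,
    read_len: int = 150,
    error_rate: float = 0.001,
    sample_label: str = "upper",
) -> ExperimentResult:
    """Simulate a mutant/control pair and run the full dual-reference caller.

    Seeds for the genome, the implants and the two read sets are derived
    from ``seed`` via ``numpy.random.SeedSequence``, so one integer pins the
    entire experiment.
    """
    ss = np.random.SeedSequence(seed)
    s_genome, s_implant, s_mut, s_ctl = [
        int(c.generate_state(1)[0]) & 0x7FFFFFFF for c in ss.spawn(4)
    ]
    genome = sim.simulate_diploid_genome(
        n_chrom=n_chrom,
        chrom_len=chrom_len,
        het_rate=het_rate,
        divergent_spec=divergent_spec,
        seed=s_genome,
    )
    implants = (
        sim.implant_somatic_mutations(
            genome,
            layer_fractions=layer_fractions,
            n_per_layer=n_per_layer,
            cell_fraction=cell_fraction,
            seed=s_implant,
            edge_margin=read_len,
        )
        if n_per_layer
        else []
    )
    common = dict(
        depth=depth,
        read_len=read_len,
        error_rate=error_rate,
        layer_fractions=layer_fractions,
    )
    mutant_truth = sim.simulate_reads(genome, implants, seed=s_mut, sample="mut", **common)
    control_truth = sim.simulate_reads(genome, [], seed=s_ctl, sample="ctl", **common)
    mutant = align_and_assign(mutant_truth)
    control = align_and_assign(control_truth)
    by_mode = {
        mode: call_mode(mode, mutant, control, genome, sample_label=sample_label)
        for mode in MODES
    }
    coord_map = CoordMap.from_synthetic_genome(genome)
    merged = merge_call_sets(
        by_mode["haploid"].calls, by_mode["diploid"].calls, coord_map
    )
    return ExperimentResult(
        genome, implants, mutant, control, by_mode, merged, coord_map
    )


def recovered_implants(result: ExperimentResult) -> dict[int, bool]:
    """Which implanted mutations reappear among the merged calls (same
    genomic site, same alternate allele)?"""
    called: set[tuple[str, int, str]] = set()
    for mc in result.merged:
        if mc.mappable:
            called.add((mc.anchor[0], mc.anchor[1], mc.alt_allele))
        else:
            called.add((mc.anchor[0], mc.anchor[1], mc.alt_allele))
    out = {}
    for i, imp in enumerate(result.implants):
        hap_key = (imp.chrom, imp.pos0 + 1, imp.alt_allele)
        dip_key = (f"{imp.chrom}_hap{imp.haplotype}", imp.pos0 + 1, imp.alt_allele)
        out[i] = hap_key in called or dip_key in called
    return out
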