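"""Synthetic diploid genomes, layer-structured somatic mutations, paired
short reads, and truth alignments.

The generator emulates the study system this package targets: a highly
heterozygous diploid genome (default 1.6% SNV heterozygosity, the kmer-based
estimate for the tree the method was developed on), including
haplotype-divergent blocks where one haplotype carries sequence absent from
the haploid assembly; somatic SNVs confined to one meristem cell layer
(L1/L2/L3) and one haplotype, so that a mutation fixed in a layer appears at
a variant allele frequency of ``layer_dna_fraction x cell_fraction / 2``;
and paired-end short reads with substitution errors.

Truth alignments carry BWA-convention alignment scores (+1 match, -4
mismatch) and a two-level MAPQ model (60 unique / 0 ambiguous): in diploid
mode a read whose span is identical between the two haplotypes has two
equally good placements and gets MAPQ 0; in haploid mode every mapped read
is unique.  Reads drawn from divergent-block hapB sequence have no
counterpart in the haploid assembly and are emitted unmapped there.

All randomness flows through a single ``numpy`` generator per operation, so
identical seeds give byte-identical FASTQ/SAM output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .core import (
    CODE2BASE,
    BASE2CODE,
    DEFAULT_SCORING,
    AlignedRead,
    ScoringModel,
    array_to_seq,
    revcomp,
)
from . import samio

DEFAULT_LAYER_FRACTIONS = {"L1": 0.18, "L2": 0.60, "L3": 0.22}

#: base qualities: positions carrying a simulated sequencing error get Q20
#: (below the stringent BQ>=30 pileup threshold), everything else Q38.
QUAL_ERROR = 20
QUAL_GOOD = 38

#: minimum alignment score for a truth alignment to be emitted as mapped,
#: mirroring bwa mem's output threshold (-T 30).
MIN_EMIT_SCORE = 30


@dataclass
class HetVariant:
    chrom: str
    pos0: int
    hapA_allele: str
    hapB_allele: str
    kind: str = "snv"


@dataclass
class DiploidGenome:
    """Two length-collinear haplotypes differing at het SNVs and inside
    divergent blocks (hapB-only sequence); coordinates are hapA-based."""

    hapA: dict[str, np.ndarray]
    hapB: dict[str, np.ndarray]
    het_variants: list[HetVariant]
    divergent_blocks: list[tuple[str, int, int]]

    def chrom_names(self) -> list[str]:
        return list(self.hapA)

    def chrom_len(self, chrom: str) -> int:
        return len(self.hapA[chrom])

    def het_mask(self, chrom: str) -> np.ndarray:
        m = np.zeros(self.chrom_len(chrom), dtype=bool)
        for v in self.het_variants:
            if v.chrom == chrom:
                m[v.pos0] = True
        return m

    def block_mask(self, chrom: str) -> np.ndarray:
        m = np.zeros(self.chrom_len(chrom), dtype=bool)
        for c, s, e in self.divergent_blocks:
            if c == chrom:
                m[s:e] = True
        return m

    def in_divergent_block(self, chrom: str, pos0: int) -> bool:
        return any(c == chrom and s <= pos0 < e for c, s, e in self.divergent_blocks)

    # -- reference export ------------------------------------------------
    def haploid_refs(self) -> dict[str, np.ndarray]:
        """The haploid assembly: hapA under the plain chromosome names."""
        return dict(self.hapA)

    def diploid_refs(self) -> dict[str, np.ndarray]:
        """The diploid assembly: both haplotypes as separate contigs."""
        out: dict[str, np.ndarray] = {}
        for c in self.hapA:
            out[f"{c}_hapA"] = self.hapA[c]
            out[f"{c}_hapB"] = self.hapB[c]
        return out

    def write_haploid_fasta(self, path) -> None:
        samio.write_fasta(path, self.haploid_refs())

    def write_diploid_fasta(self, path) -> None:
        samio.write_fasta(path, self.diploid_refs())


@dataclass
class SomaticImplant:
    """A somatic SNV fixed in one meristem layer on one haplotype.

    ``expected_vaf`` is the allele frequency expected in whole-sample reads
    against the haploid reference: the layer contributes
    ``layer_dna_fraction`` of the DNA, the mutant cells are a
    ``cell_fraction`` of that layer, and the mutation sits on one of the two
    haplotypes, hence the division by 2.
    """

    chrom: str
    pos0: int
    ref_allele: str
    alt_allele: str
    layer: str
    haplotype: str
    cell_fraction: float
    expected_vaf: float


@dataclass
class _ChromBatch:
    """Vectorised per-chromosome read data (fragments as rows)."""

    chrom: str
    starts: np.ndarray        # fragment start, 0-based
    inserts: np.ndarray
    hap: np.ndarray           # 0 = hapA, 1 = hapB
    layer: np.ndarray         # index into SimTruth.layer_names
    r1: np.ndarray            # (n, read_len) ASCII, reference orientation
    r2: np.ndarray
    q1: np.ndarray            # (n, read_len) phred
    q2: np.ndarray
    carried: dict[int, np.ndarray]  # implant index -> bool per fragment

    @property
    def n(self) -> int:
        return len(self.starts)

    def mate_starts(self, mate: int, read_len: int) -> np.ndarray:
        if mate == 1:
            return self.starts
        return self.starts + self.inserts - read_len


@dataclass
class ReadOrigin:
    haplotype: str
    chrom: str
    start0: int
    strand: str
    carried_implants: tuple[int, ...]


@dataclass
class SimTruth:
    """Ground truth for one simulated sample: the genome, the implanted
    mutations, and the per-fragment origin of every read pair."""

    genome: DiploidGenome
    implants: list[SomaticImplant]
    sample: str
    read_len: int
    layer_names: list[str]
    batches: dict[str, _ChromBatch] = field(default_factory=dict)

    @property
    def n_fragments(self) -> int:
        return sum(b.n for b in self.batches.values())

    def read_id(self, chrom: str, i: int) -> str:
        return f"{self.sample}:{chrom}:{i:07d}"

    @property
    def read_origins(self) -> dict[str, ReadOrigin]:
        out: dict[str, ReadOrigin] = {}
        for chrom, b in self.batches.items():
            carried_by_frag: dict[int, list[int]] = {}
            for imp_idx, mask in b.carried.items():
                for i in np.nonzero(mask)[0]:
                    carried_by_frag.setdefault(int(i), []).append(imp_idx)
            for i in range(b.n):
                rid = self.read_id(chrom, i)
                out[rid] = ReadOrigin(
                    haplotype="AB"[b.hap[i]],
                    chrom=chrom,
                    start0=int(b.starts[i]),
                    strand="+",
                    carried_implants=tuple(carried_by_frag.get(i, ())),
                )
        return out

    def raw_allele_counts(self, chrom: str, pos0: int) -> dict[str, int]:
        """Base counts over all simulated reads covering a position
        (no thresholds) -- the simulator-side VAF oracle."""
        b = self.batches[chrom]
        counts: dict[str, int] = {}
        for mate, seqs in ((1, b.r1), (2, b.r2)):
            starts = b.mate_starts(mate, self.read_len)
            cols = pos0 - starts
            rows = np.nonzero((cols >= 0) & (cols < self.read_len))[0]
            for r in rows:
                base = chr(seqs[r, cols[r]])
                counts[base] = counts.get(base, 0) + 1
        return counts

    def write_fastq(self, path_r1, path_r2) -> None:
        """Emit the paired reads; mate 2 is reverse-complemented into read
        orientation as a sequencer would deliver it."""
        def gen(mate):
            for chrom, b in self.batches.items():
                seqs = b.r1 if mate == 1 else b.r2
                quals = b.q1 if mate == 1 else b.q2
                for i in range(b.n):
                    rid = self.read_id(chrom, i)
                    if mate == 1:
                        yield rid, seqs[i], quals[i]
                    else:
                        yield rid, revcomp(seqs[i]), quals[i][::-1]
        samio.write_fastq(path_r1, gen(1))
        samio.write_fastq(path_r2, gen(2))


# ======================================================================
# genome
# ======================================================================

def simulate_diploid_genome(
    n_chrom: int = 1,
    chrom_len: int = 1_000_000,
    het_rate: float = 0.016,
    divergent_spec: Sequence[int] = (),
    seed: int = 0,
) -> DiploidGenome:
    """Draw a random diploid genome.

    Het SNVs are placed uniformly at ``het_rate`` per base outside the
    divergent blocks; inside each block, hapB is replaced by unrelated
    random sequence of the same length (so coordinates stay collinear).
    Blocks are placed non-overlapping, uniformly at random.
    """
    if not 0.0 <= het_rate <= 0.05:
        raise ValueError(f"het_rate {het_rate} outside [0, 0.05]")
    if chrom_len < 10_000:
        raise ValueError("chrom_len must be at least 10 kb")
    spec = [int(x) for x in divergent_spec]
    if any(x <= 0 for x in spec):
        raise ValueError("divergent block lengths must be positive")
    if sum(spec) > chrom_len:
        raise ValueError(
            f"divergent blocks ({sum(spec)} bp total) exceed chromosome length {chrom_len}"
        )
    rng = np.random.default_rng(seed)
    hapA: dict[str, np.ndarray] = {}
    hapB: dict[str, np.ndarray] = {}
    het_variants: list[HetVariant] = []
    blocks: list[tuple[str, int, int]] = []
    for ci in range(n_chrom):
        chrom = f"chr{ci + 1}"
        a_codes = rng.integers(0, 4, chrom_len, dtype=np.uint8)
        # place blocks, longest first, by rejection sampling
        placed: list[tuple[int, int]] = []
        for length in sorted(spec, reverse=True):
            if length > chrom_len:
                raise ValueError(f"divergent block of {length} bp exceeds chromosome length")
            for _ in range(1000):
                s = int(rng.integers(0, chrom_len - length + 1))
                if all(s + length <= ps or s >= pe for ps, pe in placed):
                    placed.append((s, s + length))
                    break
            else:
                raise ValueError("could not place divergent blocks without overlap")
        placed.sort()
        block_mask = np.zeros(chrom_len, dtype=bool)
        for s, e in placed:
            block_mask[s:e] = True
            blocks.append((chrom, s, e))
        het_mask = rng.random(chrom_len) < het_rate
        het_mask &= ~block_mask
        het_pos = np.nonzero(het_mask)[0]
        b_codes = a_codes.copy()
        b_codes[het_pos] = (a_codes[het_pos] + rng.integers(1, 4, len(het_pos), dtype=np.uint8)) % 4
        for s, e in placed:
            b_codes[s:e] = rng.integers(0, 4, e - s, dtype=np.uint8)
        hapA[chrom] = CODE2BASE[a_codes]
        hapB[chrom] = CODE2BASE[b_codes]
        for p in het_pos:
            het_variants.append(
                HetVariant(chrom, int(p), chr(CODE2BASE[a_codes[p]]), chr(CODE2BASE[b_codes[p]]))
            )
    return DiploidGenome(hapA, hapB, het_variants, blocks)


# ======================================================================
# somatic implants
# ======================================================================

def implant_somatic_mutations(
    genome: DiploidGenome,
    layer_fractions: Mapping[str, float] = DEFAULT_LAYER_FRACTIONS,
    n_per_layer: int | Mapping[str, int] = 10,
    cell_fraction: float = 1.0,
    seed: int = 0,
    edge_margin: int = 150,
    min_distance: int = 150,
) -> list[SomaticImplant]:
    """Choose somatic SNV positions and record their expected VAFs.

    The genome itself is left untouched: implants live only in the reads,
    where a fragment carries the alternate allele iff it derives from the
    implant's haplotype and layer (and a ``cell_fraction`` coin flip).
    Positions avoid het sites, divergent blocks, one another (at least
    ``min_distance`` apart, so no single read spans two implants -- real
    somatic mutations are orders of magnitude sparser than any desk-scale
    simulation), and an ``edge_margin`` at the chromosome ends so every
    site is fully covered by read placements.
    """
    fr = dict(layer_fractions)
    if abs(sum(fr.values()) - 1.0) > 1e-9:
        raise ValueError("layer fractions must sum to 1")
    if not 0.0 <= cell_fraction <= 1.0:
        raise ValueError("cell_fraction must be in [0, 1]")
    if isinstance(n_per_layer, int):
        n_by_layer = {layer: n_per_layer for layer in fr}
    else:
        n_by_layer = {layer: int(n_per_layer.get(layer, 0)) for layer in fr}
    total = sum(n_by_layer.values())
    if total == 0:
        return []
    rng = np.random.default_rng(seed)
    # candidate positions across all chromosomes
    chroms = genome.chrom_names()
    cand_chrom: list[str] = []
    cand_pos: list[np.ndarray] = []
    for chrom in chroms:
        ok = ~(genome.het_mask(chrom) | genome.block_mask(chrom))
        if edge_margin:
            ok[:edge_margin] = False
            ok[-edge_margin:] = False
        pos = np.nonzero(ok)[0]
        cand_chrom.append(chrom)
        cand_pos.append(pos)
    flat = np.concatenate(
        [np.stack([np.full(len(p), i), p], axis=1) for i, p in enumerate(cand_pos)]
    )
    if total > len(flat):
        raise ValueError(f"requested {total} implants but only {len(flat)} positions available")
    # greedy pick from a shuffled candidate list, enforcing min_distance
    order = rng.permutation(len(flat))
    chosen: list[tuple[int, int]] = []
    taken: dict[int, list[int]] = {}
    for j in order:
        ci, pos0 = int(flat[j][0]), int(flat[j][1])
        near = taken.setdefault(ci, [])
        if all(abs(pos0 - p) >= min_distance for p in near):
            chosen.append((ci, pos0))
            near.append(pos0)
            if len(chosen) == total:
                break
    if len(chosen) < total:
        raise ValueError(
            f"requested {total} implants but only {len(chosen)} positions satisfy "
            f"the {min_distance} bp separation"
        )
    implants: list[SomaticImplant] = []
    k = 0
    for layer in sorted(n_by_layer):
        for _ in range(n_by_layer[layer]):
            ci, pos0 = chosen[k]
            k += 1
            chrom = cand_chrom[ci]
            hap = "AB"[int(rng.integers(0, 2))]
            ref_arr = genome.hapA[chrom] if hap == "A" else genome.hapB[chrom]
            ref = chr(ref_arr[pos0])
            alt = chr(CODE2BASE[(BASE2CODE[ord(ref)] + rng.integers(1, 4)) % 4])
            implants.append(
                SomaticImplant(
                    chrom=chrom,
                    pos0=pos0,
                    ref_allele=ref,
                    alt_allele=alt,
                    layer=layer,
                    haplotype=hap,
                    cell_fraction=cell_fraction,
                    expected_vaf=fr[layer] * cell_fraction / 2.0,
                )
            )
    return implants


# ======================================================================
# reads
# ======================================================================

def simulate_reads(
    genome: DiploidGenome,
    implants: Sequence[SomaticImplant] = (),
    depth: float = 60.0,
    read_len: int = 150,
    insert_mean: float = 400.0,
    insert_sd: float = 60.0,
    error_rate: float = 0.001,
    seed: int = 0,
    sample: str = "s",
    layer_fractions: Mapping[str, float] = DEFAULT_LAYER_FRACTIONS,
) -> SimTruth:
    """Simulate paired-end reads at ``depth``-fold total coverage.

    Fragments are drawn uniformly per chromosome, from hapA or hapB with
    equal probability, and from a meristem layer with the given DNA
    fractions.  Mate 1 reads the fragment 5' end on the forward strand,
    mate 2 the 3' end on the reverse strand; both are stored in reference
    orientation.  Substitution errors occur at ``error_rate`` per base and
    drop the base quality to Q20.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if read_len > insert_mean:
        raise ValueError("read_len must not exceed insert_mean")
    fr = dict(layer_fractions)
    if abs(sum(fr.values()) - 1.0) > 1e-9:
        raise ValueError("layer fractions must sum to 1")
    layer_names = sorted(fr)
    probs = np.array([fr[l] for l in layer_names])
    layer_index = {l: i for i, l in enumerate(layer_names)}
    rng = np.random.default_rng(seed)
    truth = SimTruth(genome, list(implants), sample, read_len, layer_names)
    for chrom in genome.chrom_names():
        L = genome.chrom_len(chrom)
        n = int(round(depth * L / (2 * read_len)))
        inserts = np.clip(
            np.rint(rng.normal(insert_mean, insert_sd, n)).astype(np.int64), read_len, L
        )
        starts = np.floor(rng.random(n) * (L - inserts + 1)).astype(np.int64)
        hap = rng.integers(0, 2, n, dtype=np.int8)
        layer = rng.choice(len(layer_names), size=n, p=probs).astype(np.int8)
        cols = np.arange(read_len)
        r1 = np.empty((n, read_len), dtype=np.uint8)
        r2 = np.empty((n, read_len), dtype=np.uint8)
        s2 = starts + inserts - read_len
        for h, source in ((0, genome.hapA[chrom]), (1, genome.hapB[chrom])):
            rows = np.nonzero(hap == h)[0]
            r1[rows] = source[starts[rows, None] + cols]
            r2[rows] = source[s2[rows, None] + cols]
        # implant alleles (before errors, as in the template molecule)
        carried: dict[int, np.ndarray] = {}
        for idx, imp in enumerate(implants):
            if imp.chrom != chrom:
                continue
            eligible = (hap == ("AB".index(imp.haplotype))) & (
                layer == layer_index[imp.layer]
            )
            coin = rng.random(n) < imp.cell_fraction
            carry = eligible & coin
            carried[idx] = carry
            alt = ord(imp.alt_allele)
            for seqs, st in ((r1, starts), (r2, s2)):
                col = imp.pos0 - st
                rows = np.nonzero(carry & (col >= 0) & (col < read_len))[0]
                seqs[rows, col[rows]] = alt
        # sequencing errors
        q1 = np.full((n, read_len), QUAL_GOOD, dtype=np.uint8)
        q2 = np.full((n, read_len), QUAL_GOOD, dtype=np.uint8)
        for seqs, quals in ((r1, q1), (r2, q2)):
            if error_rate > 0:
                err = rng.random((n, read_len)) < error_rate
                ne = int(err.sum())
                if ne:
                    shift = rng.integers(1, 4, ne, dtype=np.uint8)
                    codes = BASE2CODE[seqs[err]]
                    seqs[err] = CODE2BASE[(codes + shift) % 4]
                    quals[err] = QUAL_ERROR
        truth.batches[chrom] = _ChromBatch(
            chrom, starts, inserts, hap, layer, r1, r2, q1, q2, carried
        )
    return truth


# ======================================================================
# truth alignments
# ======================================================================

def _interval_has(mask_cum: np.ndarray, start: np.ndarray, end: np.ndarray) -> np.ndarray:
    """Vectorised 'any mask position in [start, end)' via a cumulative sum
    with a leading zero."""
    return (mask_cum[end] - mask_cum[start]) > 0


def emit_truth_alignments(
    truth: SimTruth,
    reference_mode: str,
    scoring: ScoringModel = DEFAULT_SCORING,
) -> list[AlignedRead]:
    """Deterministically place every simulated read on the chosen reference.

    Haploid mode aligns everything to hapA coordinates; reads drawn from
    divergent-block hapB sequence are emitted unmapped (their sequence is
    absent from the haploid assembly).  Diploid mode places each read on its
    true haplotype contig; reads whose span is identical between haplotypes
    get the ambiguous MAPQ (two equally good placements), all others the
    unique MAPQ.  AS and NM are computed by direct comparison of the read
    sequence with the reference over the (ungapped) footprint.
    """
    if reference_mode not in ("haploid", "diploid"):
        raise ValueError("reference_mode must be 'haploid' or 'diploid'")
    genome = truth.genome
    rl = truth.read_len
    out: list[AlignedRead] = []
    cols = np.arange(rl)
    for chrom, b in truth.batches.items():
        het_cum = np.concatenate([[0], np.cumsum(genome.het_mask(chrom))])
        blk_cum = np.concatenate([[0], np.cumsum(genome.block_mask(chrom))])
        hapA = genome.hapA[chrom]
        hapB = genome.hapB[chrom]
        for mate in (1, 2):
            starts = b.mate_starts(mate, rl)
            seqs = b.r1 if mate == 1 else b.r2
            quals = b.q1 if mate == 1 else b.q2
            strand = "+" if mate == 1 else "-"
            in_block = _interval_has(blk_cum, starts, starts + rl)
            has_het = _interval_has(het_cum, starts, starts + rl)
            if reference_mode == "haploid":
                refslice = hapA[starts[:, None] + cols]
                mism = (seqs != refslice).sum(axis=1)
                mapped = ~((b.hap == 1) & in_block)
                mapq = np.full(b.n, scoring.mapq_unique)
                ref_names = np.array([chrom] * b.n, dtype=object)
            else:
                refslice = np.empty_like(seqs)
                for h, source in ((0, hapA), (1, hapB)):
                    rows = np.nonzero(b.hap == h)[0]
                    refslice[rows] = source[starts[rows, None] + cols]
                mism = (seqs != refslice).sum(axis=1)
                mapped = np.ones(b.n, dtype=bool)
                ambiguous = ~(has_het | in_block)
                mapq = np.where(ambiguous, scoring.mapq_ambiguous, scoring.mapq_unique)
                names = {0: f"{chrom}_hapA", 1: f"{chrom}_hapB"}
                ref_names = np.array([names[h] for h in b.hap], dtype=object)
            score = scoring.alignment_score(rl - mism, mism)
            cigar = f"{rl}M"
            for i in range(b.n):
                rid = truth.read_id(chrom, i)
                if mapped[i]:
                    out.append(
                        AlignedRead(
                            read_id=rid,
                            mate_index=mate,
                            ref_name=str(ref_names[i]),
                            pos0=int(starts[i]),
                            cigar=cigar,
                            mapq=int(mapq[i]),
                            align_score=int(score[i]),
                            edit_distance=int(mism[i]),
                            strand=strand,
                            seq=array_to_seq(seqs[i]),
                            base_quals=quals[i],
                        )
                    )
                else:
                    out.append(
                        AlignedRead(
                            read_id=rid,
                            mate_index=mate,
                            ref_name=None,
                            pos0=-1,
                            cigar="*",
                            mapq=0,
                            align_score=None,
                            edit_distance=None,
                            strand=strand,
                            seq=array_to_seq(seqs[i]),
                            base_quals=quals[i],
                            is_mapped=False,
                        )
                    )
    return out


def reference_lengths(genome: DiploidGenome, reference_mode: str) -> dict[str, int]:
    refs = genome.haploid_refs() if reference_mode == "haploid" else genome.diploid_refs()
    return {name: len(arr) for name, arr in refs.items()}
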