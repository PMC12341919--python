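"""bam-readcount-style per-site allele counting.

Two routes produce identical numbers:

* :func:`count_site` -- the reference semantics, one position at a time,
  walking each read's CIGAR.  Used for spot checks and small fixtures.
* :func:`pileup_matrix` -- a vectorised whole-contig engine that batches
  ungapped ``<L>M`` reads through ``numpy`` and sends anything with
  indels or clips through the per-read path.  Used by the pipeline.

Counting rules (mirroring bam-readcount as used for somatic filtering):
a read contributes at a position iff its MAPQ >= min_mapq and the base
quality there >= min_bq; overlapping mates contribute independently;
duplicate-flagged reads never contribute; a read whose deletion spans the
position, or whose insertion is anchored at it (assigned to the base on the
left), increments ``indel_evidence`` and contributes no base allele there.
Each contributing read also carries its aggregate mismatch fraction
NM / aligned-length, averaged per allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np

from .core import BASE2CODE, CODE2BASE, AlignedRead, parse_cigar
from . import samio


@dataclass(frozen=True)
class CountThresholds:
    min_mapq: int = 0
    min_bq: int = 0

    def __post_init__(self):
        if self.min_mapq < 0 or self.min_bq < 0:
            raise ValueError("thresholds must be non-negative")


#: lenient counting used for the control sample (reduce false negatives)
LENIENT = CountThresholds(0, 0)
#: stringent counting used for the mutant sample (reduce false positives)
STRINGENT = CountThresholds(10, 30)


@dataclass
class AlleleStats:
    count: int = 0
    fwd: int = 0
    rev: int = 0
    bq_sum: float = 0.0
    mm_sum: float = 0.0

    @property
    def mean_bq(self) -> float:
        return self.bq_sum / self.count if self.count else 0.0

    @property
    def mean_mismatch_fraction(self) -> float:
        return self.mm_sum / self.count if self.count else 0.0


@dataclass
class PileupSite:
    ref_name: str
    pos1: int
    ref_base: str
    depth: int
    alleles: dict[str, AlleleStats]
    indel_evidence: int
    thresholds: CountThresholds

    def allele(self, base: str) -> AlleleStats:
        return self.alleles.get(base, AlleleStats())

    def nonref_count(self) -> int:
        return sum(a.count for b, a in self.alleles.items() if b != self.ref_base)


def per_read_mismatch_fraction(read: AlignedRead) -> float:
    """Edit distance divided by the number of aligned query bases (M/=/X)."""
    if read.edit_distance is None:
        raise ValueError(f"read {read.key} has no edit distance (NM)")
    aligned = read.aligned_length
    if aligned == 0:
        raise ValueError(f"read {read.key} has no aligned bases")
    return read.edit_distance / aligned


def _contributes(read: AlignedRead, ref_name: str, thresholds: CountThresholds) -> bool:
    return (
        read.is_mapped
        and not read.is_duplicate
        and read.ref_name == ref_name
        and read.mapq >= thresholds.min_mapq
    )


def count_site(
    reads: Iterable[AlignedRead],
    ref_name: str,
    pos1: int,
    ref_base: str,
    thresholds: CountThresholds,
    ref_seq: Optional[np.ndarray] = None,
) -> PileupSite:
    """Count alleles at a single 1-based position, read by read."""
    if ref_seq is not None and chr(ref_seq[pos1 - 1]) != ref_base:
        raise ValueError(
            f"ref_base {ref_base} disagrees with reference {chr(ref_seq[pos1 - 1])} at {ref_name}:{pos1}"
        )
    pos0 = pos1 - 1
    site = PileupSite(ref_name, pos1, ref_base, 0, {}, 0, thresholds)
    for read in reads:
        if not _contributes(read, ref_name, thresholds):
            continue
        if not (read.pos0 <= pos0 < read.ref_end):
            # an insertion anchored at the last footprint base is inside the
            # footprint, so the range check above suffices
            continue
        if read.indel_touches(pos0):
            site.indel_evidence += 1
            continue
        hit = read.base_at(pos0)
        if hit is None:
            continue
        base, bq = hit
        if bq < thresholds.min_bq or base not in "ACGT":
            continue
        st = site.alleles.setdefault(base, AlleleStats())
        st.count += 1
        if read.strand == "+":
            st.fwd += 1
        else:
            st.rev += 1
        st.bq_sum += bq
        st.mm_sum += per_read_mismatch_fraction(read)
        site.depth += 1
    return site


class PileupMatrix:
    """Per-position allele planes for one contig.

    Arrays have shape ``(ref_len, 4)`` in A/C/G/T order; ``indel`` counts
    reads with indel evidence touching each position.
    """

    def __init__(self, ref_name: str, ref_seq: np.ndarray, thresholds: CountThresholds):
        self.ref_name = ref_name
        self.ref_seq = ref_seq
        self.thresholds = thresholds
        L = len(ref_seq)
        self.counts = np.zeros((L, 4), dtype=np.int64)
        self.fwd = np.zeros((L, 4), dtype=np.int64)
        self.bq_sum = np.zeros((L, 4), dtype=np.float64)
        self.mm_sum = np.zeros((L, 4), dtype=np.float64)
        self.indel = np.zeros(L, dtype=np.int64)

    # -- derived tracks -------------------------------------------------
    @property
    def depth_track(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def ref_codes(self) -> np.ndarray:
        return BASE2CODE[self.ref_seq]

    def nonref_track(self) -> np.ndarray:
        total = self.depth_track
        codes = self.ref_codes
        ok = codes < 4
        ref_counts = np.zeros(len(codes), dtype=np.int64)
        idx = np.nonzero(ok)[0]
        ref_counts[idx] = self.counts[idx, codes[idx]]
        return total - ref_counts

    def site(self, pos1: int) -> PileupSite:
        i = pos1 - 1
        ref_base = chr(self.ref_seq[i])
        alleles: dict[str, AlleleStats] = {}
        for c in range(4):
            n = int(self.counts[i, c])
            if n == 0:
                continue
            alleles[chr(CODE2BASE[c])] = AlleleStats(
                count=n,
                fwd=int(self.fwd[i, c]),
                rev=n - int(self.fwd[i, c]),
                bq_sum=float(self.bq_sum[i, c]),
                mm_sum=float(self.mm_sum[i, c]),
            )
        return PileupSite(
            self.ref_name,
            pos1,
            ref_base,
            int(self.counts[i].sum()),
            alleles,
            int(self.indel[i]),
            self.thresholds,
        )

    def iter_sites(self, positions1: Optional[Iterable[int]] = None) -> Iterator[PileupSite]:
        if positions1 is None:
            positions1 = range(1, len(self.ref_seq) + 1)
        for p in positions1:
            yield self.site(p)


def _add_read_general(mat: PileupMatrix, read: AlignedRead) -> None:
    mm = per_read_mismatch_fraction(read)
    min_bq = mat.thresholds.min_bq
    is_fwd = read.strand == "+"
    touched: set[int] = set()
    r = read.pos0
    for n, op in parse_cigar(read.cigar):
        if op == "I":
            if r - 1 >= 0:
                touched.add(r - 1)
        elif op in "DN":
            touched.update(range(r, r + n))
            r += n
        elif op in "M=X":
            r += n
    for t in sorted(touched):
        if 0 <= t < len(mat.ref_seq):
            mat.indel[t] += 1
    for qpos, rpos, op in read.aligned_pairs():
        if op not in "M=X" or rpos is None or rpos in touched:
            continue
        if not (0 <= rpos < len(mat.ref_seq)):
            continue
        bq = int(read.base_quals[qpos])
        if bq < min_bq:
            continue
        code = BASE2CODE[ord(read.seq[qpos])]
        if code >= 4:
            continue
        mat.counts[rpos, code] += 1
        if is_fwd:
            mat.fwd[rpos, code] += 1
        mat.bq_sum[rpos, code] += bq
        mat.mm_sum[rpos, code] += mm


def pileup_matrix(
    reads: Iterable[AlignedRead],
    ref_name: str,
    ref_seq: np.ndarray,
    thresholds: CountThresholds,
) -> PileupMatrix:
    """Build the full per-position allele planes for one contig."""
    mat = PileupMatrix(ref_name, ref_seq, thresholds)
    L = len(ref_seq)
    starts, seq_chunks, bq_chunks, mm_vals, fwd_flags, lens = [], [], [], [], [], []
    for read in reads:
        if not _contributes(read, ref_name, thresholds):
            continue
        rl = len(read.seq)
        if read.cigar == f"{rl}M" and read.pos0 + rl <= L:
            starts.append(read.pos0)
            seq_chunks.append(np.frombuffer(read.seq.encode("ascii"), dtype=np.uint8))
            bq_chunks.append(np.asarray(read.base_quals, dtype=np.uint8))
            mm_vals.append(per_read_mismatch_fraction(read))
            fwd_flags.append(read.strand == "+")
            lens.append(rl)
        else:
            _add_read_general(mat, read)
    if starts:
        lens_a = np.asarray(lens)
        starts_a = np.asarray(starts)
        pos = np.concatenate([np.arange(s, s + l) for s, l in zip(starts_a, lens_a)])
        seq = np.concatenate(seq_chunks)
        bq = np.concatenate(bq_chunks)
        mm = np.repeat(np.asarray(mm_vals), lens_a)
        fwd = np.repeat(np.asarray(fwd_flags), lens_a)
        code = BASE2CODE[seq]
        keep = (bq >= thresholds.min_bq) & (code < 4)
        pos, code, bq, mm, fwd = pos[keep], code[keep], bq[keep], mm[keep], fwd[keep]
        key = pos * 4 + code
        nbins = 4 * L
        mat.counts += np.bincount(key, minlength=nbins).reshape(L, 4)
        mat.fwd += np.bincount(key[fwd], minlength=nbins).reshape(L, 4)
        mat.bq_sum += np.bincount(key, weights=bq.astype(np.float64), minlength=nbins).reshape(L, 4)
        mat.mm_sum += np.bincount(key, weights=mm, minlength=nbins).reshape(L, 4)
    return mat


def depth_track(
    reads: Iterable[AlignedRead],
    ref_name: str,
    ref_seq: np.ndarray,
    thresholds: CountThresholds,
) -> np.ndarray:
    """Per-position contributing-read depth under the given thresholds."""
    return pileup_matrix(reads, ref_name, ref_seq, thresholds).depth_track


def write_pileup_tsv(path, sites: Iterable[PileupSite]) -> None:
    """bam-readcount-flavoured TSV: one row per site, per-allele blocks."""
    def rows():
        for s in sites:
            blocks = []
            for base in "ACGT":
                a = s.allele(base)
                blocks.append(
                    f"{base}:{a.count}:{a.fwd}:{a.rev}:{a.mean_bq:.2f}:{a.mean_mismatch_fraction:.4f}"
                )
            yield [s.ref_name, s.pos1, s.ref_base, s.depth, s.indel_evidence, *blocks]
    samio.write_tsv(
        path,
        ["chrom", "pos", "ref", "depth", "indel_evidence", "A", "C", "G", "T"],
        rows(),
    )
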