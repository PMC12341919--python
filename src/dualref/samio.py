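"""File-format boundary: FASTA/FASTQ/SAM/BED/TSV readers and writers.

Reading of SAM/BAM goes through pysam and FASTA through Biopython; the
writers emit the plain-text dialects directly.  Everything written here is
round-trippable with the standard tools (``samtools``, pysam, Biopython),
which the test suite exercises.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pysam
from Bio import SeqIO

from .core import AlignedRead, array_to_seq, revcomp, seq_to_array


# ---------------------------------------------------------------- FASTA

def write_fasta(path: str | Path, seqs: Mapping[str, np.ndarray], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, arr in seqs.items():
            fh.write(f">{name}\n")
            s = array_to_seq(arr) if isinstance(arr, np.ndarray) else str(arr)
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, np.ndarray]:
    return {rec.id: seq_to_array(str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------- FASTQ

def write_fastq(path: str | Path, reads: Iterable[tuple[str, np.ndarray, np.ndarray]]) -> None:
    """Write records given as (read_id, seq_bytes, phred_ints)."""
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{array_to_seq(seq)}\n+\n")
            fh.write((qual + 33).astype(np.uint8).tobytes().decode("ascii") + "\n")


# ---------------------------------------------------------------- SAM

def _sam_flag(read: AlignedRead, mate: AlignedRead | None) -> int:
    flag = 0x1  # paired
    if read.is_mapped and mate is not None and mate.is_mapped:
        flag |= 0x2
    if not read.is_mapped:
        flag |= 0x4
    if mate is not None and not mate.is_mapped:
        flag |= 0x8
    if read.strand == "-":
        flag |= 0x10
    if mate is not None and mate.strand == "-":
        flag |= 0x20
    flag |= 0x40 if read.mate_index == 1 else 0x80
    if read.is_duplicate:
        flag |= 0x400
    return flag


def _sam_line(read: AlignedRead, mate: AlignedRead | None) -> str:
    if read.is_mapped:
        rname, pos, mapq, cigar = read.ref_name, read.pos0 + 1, read.mapq, read.cigar
    else:
        rname, pos, mapq, cigar = "*", 0, 0, "*"
    if mate is not None and mate.is_mapped:
        rnext = "=" if (read.is_mapped and mate.ref_name == read.ref_name) else (mate.ref_name or "*")
        pnext = mate.pos0 + 1
    else:
        rnext, pnext = "*", 0
    tlen = 0
    if read.is_mapped and mate is not None and mate.is_mapped and mate.ref_name == read.ref_name:
        left = min(read.pos0, mate.pos0)
        right = max(read.ref_end, mate.ref_end)
        tlen = right - left
        if read.pos0 > mate.pos0 or (read.pos0 == mate.pos0 and read.strand == "-"):
            tlen = -tlen
    # SAM stores SEQ in reference orientation, which is how AlignedRead keeps
    # it already for mapped reads; unmapped reads are emitted as stored.
    qual = (read.base_quals + 33).astype(np.uint8).tobytes().decode("ascii")
    fields = [
        read.read_id,
        str(_sam_flag(read, mate)),
        rname,
        str(pos),
        str(mapq),
        cigar,
        rnext,
        str(pnext),
        str(tlen),
        read.seq,
        qual,
    ]
    if read.align_score is not None:
        fields.append(f"AS:i:{read.align_score}")
    if read.edit_distance is not None:
        fields.append(f"NM:i:{read.edit_distance}")
    return "\t".join(fields)


def write_sam(
    path: str | Path,
    records: Iterable[AlignedRead],
    ref_lengths: Mapping[str, int],
    sort: bool = True,
) -> None:
    """Write paired records as coordinate-sorted SAM with @SQ headers.

    Mate information (RNEXT/PNEXT/TLEN, mate flags) is filled in by pairing
    records that share a read_id.
    """
    records = list(records)
    by_id: dict[str, dict[int, AlignedRead]] = {}
    for r in records:
        by_id.setdefault(r.read_id, {})[r.mate_index] = r
    order = sorted(ref_lengths)
    rank = {name: i for i, name in enumerate(order)}
    if sort:
        records.sort(
            key=lambda r: (rank.get(r.ref_name, len(rank)), r.pos0 if r.is_mapped else 1 << 60, r.read_id, r.mate_index)
        )
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n" if sort else "@HD\tVN:1.6\n")
        for name in order:
            fh.write(f"@SQ\tSN:{name}\tLN:{ref_lengths[name]}\n")
        for r in records:
            mate = by_id[r.read_id].get(2 if r.mate_index == 1 else 1)
            fh.write(_sam_line(r, mate) + "\n")


def read_sam(path: str | Path) -> list[AlignedRead]:
    """Load primary records from a SAM/BAM file; secondary and supplementary
    alignments are dropped (AS/MAPQ comparison is only defined per primary)."""
    out = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for seg in fh:
            if seg.is_secondary or seg.is_supplementary:
                continue
            out.append(AlignedRead.from_pysam(seg))
    return out


# ---------------------------------------------------------------- tables

def write_tsv(path: str | Path, header: list[str], rows: Iterable[Iterable]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(header)
        w.writerows(rows)


def write_bed(path: str | Path, intervals: Iterable[tuple[str, int, int]]) -> None:
    """Write 0-based half-open intervals as BED3."""
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")
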