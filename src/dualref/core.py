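"""Shared primitives: alignment records, CIGAR arithmetic, DNA byte tables.

Sequences are handled internally as ``numpy.uint8`` arrays of ASCII codes
(``A/C/G/T``), which keeps the read simulator and the pileup engine fully
vectorisable while remaining trivially convertible to Python strings at the
I/O boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

DNA = b"ACGT"
#: ASCII byte value -> 0..3 base code (255 for anything else, incl. N)
BASE2CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(DNA):
    BASE2CODE[_b] = _i
    BASE2CODE[ord(chr(_b).lower())] = _i
#: 0..3 base code -> ASCII byte value
CODE2BASE = np.frombuffer(DNA, dtype=np.uint8).copy()

#: byte-level complement table (A<->T, C<->G; everything else maps to itself)
COMPLEMENT = np.arange(256, dtype=np.uint8)
for _x, _y in zip(b"ACGTacgt", b"TGCAtgca"):
    COMPLEMENT[_x] = _y

COMPLEMENT_STR = {"A": "T", "C": "G", "G": "C", "T": "A"}


def seq_to_array(seq: str | bytes) -> np.ndarray:
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return np.frombuffer(seq, dtype=np.uint8).copy()


def array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def revcomp(arr: np.ndarray) -> np.ndarray:
    """Reverse-complement an ASCII byte array."""
    return COMPLEMENT[arr][::-1]


_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

# ops consuming the query / the reference
_Q_OPS = set("MIS=X")
_R_OPS = set("MDN=X")
_ALIGNED_OPS = set("M=X")


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    if cigar in ("*", ""):
        return []
    ops = [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]
    if sum(n for n, op in ops if op in _Q_OPS) == 0 and ops:
        pass
    return ops


def cigar_query_length(cigar: str) -> int:
    return sum(n for n, op in parse_cigar(cigar) if op in _Q_OPS)


def cigar_ref_length(cigar: str) -> int:
    return sum(n for n, op in parse_cigar(cigar) if op in _R_OPS)


def cigar_aligned_length(cigar: str) -> int:
    """Number of query bases placed against reference bases (M/=/X)."""
    return sum(n for n, op in parse_cigar(cigar) if op in _ALIGNED_OPS)


@dataclass(frozen=True)
class ScoringModel:
    """BWA-convention ungapped scoring and the unique/ambiguous MAPQ levels.

    BWA-MEM assigns +1 per matching base and -4 per mismatch by default, so
    an ungapped, unclipped read of length L with m mismatches scores L - 5m.
    A read placed uniquely gets MAPQ 60; a read with at least one equally
    good alternative placement gets MAPQ 0.
    """

    match_score: int = 1
    mismatch_penalty: int = -4
    mapq_unique: int = 60
    mapq_ambiguous: int = 0

    def alignment_score(self, n_match: int, n_mismatch: int) -> int:
        return n_match * self.match_score + n_mismatch * self.mismatch_penalty


DEFAULT_SCORING = ScoringModel()


@dataclass
class AlignedRead:
    """One read's alignment against one reference.

    ``pos0`` is the 0-based leftmost reference position.  ``seq`` and
    ``base_quals`` are stored in *reference* orientation (as in SAM), with
    ``strand`` recording which genomic strand the read derives from.
    ``align_score``/``edit_distance`` mirror the SAM ``AS:i``/``NM:i`` tags.
    """

    read_id: str
    mate_index: int
    ref_name: Optional[str]
    pos0: int
    cigar: str
    mapq: int
    align_score: Optional[int]
    edit_distance: Optional[int]
    strand: str
    seq: str
    base_quals: np.ndarray
    is_mapped: bool = True
    is_duplicate: bool = False

    @property
    def key(self) -> tuple[str, int]:
        return (self.read_id, self.mate_index)

    @property
    def ref_end(self) -> int:
        """0-based exclusive end of the reference footprint."""
        return self.pos0 + cigar_ref_length(self.cigar)

    @property
    def aligned_length(self) -> int:
        return cigar_aligned_length(self.cigar)

    def aligned_pairs(self) -> Iterator[tuple[Optional[int], Optional[int], str]]:
        """Yield (query_pos, ref_pos, op) for M/=/X, I (ref None) and D
        (query None) operations, pysam-style."""
        q, r = 0, self.pos0
        for n, op in parse_cigar(self.cigar):
            if op in _ALIGNED_OPS:
                for k in range(n):
                    yield q + k, r + k, op
                q += n
                r += n
            elif op == "I":
                for k in range(n):
                    yield q + k, None, op
                q += n
            elif op in "DN":
                for k in range(n):
                    yield None, r + k, op
                r += n
            elif op == "S":
                q += n
            # H/P consume nothing we track

    def base_at(self, rpos0: int) -> Optional[tuple[str, int]]:
        """Base and quality this read places at reference position ``rpos0``,
        or ``None`` if the position is outside the footprint or deleted."""
        q, r = 0, self.pos0
        for n, op in parse_cigar(self.cigar):
            if op in _ALIGNED_OPS:
                if r <= rpos0 < r + n:
                    qi = q + (rpos0 - r)
                    return self.seq[qi], int(self.base_quals[qi])
                q += n
                r += n
            elif op == "I":
                q += n
            elif op in "DN":
                if r <= rpos0 < r + n:
                    return None
                r += n
            elif op == "S":
                q += n
        return None

    def indel_touches(self, rpos0: int) -> bool:
        """True if a deletion spans ``rpos0`` or an insertion is anchored at
        the base to its left (i.e. the insertion sits between ``rpos0`` and
        ``rpos0 + 1``)."""
        r = self.pos0
        for n, op in parse_cigar(self.cigar):
            if op in _ALIGNED_OPS:
                r += n
            elif op == "I":
                # inserted segment between r-1 and r; anchored to r-1
                if rpos0 == r - 1:
                    return True
            elif op in "DN":
                if r <= rpos0 < r + n:
                    return True
                r += n
        return False

    @classmethod
    def from_pysam(cls, seg) -> "AlignedRead":
        quals = seg.query_qualities
        tags = dict(seg.get_tags())
        return cls(
            read_id=seg.query_name,
            mate_index=2 if seg.is_read2 else 1,
            ref_name=seg.reference_name if not seg.is_unmapped else None,
            pos0=seg.reference_start if not seg.is_unmapped else -1,
            cigar=seg.cigarstring or "*",
            mapq=seg.mapping_quality,
            align_score=tags.get("AS"),
            edit_distance=tags.get("NM"),
            strand="-" if seg.is_reverse else "+",
            seq=seg.query_sequence or "",
            base_quals=np.array(quals, dtype=np.uint8) if quals is not None else np.zeros(0, np.uint8),
            is_mapped=not seg.is_unmapped,
            is_duplicate=seg.is_duplicate,
        )
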