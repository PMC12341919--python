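"""Per-read choice between the haploid and the diploid reference.

Each read is aligned to both assemblies; the record with the higher
alignment score wins, ties are broken by the higher MAPQ, and a full tie
goes to the diploid assembly (which represents both haplotypes and is the
safer default).  A read mapped against only one assembly stays there.
Clipped reads and duplicate-flagged reads are removed from both outputs
after the decision is logged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .core import AlignedRead, parse_cigar
from . import samio

MAPQ_UNAVAILABLE = 255  # SAM convention: mapping quality not available


@dataclass
class AssignmentDecision:
    read_id: str
    mate_index: int
    assigned_to: str  # 'haploid' | 'diploid'
    reason: str  # 'score' | 'mapq' | 'default' | 'only_mapped_one'
    hap_score: Optional[int] = None
    dip_score: Optional[int] = None
    hap_mapq: Optional[int] = None
    dip_mapq: Optional[int] = None


@dataclass
class PartitionResult:
    haploid: list[AlignedRead]
    diploid: list[AlignedRead]
    decisions: list[AssignmentDecision]
    excluded: list[tuple[tuple[str, int], str]]  # (key, cause)


def is_clipped(read: AlignedRead) -> bool:
    """True iff the CIGAR contains a soft (S) or hard (H) clip."""
    return any(op in "SH" for _, op in parse_cigar(read.cigar))


def _effective_mapq(mapq: int) -> int:
    """MAPQ 255 means 'unavailable'; it loses ties against any numeric MAPQ."""
    return -1 if mapq == MAPQ_UNAVAILABLE else mapq


def assign_read(
    hap: Optional[AlignedRead], dip: Optional[AlignedRead]
) -> AssignmentDecision:
    """Apply the alignment-score -> MAPQ -> diploid-default hierarchy."""
    hap_ok = hap is not None and hap.is_mapped
    dip_ok = dip is not None and dip.is_mapped
    if not hap_ok and not dip_ok:
        raise ValueError("assign_read requires at least one mapped record")
    rid, mate = (hap.key if hap_ok else dip.key)
    kw = dict(
        hap_score=hap.align_score if hap_ok else None,
        dip_score=dip.align_score if dip_ok else None,
        hap_mapq=hap.mapq if hap_ok else None,
        dip_mapq=dip.mapq if dip_ok else None,
    )
    if hap_ok and not dip_ok:
        return AssignmentDecision(rid, mate, "haploid", "only_mapped_one", **kw)
    if dip_ok and not hap_ok:
        return AssignmentDecision(rid, mate, "diploid", "only_mapped_one", **kw)
    if hap.align_score is None or dip.align_score is None:
        raise ValueError(f"mapped record without alignment score for {rid}/{mate}")
    if hap.align_score != dip.align_score:
        side = "haploid" if hap.align_score > dip.align_score else "diploid"
        return AssignmentDecision(rid, mate, side, "score", **kw)
    hq, dq = _effective_mapq(hap.mapq), _effective_mapq(dip.mapq)
    if hq != dq:
        side = "haploid" if hq > dq else "diploid"
        return AssignmentDecision(rid, mate, side, "mapq", **kw)
    return AssignmentDecision(rid, mate, "diploid", "default", **kw)


def _index(stream: Iterable[AlignedRead], label: str) -> dict[tuple[str, int], AlignedRead]:
    idx: dict[tuple[str, int], AlignedRead] = {}
    for r in stream:
        if r.key in idx:
            raise ValueError(f"duplicate primary record for {r.key} in {label} stream")
        idx[r.key] = r
    return idx


def partition_alignments(
    hap_stream: Iterable[AlignedRead],
    dip_stream: Iterable[AlignedRead],
) -> PartitionResult:
    """Assign every mapped read to exactly one reference.

    Outputs are disjoint by (read_id, mate).  Reads clipped in either
    mapping, or flagged as duplicates, are excluded from both outputs (the
    decision is still logged).  Reads unmapped on both sides are skipped.
    """
    hap_idx = _index(hap_stream, "haploid")
    dip_idx = _index(dip_stream, "diploid")
    keys = sorted(set(hap_idx) | set(dip_idx))
    res = PartitionResult([], [], [], [])
    for key in keys:
        hap = hap_idx.get(key)
        dip = dip_idx.get(key)
        hap_ok = hap is not None and hap.is_mapped
        dip_ok = dip is not None and dip.is_mapped
        if not hap_ok and not dip_ok:
            continue
        dec = assign_read(hap if hap_ok else None, dip if dip_ok else None)
        res.decisions.append(dec)
        if (hap_ok and is_clipped(hap)) or (dip_ok and is_clipped(dip)):
            res.excluded.append((key, "clipped"))
            continue
        if (hap_ok and hap.is_duplicate) or (dip_ok and dip.is_duplicate):
            res.excluded.append((key, "duplicate"))
            continue
        if dec.assigned_to == "haploid":
            res.haploid.append(hap)
        else:
            res.diploid.append(dip)
    return res


def write_decision_log(path, decisions: Iterable[AssignmentDecision]) -> None:
    samio.write_tsv(
        path,
        ["read_id", "mate", "hap_AS", "dip_AS", "hap_MQ", "dip_MQ", "assigned_to", "reason"],
        (
            [d.read_id, d.mate_index, d.hap_score, d.dip_score, d.hap_mapq, d.dip_mapq, d.assigned_to, d.reason]
            for d in decisions
        ),
    )
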