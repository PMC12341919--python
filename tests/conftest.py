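"""Shared fixtures: hand-built reads and session-scoped simulations.

The expensive end-to-end simulations (the 50-implant recovery run and the
ten null replicates) are session-scoped so the somatic-calling unit tests
and the acceptance tests share one computation.
"""

import numpy as np
import pytest

from dualref.core import AlignedRead
from dualref.pipeline import run_synthetic_experiment

RECOVERY_SEED = 101
NULL_SEEDS = list(range(201, 211))


def make_read(
    read_id="r1",
    mate_index=1,
    ref_name="chr1",
    pos0=0,
    cigar=None,
    mapq=60,
    align_score=None,
    edit_distance=0,
    strand="+",
    seq="A" * 100,
    bq=38,
    is_mapped=True,
    is_duplicate=False,
):
    """Construct an AlignedRead with sensible defaults for fixtures."""
    if cigar is None:
        cigar = f"{len(seq)}M"
    if align_score is None:
        align_score = len(seq) - 5 * (edit_distance or 0)
    quals = np.full(len(seq), bq, dtype=np.uint8) if np.isscalar(bq) else np.asarray(bq, np.uint8)
    return AlignedRead(
        read_id=read_id,
        mate_index=mate_index,
        ref_name=ref_name,
        pos0=pos0,
        cigar=cigar,
        mapq=mapq,
        align_score=align_score,
        edit_distance=edit_distance,
        strand=strand,
        seq=seq,
        base_quals=quals,
        is_mapped=is_mapped,
        is_duplicate=is_duplicate,
    )


@pytest.fixture(scope="session")
def recovery_result():
    """Mutant/control pair at 60x with 50 L2-fixed implants (VAF 0.3)."""
    return run_synthetic_experiment(
        seed=RECOVERY_SEED, chrom_len=200_000, n_per_layer={"L2": 50}, depth=60
    )


@pytest.fixture(scope="session")
def null_results():
    """Ten replicate mutant/control pairs with zero implants at 60x."""
    return [
        run_synthetic_experiment(seed=s, chrom_len=100_000, n_per_layer=0, depth=60)
        for s in NULL_SEEDS
    ]
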