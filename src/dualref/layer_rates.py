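"""Meristem-layer VAF model, transmissible-mutation classification,
mutation rates, and the substitution spectrum.

The shoot apical meristem of seed plants maintains clonally segregated cell
layers: L1 (epidermis), L2 (photosynthetic and germ tissue) and L3 (ground
tissue).  A somatic mutation fixed in one layer appears in whole-organ
sequencing at a VAF of half that layer's DNA contribution (it sits on one
haplotype).  The L2 fraction is estimated from mutations shared between
leaves and embryonic tissue (which derives from L2): if their median VAF is
v, L2 contributes 2v of the sample DNA, L1 + L3 contribute 1 - 2v, and
since L1 contributes less than L3 its share is bounded by half of that
remainder.  Only L2 mutations can reach the next generation, so mutation
rates are computed over calls at or above the L2-consistent VAF thresholds
(0.2 against the haploid reference; 0.4 against the diploid reference,
where coverage is split between haplotypes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .core import COMPLEMENT_STR
from .somatic_calling import SomaticCall
from . import samio

#: the six pyrimidine-context substitution classes
PYRIMIDINE_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: both-strand notation, e.g. C>T is reported as C:G>T:A
BOTH_STRAND_LABELS = {
    "C>A": "C:G>A:T",
    "C>G": "C:G>G:C",
    "C>T": "C:G>T:A",
    "T>A": "T:A>A:T",
    "T>C": "T:A>C:G",
    "T>G": "T:A>G:C",
}


@dataclass
class LayerModel:
    """Layer DNA fractions and VAF expectations derived from shared-SNV VAFs."""

    median_shared_vaf: float
    vaf_threshold_haploid: float = 0.2
    vaf_threshold_diploid: float = 0.4

    @property
    def l2_fraction(self) -> float:
        return 2.0 * self.median_shared_vaf

    @property
    def l1_plus_l3_fraction(self) -> float:
        return 1.0 - self.l2_fraction

    @property
    def l1_upper_bound(self) -> float:
        # L1 contributes less than L3, so at most half the non-L2 DNA
        return self.l1_plus_l3_fraction / 2.0

    @property
    def expected_l1_vaf_upper(self) -> float:
        return self.l1_upper_bound / 2.0

    def as_dict(self) -> dict[str, float]:
        return {
            "median_shared_vaf": self.median_shared_vaf,
            "l2_fraction": self.l2_fraction,
            "l1_plus_l3_fraction": self.l1_plus_l3_fraction,
            "l1_upper_bound": self.l1_upper_bound,
            "expected_l1_vaf_upper": self.expected_l1_vaf_upper,
            "vaf_threshold_haploid": self.vaf_threshold_haploid,
            "vaf_threshold_diploid": self.vaf_threshold_diploid,
        }


def estimate_layer_model(
    shared_vafs: Sequence[float], statistic: str = "median"
) -> LayerModel:
    """Estimate the layer model from VAFs of leaf/embryo-shared mutations."""
    vafs = [float(v) for v in shared_vafs]
    if not vafs:
        raise ValueError("at least one shared VAF is required")
    if any(not (0.0 < v <= 0.5) for v in vafs):
        raise ValueError("shared VAFs must lie in (0, 0.5]")
    if statistic == "median":
        center = float(np.median(vafs))
    elif statistic == "mean":
        center = float(np.mean(vafs))
    else:
        raise ValueError("statistic must be 'median' or 'mean'")
    return LayerModel(median_shared_vaf=center)


def classify_l2_calls(
    calls: Iterable[SomaticCall], model: LayerModel
) -> list[SomaticCall]:
    """Calls consistent with fixation in L2 (hence transmissible): VAF at
    least 0.2 in haploid mode or 0.4 in diploid mode."""
    out = []
    for c in calls:
        thr = (
            model.vaf_threshold_haploid
            if c.mode == "haploid"
            else model.vaf_threshold_diploid
        )
        if c.vaf >= thr:
            out.append(c)
    return out


@dataclass
class MutationRateEstimate:
    n_mutations: int
    effective_sites: float
    age_years: float
    generation_years: float

    @property
    def raw_rate(self) -> float:
        """Mutations per effective site (bp^-1)."""
        return self.n_mutations / self.effective_sites

    @property
    def annual_rate(self) -> float:
        """bp^-1 year^-1."""
        return self.raw_rate / self.age_years

    @property
    def generational_rate(self) -> float:
        """bp^-1 generation^-1 (a lower bound, since mutations arising after
        the sampled branch formed are mostly unseen)."""
        return self.annual_rate * self.generation_years

    def rounded(self, sigfigs: int = 2) -> dict[str, float]:
        return {
            "raw_rate": round_sig(self.raw_rate, sigfigs),
            "annual_rate": round_sig(self.annual_rate, sigfigs),
            "generational_rate": round_sig(self.generational_rate, sigfigs),
        }


def round_sig(x: float, sigfigs: int) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sigfigs - 1))


def mutation_rate(
    n: int,
    effective_sites: float,
    age_years: float = 234.0,
    generation_years: float = 50.0,
) -> MutationRateEstimate:
    """Per-site, annual and generational mutation rates.

    ``age_years`` defaults to the sampled tree's age; ``generation_years``
    to a typical oak generation time.
    """
    if effective_sites <= 0:
        raise ValueError("effective_sites must be positive")
    if age_years <= 0 or generation_years <= 0:
        raise ValueError("age and generation time must be positive")
    if n < 0:
        raise ValueError("n must be non-negative")
    return MutationRateEstimate(n, effective_sites, age_years, generation_years)


# ---------------------------------------------------------------- spectrum

def fold_substitution(ref: str, alt: str) -> str:
    """Fold a substitution onto the pyrimidine strand (G>A -> C>T etc.)."""
    ref, alt = ref.upper(), alt.upper()
    if ref not in "ACGT" or alt not in "ACGT":
        raise ValueError(f"ambiguous or non-DNA alleles: {ref}>{alt}")
    if ref == alt:
        raise ValueError(f"ref and alt alleles are identical: {ref}")
    if ref in "AG":
        ref, alt = COMPLEMENT_STR[ref], COMPLEMENT_STR[alt]
    return f"{ref}>{alt}"


@dataclass
class SpectrumTable:
    counts: dict[str, int] = field(
        default_factory=lambda: {k: 0 for k in PYRIMIDINE_CLASSES}
    )

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def fractions(self) -> dict[str, float]:
        t = self.total
        return {k: (v / t if t else 0.0) for k, v in self.counts.items()}

    def both_strand(self) -> dict[str, int]:
        return {BOTH_STRAND_LABELS[k]: v for k, v in self.counts.items()}

    def to_tsv(self, path) -> None:
        samio.write_tsv(
            path,
            ["class", "both_strand", "count", "fraction"],
            (
                [k, BOTH_STRAND_LABELS[k], self.counts[k], f"{f:.4f}"]
                for k, f in self.fractions().items()
            ),
        )


def mutation_spectrum(
    calls: Iterable[SomaticCall],
    reference: Optional[Mapping[str, np.ndarray]] = None,
) -> SpectrumTable:
    """Tabulate SNVs over the six pyrimidine-context classes.

    When a reference is supplied, each call's ref allele is checked against
    it (a mismatch indicates a coordinate/allele bookkeeping bug upstream).
    """
    table = SpectrumTable()
    for c in calls:
        if reference is not None:
            ref_base = chr(reference[c.ref_name][c.pos1 - 1])
            if ref_base != c.ref_allele:
                raise ValueError(
                    f"call ref allele {c.ref_allele} disagrees with reference "
                    f"{ref_base} at {c.ref_name}:{c.pos1}"
                )
        table.counts[fold_substitution(c.ref_allele, c.alt_allele)] += 1
    return table
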