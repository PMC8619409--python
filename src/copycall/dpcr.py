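"""Digital PCR absolute quantification under the Poisson occupancy model.

Template molecules distribute over thousands of partitions at random, so
the fraction of positive partitions p yields the mean copies per partition
lambda = -ln(1 - p) per channel.  The per-genome transgene dosage is then
2 * lambda_target / lambda_reference, since the endogenous reference gene
sits at two copies per diploid genome.  Used to cross-validate the qPCR
copy calls on an independent chemistry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from copycall.quantification import DEFAULT_AMBIGUITY_HALFWIDTH, call_copy_class

#: reference-gene copies per diploid genome
DEFAULT_REFERENCE_PLOIDY = 2.0


@dataclass(frozen=True)
class PartitionCount:
    """Positive/total partition counts for one chip channel."""

    channel: str  # "transgene" | "reference"
    n_positive: int
    n_total: int
    partition_volume_nl: float | None = None

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")
        if not 0 <= self.n_positive <= self.n_total:
            raise ValueError("n_positive must be within [0, n_total]")
        if self.partition_volume_nl is not None and self.partition_volume_nl <= 0:
            raise ValueError("partition_volume_nl must be positive")

    @property
    def positive_fraction(self) -> float:
        return self.n_positive / self.n_total


@dataclass(frozen=True)
class DpcrCopyResult:
    lambda_target: float
    lambda_ref: float
    copies_per_genome: float
    copy_class: object
    ambiguous: bool
    copies_per_ul: float | None = None


def lambda_from_partitions(pc: PartitionCount) -> float:
    """Mean template copies per partition, lambda = -ln(1 - p).

    Saturated chips (every partition positive) carry no quantitative
    information and are rejected.
    """
    if pc.n_positive == pc.n_total:
        raise ValueError("chip saturated (all partitions positive); lambda undefined")
    return -math.log1p(-pc.positive_fraction)


def lambda_confidence_interval(pc: PartitionCount, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval on the positive fraction, propagated to lambda."""
    z = stats.norm.ppf(0.5 + level / 2.0)
    n, p = pc.n_total, pc.positive_fraction
    denom = 1 + z**2 / n
    centre = (p + z**2 / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    lo, hi = max(0.0, centre - half), min(centre + half, 1.0 - 1e-12)
    return -math.log1p(-lo), -math.log1p(-hi)


def dpcr_copy_number(
    target: PartitionCount,
    ref: PartitionCount,
    reference_ploidy: float = DEFAULT_REFERENCE_PLOIDY,
    ambiguity_halfwidth: float = DEFAULT_AMBIGUITY_HALFWIDTH,
) -> DpcrCopyResult:
    """Per-genome transgene copy number from one duplexed chip.

    copies/genome = reference_ploidy * lambda_target / lambda_ref.  The
    integer class uses the same nearest-integer-with-dead-zone rule as the
    qPCR pipeline, so the two methods are directly comparable.  Copies/uL
    is populated only when both channels carry partition volumes.
    """
    lam_t = lambda_from_partitions(target)
    lam_r = lambda_from_partitions(ref)
    if lam_r <= 0:
        raise ValueError("reference channel all-negative; cannot normalize")
    copies = reference_ploidy * lam_t / lam_r
    cls, ambiguous = call_copy_class(copies, ambiguity_halfwidth)
    per_ul = None
    if target.partition_volume_nl is not None:
        per_ul = lam_t / (target.partition_volume_nl * 1e-3)
    return DpcrCopyResult(
        lambda_target=lam_t,
        lambda_ref=lam_r,
        copies_per_genome=copies,
        copy_class=cls,
        ambiguous=ambiguous,
        copies_per_ul=per_ul,
    )
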