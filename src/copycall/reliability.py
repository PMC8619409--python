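"""Replicate-reliability estimation by simple random subsampling.

How much accuracy is lost by running one technical replicate instead of
three?  Taking the three-replicate mean as the true value, r replicates are
drawn at random from each sampled individual's three, averaged, re-called,
and compared with the truth.  The per-class concordance fraction estimates
the reliability of an r-replicate assay; it is 1 at r = 3 by construction
and decreases as class midpoints crowd together (two-copy calls are less
robust than one-copy calls under the same Ct noise).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from copycall.quantification import (
    DEFAULT_AMBIGUITY_HALFWIDTH,
    DEFAULT_CALIBRATOR_COPIES,
    PfafflInput,
    call_copy_class,
    pfaffl_copy_number,
)


@dataclass(frozen=True)
class ReplicateTriple:
    """One sample's three technical replicates (test-well Cts, both channels)."""

    sample_id: str
    ct_target: tuple[float, float, float]
    ct_ref: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.ct_target) != 3 or len(self.ct_ref) != 3:
            raise ValueError("exactly 3 technical replicates are required per channel")


@dataclass(frozen=True)
class QuantContext:
    """Calibrator Cts and assay efficiencies shared by a whole dataset."""

    e_target: float
    e_ref: float
    ct_target_cal: float
    ct_ref_cal: float
    calibrator_copies: float = DEFAULT_CALIBRATOR_COPIES
    ambiguity_halfwidth: float = DEFAULT_AMBIGUITY_HALFWIDTH


@dataclass(frozen=True)
class ConcordanceReport:
    r: int
    n_sampled: int
    n_draws: int
    per_class: dict
    seed: int


def _call(ctx: QuantContext, ct_t: float, ct_r: float):
    est = pfaffl_copy_number(
        PfafflInput(
            e_target=ctx.e_target,
            e_ref=ctx.e_ref,
            ct_target_cal=ctx.ct_target_cal,
            ct_target_test=ct_t,
            ct_ref_cal=ctx.ct_ref_cal,
            ct_ref_test=ct_r,
        ),
        calibrator_copies=ctx.calibrator_copies,
    )
    cls, _ = call_copy_class(est, ctx.ambiguity_halfwidth)
    return cls


def truth_classes(dataset: Sequence[ReplicateTriple], ctx: QuantContext) -> list:
    """Copy class of each sample from its three-replicate mean Ct."""
    return [
        _call(ctx, float(np.mean(t.ct_target)), float(np.mean(t.ct_ref)))
        for t in dataset
    ]


def subsample_concordance(
    dataset: Sequence[ReplicateTriple],
    ctx: QuantContext,
    r: int,
    n: int | None = None,
    n_draws: int = 1,
    seed: int = 0,
    average: str = "ct",
) -> ConcordanceReport:
    """Estimate r-replicate concordance with the 3-replicate truth.

    Each draw samples ``n`` individuals without replacement; for each, ``r``
    of its three replicates are drawn without replacement and averaged —
    per-channel Ct averaging then one ratio by default, or per-replicate
    estimates averaged when ``average="estimate"``.  The re-called class is
    compared with the sample's own 3-replicate truth; fractions are
    reported per truth class, pooled over draws.  All randomness flows from
    one seeded generator, so reports are reproducible bit-for-bit.
    """
    if r not in (1, 2, 3):
        raise ValueError("r must be 1, 2 or 3")
    if n is None:
        n = len(dataset)
    if n > len(dataset):
        raise ValueError(f"n = {n} exceeds dataset size {len(dataset)}")
    if average not in ("ct", "estimate"):
        raise ValueError(f"unknown average mode {average!r}")

    rng = np.random.default_rng(seed)
    truths = truth_classes(dataset, ctx)
    agree: dict[object, int] = {}
    total: dict[object, int] = {}
    for _ in range(n_draws):
        idx = rng.choice(len(dataset), size=n, replace=False)
        for i in idx:
            triple = dataset[i]
            reps = rng.choice(3, size=r, replace=False)
            if average == "ct":
                called = _call(
                    ctx,
                    float(np.mean([triple.ct_target[j] for j in reps])),
                    float(np.mean([triple.ct_ref[j] for j in reps])),
                )
            else:
                ests = [
                    pfaffl_copy_number(
                        PfafflInput(
                            e_target=ctx.e_target,
                            e_ref=ctx.e_ref,
                            ct_target_cal=ctx.ct_target_cal,
                            ct_target_test=triple.ct_target[j],
                            ct_ref_cal=ctx.ct_ref_cal,
                            ct_ref_test=triple.ct_ref[j],
                        ),
                        calibrator_copies=ctx.calibrator_copies,
                    )
                    for j in reps
                ]
                called, _ = call_copy_class(float(np.mean(ests)), ctx.ambiguity_halfwidth)
            truth = truths[i]
            total[truth] = total.get(truth, 0) + 1
            if called == truth:
                agree[truth] = agree.get(truth, 0) + 1
    per_class = {cls: agree.get(cls, 0) / cnt for cls, cnt in sorted(total.items(), key=str)}
    return ConcordanceReport(r=r, n_sampled=n, n_draws=n_draws, per_class=per_class, seed=seed)
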