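"""Efficiency-corrected relative quantification and integer copy calling.

The core statistic is the Pfaffl ratio against an inter-run calibrator of
known transgene dosage:

    copies = C_cal * (1 + E_target)^(Ct_target,cal - Ct_target,test)
                   / (1 + E_ref)^(Ct_ref,cal - Ct_ref,test)

where E are the per-assay amplification efficiencies from the standard
curves and C_cal is the calibrator's diploid transgene dosage (default 2,
i.e. a homozygous single-locus calibrator; with equal efficiencies and a
doubling base this collapses to the familiar 2^-ddCt form).  Continuous
estimates are then snapped to integer copy classes {0, 1, 2, >2} with an
explicit ambiguity dead-zone around the class midpoints.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from copycall.plates import (
    DEFAULT_CT_CUTOFF,
    CtRecord,
    SampleRole,
    validate_controls,
)
from copycall.standard_curve import StandardCurveFit

COPY_CLASSES = (0, 1, 2, "gt2")

#: calibrator transgene copies per diploid genome reproducing the standard
#: prefactor of 2 in the quantification formula
DEFAULT_CALIBRATOR_COPIES = 2.0

#: half-width of the ambiguity dead zone around class midpoints k + 0.5
DEFAULT_AMBIGUITY_HALFWIDTH = 0.15


@dataclass(frozen=True)
class ReplicateSummary:
    """Mean/SD/CV of technical-replicate Ct values."""

    n: int
    mean_ct: float
    sd_ct: float
    cv_percent: float


@dataclass(frozen=True)
class PfafflInput:
    """The four Ct values and two efficiencies entering the ratio."""

    e_target: float
    e_ref: float
    ct_target_cal: float
    ct_target_test: float
    ct_ref_cal: float
    ct_ref_test: float

    def __post_init__(self) -> None:
        for name in ("e_target", "e_ref"):
            e = getattr(self, name)
            if not 0.0 < e <= 1.2:
                raise ValueError(f"{name} must be in (0, 1.2], got {e}")
        for name in ("ct_target_cal", "ct_target_test", "ct_ref_cal", "ct_ref_test"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class CopyCall:
    """Continuous copy estimate plus its integer class for one sample."""

    sample_id: str
    estimate: float | None
    copy_class: object | None  # 0, 1, 2 or "gt2"; None when no call
    ambiguous: bool = False
    notes: tuple[str, ...] = field(default_factory=tuple)


def aggregate_replicates(cts: Sequence[float], sd_mode: str = "sample") -> ReplicateSummary:
    """Mean, SD and CV% of replicate Ct values.

    CV = 100 * SD / mean.  ``sd_mode`` selects the n-1 (sample, default) or
    n (population) denominator; a single replicate has SD defined as 0.
    """
    if len(cts) == 0:
        raise ValueError("empty replicate set")
    if any(not math.isfinite(c) for c in cts):
        raise ValueError("non-finite Ct in replicate set")
    if sd_mode not in ("sample", "population"):
        raise ValueError(f"unknown sd_mode {sd_mode!r}")
    mean = statistics.fmean(cts)
    if len(cts) == 1:
        sd = 0.0
    elif sd_mode == "sample":
        sd = statistics.stdev(cts)
    else:
        sd = statistics.pstdev(cts)
    cv = 100.0 * sd / mean if mean > 0 else 0.0
    return ReplicateSummary(n=len(cts), mean_ct=mean, sd_ct=sd, cv_percent=cv)


def pfaffl_copy_number(
    inp: PfafflInput, calibrator_copies: float = DEFAULT_CALIBRATOR_COPIES
) -> float:
    """Efficiency-corrected copy estimate against the inter-run calibrator.

    Ct differences are taken calibrator minus test; the per-cycle
    amplification base is 1 + efficiency, so E = 1 means doubling.
    """
    num = (1.0 + inp.e_target) ** (inp.ct_target_cal - inp.ct_target_test)
    den = (1.0 + inp.e_ref) ** (inp.ct_ref_cal - inp.ct_ref_test)
    return calibrator_copies * num / den


def call_copy_class(
    estimate: float, ambiguity_halfwidth: float = DEFAULT_AMBIGUITY_HALFWIDTH
) -> tuple[object, bool]:
    """Snap a continuous estimate to {0, 1, 2, "gt2"}.

    The class is the nearest integer, capped at ">2".  Estimates within
    ``ambiguity_halfwidth`` of a class midpoint (k + 0.5) fall in a dead
    zone and are flagged ambiguous; the nearest class is still reported.
    """
    if not math.isfinite(estimate) or estimate < 0:
        raise ValueError(f"estimate must be finite and >= 0, got {estimate}")
    if not 0 <= ambiguity_halfwidth < 0.5:
        raise ValueError("ambiguity_halfwidth must be in [0, 0.5)")
    nearest = int(round(estimate))
    # distance to the nearest midpoint k + 0.5; estimates below 0.5 have no
    # lower midpoint and are never ambiguous toward zero from below
    frac = estimate - math.floor(estimate)
    ambiguous = abs(frac - 0.5) <= ambiguity_halfwidth and estimate >= 0.5 - ambiguity_halfwidth
    cls: object = nearest if nearest <= 2 else "gt2"
    if estimate > 2.5:  # anything past the 2/3 midpoint reports as >2
        cls = "gt2"
    return cls, ambiguous


@dataclass
class BatchReport:
    """Per-batch metadata accompanying the copy calls."""

    calibrator_id: str
    n_samples: int
    n_called: int
    n_ambiguous: int
    control_report: object | None = None
    notes: tuple[str, ...] = field(default_factory=tuple)


def _collect_cts(
    records: Sequence[CtRecord],
) -> dict[str, dict[str, list[float | None]]]:
    by_sample: dict[str, dict[str, list[float | None]]] = {}
    for rec in records:
        by_sample.setdefault(rec.sample_id, {"transgene": [], "reference": []})[
            rec.target
        ].append(rec.ct)
    return by_sample


def analyze_t0_batch(
    records: Sequence[CtRecord],
    layout: Mapping[str, SampleRole],
    curves: Mapping[str, StandardCurveFit],
    calibrator_id: str,
    calibrator_copies: float = DEFAULT_CALIBRATOR_COPIES,
    ambiguity_halfwidth: float = DEFAULT_AMBIGUITY_HALFWIDTH,
    ct_cutoff: float = DEFAULT_CT_CUTOFF,
    force: bool = False,
) -> tuple[list[CopyCall], BatchReport]:
    """Copy-call every test sample of one batch against its calibrator.

    Technical replicates are averaged per channel before the ratio is
    formed.  A sample whose transgene channel never amplified but whose
    reference channel did is a transformation escape (class 0); a sample
    with a failed reference channel gets no call.  Control validation must
    pass unless ``force`` is set (recorded in the report notes).
    """
    notes: list[str] = []
    control_report = validate_controls(records, layout, ct_cutoff)
    if not control_report.passed:
        if not force:
            raise ValueError("control validation failed:\n" + control_report.to_text())
        notes.append("control validation FAILED; proceeding under force override")

    by_sample = _collect_cts(records)
    if calibrator_id not in by_sample:
        raise ValueError(f"calibrator {calibrator_id!r} not present in batch")
    cal = by_sample[calibrator_id]
    cal_t = [c for c in cal["transgene"] if c is not None]
    cal_r = [c for c in cal["reference"] if c is not None]
    if not cal_t or not cal_r:
        raise ValueError(f"calibrator {calibrator_id!r} has an undetermined channel")
    ct_target_cal = aggregate_replicates(cal_t).mean_ct
    ct_ref_cal = aggregate_replicates(cal_r).mean_ct
    e_target = curves["transgene"].efficiency
    e_ref = curves["reference"].efficiency

    roles_by_sample: dict[str, str] = {}
    for rec in records:
        role = layout.get(rec.well.key, layout.get(rec.well.label))
        if role is not None:
            roles_by_sample.setdefault(rec.sample_id, role.role)

    calls: list[CopyCall] = []
    for sample_id, channels in by_sample.items():
        if roles_by_sample.get(sample_id) != "test":
            continue
        t_cts = [c for c in channels["transgene"] if c is not None and c < ct_cutoff]
        r_cts = [c for c in channels["reference"] if c is not None and c < ct_cutoff]
        if not r_cts:
            calls.append(
                CopyCall(sample_id, None, None, notes=("reference channel undetermined; no call",))
            )
            continue
        if not t_cts:
            calls.append(
                CopyCall(sample_id, 0.0, 0, notes=("transgene channel undetermined; escape",))
            )
            continue
        est = pfaffl_copy_number(
            PfafflInput(
                e_target=e_target,
                e_ref=e_ref,
                ct_target_cal=ct_target_cal,
                ct_target_test=aggregate_replicates(t_cts).mean_ct,
                ct_ref_cal=ct_ref_cal,
                ct_ref_test=aggregate_replicates(r_cts).mean_ct,
            ),
            calibrator_copies=calibrator_copies,
        )
        cls, ambiguous = call_copy_class(est, ambiguity_halfwidth)
        calls.append(CopyCall(sample_id, est, cls, ambiguous=ambiguous))

    report = BatchReport(
        calibrator_id=calibrator_id,
        n_samples=len(calls),
        n_called=sum(1 for c in calls if c.copy_class is not None),
        n_ambiguous=sum(1 for c in calls if c.ambiguous),
        control_report=control_report,
        notes=tuple(notes),
    )
    return calls, report
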