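"""Cross-method agreement summaries.

Copy calls from independent methods (duplexed TaqMan, Southern blot, dPCR)
or from progeny verification are compared per copy class: how many samples
called k copies by one method were also called k by the other, with
percentages rounded half-up to one decimal as in the customary reporting
tables.  An inter-method regression on the numeric copy values summarises
overall agreement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from copycall._util import round_half_up

CLASS_ORDER = (0, 1, 2, "gt2")


@dataclass(frozen=True)
class ClassRow:
    copy_class: object
    n_called: int
    n_assayed_by_other: int
    n_consistent: int
    percent_consistent: float | None  # None when nothing was assayed


@dataclass(frozen=True)
class ConcordanceTable:
    rows: tuple[ClassRow, ...]
    n_shared: int

    def row(self, copy_class: object) -> ClassRow:
        for r in self.rows:
            if r.copy_class == copy_class:
                return r
        raise KeyError(copy_class)


def _percent(consistent: int, assayed: int) -> float | None:
    if assayed == 0:
        return None
    return round_half_up(100.0 * consistent / assayed, 1)


def crosstab_methods(
    calls_a: Mapping[str, object], calls_b: Mapping[str, object]
) -> ConcordanceTable:
    """Per-class agreement of method B with method A on their shared samples.

    Rows are keyed by method A's class; a sample is consistent when method B
    assigns the same class.
    """
    shared = sorted(set(calls_a) & set(calls_b))
    if not shared:
        raise ValueError("no shared samples between the two call sets")
    rows = []
    for cls in CLASS_ORDER:
        in_class = [s for s in shared if calls_a[s] == cls]
        consistent = sum(1 for s in in_class if calls_b[s] == cls)
        rows.append(
            ClassRow(
                copy_class=cls,
                n_called=len(in_class),
                n_assayed_by_other=len(in_class),
                n_consistent=consistent,
                percent_consistent=_percent(consistent, len(in_class)),
            )
        )
    return ConcordanceTable(rows=tuple(rows), n_shared=len(shared))


def consistency_percent(n_consistent: int, n_assayed: int) -> float:
    """Printed-table consistency percentage (half-up, 1 decimal)."""
    if n_assayed <= 0:
        raise ValueError("n_assayed must be positive")
    if n_consistent > n_assayed:
        raise ValueError("n_consistent cannot exceed n_assayed")
    return _percent(n_consistent, n_assayed)


def progeny_verification_summary(
    t0_calls: Mapping[str, object], verified: Mapping[str, object]
) -> dict:
    """Agreement of original calls with progeny-verified true classes.

    Every original call must have a verified counterpart.  Returns the
    consistent count/percentage plus a breakdown of the discordant samples
    by their verified class.
    """
    missing = sorted(set(t0_calls) - set(verified))
    if missing:
        raise ValueError(f"unverified samples present: {missing[:5]}")
    n = len(t0_calls)
    n_consistent = sum(1 for s, c in t0_calls.items() if verified[s] == c)
    breakdown: dict[object, int] = {}
    for s, c in t0_calls.items():
        if verified[s] != c:
            breakdown[verified[s]] = breakdown.get(verified[s], 0) + 1
    return {
        "n": n,
        "n_consistent": n_consistent,
        "percent_consistent": _percent(n_consistent, n),
        "discordant_by_verified_class": breakdown,
    }


def method_regression(
    calls_a: Sequence[float], calls_b: Sequence[float]
) -> tuple[float, float, float]:
    """OLS of method B's numeric copy values on method A's.

    Returns (slope, intercept, R^2).  Categorical ">2" calls must be
    excluded or numerically coded by the caller before regression.
    """
    a = np.asarray(calls_a, dtype=float)
    b = np.asarray(calls_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 paired samples")
    if np.ptp(a) == 0:
        raise ValueError("zero variance in the predictor")
    res = stats.linregress(a, b)
    return float(res.slope), float(res.intercept), float(res.rvalue) ** 2
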