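"""Zygosity calling and Mendelian segregation analysis.

Selfing a hemizygous single-locus transformant yields a 1:2:1
homozygous : hemizygous : null segregation in copy-class space (2 : 1 : 0
transgene copies per diploid genome), so T1 zygosity can be read directly
off the copy class.  Families are tested against the expected ratio with a
Pearson chi-square goodness-of-fit test, and putative homozygotes are
confirmed when all their selfed T2 progeny carry two copies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from copycall.quantification import CopyCall

ZYGOSITIES = ("null_segregant", "hemizygous", "homozygous", "indeterminate")

#: copy class -> zygosity for a single-locus line
_CLASS_TO_ZYGOSITY = {0: "null_segregant", 1: "hemizygous", 2: "homozygous"}

DEFAULT_ALPHA = 0.05
RATIO_1_2_1 = (1.0, 2.0, 1.0)
RATIO_3_1 = (3.0, 1.0)


@dataclass(frozen=True)
class ZygosityCall:
    sample_id: str
    zygosity: str
    notes: tuple[str, ...] = ()


@dataclass(frozen=True)
class SegregationResult:
    """Pearson goodness-of-fit of observed class counts to an expected ratio."""

    observed: tuple[int, ...]
    expected_ratio: tuple[float, ...]
    chi_square: float
    df: int
    p_value: float
    verdict: str  # "consistent" | "rejected"
    alpha: float = DEFAULT_ALPHA


def call_zygosity(copy_call: CopyCall, line_is_single_locus: bool = True) -> ZygosityCall:
    """Map a copy class to zygosity under the single-locus model.

    Classes above two copies, ambiguous estimates, and multi-locus lines
    fall outside the model and are returned indeterminate.
    """
    if not line_is_single_locus:
        return ZygosityCall(copy_call.sample_id, "indeterminate", ("multi-locus line",))
    if copy_call.copy_class is None:
        return ZygosityCall(copy_call.sample_id, "indeterminate", ("no copy call",))
    if copy_call.ambiguous:
        return ZygosityCall(copy_call.sample_id, "indeterminate", ("ambiguous copy estimate",))
    zyg = _CLASS_TO_ZYGOSITY.get(copy_call.copy_class)
    if zyg is None:
        return ZygosityCall(
            copy_call.sample_id, "indeterminate", (f"copy class {copy_call.copy_class} outside single-locus model",)
        )
    return ZygosityCall(copy_call.sample_id, zyg)


def chi_square_segregation(
    observed: Sequence[int],
    expected_ratio: Sequence[float] = RATIO_1_2_1,
    alpha: float = DEFAULT_ALPHA,
    yates: bool = False,
) -> SegregationResult:
    """Pearson chi-square test of class counts against a Mendelian ratio.

    Expected counts are n * ratio / sum(ratio); df = k - 1.  The optional
    Yates continuity correction applies to two-class ratios only.
    """
    obs = np.asarray(observed, dtype=float)
    ratio = np.asarray(expected_ratio, dtype=float)
    if obs.shape != ratio.shape:
        raise ValueError("observed and expected_ratio must have equal length")
    n = obs.sum()
    if n <= 0:
        raise ValueError("total count must be positive")
    if (ratio <= 0).any():
        raise ValueError("all ratio weights must be positive")
    exp = n * ratio / ratio.sum()
    if yates:
        if len(obs) != 2:
            raise ValueError("Yates correction applies to 2-class tests only")
        chi2 = float((((np.abs(obs - exp) - 0.5).clip(min=0)) ** 2 / exp).sum())
    else:
        chi2 = float(((obs - exp) ** 2 / exp).sum())
    df = len(obs) - 1
    p = float(stats.chi2.sf(chi2, df))
    return SegregationResult(
        observed=tuple(int(o) for o in obs),
        expected_ratio=tuple(float(r) for r in ratio),
        chi_square=chi2,
        df=df,
        p_value=p,
        verdict="rejected" if p < alpha else "consistent",
        alpha=alpha,
    )


def verify_homozygotes(
    t1_predicted_homozygous: Sequence[str],
    t2_calls_by_family: Mapping[str, Sequence[CopyCall]],
) -> dict[str, str]:
    """Confirm putative T1 homozygotes from their selfed T2 progeny.

    A family is confirmed when every T2 plant carries two copies, refuted
    by any unambiguous class-0/1 plant (the parent still segregates), and
    insufficient when only ambiguous or uncalled progeny remain.
    """
    verdicts: dict[str, str] = {}
    for family in t1_predicted_homozygous:
        calls = t2_calls_by_family.get(family)
        if not calls:
            raise ValueError(f"family {family!r} has no T2 data")
        usable = [c for c in calls if c.copy_class is not None and not c.ambiguous]
        if not usable:
            verdicts[family] = "insufficient"
        elif any(c.copy_class in (0, 1) for c in usable):
            verdicts[family] = "refuted"
        elif all(c.copy_class == 2 for c in usable):
            verdicts[family] = "confirmed"
        else:  # gt2 progeny: outside the single-locus model
            verdicts[family] = "insufficient"
    return verdicts
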