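"""Standard-curve fitting and amplification-efficiency estimation.

A serial plasmid dilution (e.g. 1e7 .. 1e3 copies/uL) measured in replicate
gives a line of Ct against log10(copies).  Its slope carries the per-cycle
amplification efficiency,

    E = 10^(-1/slope) - 1,

with E = 1 meaning perfect doubling (slope about -3.32).  A well-optimised
assay shows a linear curve (R^2 > 0.98) and efficiency within 90-105%.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from copycall._util import round_half_up

#: QC hallmarks for a well-optimised assay.
DEFAULT_R2_MIN = 0.980
DEFAULT_EFF_WINDOW = (0.90, 1.05)


@dataclass(frozen=True)
class DilutionPoint:
    """One well of the dilution series: known concentration and observed Ct."""

    copies_per_ul: float
    ct: float

    def __post_init__(self) -> None:
        if self.copies_per_ul <= 0:
            raise ValueError("copies_per_ul must be positive (log10 is taken)")
        if not math.isfinite(self.ct) or self.ct < 0:
            raise ValueError(f"Ct must be finite and >= 0, got {self.ct}")


@dataclass(frozen=True)
class StandardCurveFit:
    """Least-squares calibration line Ct = slope * log10(copies) + intercept."""

    slope: float
    intercept: float
    r_squared: float
    efficiency: float
    n_points: int
    qc_pass: bool = False
    qc_messages: tuple[str, ...] = field(default_factory=tuple)

    def predict_ct(self, copies_per_ul: float) -> float:
        return self.slope * math.log10(copies_per_ul) + self.intercept

    def to_json(self) -> str:
        return json.dumps(
            {
                "slope": self.slope,
                "intercept": self.intercept,
                "r_squared": self.r_squared,
                "efficiency": self.efficiency,
                "efficiency_3dp": round_half_up(self.efficiency, 3),
                "n_points": self.n_points,
                "qc_pass": self.qc_pass,
                "qc_messages": list(self.qc_messages),
            },
            indent=2,
        )

    @classmethod
    def from_dict(cls, d: dict) -> "StandardCurveFit":
        return cls(
            slope=d["slope"],
            intercept=d["intercept"],
            r_squared=d["r_squared"],
            efficiency=d["efficiency"],
            n_points=d.get("n_points", 0),
            qc_pass=d.get("qc_pass", False),
            qc_messages=tuple(d.get("qc_messages", ())),
        )


def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency fraction from a standard-curve slope.

    E = 10^(-1/slope) - 1; a slope of -1/log10(2) (~ -3.3219) gives exactly
    E = 1 (template doubles every cycle).  Non-negative slopes indicate an
    inverted axis or broken fit and are rejected.
    """
    if not math.isfinite(slope) or slope >= 0:
        raise ValueError(f"slope must be finite and negative, got {slope}")
    return 10.0 ** (-1.0 / slope) - 1.0


def fit_standard_curve(points: Sequence[DilutionPoint]) -> StandardCurveFit:
    """Ordinary least squares of Ct on log10(copies/uL).

    Replicate wells at one dilution enter as individual points.  At least
    three distinct concentration levels are required.
    """
    if len({p.copies_per_ul for p in points}) < 3:
        raise ValueError("need at least 3 distinct concentration levels")
    x = np.log10([p.copies_per_ul for p in points])
    y = np.array([p.ct for p in points])
    if np.ptp(x) == 0:
        raise ValueError("zero variance in log10(copies)")
    res = stats.linregress(x, y)
    return StandardCurveFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        efficiency=efficiency_from_slope(float(res.slope)),
        n_points=len(points),
    )


def qc_standard_curve(
    fit: StandardCurveFit,
    r2_min: float = DEFAULT_R2_MIN,
    eff_lo: float = DEFAULT_EFF_WINDOW[0],
    eff_hi: float = DEFAULT_EFF_WINDOW[1],
) -> StandardCurveFit:
    """Apply the linearity and efficiency hallmarks; returns a new fit with
    ``qc_pass`` and one message per failed hallmark."""
    messages: list[str] = []
    if not fit.r_squared > r2_min:
        messages.append(f"linearity: R^2 {fit.r_squared:.4f} <= {r2_min}")
    if not eff_lo <= fit.efficiency <= eff_hi:
        messages.append(
            f"efficiency: E {fit.efficiency:.3f} outside [{eff_lo:.2f}, {eff_hi:.2f}]"
        )
    return replace(fit, qc_pass=not messages, qc_messages=tuple(messages))


def interpolate_copies(fit: StandardCurveFit, ct: float, allow_qc_fail: bool = False) -> float:
    """Invert the calibration line: copies/uL giving the observed Ct.

    Values below 1 copy/uL are extrapolations beyond the intercept and are
    returned as computed (callers may flag them).
    """
    if not fit.qc_pass and not allow_qc_fail:
        raise ValueError("fit failed QC; pass allow_qc_fail=True to override")
    if fit.slope == 0:
        raise ZeroDivisionError("slope is zero")
    return 10.0 ** ((ct - fit.intercept) / fit.slope)
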