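"""Plate data model, Ct-table ingestion, 96-to-384 quadrant mapping and
negative-control validation.

Instrument exports arrive as long-format CSV with one row per well and
channel; "Undetermined" wells (no threshold crossing within the run) are a
typed absence, never a numeric sentinel.  Samples are extracted on 96-well
plates and assayed four-plates-to-one on a 384-well plate, so the module
also provides the deterministic source-to-destination well mapping.
"""

from __future__ import annotations

import json
import math
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

ROWS_96 = string.ascii_uppercase[:8]    # A-H
ROWS_384 = string.ascii_uppercase[:16]  # A-P

TARGETS = ("transgene", "reference")
ROLES = ("test", "calibrator", "ntc", "wt_negative", "standard")

#: Default Ct above which a channel is treated as "no amplification"
#: (the runs are 40 cycles; late signal past this point is noise).
DEFAULT_CT_CUTOFF = 38.0


@dataclass(frozen=True, order=True)
class WellAddress:
    """A well on a named plate; rows are letters, columns 1-based."""

    plate_id: str
    row: str
    col: int

    def __post_init__(self) -> None:
        if self.row not in ROWS_384:
            raise ValueError(f"invalid row {self.row!r}")
        if not 1 <= self.col <= 24:
            raise ValueError(f"invalid column {self.col}")

    @classmethod
    def parse(cls, label: str, plate_id: str = "") -> "WellAddress":
        """Parse an instrument-style label like ``A1``, ``H12`` or the
        plate-qualified form ``P1:A1``."""
        label = label.strip()
        if ":" in label:
            plate_id, label = label.split(":", 1)
        label = label.strip().upper()
        if not label or label[0] not in ROWS_384 or not label[1:].isdigit():
            raise ValueError(f"cannot parse well label {label!r}")
        return cls(plate_id, label[0], int(label[1:]))

    @property
    def label(self) -> str:
        return f"{self.row}{self.col}"

    @property
    def key(self) -> str:
        """Plate-qualified label, unique across multi-plate datasets."""
        return f"{self.plate_id}:{self.label}" if self.plate_id else self.label


@dataclass(frozen=True)
class SampleRole:
    """Role of a sample within a run, with role-specific metadata."""

    role: str
    known_copy_class: int | None = None
    standard_copies_per_ul: float | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if (self.role == "standard") != (self.standard_copies_per_ul is not None):
            raise ValueError("standard_copies_per_ul present iff role is 'standard'")
        if self.standard_copies_per_ul is not None and self.standard_copies_per_ul <= 0:
            raise ValueError("standard_copies_per_ul must be positive")


@dataclass(frozen=True)
class CtRecord:
    """One well x channel quantification-cycle observation.

    ``ct is None`` encodes an undetermined well (no amplification signal).
    """

    well: WellAddress
    sample_id: str
    target: str
    reporter: str
    ct: float | None
    run_id: str = "run1"

    def __post_init__(self) -> None:
        if self.target not in TARGETS:
            raise ValueError(f"target must be one of {TARGETS}, got {self.target!r}")
        if self.ct is not None and (not math.isfinite(self.ct) or self.ct < 0):
            raise ValueError(f"Ct must be finite and >= 0, got {self.ct}")


# ---------------------------------------------------------------------------
# 96 -> 384 quadrant mapping

_INTERLEAVED_OFFSETS = ((0, 0), (0, 1), (1, 0), (1, 1))


def build_quadrant_map(
    scheme: str = "interleaved",
    plate_ids: Sequence[str] = ("P1", "P2", "P3", "P4"),
    dest_plate_id: str = "384",
) -> dict[WellAddress, WellAddress]:
    """Map every well of four 96-well source plates onto a 384-well plate.

    ``interleaved`` nests a 2x2 block of sources into each destination
    2x2 cell: plate 1 -> even rows/cols, plate 2 shifted one column,
    plate 3 one row, plate 4 both (so P1:A1->A1, P2:A1->A2, P3:A1->B1,
    P4:A1->B2).  ``block`` tiles the four plates as quadrants: plate 1
    rows A-H cols 1-12, plate 2 rows A-H cols 13-24, plate 3 rows I-P
    cols 1-12, plate 4 rows I-P cols 13-24.  Both are bijections.
    """
    if len(plate_ids) != 4 or len(set(plate_ids)) != 4:
        raise ValueError("exactly four distinct source plate IDs are required")
    mapping: dict[WellAddress, WellAddress] = {}
    for q, pid in enumerate(plate_ids):
        for r in range(8):
            for c in range(12):
                src = WellAddress(pid, ROWS_96[r], c + 1)
                if scheme == "interleaved":
                    dr, dc = _INTERLEAVED_OFFSETS[q]
                    dest = WellAddress(dest_plate_id, ROWS_384[2 * r + dr], 2 * c + 1 + dc)
                elif scheme == "block":
                    dest = WellAddress(
                        dest_plate_id, ROWS_384[8 * (q // 2) + r], 12 * (q % 2) + c + 1
                    )
                else:
                    raise ValueError(f"unknown scheme {scheme!r}")
                mapping[src] = dest
    return mapping


# ---------------------------------------------------------------------------
# CSV ingestion

#: header-name remapping: canonical name -> accepted aliases (lowercased)
DEFAULT_DIALECT: dict[str, tuple[str, ...]] = {
    "well": ("well", "well position"),
    "sample": ("sample", "sample_id", "sample name"),
    "target": ("target", "target name", "gene"),
    "reporter": ("reporter", "dye"),
    "ct": ("ct", "cq", "ct value"),
}

_UNDETERMINED = {"", "undetermined", "undet", "na", "n/a", "nan"}

#: accepted spellings for the two duplexed channels
_TARGET_ALIASES = {
    "transgene": "transgene", "bar": "transgene", "fam": "transgene",
    "reference": "reference", "hmg": "reference", "vic": "reference",
}


def _resolve_columns(columns: Iterable[str], dialect: Mapping[str, tuple[str, ...]]) -> dict[str, str]:
    lower = {c.lower().strip(): c for c in columns}
    resolved = {}
    for canon, aliases in dialect.items():
        for a in aliases:
            if a in lower:
                resolved[canon] = lower[a]
                break
        else:
            raise ValueError(f"mandatory column {canon!r} not found (aliases {aliases})")
    return resolved


def parse_ct(value: object) -> float | None:
    """Parse a Ct cell; undetermined sentinels become ``None``."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    if s.lower() in _UNDETERMINED:
        return None
    try:
        ct = float(s)
    except ValueError as exc:
        raise ValueError(f"unparseable Ct value {s!r}") from exc
    if not math.isfinite(ct) or ct < 0:
        raise ValueError(f"Ct out of range: {ct}")
    return ct


def read_ct_export(
    path: str | Path,
    dialect: Mapping[str, tuple[str, ...]] | None = None,
    plate_id: str = "",
    run_id: str = "run1",
) -> list[CtRecord]:
    """Read a long-format Ct CSV into :class:`CtRecord` objects.

    Row order is preserved; duplicate (well, target, run) rows raise with
    the colliding well named.
    """
    df = pd.read_csv(path, dtype=str)
    cols = _resolve_columns(df.columns, dialect or DEFAULT_DIALECT)
    records: list[CtRecord] = []
    seen: set[tuple[str, str, str]] = set()
    for _, row in df.iterrows():
        well = WellAddress.parse(str(row[cols["well"]]), plate_id)
        raw_target = str(row[cols["target"]]).strip().lower()
        target = _TARGET_ALIASES.get(raw_target)
        if target is None:
            raise ValueError(f"unrecognized target {row[cols['target']]!r} in well {well.label}")
        key = (well.key, target, run_id)
        if key in seen:
            raise ValueError(f"duplicate (well, target, run) entry at well {well.key}")
        seen.add(key)
        records.append(
            CtRecord(
                well=well,
                sample_id=str(row[cols["sample"]]).strip(),
                target=target,
                reporter=str(row[cols["reporter"]]).strip(),
                ct=parse_ct(row[cols["ct"]]),
                run_id=run_id,
            )
        )
    return records


def write_ct_export(records: Sequence[CtRecord], path: str | Path) -> None:
    """Write records back to the canonical CSV dialect (round-trips with
    :func:`read_ct_export`)."""
    df = pd.DataFrame(
        {
            "well": [r.well.key for r in records],
            "sample": [r.sample_id for r in records],
            "target": [r.target for r in records],
            "reporter": [r.reporter for r in records],
            "ct": ["Undetermined" if r.ct is None else repr(r.ct) for r in records],
        }
    )
    df.to_csv(path, index=False)


def read_layout(path: str | Path) -> dict[str, SampleRole]:
    """Read a plate-layout manifest CSV (well, sample_id, role[, source_plate,
    known_copy_class, standard_copies_per_ul]) keyed by well label."""
    df = pd.read_csv(path, dtype=str)
    layout: dict[str, SampleRole] = {}
    for _, row in df.iterrows():
        kcc = row.get("known_copy_class")
        scu = row.get("standard_copies_per_ul")
        layout[WellAddress.parse(str(row["well"])).key] = SampleRole(
            role=str(row["role"]).strip(),
            known_copy_class=int(kcc) if isinstance(kcc, str) and kcc.strip() else None,
            standard_copies_per_ul=float(scu) if isinstance(scu, str) and scu.strip() else None,
        )
    return layout


# ---------------------------------------------------------------------------
# Control validation


@dataclass
class ControlReport:
    """Outcome of negative-control screening for one batch."""

    passed: bool
    violations: list[dict] = field(default_factory=list)
    ct_cutoff: float = DEFAULT_CT_CUTOFF

    def to_json(self) -> str:
        return json.dumps(
            {"pass": self.passed, "ct_cutoff": self.ct_cutoff, "violations": self.violations},
            indent=2,
        )

    def to_text(self) -> str:
        if self.passed:
            return f"Control validation PASS (Ct cutoff {self.ct_cutoff})"
        lines = [f"Control validation FAIL (Ct cutoff {self.ct_cutoff}):"]
        lines += [f"  {v['well']}: {v['reason']}" for v in self.violations]
        return "\n".join(lines)


def validate_controls(
    records: Sequence[CtRecord],
    layout: Mapping[str, SampleRole],
    ct_cutoff: float = DEFAULT_CT_CUTOFF,
) -> ControlReport:
    """Screen NTC and wild-type negative controls for contamination.

    An NTC well must show no amplification in either channel (Ct absent or
    past the cutoff).  A wild-type negative must show no transgene signal
    while its reference channel *does* amplify — a silent reference channel
    means the DNA or reaction failed, which is also flagged.
    """
    violations: list[dict] = []
    for rec in records:
        role = layout.get(rec.well.key, layout.get(rec.well.label))
        if role is None:
            raise ValueError(f"layout does not cover well {rec.well.key}")
        amplified = rec.ct is not None and rec.ct < ct_cutoff
        if role.role == "ntc" and amplified:
            violations.append(
                {
                    "well": rec.well.label,
                    "reason": f"NTC amplification in {rec.target} channel (Ct {rec.ct:.2f} < {ct_cutoff})",
                }
            )
        elif role.role == "wt_negative":
            if rec.target == "transgene" and amplified:
                violations.append(
                    {
                        "well": rec.well.label,
                        "reason": f"transgene amplification in WT negative (Ct {rec.ct:.2f} < {ct_cutoff})",
                    }
                )
            elif rec.target == "reference" and not amplified:
                shown = "undetermined" if rec.ct is None else f"{rec.ct:.2f} >= {ct_cutoff}"
                violations.append(
                    {
                        "well": rec.well.label,
                        "reason": f"WT negative reference channel failed (Ct {shown})",
                    }
                )
    return ControlReport(passed=not violations, violations=violations, ct_cutoff=ct_cutoff)
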