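"""Screen primer/probe annealing sites for SNPs across an amplicon panel.

A quantitative assay's reference gene must amplify uniformly across
germplasm: a mismatch under a primer or probe shifts the efficiency and
biases every copy-number ratio built on it.  Given an assay definition
(forward primer, reverse primer, probe, reference amplicon) and a panel of
per-line amplicon sequences, this module anchors each oligo exactly on the
reference, compares the panel column-by-column inside the annealing sites,
and reports variants in each oligo's own orientation — offset counted from
the oligo's 5' end, bases complemented for the reverse primer.

Same-primer PCR amplicons are fixed-length, so anchored columnwise
comparison replaces multiple alignment; sequences of deviating length are
rejected rather than aligned.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

_DNA = set("ACGT")
_IUPAC = set("ACGTRYSWKMBDHVN")

OLIGOS = ("forward", "reverse", "probe")


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class AssayDefinition:
    """A TaqMan assay: two primers, a probe and the reference amplicon.

    The reverse primer is given 5'->3' on the bottom strand, as synthesized;
    forward primer and probe lie on the top strand.
    """

    name: str
    forward_primer: str
    reverse_primer: str
    probe: str
    reference_amplicon: str

    def __post_init__(self) -> None:
        for attr in ("forward_primer", "reverse_primer", "probe", "reference_amplicon"):
            seq = getattr(self, attr).upper()
            object.__setattr__(self, attr, seq)
            if not set(seq) <= _DNA:
                raise ValueError(f"{attr} contains non-ACGT characters")

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None) -> "AssayDefinition":
        """Read a FASTA-style assay file with records named ``forward``,
        ``reverse``, ``probe`` and ``amplicon``."""
        records = {r.id.lower(): str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
        missing = {"forward", "reverse", "probe", "amplicon"} - set(records)
        if missing:
            raise ValueError(f"assay file missing records: {sorted(missing)}")
        return cls(
            name=name or Path(path).stem,
            forward_primer=records["forward"],
            reverse_primer=records["reverse"],
            probe=records["probe"],
            reference_amplicon=records["amplicon"],
        )


@dataclass(frozen=True)
class OligoSite:
    """Annealing site of one oligo on the reference amplicon.

    ``start``/``end`` are 0-based half-open top-strand coordinates; the
    1-based inclusive span users see is (start+1, end).
    """

    oligo: str
    start: int
    end: int
    strand: str  # "+" top, "-" bottom

    @property
    def span_1based(self) -> tuple[int, int]:
        return self.start + 1, self.end

    def offset_to_amplicon(self, offset: int) -> int:
        """1-based oligo offset (from its own 5' end) -> 1-based top-strand
        amplicon position."""
        if not 1 <= offset <= self.end - self.start:
            raise ValueError(f"offset {offset} outside oligo of length {self.end - self.start}")
        if self.strand == "+":
            return self.start + offset
        return self.end - offset + 1

    def amplicon_to_offset(self, position: int) -> int:
        """Inverse of :meth:`offset_to_amplicon`."""
        if not self.start + 1 <= position <= self.end:
            raise ValueError(f"position {position} outside site {self.span_1based}")
        if self.strand == "+":
            return position - self.start
        return self.end - position + 1


@dataclass(frozen=True)
class SnpHit:
    """One substitution inside an oligo site, aggregated over carrier lines.

    Reported in the oligo's own orientation: the offset counts from the
    oligo's 5' end as synthesized, and for the reverse primer the bases are
    complemented relative to the top strand.
    """

    oligo: str
    offset_from_5prime: int
    ref_base: str
    alt_base: str
    amplicon_position: int
    carrier_count: int
    frequency_percent: float
    line_ids: tuple[str, ...]
    is_iupac_ambiguity: bool = False


def _find_unique(amplicon: str, oligo_seq: str, oligo: str) -> int:
    pos = amplicon.find(oligo_seq)
    if pos < 0:
        raise ValueError(f"{oligo} oligo not found on the reference amplicon (exact anchoring)")
    if amplicon.find(oligo_seq, pos + 1) >= 0:
        raise ValueError(f"{oligo} oligo found at more than one amplicon position")
    return pos


def locate_assay_sites(assay: AssayDefinition) -> dict[str, OligoSite]:
    """Anchor the three oligos exactly on the reference amplicon.

    The forward primer and probe match the top strand; the reverse primer's
    reverse-complement matches the top strand and the site carries
    bottom-strand orientation.  Any mismatch or multiple match is an error.
    """
    amp = assay.reference_amplicon
    sites: dict[str, OligoSite] = {}
    for oligo, seq, strand in (
        ("forward", assay.forward_primer, "+"),
        ("reverse", _revcomp(assay.reverse_primer), "-"),
        ("probe", assay.probe, "+"),
    ):
        start = _find_unique(amp, seq, oligo)
        sites[oligo] = OligoSite(oligo=oligo, start=start, end=start + len(seq), strand=strand)
    return sites


def _as_items(panel: Mapping[str, str] | Iterable[tuple[str, str]]) -> list[tuple[str, str]]:
    if isinstance(panel, Mapping):
        return list(panel.items())
    return list(panel)


def read_panel_fasta(path: str | Path) -> dict[str, str]:
    """Read a per-line amplicon panel FASTA keyed by record id."""
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


def scan_panel_for_snps(
    panel: Mapping[str, str] | Iterable[tuple[str, str]],
    assay: AssayDefinition,
) -> list[SnpHit]:
    """Column-by-column comparison of every panel line inside the oligo sites.

    Every sequence must equal the reference in length (indel-free amplicons);
    deviating lines are rejected.  Variants are aggregated by
    (oligo, offset, alt base) with carrier counts and panel frequencies;
    IUPAC ambiguity codes are flagged separately from clean substitutions.
    """
    items = _as_items(panel)
    ref = assay.reference_amplicon
    sites = locate_assay_sites(assay)
    carriers: dict[tuple[str, int, str, str], list[str]] = {}
    for line_id, seq in items:
        seq = seq.upper()
        if len(seq) != len(ref):
            raise ValueError(
                f"line {line_id!r}: length {len(seq)} != reference length {len(ref)} "
                "(indel-containing amplicons are rejected)"
            )
        if not set(seq) <= _IUPAC:
            raise ValueError(f"line {line_id!r}: non-IUPAC characters in sequence")
        for site in sites.values():
            for pos0 in range(site.start, site.end):
                if seq[pos0] == ref[pos0]:
                    continue
                offset = site.amplicon_to_offset(pos0 + 1)
                if site.strand == "+":
                    ref_b, alt_b = ref[pos0], seq[pos0]
                else:
                    ref_b, alt_b = _revcomp(ref[pos0]), _revcomp(seq[pos0])
                carriers.setdefault((site.oligo, offset, ref_b, alt_b), []).append(line_id)
    n = len(items)
    hits = [
        SnpHit(
            oligo=oligo,
            offset_from_5prime=offset,
            ref_base=ref_b,
            alt_base=alt_b,
            amplicon_position=sites[oligo].offset_to_amplicon(offset),
            carrier_count=len(lines),
            frequency_percent=100.0 * len(lines) / n,
            line_ids=tuple(lines),
            is_iupac_ambiguity=alt_b not in _DNA,
        )
        for (oligo, offset, ref_b, alt_b), lines in carriers.items()
    ]
    hits.sort(key=lambda h: (OLIGOS.index(h.oligo), h.offset_from_5prime, h.alt_base))
    return hits


def uniformity_verdict(hits: Sequence[SnpHit], assay: AssayDefinition) -> dict:
    """Per-oligo clean/variant flags and an assay-level redesign recommendation.

    An oligo is clean iff no panel line varies inside its annealing site;
    any variant in any oligo flags the assay for redesign (move the oligo
    off the polymorphic position).
    """
    per_oligo = {
        oligo: "variant_detected" if any(h.oligo == oligo for h in hits) else "clean"
        for oligo in OLIGOS
    }
    return {
        "assay": assay.name,
        "oligos": per_oligo,
        "assay_clean": all(v == "clean" for v in per_oligo.values()),
        "redesign_recommended": any(v == "variant_detected" for v in per_oligo.values()),
    }
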