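"""Synthetic-data generators for every input the pipeline consumes.

Real inputs are plate exports from a qPCR instrument, dPCR chip counts and
Sanger-sequenced amplicon panels; none are distributable.  These generators
emulate their statistical structure instead: Ct values log-linear in
template dose with Gaussian per-well noise, transformant cohorts with a
realistic copy-class mix, selfed families segregating 1:2:1, Poisson
partition occupancy on dPCR chips, and amplicon panels carrying planted
primer-site SNPs at specified carrier counts.  Every generator is a pure
function of its configuration and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from copycall.dpcr import PartitionCount
from copycall.plates import ROWS_384, CtRecord, SampleRole, WellAddress
from copycall.quantification import DEFAULT_CALIBRATOR_COPIES
from copycall.reliability import QuantContext, ReplicateTriple
from copycall.snp_screen import AssayDefinition, locate_assay_sites
from copycall.standard_curve import DilutionPoint, StandardCurveFit, efficiency_from_slope

#: slope giving exactly doubling efficiency
PERFECT_SLOPE = -1.0 / math.log10(2.0)

#: dilution levels of the plasmid standard series, copies/uL
DEFAULT_LEVELS = (1e7, 1e6, 1e5, 1e4, 1e3)

#: T0 copy-class mix of a typical transformation cohort
DEFAULT_CLASS_DISTRIBUTION: dict = {0: 0.044, 1: 0.734, 2: 0.133, "gt2": 0.089}

#: primer-site variants of the legacy reference assay: carrier counts out of
#: a 633-line panel (forward primer 5'-terminal T>A; reverse primer
#: second-base G>T)
DEFAULT_VARIANT_SPECS = (
    ("forward", 1, "T", "A", 112),
    ("reverse", 2, "G", "T", 3),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generators.

    Default curves reproduce assays with efficiencies 0.993 (transgene) and
    1.000 (reference); intercepts place the 1e3 copies/uL standard near Ct
    29.6 / 28.4.  Per-well Ct noise defaults to 0.3 cycles, the scale of
    inter-assay SDs seen on plasmid standards; the calibrator is a
    homozygous single-locus plant (2 copies per diploid genome).
    """

    seed: int = 0
    slope_target: float = -1.0 / math.log10(1.993)
    intercept_target: float = 39.65
    slope_ref: float = PERFECT_SLOPE
    intercept_ref: float = 38.40
    ct_noise_sd: float = 0.3
    #: shared per-sample noise (pipetting) added to both channels
    correlated_noise_sd: float = 0.0
    calibrator_class: int = int(DEFAULT_CALIBRATOR_COPIES)
    class_distribution: Mapping = field(
        default_factory=lambda: dict(DEFAULT_CLASS_DISTRIBUTION)
    )
    family_size: int = 24
    panel_size: int = 633
    variant_specs: tuple = DEFAULT_VARIANT_SPECS
    partitions_per_chip: int = 20_000
    #: baseline Cts of the calibrator sample, per channel
    ct_target_cal: float = 25.0
    ct_ref_cal: float = 24.0
    #: copies simulated for the ">2" class
    gt2_copies: int = 3

    def __post_init__(self) -> None:
        total = sum(self.class_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class probabilities must sum to 1, got {total}")
        if self.ct_noise_sd < 0 or self.correlated_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")

    @property
    def e_target(self) -> float:
        return efficiency_from_slope(self.slope_target)

    @property
    def e_ref(self) -> float:
        return efficiency_from_slope(self.slope_ref)

    def curves(self) -> dict[str, StandardCurveFit]:
        """The generator's own calibration lines as ready-made fits."""
        return {
            "transgene": StandardCurveFit(
                self.slope_target, self.intercept_target, 1.0, self.e_target, 0, qc_pass=True
            ),
            "reference": StandardCurveFit(
                self.slope_ref, self.intercept_ref, 1.0, self.e_ref, 0, qc_pass=True
            ),
        }

    def quant_context(self) -> QuantContext:
        return QuantContext(
            e_target=self.e_target,
            e_ref=self.e_ref,
            ct_target_cal=self.ct_target_cal,
            ct_ref_cal=self.ct_ref_cal,
            calibrator_copies=float(self.calibrator_class),
        )


def _class_copies(cfg: SimulationConfig, cls: object) -> int:
    return cfg.gt2_copies if cls == "gt2" else int(cls)


def _true_ct(
    cfg: SimulationConfig, copies: float, channel: str
) -> float | None:
    """Noise-free test-well Ct for a sample carrying ``copies`` per genome."""
    if channel == "transgene":
        if copies == 0:
            return None
        base = 1.0 + cfg.e_target
        return cfg.ct_target_cal - math.log(copies / cfg.calibrator_class, base)
    return cfg.ct_ref_cal


def simulate_dilution_series(
    cfg: SimulationConfig,
    levels: Sequence[float] = DEFAULT_LEVELS,
    replicates: int = 3,
    gene: str = "reference",
) -> list[DilutionPoint]:
    """Standard-series Cts: intercept + slope*log10(copies) + N(0, sd)."""
    if any(level <= 0 for level in levels):
        raise ValueError("dilution levels must be positive")
    rng = np.random.default_rng(cfg.seed)
    slope, intercept = (
        (cfg.slope_target, cfg.intercept_target)
        if gene == "transgene"
        else (cfg.slope_ref, cfg.intercept_ref)
    )
    points = []
    for level in levels:
        for _ in range(replicates):
            ct = intercept + slope * math.log10(level) + rng.normal(0.0, cfg.ct_noise_sd)
            points.append(DilutionPoint(copies_per_ul=level, ct=ct))
    return points


def _well_iter(plate_prefix: str):
    plate = 0
    while True:
        plate += 1
        pid = f"{plate_prefix}{plate}"
        for row in ROWS_384:
            for col in range(1, 25):
                yield WellAddress(pid, row, col)


def simulate_t0_cohort(
    cfg: SimulationConfig,
    n: int,
    replicates: int = 1,
) -> tuple[list[CtRecord], dict[str, SampleRole], dict[str, object]]:
    """A transformant screening batch: test samples, calibrator, NTC and WT.

    Returns (Ct records, layout keyed by well, truth classes by sample).
    True classes are drawn from the configured class mix; the transgene Ct
    sits ``log_b(copies / calibrator_copies)`` cycles off the calibrator's,
    class-0 transgene channels are emitted undetermined, and every well
    receives independent Gaussian noise (plus an optional shared per-sample
    component).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(cfg.seed)
    classes = list(cfg.class_distribution)
    probs = np.array([cfg.class_distribution[c] for c in classes], dtype=float)
    truth: dict[str, object] = {
        f"S{i + 1:04d}": classes[j] for i, j in enumerate(rng.choice(len(classes), size=n, p=probs))
    }

    wells = _well_iter("T0P")
    records: list[CtRecord] = []
    layout: dict[str, SampleRole] = {}

    def emit(sample_id: str, role: SampleRole, copies: float | None) -> None:
        well = next(wells)
        layout[well.key] = role
        shared = rng.normal(0.0, cfg.correlated_noise_sd) if cfg.correlated_noise_sd else 0.0
        for _ in range(replicates):
            for channel, reporter in (("transgene", "FAM"), ("reference", "VIC")):
                if copies is None:  # NTC: nothing amplifies
                    ct = None
                elif role.role == "wt_negative" and channel == "transgene":
                    ct = None
                else:
                    ct0 = _true_ct(cfg, copies, channel)
                    ct = (
                        None
                        if ct0 is None
                        else ct0 + shared + rng.normal(0.0, cfg.ct_noise_sd)
                    )
                records.append(
                    CtRecord(well=well, sample_id=sample_id, target=channel,
                             reporter=reporter, ct=ct, run_id="sim")
                )

    emit("CAL01", SampleRole("calibrator", known_copy_class=cfg.calibrator_class),
         float(cfg.calibrator_class))
    emit("NTC", SampleRole("ntc"), None)
    emit("WT", SampleRole("wt_negative"), 0.0)
    for sample_id, cls in truth.items():
        emit(sample_id, SampleRole("test"), float(_class_copies(cfg, cls)))
    return records, layout, truth


def simulate_t1_families(
    cfg: SimulationConfig,
    n_families: int,
    family_size: int | None = None,
) -> tuple[list[CtRecord], dict[str, SampleRole], dict[str, object], dict[str, list[str]]]:
    """Selfed progeny of hemizygous single-locus parents, segregating 1:2:1.

    Returns (records, layout, truth classes, family membership).  Each
    plant's class is an independent draw from (1/4, 1/2, 1/4) over
    {0, 1, 2}; Ct synthesis matches :func:`simulate_t0_cohort`, including
    the calibrator/NTC/WT wells.
    """
    size = cfg.family_size if family_size is None else family_size
    if n_families <= 0 or size <= 0:
        raise ValueError("n_families and family_size must be positive")
    rng = np.random.default_rng(cfg.seed)
    fam_cfg = replace(cfg, seed=int(rng.integers(2**31)),
                      class_distribution={0: 0.25, 1: 0.5, 2: 0.25})
    families: dict[str, list[str]] = {}
    records, layout, truth = simulate_t0_cohort(fam_cfg, n_families * size)
    sample_ids = list(truth)
    renamed_records: list[CtRecord] = []
    rename: dict[str, str] = {}
    for f in range(n_families):
        fam_id = f"F{f + 1:03d}"
        members = []
        for k in range(size):
            old = sample_ids[f * size + k]
            new = f"{fam_id}-{k + 1:02d}"
            rename[old] = new
            members.append(new)
        families[fam_id] = members
    truth = {rename.get(s, s): c for s, c in truth.items()}
    for rec in records:
        renamed_records.append(
            replace_sample(rec, rename.get(rec.sample_id, rec.sample_id))
        )
    return renamed_records, layout, truth, families


def replace_sample(rec: CtRecord, sample_id: str) -> CtRecord:
    return CtRecord(well=rec.well, sample_id=sample_id, target=rec.target,
                    reporter=rec.reporter, ct=rec.ct, run_id=rec.run_id)


def simulate_replicate_triples(
    cfg: SimulationConfig,
    n: int,
    class_distribution: Mapping | None = None,
) -> tuple[list[ReplicateTriple], list[object]]:
    """Per-sample technical triples for the reliability resampling analysis.

    Only classes with an amplifying transgene channel make sense here, so
    the class mix defaults to {1: 1/2, 2: 1/2}.
    """
    dist = dict(class_distribution or {1: 0.5, 2: 0.5})
    if 0 in dist:
        raise ValueError("class 0 has no transgene Ct; excluded from triples")
    rng = np.random.default_rng(cfg.seed)
    classes = list(dist)
    probs = np.array([dist[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    draws = rng.choice(len(classes), size=n, p=probs)
    dataset: list[ReplicateTriple] = []
    truth: list[object] = []
    for i, j in enumerate(draws):
        cls = classes[j]
        copies = float(_class_copies(cfg, cls))
        ct_t0 = _true_ct(cfg, copies, "transgene")
        ct_r0 = _true_ct(cfg, copies, "reference")
        dataset.append(
            ReplicateTriple(
                sample_id=f"R{i + 1:05d}",
                ct_target=tuple(ct_t0 + rng.normal(0.0, cfg.ct_noise_sd) for _ in range(3)),
                ct_ref=tuple(ct_r0 + rng.normal(0.0, cfg.ct_noise_sd) for _ in range(3)),
            )
        )
        truth.append(cls)
    return dataset, truth


def simulate_partition_counts(
    cfg: SimulationConfig,
    true_copies_per_genome: float,
    genomes_per_chip: float,
    reference_ploidy: float = 2.0,
) -> tuple[PartitionCount, PartitionCount]:
    """One duplexed dPCR chip under Poisson occupancy.

    Channel means are lambda = (dose * genomes) / partitions with dose =
    ``reference_ploidy`` for the reference gene and ``true_copies`` for the
    transgene; positives are Binomial(partitions, 1 - e^-lambda).
    """
    n = cfg.partitions_per_chip
    if n <= 0:
        raise ValueError("partitions_per_chip must be positive")
    rng = np.random.default_rng(cfg.seed)
    counts = []
    for channel, dose in (("transgene", true_copies_per_genome), ("reference", reference_ploidy)):
        lam = dose * genomes_per_chip / n
        p = 1.0 - math.exp(-lam)
        k = int(rng.binomial(n, p))
        if k == n:
            raise ValueError(f"{channel} channel saturated at lambda {lam:.3f}; dilute the chip")
        counts.append(PartitionCount(channel=channel, n_positive=k, n_total=n))
    return counts[0], counts[1]


# ---------------------------------------------------------------------------
# Amplicon panel with planted primer-site SNPs

_AMPLICON_LEN = 201


def default_assay(seed: int = 20140905) -> AssayDefinition:
    """A synthetic reference-gene assay on a deterministic 201-bp amplicon.

    Stand-in for a real assay definition (real primer/probe/amplicon
    sequences are proprietary to their instruments' suppliers); the layout
    mirrors a typical duplex design: 22-nt primers flanking a 25-nt
    internal probe.  The forward primer starts with T and the reverse
    primer's second base is G, so the panel generator's default variant
    specs apply cleanly.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    while True:
        amp = "".join(rng.choice(bases, size=_AMPLICON_LEN))
        fwd = amp[8:30]
        rev = _rc(amp[171:193])
        probe = amp[85:110]
        if fwd[0] != "T" or rev[1] != "G":
            continue
        assay = AssayDefinition(
            name="synthetic-ref-assay",
            forward_primer=fwd,
            reverse_primer=rev,
            probe=probe,
            reference_amplicon=amp,
        )
        try:
            locate_assay_sites(assay)
        except ValueError:  # an oligo happened to match twice; resample
            continue
        return assay


def _rc(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp[b] for b in reversed(seq))


def simulate_amplicon_panel(
    cfg: SimulationConfig,
    assay: AssayDefinition | None = None,
) -> tuple[dict[str, str], list[dict]]:
    """Per-line amplicon sequences with planted primer/probe-site variants.

    Carrier lines are drawn without replacement per variant spec
    (oligo, offset, ref, alt, carrier_count); substitutions land on the
    top strand at the mapped coordinate, complemented for reverse-primer
    specs.  Returns the panel and the planted truth (one record per spec
    with its amplicon position and expected frequency).
    """
    assay = assay or default_assay()
    sites = locate_assay_sites(assay)
    rng = np.random.default_rng(cfg.seed)
    line_ids = [f"L{i + 1:04d}" for i in range(cfg.panel_size)]
    seqs = {lid: list(assay.reference_amplicon) for lid in line_ids}
    truth: list[dict] = []
    used_positions: set[int] = set()
    for oligo, offset, ref_b, alt_b, carriers in cfg.variant_specs:
        if carriers > cfg.panel_size:
            raise ValueError("carrier_count exceeds panel_size")
        site = sites[oligo]
        pos1 = site.offset_to_amplicon(offset)
        if pos1 in used_positions:
            raise ValueError(f"overlapping variant specs at amplicon position {pos1}")
        used_positions.add(pos1)
        top_ref, top_alt = (ref_b, alt_b) if site.strand == "+" else (_rc(ref_b), _rc(alt_b))
        if assay.reference_amplicon[pos1 - 1] != top_ref:
            raise ValueError(
                f"spec ref base {ref_b!r} does not match amplicon at position {pos1}"
            )
        chosen = rng.choice(cfg.panel_size, size=carriers, replace=False)
        for i in chosen:
            seqs[line_ids[i]][pos1 - 1] = top_alt
        truth.append(
            {
                "oligo": oligo,
                "offset_from_5prime": offset,
                "ref_base": ref_b,
                "alt_base": alt_b,
                "amplicon_position": pos1,
                "carrier_count": carriers,
                "frequency_percent": 100.0 * carriers / cfg.panel_size,
            }
        )
    return {lid: "".join(s) for lid, s in seqs.items()}, truth


def write_panel_fasta(panel: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for lid, seq in panel.items():
            fh.write(f">{lid}\n{seq}\n")
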