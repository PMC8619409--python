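# Methods

## Problem and model

`copycall` determines transgene copy number and zygosity in diploid plants
from duplexed TaqMan qPCR, the workhorse assay of transformation pipelines:
a transgene channel (e.g. *bar*, FAM) and a single-copy endogenous
reference channel (e.g. maize *hmg*, VIC) are amplified in one well, and
the test sample's ratio to an inter-run calibrator of known dosage gives
its copy number.

### Amplification efficiency

A serial plasmid dilution measured in replicate gives the calibration line
Ct = m·log10(copies) + b, fitted by ordinary least squares with replicate
wells entering individually. The per-cycle efficiency is

    E = 10^(−1/m) − 1,

so m = −1/log10(2) ≈ −3.32 corresponds to perfect doubling (E = 1). QC
hallmarks: R² > 0.980 and E within 90–105% (both configurable). Efficiency
is stored as a fraction and rounded half-up to three decimals in reports;
half-up matches the convention of printed assay tables (Python's builtin
`round` is banker's rounding).

### Efficiency-corrected copy number

The copy estimate is the Pfaffl ratio

    copies = C_cal · (1+E_t)^(ΔCt_t) / (1+E_r)^(ΔCt_r),   ΔCt = Ct_cal − Ct_test

with per-assay efficiencies from the standard curves. `C_cal` is the
calibrator's transgene dosage per diploid genome; its default of 2
reproduces the conventional prefactor and corresponds to a homozygous
single-locus calibrator. The literature is not always explicit about
calibrator zygosity, so `calibrator_copies` is an exposed parameter rather
than a constant. With E_t = E_r = 1 the formula collapses to the familiar
2^−ΔΔCt comparative form; the efficiency-corrected form is preferred
because equal near-100% efficiencies are rarely met in practice.

Technical replicates are averaged on the Ct scale per channel before the
ratio is formed (one ratio per sample), not averaged as per-replicate
estimates; the latter is available as an option in the reliability module.

### Integer copy classes

Estimates snap to the nearest integer, capped into {0, 1, 2, >2}.
Estimates within a dead zone of half-width 0.15 (default) around a class
midpoint k + 0.5 are flagged ambiguous but still receive their nearest
class; ambiguous calls are reported, never dropped, and propagate to an
`indeterminate` zygosity. A sample whose transgene channel never amplifies
while its reference channel does is a transformation escape (class 0); a
dead reference channel yields no call.

### Zygosity and segregation

For a single-locus line, T1 copy class maps directly to zygosity
(0 → null segregant, 1 → hemizygous, 2 → homozygous; >2 or ambiguous →
indeterminate). Families are tested against the Mendelian 1:2:1
expectation (3:1 presence/absence alternative) with a Pearson chi-square
goodness-of-fit test, df = k−1, no continuity correction by default
(Yates optional for 2-class tests); α defaults to 0.05. Families that fail
the test keep their individual calls, flagged with the family verdict.
Predicted homozygotes are confirmed when every unambiguous T2 progeny call
is class 2, refuted by any class-0/1 progeny, and insufficient otherwise.

### Replicate reliability

The subsampling procedure quantifies what is lost by running fewer than
three technical replicates: taking each sample's 3-replicate mean as truth,
r replicates are drawn without replacement, averaged, re-called, and
compared. Concordance is 1 at r = 3 by construction and non-decreasing in
r in expectation. Under homoscedastic Ct noise, two-copy concordance is
below one-copy concordance because class midpoints are more closely spaced
on the Ct scale around two copies (log2(2.5/2) ≈ 0.32 cycles vs
log2(1.5/1) ≈ 0.58). All draws flow from one seeded generator in dataset
order, so reports are reproducible under re-runs but not under dataset
reordering.

### Digital PCR

Partition counts follow Poisson occupancy: λ = −ln(1 − p) with p the
positive fraction; saturated chips are rejected. Copies per genome =
2·λ_target/λ_ref (the 2 is the diploid reference dosage, configurable),
classed by the same dead-zone rule as qPCR so the methods cross-tabulate
directly. A Wilson interval on p, propagated to λ, is available; no
dead-partition correction is applied.

### SNP screen of assay oligos

Primer and probe sites are anchored exactly (unique match required) on the
reference amplicon — forward primer and probe on the top strand, the
reverse primer via its reverse complement. Because same-primer amplicons
are fixed-length, anchored columnwise comparison replaces multiple
alignment; sequences of deviating length are rejected rather than aligned,
a deliberate simplification that keeps the screen deterministic. Variants
are reported in each oligo's own orientation (offset from its 5′ end,
complemented bases for the reverse primer), matching how bench scientists
describe primer mismatches. User-facing coordinates are 1-based inclusive;
internal ones 0-based half-open. IUPAC ambiguity codes count as mismatches
but are flagged separately. Any variant in any oligo recommends redesign.

### Plate handling

Four 96-well source plates map onto one 384-well assay plate. Instruments
differ in placement and the convention is rarely recorded, so both common
bijections are implemented: `interleaved` (2×2 nesting; P1:A1→A1,
P2:A1→A2, P3:A1→B1, P4:A1→B2) as default and `block` (quadrant tiling).
Undetermined Ct is a typed absence (`None`), never a numeric sentinel such
as 40. Negative controls are screened before any batch is quantified: an
NTC must be silent in both channels below the no-amplification cutoff
(default Ct 38 on a 40-cycle run), and a wild-type negative must be silent
in the transgene channel while amplifying in the reference channel.
Control failure aborts the batch unless forced, and the override is
recorded.

## Synthetic data

The generators emulate the statistical structure the analysis assumes —
not amplification kinetics, inhibitors or extraction yield:

- Ct values are log-linear in template dose with independent Gaussian
  per-well noise (default σ = 0.3 cycles, the scale of inter-assay SDs on
  plasmid standards); an optional shared per-sample component models
  pipetting error.
- Default efficiencies are 0.993 (transgene) and 1.000 (reference),
  typical of a well-optimised duplex.
- T0 cohorts draw classes from a realistic transformation mix
  (≈4% escapes, 73% single-copy, 13% two-copy, 9% higher); the ">2" class
  simulates as 3 copies. T1 families draw Multinomial(1; ¼, ½, ¼).
- dPCR chips draw positives as Binomial(partitions, 1 − e^−λ) with 20,000
  partitions per chip.
- Amplicon panels plant specified variants (default: a forward-primer
  5′-terminal T>A in 112 of 633 lines and a reverse-primer second-base G>T
  in 3 of 633) on a deterministic synthetic 201-bp amplicon/assay
  (`default_assay()`), since real assay oligo sequences are proprietary.

Because the generators share the calling model's assumptions, passing
recovery tests demonstrates the correctness of the computations, not
robustness to real-data pathologies (degraded DNA, inhibition,
heteroscedastic noise, multi-locus inserts).

## Numerical and design choices

- OLS via `scipy.stats.linregress`; R² is the squared Pearson correlation.
- Pearson chi-square computed directly, p from `scipy.stats.chi2.sf`
  (for df = 2, p = e^(−χ²/2), used as an independent check).
- Sample SD (n−1) by default; CV = 100·SD/mean, 0 when SD is 0; n = 1 has
  SD defined as 0.
- Consistency percentages round half-up to 1 decimal; efficiencies to 3.
- All simulations are pure functions of (config, seed) using
  `numpy.random.default_rng`.
- Test problem sizes: 1000-sample cohorts with triplicate wells at
  σ_Ct = 0.1 for recovery; 2000 triples × 50 draws for reliability;
  1000 chips for dPCR; 2000 families of 200 for type-I calibration —
  large enough for stable Monte-Carlo margins while keeping the suite
  fast.

## Known limitations

- Single-locus model only: tandem or multi-locus inserts are reported as
  >2/indeterminate, never deconvolved.
- Ct values are taken as exported; no fluorescence-curve baselining or
  thresholding.
- The SNP screen assumes indel-free, fixed-length amplicons; structural
  variants under an oligo require true alignment, out of scope.
- No LOD/LOQ estimation or nonlinear amplification-curve modelling.
- dPCR volumes are metadata only; chip QC (dead partitions, rain) is not
  modelled.
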