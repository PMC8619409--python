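# copycall

Transgene copy-number and zygosity genotyping from duplexed TaqMan qPCR,
for plant transformation and molecular-breeding pipelines that screen
hundreds to thousands of plants per run.

Transformation programs need single-copy, ultimately homozygous events.
`copycall` implements the computational half of a high-throughput screen:
it ingests plate-level Ct exports, validates the negative controls, fits
standard curves to derive per-assay amplification efficiencies, estimates
each sample's copy number against an inter-run calibrator with the
efficiency-corrected (Pfaffl) ratio

    copies = C_cal · (1+E_t)^(ΔCt_t) / (1+E_r)^(ΔCt_r),   ΔCt = Ct_cal − Ct_test
    E = 10^(−1/slope) − 1   (from the standard-curve slope)

snaps estimates to integer classes {0, 1, 2, >2} with an explicit
ambiguity dead-zone, calls T1 zygosity under the single-locus Mendelian
model (1:2:1 chi-square segregation tests, T2 progeny verification of
homozygotes), quantifies replicate reliability by random subsampling,
cross-validates against digital PCR via the Poisson model
λ = −ln(1 − p), and screens the assay's primer/probe annealing sites for
SNPs across an amplicon panel. A synthetic-data module generates every
input with the statistical structure the analysis assumes, so the whole
pipeline is testable end to end without instrument data.

## Worked example

Simulate a 45-plant T0 screening batch (with calibrator, NTC and
wild-type control wells) and copy-call it:

```console
$ copycall simulate t0 --seed 7 --n 45 --ct-noise-sd 0.05 --outdir sim
simulate t0: seed 7 -> sim
$ copycall t0 --ct sim/ct.csv --layout sim/layout.csv \
    --curves sim/curves.json --calibrator CAL01 \
    --out calls.csv --report report.json
t0: 45/45 samples called (2 ambiguous) -> calls.csv
$ head -4 calls.csv
sample_id,estimate,copy_class,ambiguous,notes
S0001,1.0769443516550479,1,False,
S0002,2.119248596254221,2,False,
S0003,1.1553593794349362,1,False,
```

`estimate` is the continuous Pfaffl ratio (S0001 carries ≈1.08 transgene
copies per diploid genome relative to the two-copy calibrator) and
`copy_class` its integer call; estimates near a class midpoint are flagged
`ambiguous`. At this noise level the called class distribution
`{1: 29, 2: 8, 0: 5, gt2: 3}` matches the simulation's planted truth
exactly — the five class-0 plants are escapes whose transgene channel
never amplified.

Downstream, `copycall t1` turns calls plus a pedigree into per-plant
zygosity, per-family chi-square verdicts and a keep-list of homozygotes;
`copycall verify-t2` confirms them from progeny; `copycall dpcr`,
`copycall snpscan`, `copycall reliability` and `copycall concordance`
cover cross-validation, assay uniformity screening, replicate-number
design and method agreement. Every subcommand is a thin wrapper over
`import copycall` — see `docs/methods.md` for the model details.

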