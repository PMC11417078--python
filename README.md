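# ctdnamon

Circulating tumor DNA (ctDNA) therapy monitoring for locally advanced
rectal cancer, built for translational researchers who want to track
molecular response to neoadjuvant radio(chemo)therapy from duplicate
plasma draws — without a tumor-tissue biopsy.

## What it does

Plasma cell-free DNA (cfDNA) mixes DNA shed by normal tissue, by blood-cell
clones (clonal hematopoiesis, CHIP) and — in cancer patients — by the tumor.
`ctdnamon` separates these from ultradeep targeted sequencing of duplicate
cfDNA libraries drawn before (t0) and immediately after (t1) radiotherapy,
with one matched leukocyte (buffycoat) library per patient:

1. **Candidate somatic detection** — a site is a candidate only if *both*
   duplicate libraries carry ≥ 3 alternate reads (at ≥ 100× each) at some
   timepoint, and the patient's own buffycoat does not look germline
   (VAF ≥ 0.25 with ≥ 10 alt reads).
2. **Cohort buffycoat quantile filter** — the core statistic. For variant
   VAF `v` at position *i*, with `q95(i)` the 95th-percentile VAF across
   *all* patients' buffycoat libraries at that position, the variant is
   validated iff

   `v > 2 · q95(i)`

   (strict inequality; percentile by sorted linear interpolation at rank
   `p/100 · (n−1)`). Recurrent sequencing artifacts and CHIP hotspots are
   elevated in everyone's leukocyte DNA, so they fail; patient-private
   tumor signal passes.
3. **cfDNA quantification** — a sample of `m` ng holds
   `⌊1000·m / 6.51⌋` diploid genome copies (6.51 pg per diploid genome),
   twice that many haploid copies `H`, and a biological limit of detection
   of `VAF_min = 100/H` percent: with little cfDNA in the tube, no depth
   can rescue sensitivity.
4. **Response classification** — each validated variant's pooled VAF
   trajectory is `down`, `up` or `stable` (±10 % relative band); patients
   become `decrease`, `increase`, `mixed` or `ctdna_negative`, and ctDNA
   status is tested against the Dworak tumor-regression grade (responder =
   TRG 3–4) with a two-tailed Fisher's exact test computed by exact
   hypergeometric enumeration.

A synthetic cohort generator (`ctdnamon.simulate`) produces truth-labelled
cohorts with the same structure — planted tumor / CHIP / germline variants,
binomial read noise at Poisson depth, position-specific error rates — so
every stage is testable without patient data. The published per-patient
cfDNA masses and clinical annotations ship as bundled tables
(`ctdnamon.datasets`).

## Worked example

```bash
python examples/01_cfdna_quantification.py
```

```text
t0: cfDNA 6.4-176.0 ng (median 29 ng over 17 patients)
t1: cfDNA 5.25-366.0 ng (median 44 ng over 17 patients)
t0: 983-27,035 diploid genome copies per sample
  scarcest sample (HROC586, 6.4 ng): 1 tumor genome in 1,966 haploid copies = min VAF 0.05%
t1: 806-56,221 diploid genome copies per sample
  scarcest sample (HROC566, 5.25 ng): 1 tumor genome in 1,612 haploid copies = min VAF 0.06%
```

The first two lines summarize how much cfDNA each blood draw yielded; the
copy numbers translate those masses into the number of genomes actually in
the tube; the "min VAF" lines are the biological detection floor of the
worst-provisioned samples — a tumor fraction below 0.05 % is invisible at
t0 no matter how deeply one sequences.

On a synthetic cohort (`examples/03_call_and_filter.py`, seed 5) the two
validation stages compress ~108 candidates per patient to ~1.4 validated
mutations per patient, every one of them a planted tumor variant:

```text
candidates: 1839 (~108/patient) -> validated: 23 (~1.4/patient)
detection rate: 64.7% of patients ctDNA-positive
validated variants by truth label: {'tumor': 23}
```

`examples/04_response_association.py` then classifies each patient's VAF
dynamic and prints the (underpowered, non-significant) Fisher association
with clinical response.

The same stages are available as a CLI:
`ctdnamon simulate | validate-inputs | quantify | call | filter | respond | report`.

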