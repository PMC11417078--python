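# Methods

## The monitoring problem

Neoadjuvant radio(chemo)therapy for locally advanced rectal cancer lacks a
cheap, repeatable readout of molecular response. Plasma cfDNA offers one:
somatic mutations present in plasma but absent from the patient's leukocyte
DNA mark circulating tumor DNA, and their variant-allele-frequency (VAF)
trajectory between a pre-therapy draw (t0) and a draw right after the last
radiation fraction (t1) summarizes how the tumor's contribution to plasma
changed under treatment. The difficulty is that at the relevant VAFs
(0.1–10 %) three confounders dominate: recurrent position-specific
sequencing artifacts, clonal-hematopoiesis (CHIP) variants shed by blood
cells into plasma, and ordinary germline polymorphisms. The pipeline's job
is to strip all three with nothing but count data and matched buffycoat
libraries.

## Model and procedure

**Inputs.** Per-library site count tables (chrom, 1-based pos, anchored
ref/alt alleles, ref/alt read counts, gene, consequence class), a manifest
tying duplicate plasma libraries and one buffycoat library to each patient
and timepoint with the sample's cfDNA mass, and a clinical table (protocol,
Dworak TRG, downstaging, staging). Counts are the ingestion boundary;
alignment and raw pileup handling are upstream concerns.

**Candidate detection.** VAF is `alt / (alt + ref)`; reads supporting
neither allele are ignored. A site is a candidate somatic variant when at
≥ 1 timepoint *both* duplicates show ≥ `min_alt_reads` (default 3)
alternate reads at ≥ `min_depth` (default 100), and the patient's
buffycoat is evaluable (depth ≥ `min_depth`) and not germline
(VAF ≥ 0.25 *and* ≥ 10 alt reads). Duplicate concordance is the first
validation stage: independent library preparation makes concordant noise
quadratically rarer. The defaults give ≥ 95 % binomial detection
probability per duplicate at the worst-case biological detection limit
(VAF 5×10⁻⁴ at 10,000×), which is why 3 reads rather than a higher cut.
Either-timepoint support is deliberate: variants that vanish at t1 are a
response signal, not a miss. Germline status is decided on the patient's
own buffycoat only; the 0.25 threshold catches heterozygous (≈0.5) and
homozygous sites while leaving low-VAF CHIP to the cohort filter — that
split of labor is the design's backbone.

**The quantile filter.** For each candidate position the VAFs of *all*
patients' buffycoat libraries (the patient's own included; zero-depth
libraries excluded and counted as missing) form the background
distribution. With `q95` its 95th percentile — sorted linear interpolation
at rank `p/100·(n−1)` — the variant is validated iff
`max(vaf_t0, vaf_t1) > 2·q95`, strictly. Per-timepoint verdicts are kept
for audit, the maximum decides: a variant real at either timepoint is
real. Position-specific artifacts reproduce across libraries at the same
position, and recurrent CHIP hotspots are elevated across leukocyte
libraries, so both fail the doubled percentile; patient-private tumor
signal at a clean position faces a threshold near zero but still had to
clear the duplicate-concordance stage, so noise does not flood through.

**Quantification.** A diploid human genome weighs 6.51 pg, so `m` ng of
cfDNA contains `⌊1000·m/6.51⌋` diploid copies — truncated, not rounded: a
fractional genome is not a detectable template, and truncation is the only
rule consistent with the published copy numbers (5.25 ng → 806 diploid /
1612 haploid; half-up rounding would give 1613). The biological limit of
detection is one haploid tumor genome among `H = 2·⌊1000·m/6.51⌋` haploid
copies, i.e. `100/H` percent, reported half-up to 2 decimals. Cohort mass
medians are order statistics reported both raw and to the nearest ng.

**Response classes.** Variant direction is `stable` when
`|v1 − v0| ≤ 0.10 · max(v0, v1)` (or both zero), else `down`/`up` by sign.
The 10 % band quantifies "nearly constant" and is a parameter. Patient
classes: `ctdna_negative` without validated variants; `decrease` with ≥ 1
down and no up; `increase` in the mirror case; `mixed` with both.
All-stable patients carry persistent ctDNA — a non-clearing signal — and
are grouped with `increase` under a `stable_only` flag rather than given a
fifth class. Responder = Dworak TRG ≥ 3 (the cohort contains no TRG 2;
the ≥ 3 rule extends the printed dichotomy conservatively); downstaging
requires a decrease in both T and N category. Association is tested on
the 2×2 table (ctDNA-negative/positive × responder/non-responder) with a
two-tailed Fisher's exact test under the probability-mass rule, summed in
exact integer/rational arithmetic so ties at the observed table's
probability are decided exactly.

**Reports.** The oncoplot matrix uses patients with ≥ 1 validated mutation
as the gene-frequency denominator — the only denominator under which a
gene hit in 3 of 12 mutated patients is a 25 % gene. Multiple hits per
gene/patient cell collapse to the most severe consequence
(stop gained > frameshift > essential splice > inframe indel > missense),
with the hit count retained. Stacked-bar tables keep one row per validated
variant with both pooled VAFs; a t1 VAF of zero stays in the table because
the disappearing bar is the result.

## The synthetic cohort generator

`SimConfig` defaults are the study conditions: 17 patients allocated
6 RAPIDO / 6 fRCT / 5 SCRT by largest-remainder proportion, responder
probability 9/17, ctDNA-positive probability 12/17, 1–4 tumor variants per
positive patient with t0 VAFs log-uniform on 0.001–0.084, duplicate
plasma libraries at Poisson(10,000)× depth, CHIP VAFs uniform on
0.005–0.03, three germline hets per patient, and per-site background error
rates Gamma-distributed (shape 0.5, mean 5×10⁻⁴, capped at 5×10⁻³),
constant across libraries at a position — the recurrent-artifact structure
the filter targets. Responders' tumor VAFs are scaled ×0.2 at t1 and
non-responders' ×1.5, each with per-variant lognormal jitter (σ = 0.5) so
mixed responses arise naturally. Alternate reads are binomial with success
probability = expected compartment VAF + site error.

Two structural choices matter. CHIP hotspots are cohort-shared (every
patient carries each hotspot at a patient-specific VAF in both plasma and
buffycoat): recurrent hotspot positions are what a cohort-wide buffycoat
panel can recognise, and patient-private CHIP would be indistinguishable
from tumor signal for *any* panel-of-normals method — a genuine limitation
of the approach, not of this implementation. Germline sites are drawn per
patient from a shared common-SNP pool, as polymorphisms recur across
individuals.

The site universe is a desk-scale stand-in: 2 assayable positions per gene
for 127 genes (254 sites) instead of 800 kb, with `PanelDesign` recording
the real panel's parameters. Consequence classes are site-level
annotations drawn at 22:13:5:2:1
(missense:frameshift:inframe:stop:splice); indel-class sites get anchored
indel alleles. What the generator does **not** emulate: read-level errors
and UMIs, depth variation along the panel, GC or fragmentation biases,
inter-library error-rate drift, tri-allelic sites, and tumor-fraction
coupling between variants of one patient (each variant's VAF is drawn
independently). Passing recovery tests therefore demonstrates the
statistical logic of the filter chain under its own model, not performance
on real sequencing data.

One published-cohort quirk surfaces in the bundled tables: the clinical
table lists patient HROC561 where the mass table lists HROC601, and the
prose and tables disagree on the fRCT/SCRT split (the bundled tables keep
each source as printed). One mass is printed as 5.3 ng in the table but
5.25 ng in the text; 5.25 is stored, being the value consistent with the
published copy numbers.

## Numerical choices and degenerate inputs

Percentiles via numpy's linear interpolation (the dominant convention;
an independent sort-and-interpolate oracle pins it in tests). The filter
comparison is strictly `>`: at a clean position (`q95 = 0`) any nonzero
pooled VAF passes, which is intended — caller-stage thresholds already
gate raw noise. Zero-depth VAF is an error, never 0/0 = 0; zero-depth
buffycoat libraries are excluded from the panel per position; positions
absent from every buffycoat library raise. Pooled VAF at a timepoint with
no reads is reported as 0.0 (the variant may genuinely be gone). Fisher's
test refuses degenerate margins. Fixed seeds make every generator output
byte-reproducible; the truth table round-trips at full float precision.

## Problem sizes

Recovery benchmarks run 50 simulated cohorts (default 17 patients,
254 sites, 85 libraries each — about a minute in total), the quantile
oracle check 10,000 randomized instances, the Fisher oracle 2,000 random
tables with N ≤ 200. These sizes give ≥ 1,200 eligible tumor variants,
1,700 CHIP and 2,550 germline truth labels per run, enough to resolve the
5–10 % tolerance bands the recovery checks use.

## Known limitations

The detection thresholds (3 reads / 100×) are this package's choices, not
published values; sensitivity claims are relative to the simulator's error
model. The cohort detection rate, per-gene frequencies and mutation
tallies of the real study depend on unreleased patient sequencing data and
are exercised here only as report logic on synthetic fixtures. The filter
evaluates the maximum over timepoints; a per-timepoint decision rule is
emitted alongside but does not drive validation. Survival and recurrence
endpoints are out of scope.
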