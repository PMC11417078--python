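"""Generate a truth-labelled synthetic cohort and inspect its structure.

The generator emulates the monitored study population: 17 patients
(6 RAPIDO / 6 fRCT / 5 SCRT), duplicate 10,000x plasma libraries at two
timepoints plus one buffycoat library each, with planted tumor, CHIP and
germline variants and position-specific background error.
"""

from collections import Counter

from ctdnamon.simulate import SimConfig, generate_cohort, generate_site_counts

config = SimConfig(seed=5)
truth = generate_cohort(config)
counts = generate_site_counts(truth)

print(f"patients: {len(truth.patients)}  libraries: {len(counts)}")
print("protocols:", dict(Counter(p.protocol for p in truth.patients)))
print(
    "responders (Dworak TRG >= 3):",
    sum(p.dworak_trg >= 3 for p in truth.patients),
)
print("true variants by origin:", dict(Counter(v.origin for v in truth.true_variants)))

tumor = [v for v in truth.true_variants if v.origin == "tumor"]
print(
    f"tumor VAFs at t0: {min(v.vaf_t0 for v in tumor):.4f}"
    f"-{max(v.vaf_t0 for v in tumor):.4f}"
)

# Each library is a plain count table; this is the pipeline's only input.
lib = truth.samples[0].library_ids[0]
print(f"\nfirst rows of {lib}:")
print(counts[lib].head(3).to_string(index=False))

# Germline sites sit at VAF ~0.5 in every compartment, CHIP is shared
# between plasma and buffycoat, tumor signal is plasma-only — exactly the
# three contamination/signal classes the pipeline has to separate.
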