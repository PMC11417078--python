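"""How much tumor signal can each plasma sample possibly show?

Loads the bundled per-patient cfDNA masses (17 rectal-cancer patients,
drawn before and right after neoadjuvant radiotherapy), converts each mass
into diploid/haploid genome equivalents and prints the biological limit of
detection of the scarcest samples.
"""

from ctdnamon import datasets
from ctdnamon.quantify import detection_limit, diploid_copies, summarize_masses

samples, _ = datasets.cfdna_manifest()

summary = summarize_masses(samples)
for tp in ("t0", "t1"):
    s = summary[tp]
    print(
        f"{tp}: cfDNA {s['min_ng']}-{s['max_ng']} ng "
        f"(median {s['median_ng_rounded']} ng over {s['n']} patients)"
    )

for tp in ("t0", "t1"):
    tp_samples = [s for s in samples if s.timepoint == tp]
    copies = [diploid_copies(s.cfdna_ng) for s in tp_samples]
    print(f"{tp}: {min(copies):,}-{max(copies):,} diploid genome copies per sample")
    worst = min(tp_samples, key=lambda s: s.cfdna_ng)
    lim = detection_limit(worst.cfdna_ng)
    print(
        f"  scarcest sample ({worst.patient_id}, {worst.cfdna_ng} ng): "
        f"1 tumor genome in {lim.haploid_copies:,} haploid copies "
        f"= min VAF {lim.min_vaf_percent}%"
    )

# The detection limit is biology, not chemistry: with only ~1,966 haploid
# genomes in the tube, no sequencing depth can see a tumor fraction below
# 1/1966 (VAF 0.05%).
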