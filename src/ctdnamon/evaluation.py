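"""Parameter-recovery benchmarks of the full pipeline on synthetic cohorts.

Runs the complete analysis (detection -> quantile filter -> response
classification) on freshly generated truth-labelled cohorts and scores how
well the truth is recovered:

* a true tumor variant is *eligible* when its VAF clears the quantile
  threshold with a 3-binomial-SE margin (anything closer to the threshold
  is expected to fail stochastically and says nothing about the method);
* CHIP variants and germline heterozygous sites should never come out as
  validated somatic mutations;
* ctDNA-positive responders (whose t1 tumor VAFs the generator scales
  down) should be classified `decrease`.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable

from .pipeline import run_pipeline
from .simulate import SimConfig, generate_cohort, generate_site_counts

__all__ = ["RecoveryMetrics", "recovery_metrics"]


@dataclass
class RecoveryMetrics:
    """Aggregated truth-recovery counts over one or more simulated cohorts."""

    n_seeds: int = 0
    n_tumor_eligible: int = 0
    n_tumor_recovered: int = 0
    n_chip: int = 0
    n_chip_passed: int = 0
    n_germline: int = 0
    n_germline_passed: int = 0
    n_positive_responders: int = 0
    n_positive_responders_decrease: int = 0
    classes_partition_cohort: bool = True

    @property
    def tumor_recovery_rate(self) -> float:
        return self.n_tumor_recovered / max(self.n_tumor_eligible, 1)

    @property
    def chip_rejection_rate(self) -> float:
        return 1.0 - self.n_chip_passed / max(self.n_chip, 1)

    @property
    def germline_rejection_rate(self) -> float:
        return 1.0 - self.n_germline_passed / max(self.n_germline, 1)

    @property
    def responder_decrease_rate(self) -> float:
        return self.n_positive_responders_decrease / max(self.n_positive_responders, 1)


def recovery_metrics(
    seeds: Iterable[int], config: SimConfig | None = None
) -> RecoveryMetrics:
    """Score full-pipeline truth recovery over one cohort per seed."""
    base = config or SimConfig()
    m = RecoveryMetrics()
    for seed in seeds:
        cfg = replace(base, seed=int(seed))
        truth = generate_cohort(cfg)
        counts = generate_site_counts(truth, cfg)
        result = run_pipeline(counts, truth.samples, truth.buffycoat_libraries)
        m.n_seeds += 1

        passed = {
            (v.patient_id, v.candidate.site) for v in result.validated if v.passed
        }
        pooled_depth = 2 * cfg.depth_mean  # duplicates pooled
        multiplier = 2.0
        for v in truth.true_variants:
            key = (v.patient_id, v.site)
            if v.origin == "tumor":
                q = result.panel.q.get(v.site, 0.0)
                vmax = max(v.vaf_t0, v.vaf_t1)
                se = math.sqrt(vmax * (1.0 - vmax) / pooled_depth)
                if vmax > multiplier * q + 3.0 * se:
                    m.n_tumor_eligible += 1
                    m.n_tumor_recovered += key in passed
            elif v.origin == "chip":
                m.n_chip += 1
                m.n_chip_passed += key in passed
            elif v.origin == "germline":
                m.n_germline += 1
                m.n_germline_passed += key in passed

        class_counts = Counter(c.call_class for c in result.calls)
        if sum(class_counts.values()) != len(truth.patients):
            m.classes_partition_cohort = False

        calls = {c.patient_id: c.call_class for c in result.calls}
        positive = {
            v.patient_id for v in truth.true_variants if v.origin == "tumor"
        }
        for p in truth.patients:
            if p.dworak_trg >= 3 and p.patient_id in positive:
                m.n_positive_responders += 1
                m.n_positive_responders_decrease += (
                    calls.get(p.patient_id) == "decrease"
                )
    return m
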