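"""Cohort-wide buffycoat quantile filter for recurrent sequencing artifacts.

Ultradeep targeted sequencing shows recurrent, position-specific technical
artifacts: some genomic positions accumulate low-level alternate reads in
every library regardless of biology.  The buffycoat libraries of all
patients form a panel of normals for exactly this background.  For each
candidate somatic variant the filter computes the 95th-percentile VAF of
the cohort's buffycoat libraries at that position and deems the variant
true only if its plasma VAF is strictly greater than twice that percentile.
Because clonal-hematopoiesis hotspots are likewise elevated across
leukocyte libraries, the same comparison removes CHIP contamination.

Percentiles use sorted linear interpolation between order statistics
(rank = p/100 * (n-1)), numpy's default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .calling import CandidateVariant

__all__ = [
    "FilterParams",
    "BuffycoatPanel",
    "ValidatedVariant",
    "FilterSummary",
    "PanelError",
    "build_panel",
    "validate_variant",
    "filter_cohort",
]

Site = tuple[str, int, str, str]


class PanelError(KeyError):
    """A queried position is absent from every buffycoat library."""


@dataclass(frozen=True)
class FilterParams:
    """Percentile (of the buffycoat VAF distribution) and multiplier."""

    percentile: float = 95.0
    multiplier: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.percentile < 100:
            raise ValueError("percentile must be in (0, 100)")
        if not self.multiplier > 0:
            raise ValueError("multiplier must be positive")


@dataclass(frozen=True)
class BuffycoatPanel:
    """Per-position background VAF distribution over all patients' buffycoats.

    ``vafs`` maps a site to the VAF observed in each buffycoat library that
    covers it (zero-depth libraries excluded, their count in ``n_missing``);
    ``q`` holds the precomputed percentile per site.
    """

    vafs: Mapping[Site, np.ndarray]
    q: Mapping[Site, float]
    n_missing: Mapping[Site, int]
    n_libraries: int
    percentile: float

    def quantile(self, site: Site) -> float:
        try:
            return self.q[site]
        except KeyError:
            raise PanelError(
                f"position {site[0]}:{site[1]} {site[2]}>{site[3]} absent from "
                f"every buffycoat library"
            ) from None


def build_panel(
    buffycoat_frames: Iterable[pd.DataFrame],
    positions: Iterable[Site] | None = None,
    percentile: float = 95.0,
) -> BuffycoatPanel:
    """Assemble the panel of normals from all patients' buffycoat count tables.

    ``positions`` restricts the panel to the queried sites (default: every
    site covered by any library).  A library with zero depth at a site is
    recorded as missing there rather than contributing a VAF of 0/0.
    """
    frames = list(buffycoat_frames)
    if len(frames) < 2:
        raise ValueError(f"panel needs >=2 buffycoat libraries, got {len(frames)}")
    long = pd.concat(
        [f[["chrom", "pos", "ref", "alt", "ref_reads", "alt_reads"]] for f in frames],
        ignore_index=True,
    )
    long["depth"] = long["ref_reads"] + long["alt_reads"]
    covered = long[long["depth"] > 0].copy()
    covered["vaf"] = covered["alt_reads"] / covered["depth"]
    grouped = covered.groupby(["chrom", "pos", "ref", "alt"], sort=False)["vaf"]

    vafs: dict[Site, np.ndarray] = {}
    for site, series in grouped:
        vafs[site] = series.to_numpy()

    if positions is None:
        wanted = list(vafs)
    else:
        wanted = list(dict.fromkeys(positions))
    q: dict[Site, float] = {}
    n_missing: dict[Site, int] = {}
    for site in wanted:
        if site not in vafs:
            raise PanelError(
                f"position {site[0]}:{site[1]} {site[2]}>{site[3]} absent from "
                f"every buffycoat library"
            )
        q[site] = float(np.percentile(vafs[site], percentile))
        n_missing[site] = len(frames) - len(vafs[site])
    return BuffycoatPanel(
        vafs={s: vafs[s] for s in wanted},
        q=q,
        n_missing=n_missing,
        n_libraries=len(frames),
        percentile=percentile,
    )


@dataclass(frozen=True)
class ValidatedVariant:
    """A candidate with its quantile-filter verdict, thresholds kept for audit."""

    candidate: CandidateVariant
    q95: float
    threshold: float
    evaluated_vaf: float
    passed: bool
    passed_t0: bool
    passed_t1: bool

    @property
    def patient_id(self) -> str:
        return self.candidate.patient_id


def validate_variant(
    candidate: CandidateVariant,
    panel: BuffycoatPanel,
    params: FilterParams = FilterParams(),
) -> ValidatedVariant:
    """Apply the quantile filter to one candidate.

    The decisive VAF is the maximum of the pooled t0/t1 VAFs (a variant
    real at either timepoint is real); per-timepoint verdicts are also
    recorded.  The comparison is strictly greater-than: a VAF exactly at
    the threshold fails.
    """
    q = panel.quantile(candidate.site)
    threshold = params.multiplier * q
    evaluated = max(candidate.vaf_t0, candidate.vaf_t1)
    return ValidatedVariant(
        candidate=candidate,
        q95=q,
        threshold=threshold,
        evaluated_vaf=evaluated,
        passed=evaluated > threshold,
        passed_t0=candidate.vaf_t0 > threshold,
        passed_t1=candidate.vaf_t1 > threshold,
    )


@dataclass(frozen=True)
class FilterSummary:
    """Per-patient candidate/validated tallies and the cohort detection rate."""

    n_candidates: dict[str, int]
    n_validated: dict[str, int]
    detection_rate: float


def filter_cohort(
    candidates: Sequence[CandidateVariant],
    panel: BuffycoatPanel,
    params: FilterParams = FilterParams(),
    patient_ids: Sequence[str] | None = None,
) -> tuple[list[ValidatedVariant], FilterSummary]:
    """Annotate every candidate with its verdict and summarize the cohort.

    ``patient_ids`` fixes the denominator of the detection rate (fraction
    of patients with >=1 validated variant); by default only patients that
    contributed candidates are counted.
    """
    validated = [validate_variant(c, panel, params) for c in candidates]
    if patient_ids is None:
        patient_ids = sorted({c.patient_id for c in candidates})
    n_candidates = {pid: 0 for pid in patient_ids}
    n_validated = {pid: 0 for pid in patient_ids}
    for v in validated:
        n_candidates.setdefault(v.patient_id, 0)
        n_validated.setdefault(v.patient_id, 0)
        n_candidates[v.patient_id] += 1
        if v.passed:
            n_validated[v.patient_id] += 1
    rate = (
        sum(1 for pid in patient_ids if n_validated.get(pid, 0) > 0) / len(patient_ids)
        if patient_ids
        else 0.0
    )
    return validated, FilterSummary(
        n_candidates=n_candidates, n_validated=n_validated, detection_rate=rate
    )
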