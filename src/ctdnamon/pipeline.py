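"""End-to-end orchestration: counts + manifest in, validated variants and
response calls out."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .artifact_filter import (
    BuffycoatPanel,
    FilterParams,
    FilterSummary,
    ValidatedVariant,
    build_panel,
    filter_cohort,
)
from .calling import CallerParams, CandidateVariant, PatientLibraries, detect_candidates
from .report import CohortReport, cohort_report
from .response import ResponseCall, build_contingency, classify_cohort, fisher_exact_2x2
from .variant_io import PatientRecord, PlasmaSample, read_clinical, read_counts_frame, read_manifest

__all__ = ["PipelineResult", "run_pipeline", "load_cohort_dir"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineResult:
    """All intermediate and final products of one cohort analysis."""

    candidates: list[CandidateVariant]
    panel: BuffycoatPanel
    validated: list[ValidatedVariant]
    summary: FilterSummary
    calls: list[ResponseCall]
    report: CohortReport
    p_value: float | None = None
    contingency: tuple[int, int, int, int] | None = None


def _patient_libraries(
    patient_id: str,
    samples: Sequence[PlasmaSample],
    buffycoat_library: str,
    counts: Mapping[str, pd.DataFrame],
) -> PatientLibraries:
    plasma = {}
    for s in samples:
        if s.patient_id == patient_id:
            plasma[s.timepoint] = tuple(counts[lib] for lib in s.library_ids)
    return PatientLibraries(
        patient_id=patient_id, plasma=plasma, buffycoat=counts[buffycoat_library]
    )


def run_pipeline(
    counts: Mapping[str, pd.DataFrame],
    samples: Sequence[PlasmaSample],
    buffycoat_map: Mapping[str, str],
    clinical: Sequence[PatientRecord] | None = None,
    caller_params: CallerParams = CallerParams(),
    filter_params: FilterParams = FilterParams(),
    stable_rel_tol: float = 0.10,
) -> PipelineResult:
    """Run detection, quantile filtering and response classification.

    Patients without a buffycoat library are skipped with a warning, as no
    germline comparison is possible for them.
    """
    patient_ids = sorted({s.patient_id for s in samples})
    usable = []
    for pid in patient_ids:
        if pid not in buffycoat_map:
            logger.warning("patient %s skipped: no buffycoat library", pid)
            continue
        usable.append(pid)

    candidates: list[CandidateVariant] = []
    for pid in usable:
        libs = _patient_libraries(pid, samples, buffycoat_map[pid], counts)
        candidates.extend(detect_candidates(libs, caller_params))

    panel = build_panel(
        [counts[buffycoat_map[pid]] for pid in usable],
        percentile=filter_params.percentile,
    )
    validated, summary = filter_cohort(
        candidates, panel, filter_params, patient_ids=usable
    )
    calls = classify_cohort(validated, usable, stable_rel_tol)
    report = cohort_report(validated, usable, summary.n_candidates)

    p_value = None
    contingency = None
    if clinical is not None:
        known = {r.patient_id for r in clinical}
        cohort_calls = [c for c in calls if c.patient_id in known]
        if cohort_calls:
            table = build_contingency(cohort_calls, clinical)
            contingency = table.cells
            try:
                p_value = fisher_exact_2x2(table)
            except ValueError:  # degenerate margins in small synthetic cohorts
                p_value = None
    return PipelineResult(
        candidates=candidates,
        panel=panel,
        validated=validated,
        summary=summary,
        calls=calls,
        report=report,
        p_value=p_value,
        contingency=contingency,
    )


def load_cohort_dir(
    directory: str | Path,
) -> tuple[dict[str, pd.DataFrame], list[PlasmaSample], dict[str, str], list[PatientRecord] | None]:
    """Load a fixture directory written by :func:`ctdnamon.simulate.write_fixture`."""
    directory = Path(directory)
    samples, buffycoat_map = read_manifest(directory / "manifest.tsv")
    libraries = [lib for s in samples for lib in s.library_ids]
    libraries += list(buffycoat_map.values())
    counts = {
        lib: read_counts_frame(directory / "counts" / f"{lib}.tsv") for lib in libraries
    }
    clinical_path = directory / "clinical.tsv"
    clinical = read_clinical(clinical_path) if clinical_path.exists() else None
    return counts, samples, buffycoat_map, clinical
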