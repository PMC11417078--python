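"""Cohort-level report tables: oncoplot matrix, VAF bars, summary counts."""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Mapping, Sequence

import pandas as pd

from .artifact_filter import ValidatedVariant
from .response import responder_from_trg
from .variant_io import PatientRecord

__all__ = [
    "SEVERITY_ORDER",
    "OncoplotMatrix",
    "CohortReport",
    "oncoplot_matrix",
    "stacked_bar_data",
    "cohort_report",
]

#: Most to least severe; used to collapse multiple hits in one gene/patient cell.
SEVERITY_ORDER = (
    "stop_gained",
    "frameshift",
    "essential_splice",
    "inframe_indel",
    "missense",
)


def _severity(consequence: str) -> int:
    try:
        return SEVERITY_ORDER.index(consequence)
    except ValueError:
        return len(SEVERITY_ORDER)


def _responder_map(records: Sequence[PatientRecord]) -> dict[str, bool]:
    return {r.patient_id: responder_from_trg(r.dworak_trg) for r in records}


@dataclass(frozen=True)
class OncoplotMatrix:
    """Genes x patients grid of consequence classes with per-gene frequencies.

    Frequencies are percentages of *mutated* patients (those with >=1
    validated mutation) carrying the gene — the denominator that makes a
    gene hit in 3 of 12 mutated patients a 25% gene.
    """

    matrix: pd.DataFrame  # index genes, columns patients, values consequence or ""
    gene_frequency: dict[str, float]  # percent, 1 decimal
    n_mutated_patients: int
    hit_counts: dict[tuple[str, str], int]  # (gene, patient) -> n hits collapsed


def oncoplot_matrix(
    validated: Sequence[ValidatedVariant], records: Sequence[PatientRecord]
) -> OncoplotMatrix:
    """Build the mutation-landscape matrix from passing variants.

    Genes are ordered by descending frequency then name; patients
    responder-first, then by id.  Multiple hits in one gene and patient
    collapse to the most severe consequence; the hit count is retained.
    """
    passed = [v for v in validated if v.passed]
    responder = _responder_map(records)
    carriers = sorted({v.patient_id for v in passed})
    if not carriers:
        return OncoplotMatrix(pd.DataFrame(), {}, 0, {})

    cells: dict[tuple[str, str], list[str]] = {}
    for v in passed:
        cells.setdefault((v.candidate.gene, v.patient_id), []).append(
            v.candidate.consequence
        )
    genes = sorted({g for g, _ in cells})
    freq = {
        g: round(100.0 * sum(1 for p in carriers if (g, p) in cells) / len(carriers), 1)
        for g in genes
    }
    genes.sort(key=lambda g: (-freq[g], g))
    patients = sorted(
        carriers, key=lambda p: (not responder.get(p, False), p)
    )
    matrix = pd.DataFrame("", index=genes, columns=patients)
    hit_counts = {}
    for (g, p), csqs in cells.items():
        matrix.loc[g, p] = min(csqs, key=_severity)
        hit_counts[(g, p)] = len(csqs)
    return OncoplotMatrix(matrix, freq, len(carriers), hit_counts)


def stacked_bar_data(
    validated: Sequence[ValidatedVariant],
    records: Sequence[PatientRecord] | None = None,
) -> pd.DataFrame:
    """Long-format table behind the stacked VAF bars: one row per passing
    variant with both pooled timepoint VAFs.

    A variant undetectable at t1 keeps its row with ``vaf_t1 = 0`` — the
    disappearing bar is the signal.  With clinical records, patients are
    partitioned responders-first.
    """
    passed = [v for v in validated if v.passed]
    rows = [
        {
            "patient_id": v.patient_id,
            "gene": v.candidate.gene,
            "chrom": v.candidate.chrom,
            "pos": v.candidate.pos,
            "ref": v.candidate.ref,
            "alt": v.candidate.alt,
            "consequence": v.candidate.consequence,
            "vaf_t0": v.candidate.vaf_t0,
            "vaf_t1": v.candidate.vaf_t1,
        }
        for v in passed
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "gene",
            "chrom",
            "pos",
            "ref",
            "alt",
            "consequence",
            "vaf_t0",
            "vaf_t1",
        ],
    )
    if records is not None and len(df):
        responder = _responder_map(records)
        df["responder"] = df["patient_id"].map(responder)
        df = df.sort_values(
            ["responder", "patient_id", "gene", "pos"],
            ascending=[False, True, True, True],
            kind="stable",
        ).reset_index(drop=True)
    return df


@dataclass(frozen=True)
class CohortReport:
    """Headline numbers of one cohort run."""

    n_patients: int
    n_mutated_patients: int
    detection_rate: float  # fraction of patients with >=1 validated variant
    n_distinct_mutations: int
    consequence_counts: dict[str, int]
    candidates_per_patient: dict[str, int]
    validated_per_patient: dict[str, int]
    mean_candidates_per_patient: float
    mean_validated_per_patient: float
    vaf_summary: dict[str, dict[str, float]]  # per timepoint: min/max/median

    def as_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "n_mutated_patients": self.n_mutated_patients,
            "detection_rate": self.detection_rate,
            "n_distinct_mutations": self.n_distinct_mutations,
            "consequence_counts": self.consequence_counts,
            "mean_candidates_per_patient": self.mean_candidates_per_patient,
            "mean_validated_per_patient": self.mean_validated_per_patient,
            "vaf_summary": self.vaf_summary,
        }


def cohort_report(
    validated: Sequence[ValidatedVariant],
    patient_ids: Sequence[str],
    candidates_per_patient: Mapping[str, int] | None = None,
) -> CohortReport:
    """Summarize the validated mutation landscape of a cohort.

    ``patient_ids`` is the full cohort (denominator of the detection rate);
    ``candidates_per_patient`` comes from the filter summary when available.
    """
    passed = [v for v in validated if v.passed]
    per_patient = {pid: 0 for pid in patient_ids}
    for v in passed:
        per_patient.setdefault(v.patient_id, 0)
        per_patient[v.patient_id] += 1
    mutated = [pid for pid, n in per_patient.items() if n > 0]
    csq_counts: dict[str, int] = {}
    for v in passed:
        csq_counts[v.candidate.consequence] = (
            csq_counts.get(v.candidate.consequence, 0) + 1
        )
    distinct = {
        (v.candidate.chrom, v.candidate.pos, v.candidate.ref, v.candidate.alt)
        for v in passed
    }
    vaf_summary = {}
    for tp, getter in (("t0", lambda v: v.candidate.vaf_t0), ("t1", lambda v: v.candidate.vaf_t1)):
        vals = [getter(v) for v in passed]
        vaf_summary[tp] = (
            {"min": min(vals), "max": max(vals), "median": median(vals)}
            if vals
            else {"min": 0.0, "max": 0.0, "median": 0.0}
        )
    n = len(per_patient)
    cand = dict(candidates_per_patient) if candidates_per_patient else {}
    return CohortReport(
        n_patients=n,
        n_mutated_patients=len(mutated),
        detection_rate=len(mutated) / n if n else 0.0,
        n_distinct_mutations=len(distinct),
        consequence_counts=csq_counts,
        candidates_per_patient=cand,
        validated_per_patient=per_patient,
        mean_candidates_per_patient=(
            sum(cand.values()) / len(per_patient) if cand and per_patient else 0.0
        ),
        mean_validated_per_patient=(len(passed) / n if n else 0.0),
        vaf_summary=vaf_summary,
    )
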