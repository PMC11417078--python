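"""Flat TSV serialization of candidate and validated variants.

These tables are the hand-off format between pipeline stages (and their
CLI commands): one row per variant, with the per-library read counts kept
so later stages can re-derive any VAF.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .artifact_filter import ValidatedVariant
from .calling import CandidateVariant
from .variant_io import SiteCounts

__all__ = [
    "candidates_to_frame",
    "frame_to_candidates",
    "validated_to_frame",
    "frame_to_validated",
]

_LIB_SLOTS = ("t0_r1", "t0_r2", "t1_r1", "t1_r2", "bc")


def candidates_to_frame(candidates: Sequence[CandidateVariant]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        libs = dict(zip(_LIB_SLOTS, (*c.t0_libraries, *c.t1_libraries, c.buffycoat)))
        row = {
            "patient_id": c.patient_id,
            "chrom": c.chrom,
            "pos": c.pos,
            "ref": c.ref,
            "alt": c.alt,
            "gene": c.gene,
            "consequence": c.consequence,
            "vaf_t0": c.vaf_t0,
            "vaf_t1": c.vaf_t1,
        }
        for slot, sc in libs.items():
            row[f"{slot}_library"] = sc.library_id
            row[f"{slot}_ref_reads"] = sc.ref_reads
            row[f"{slot}_alt_reads"] = sc.alt_reads
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_candidates(df: pd.DataFrame) -> list[CandidateVariant]:
    out = []
    for r in df.itertuples(index=False):
        def sc(slot: str) -> SiteCounts:
            return SiteCounts(
                library_id=getattr(r, f"{slot}_library"),
                chrom=r.chrom,
                pos=int(r.pos),
                ref=r.ref,
                alt=r.alt,
                ref_reads=int(getattr(r, f"{slot}_ref_reads")),
                alt_reads=int(getattr(r, f"{slot}_alt_reads")),
                gene=r.gene,
                consequence=r.consequence,
            )

        out.append(
            CandidateVariant(
                patient_id=r.patient_id,
                chrom=r.chrom,
                pos=int(r.pos),
                ref=r.ref,
                alt=r.alt,
                gene=r.gene,
                consequence=r.consequence,
                t0_libraries=(sc("t0_r1"), sc("t0_r2")),
                t1_libraries=(sc("t1_r1"), sc("t1_r2")),
                buffycoat=sc("bc"),
                vaf_t0=float(r.vaf_t0),
                vaf_t1=float(r.vaf_t1),
            )
        )
    return out


def validated_to_frame(validated: Sequence[ValidatedVariant]) -> pd.DataFrame:
    base = candidates_to_frame([v.candidate for v in validated])
    base["q95"] = [v.q95 for v in validated]
    base["threshold"] = [v.threshold for v in validated]
    base["evaluated_vaf"] = [v.evaluated_vaf for v in validated]
    base["passed"] = [v.passed for v in validated]
    base["passed_t0"] = [v.passed_t0 for v in validated]
    base["passed_t1"] = [v.passed_t1 for v in validated]
    return base


def frame_to_validated(df: pd.DataFrame) -> list[ValidatedVariant]:
    candidates = frame_to_candidates(df)
    out = []
    for c, r in zip(candidates, df.itertuples(index=False)):
        out.append(
            ValidatedVariant(
                candidate=c,
                q95=float(r.q95),
                threshold=float(r.threshold),
                evaluated_vaf=float(r.evaluated_vaf),
                passed=bool(r.passed),
                passed_t0=bool(r.passed_t0),
                passed_t1=bool(r.passed_t1),
            )
        )
    return out
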