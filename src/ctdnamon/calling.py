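"""Candidate somatic variant detection from duplicate cfDNA libraries.

A site becomes a candidate somatic variant when, at at least one timepoint,
BOTH duplicate plasma libraries independently show alternate-allele support
(``min_alt_reads`` each, at ``min_depth``), and the patient's own buffycoat
(leukocyte) library does not look germline at that position.  Duplicate
concordance is the first validation stage: a single-library signal at
ultradeep depth is as likely a PCR/sequencing artifact as a mutation.
Germline heterozygous and homozygous sites sit at VAF ~0.5/1.0 in leukocyte
DNA and are excluded here; low-VAF clonal-hematopoiesis contamination is
left for the cohort-wide quantile filter downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .quantify import compute_vaf
from .variant_io import SiteCounts

__all__ = [
    "CallerParams",
    "CandidateVariant",
    "PatientLibraries",
    "UnevaluableSiteError",
    "pool_duplicates",
    "flag_germline",
    "detect_candidates",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CallerParams:
    """Thresholds of the count-based caller.

    min_alt_reads: alternate reads required in EACH duplicate library.
    min_depth: minimum depth per library for a site to be evaluable.
    germline_vaf_threshold / germline_min_alt: a buffycoat site at or above
    both is treated as germline and excluded from somatic calling.
    """

    min_alt_reads: int = 3
    min_depth: int = 100
    germline_vaf_threshold: float = 0.25
    germline_min_alt: int = 10

    def __post_init__(self) -> None:
        if min(self.min_alt_reads, self.min_depth, self.germline_min_alt) < 0:
            raise ValueError("caller thresholds must be non-negative")
        if not 0 < self.germline_vaf_threshold < 1:
            raise ValueError("germline_vaf_threshold must be in (0, 1)")


class UnevaluableSiteError(ValueError):
    """Buffycoat depth too low to decide germline status at this site."""


@dataclass(frozen=True)
class CandidateVariant:
    """A candidate somatic mutation in one patient, before artifact filtering."""

    patient_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    t0_libraries: tuple[SiteCounts, SiteCounts]
    t1_libraries: tuple[SiteCounts, SiteCounts]
    buffycoat: SiteCounts
    vaf_t0: float
    vaf_t1: float

    @property
    def site(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class PatientLibraries:
    """All count tables of one patient, keyed for the caller.

    ``plasma`` maps timepoint -> (replicate 1 frame, replicate 2 frame);
    ``buffycoat`` is the single leukocyte library frame.  Frames follow the
    count-table schema of :mod:`ctdnamon.variant_io`.
    """

    patient_id: str
    plasma: Mapping[str, tuple[pd.DataFrame, pd.DataFrame]]
    buffycoat: pd.DataFrame


def pool_duplicates(a: SiteCounts, b: SiteCounts) -> SiteCounts:
    """Sum read counts of the two duplicate libraries at one site.

    The pooled VAF is then the depth-weighted mean of the duplicates' VAFs.
    """
    if a.site != b.site:
        raise ValueError(f"cannot pool mismatched sites {a.site} and {b.site}")
    return SiteCounts(
        library_id=f"{a.library_id}+{b.library_id}",
        chrom=a.chrom,
        pos=a.pos,
        ref=a.ref,
        alt=a.alt,
        ref_reads=a.ref_reads + b.ref_reads,
        alt_reads=a.alt_reads + b.alt_reads,
        gene=a.gene or b.gene,
        consequence=a.consequence or b.consequence,
    )


def flag_germline(buffycoat: SiteCounts, params: CallerParams = CallerParams()) -> bool:
    """True iff the buffycoat counts look germline at this site.

    Requires both a VAF at or above ``germline_vaf_threshold`` (captures
    heterozygous ~0.5 and homozygous ~1.0 sites) and ``germline_min_alt``
    supporting reads, so a handful of noise reads at low depth cannot mark a
    site germline.
    """
    if buffycoat.depth < params.min_depth:
        raise UnevaluableSiteError(
            f"buffycoat depth {buffycoat.depth} < {params.min_depth} at "
            f"{buffycoat.chrom}:{buffycoat.pos}"
        )
    vaf = compute_vaf(buffycoat.alt_reads, buffycoat.ref_reads)
    return vaf >= params.germline_vaf_threshold and (
        buffycoat.alt_reads >= params.germline_min_alt
    )


_SITE = ["chrom", "pos", "ref", "alt"]


def _indexed(df: pd.DataFrame, suffix: str) -> pd.DataFrame:
    out = df.set_index(_SITE)[["ref_reads", "alt_reads", "gene", "consequence"]]
    if out.index.has_duplicates:
        dup = out.index[out.index.duplicated()][0]
        raise ValueError(f"duplicate site {dup} in one library")
    return out.rename(
        columns={
            "ref_reads": f"ref_{suffix}",
            "alt_reads": f"alt_{suffix}",
            "gene": f"gene_{suffix}",
            "consequence": f"csq_{suffix}",
        }
    )


def detect_candidates(
    libs: PatientLibraries, params: CallerParams = CallerParams()
) -> list[CandidateVariant]:
    """Candidate somatic variants of one patient.

    A site qualifies when at >=1 timepoint both duplicates carry
    ``min_alt_reads`` alternate reads at ``min_depth``, and the buffycoat is
    evaluable and not germline.  Candidates carry pooled VAFs at both
    timepoints (a pooled VAF of 0 at the other timepoint is legitimate: a
    variant may appear or disappear under therapy).  Sites whose buffycoat
    is below ``min_depth`` are unevaluable and excluded with a logged
    warning.
    """
    if set(libs.plasma) - {"t0", "t1"}:
        raise ValueError(f"unknown timepoints {set(libs.plasma) - {'t0', 't1'}}")
    frames = []
    for tp, (rep1, rep2) in libs.plasma.items():
        frames.append(_indexed(rep1, f"{tp}a"))
        frames.append(_indexed(rep2, f"{tp}b"))
    bc = _indexed(libs.buffycoat, "bc")
    merged = pd.concat(frames, axis=1, join="outer")
    merged = merged.join(bc, how="left")
    counts = [c for c in merged.columns if c.startswith(("ref_", "alt_"))]
    merged[counts] = merged[counts].fillna(0).astype(int)

    def support(tp: str) -> pd.Series:
        a_alt, b_alt = merged[f"alt_{tp}a"], merged[f"alt_{tp}b"]
        a_dp = merged[f"ref_{tp}a"] + a_alt
        b_dp = merged[f"ref_{tp}b"] + b_alt
        return (
            (a_alt >= params.min_alt_reads)
            & (b_alt >= params.min_alt_reads)
            & (a_dp >= params.min_depth)
            & (b_dp >= params.min_depth)
        )

    supported = pd.Series(False, index=merged.index)
    for tp in libs.plasma:
        supported |= support(tp)

    bc_depth = merged["ref_bc"] + merged["alt_bc"]
    evaluable = bc_depth >= params.min_depth
    n_unevaluable = int((supported & ~evaluable).sum())
    if n_unevaluable:
        logger.warning(
            "%s: %d supported site(s) excluded, buffycoat depth < %d",
            libs.patient_id,
            n_unevaluable,
            params.min_depth,
        )
    with pd.option_context("mode.chained_assignment", None):
        bc_vaf = (merged["alt_bc"] / bc_depth.where(bc_depth > 0)).fillna(0.0)
    germline = evaluable & (bc_vaf >= params.germline_vaf_threshold) & (
        merged["alt_bc"] >= params.germline_min_alt
    )

    selected = merged[supported & evaluable & ~germline]
    # library ids travel in DataFrame.attrs when loaded from disk
    lib_ids: dict[str, str] = {}
    for tp, pair in libs.plasma.items():
        for r, df in zip("ab", pair):
            lib_ids[f"{tp}{r}"] = df.attrs.get(
                "library_id", f"{libs.patient_id}_{tp}_{r}"
            )

    candidates = []
    for key, row in selected.iterrows():
        chrom, pos, ref, alt = key
        gene = next(
            (row[c] for c in ("gene_t0a", "gene_t1a", "gene_bc") if c in row and pd.notna(row[c])),
            "",
        )
        csq = next(
            (row[c] for c in ("csq_t0a", "csq_t1a", "csq_bc") if c in row and pd.notna(row[c])),
            "",
        )

        def lib(tp: str, r: str) -> SiteCounts:
            return SiteCounts(
                library_id=lib_ids.get(f"{tp}{r}", f"{libs.patient_id}_{tp}_{r}"),
                chrom=chrom,
                pos=int(pos),
                ref=ref,
                alt=alt,
                ref_reads=int(row.get(f"ref_{tp}{r}", 0)),
                alt_reads=int(row.get(f"alt_{tp}{r}", 0)),
                gene=gene,
                consequence=csq,
            )

        def pooled_vaf(tp: str) -> float:
            alt_n = int(row.get(f"alt_{tp}a", 0)) + int(row.get(f"alt_{tp}b", 0))
            dp = (
                int(row.get(f"ref_{tp}a", 0))
                + int(row.get(f"ref_{tp}b", 0))
                + alt_n
            )
            return alt_n / dp if dp > 0 else 0.0

        candidates.append(
            CandidateVariant(
                patient_id=libs.patient_id,
                chrom=chrom,
                pos=int(pos),
                ref=ref,
                alt=alt,
                gene=gene,
                consequence=csq,
                t0_libraries=(lib("t0", "a"), lib("t0", "b")),
                t1_libraries=(lib("t1", "a"), lib("t1", "b")),
                buffycoat=SiteCounts(
                    library_id=f"{libs.patient_id}_bc",
                    chrom=chrom,
                    pos=int(pos),
                    ref=ref,
                    alt=alt,
                    ref_reads=int(row["ref_bc"]),
                    alt_reads=int(row["alt_bc"]),
                    gene=gene,
                    consequence=csq,
                ),
                vaf_t0=pooled_vaf("t0"),
                vaf_t1=pooled_vaf("t1"),
            )
        )
    from .variant_io import chrom_sort_key

    candidates.sort(key=lambda c: (chrom_sort_key(c.chrom), c.pos, c.ref, c.alt))
    return candidates
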