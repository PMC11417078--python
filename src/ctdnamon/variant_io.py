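"""Tabular and variant I/O for the ctDNA monitoring pipeline.

All on-disk formats are plain text: tab-separated count tables and
manifests on the way in, VCF 4.2 on the way out.  Genomic coordinates are
1-based inclusive (VCF convention) throughout; indels are represented with
anchored ref/alt allele strings, and the functional class (frameshift,
inframe indel, ...) lives in the ``consequence`` column, not in the allele
encoding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import pysam

__all__ = [
    "CONSEQUENCE_CLASSES",
    "SiteCounts",
    "PatientRecord",
    "PlasmaSample",
    "ValidationError",
    "read_site_counts",
    "read_counts_frame",
    "write_counts_frame",
    "read_manifest",
    "read_clinical",
    "write_validated_vcf",
]

#: Functional consequence classes recognised by the pipeline.
CONSEQUENCE_CLASSES = (
    "missense",
    "frameshift",
    "inframe_indel",
    "stop_gained",
    "essential_splice",
)

COUNTS_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "ref_reads",
    "alt_reads",
    "gene",
    "consequence",
]

MANIFEST_COLUMNS = [
    "patient_id",
    "timepoint",
    "library_id",
    "replicate",
    "compartment",
    "cfdna_ng",
]

TIMEPOINTS = ("t0", "t1")


class ValidationError(ValueError):
    """An input file violates the schema; the message names the offender."""


@dataclass(frozen=True)
class SiteCounts:
    """Reference/alternate read counts at one genomic position in one library.

    The unit of all calling and filtering: every downstream decision is a
    function of these counts.
    """

    library_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    ref_reads: int
    alt_reads: int
    gene: str = ""
    consequence: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValidationError(
                f"ref and alt alleles are identical ({self.ref}) at "
                f"{self.chrom}:{self.pos}"
            )
        if self.ref_reads < 0 or self.alt_reads < 0:
            raise ValidationError(
                f"negative read count at {self.chrom}:{self.pos} "
                f"({self.ref_reads}/{self.alt_reads})"
            )

    @property
    def depth(self) -> int:
        return self.ref_reads + self.alt_reads

    @property
    def site(self) -> tuple[str, int, str, str]:
        """Hashable site key (chrom, pos, ref, alt)."""
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class PatientRecord:
    """Clinical annotation of one patient: protocol, regression grade, staging."""

    patient_id: str
    protocol: str  # SCRT, RAPIDO or fRCT
    dworak_trg: int  # tumor regression grade, 0-4
    downstaging: bool
    cT: int | None = None
    cN: int | None = None
    ypT: int | None = None
    ypN: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.dworak_trg <= 4:
            raise ValidationError(
                f"{self.patient_id}: Dworak TRG {self.dworak_trg} outside 0-4"
            )


@dataclass(frozen=True)
class PlasmaSample:
    """One timepoint-tagged plasma draw, sequenced as two duplicate libraries."""

    patient_id: str
    timepoint: str  # "t0" or "t1"
    cfdna_ng: float
    library_ids: tuple[str, str]

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValidationError(
                f"{self.patient_id}: timepoint {self.timepoint!r} not in {TIMEPOINTS}"
            )
        if not self.cfdna_ng > 0:
            raise ValidationError(
                f"{self.patient_id} {self.timepoint}: cfDNA mass must be positive, "
                f"got {self.cfdna_ng}"
            )
        if len(self.library_ids) != 2:
            raise ValidationError(
                f"{self.patient_id} {self.timepoint}: expected exactly 2 duplicate "
                f"libraries, got {len(self.library_ids)}"
            )


def _validate_counts_frame(df: pd.DataFrame, source: str) -> pd.DataFrame:
    missing = [c for c in COUNTS_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{source}: missing columns {missing}")
    df = df[COUNTS_COLUMNS].copy()
    if len(df) == 0:
        return df.astype(
            {"pos": int, "ref_reads": int, "alt_reads": int}, errors="ignore"
        )
    df["pos"] = df["pos"].astype(int)
    df["ref_reads"] = df["ref_reads"].astype(int)
    df["alt_reads"] = df["alt_reads"].astype(int)
    bad = df.index[df["pos"] < 1]
    if len(bad):
        raise ValidationError(f"{source}: pos < 1 at row {bad[0] + 2}")
    bad = df.index[(df["ref_reads"] < 0) | (df["alt_reads"] < 0)]
    if len(bad):
        raise ValidationError(f"{source}: negative read count at row {bad[0] + 2}")
    bad = df.index[df["ref"] == df["alt"]]
    if len(bad):
        raise ValidationError(f"{source}: ref == alt at row {bad[0] + 2}")
    return df


def read_counts_frame(path: str | Path) -> pd.DataFrame:
    """Read one library's count table into a validated DataFrame, order preserved."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    df = _validate_counts_frame(df, path.name)
    df.attrs["library_id"] = path.stem
    return df


def write_counts_frame(df: pd.DataFrame, path: str | Path) -> None:
    """Write a count table; inverse of :func:`read_counts_frame` on valid data."""
    _validate_counts_frame(df, str(path)).to_csv(path, sep="\t", index=False)


def read_site_counts(path: str | Path, library_id: str | None = None) -> list[SiteCounts]:
    """Read one library's count table as a list of :class:`SiteCounts`.

    The library id defaults to the file stem (``counts/<library_id>.tsv``).
    """
    path = Path(path)
    if library_id is None:
        library_id = path.stem
    df = read_counts_frame(path)
    return [
        SiteCounts(
            library_id=library_id,
            chrom=row.chrom,
            pos=int(row.pos),
            ref=row.ref,
            alt=row.alt,
            ref_reads=int(row.ref_reads),
            alt_reads=int(row.alt_reads),
            gene=row.gene,
            consequence=row.consequence,
        )
        for row in df.itertuples(index=False)
    ]


def read_manifest(path: str | Path) -> tuple[list[PlasmaSample], dict[str, str]]:
    """Read a sample manifest.

    Returns the plasma samples (one per patient and timepoint, each carrying
    its two duplicate library ids and cfDNA mass) and a mapping from patient
    id to the patient's single buffycoat library id.  Schema violations raise
    :class:`ValidationError` naming the offending patient or row.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing columns {missing}")
    if len(df) == 0:
        return [], {}

    dup = df["library_id"][df["library_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"{path.name}: duplicate library id {dup.iloc[0]!r}")
    bad_comp = df.index[~df["compartment"].isin(["plasma", "buffycoat"])]
    if len(bad_comp):
        raise ValidationError(
            f"{path.name}: unknown compartment at row {bad_comp[0] + 2}"
        )

    samples: list[PlasmaSample] = []
    buffycoat: dict[str, str] = {}
    for patient_id, sub in df.groupby("patient_id", sort=False):
        bc = sub[sub["compartment"] == "buffycoat"]
        if len(bc) != 1:
            raise ValidationError(
                f"{path.name}: patient {patient_id} has {len(bc)} buffycoat "
                f"libraries, expected exactly 1"
            )
        buffycoat[patient_id] = bc["library_id"].iloc[0]
        plasma = sub[sub["compartment"] == "plasma"]
        for tp in TIMEPOINTS:
            rows = plasma[plasma["timepoint"] == tp]
            if len(rows) != 2:
                raise ValidationError(
                    f"{path.name}: patient {patient_id} has {len(rows)} plasma "
                    f"libraries at {tp}, expected 2 duplicates"
                )
            masses = {float(m) for m in rows["cfdna_ng"]}
            if len(masses) != 1:
                raise ValidationError(
                    f"{path.name}: patient {patient_id} {tp}: duplicate rows "
                    f"disagree on cfdna_ng ({sorted(masses)})"
                )
            reps = rows.sort_values("replicate")
            samples.append(
                PlasmaSample(
                    patient_id=patient_id,
                    timepoint=tp,
                    cfdna_ng=masses.pop(),
                    library_ids=tuple(reps["library_id"]),
                )
            )
    return samples, buffycoat


def _parse_stage(value, label: str, row: int) -> int | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    if s == "":
        return None
    digits = "".join(ch for ch in s if ch.isdigit())
    if not digits:
        raise ValidationError(f"row {row}: unparsable {label} category {value!r}")
    return int(digits)


def read_clinical(path: str | Path) -> list[PatientRecord]:
    """Read the clinical table (protocol, Dworak TRG, downstaging, staging)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["patient_id", "protocol", "dworak_trg", "downstaging"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing columns {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        ds = str(row.downstaging).strip().lower()
        if ds not in {"yes", "no", "true", "false", "1", "0"}:
            raise ValidationError(
                f"{path.name} row {i + 2}: downstaging {row.downstaging!r} "
                f"not interpretable as yes/no"
            )
        records.append(
            PatientRecord(
                patient_id=row.patient_id,
                protocol=row.protocol,
                dworak_trg=int(row.dworak_trg),
                downstaging=ds in {"yes", "true", "1"},
                cT=_parse_stage(getattr(row, "cT", None), "cT", i + 2),
                cN=_parse_stage(getattr(row, "cN", None), "cN", i + 2),
                ypT=_parse_stage(getattr(row, "ypT", None), "ypT", i + 2),
                ypN=_parse_stage(getattr(row, "ypN", None), "ypN", i + 2),
            )
        )
    return records


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Natural chromosome order: chr1..chr22, chrX, chrY, chrM, then lexical."""
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if name.isdigit():
        return (int(name), "")
    special = {"X": 23, "Y": 24, "M": 25, "MT": 25}
    if name.upper() in special:
        return (special[name.upper()], "")
    return (100, name)


def write_validated_vcf(variants: Iterable, path: str | Path) -> None:
    """Write filter verdicts as a minimal VCF 4.2.

    One record per validated variant, sorted by chromosome then position,
    with INFO keys GENE, CSQ, VAF_T0, VAF_T1, Q95 and FILTER set to PASS or
    ``quantile_fail``.  ``variants`` are ``ValidatedVariant`` objects from
    :mod:`ctdnamon.artifact_filter`.
    """
    variants = list(variants)
    header = pysam.VariantHeader()
    for chrom in sorted({v.candidate.chrom for v in variants}, key=chrom_sort_key):
        header.contigs.add(chrom)
    header.info.add("GENE", 1, "String", "Gene symbol")
    header.info.add("CSQ", 1, "String", "Functional consequence class")
    header.info.add("VAF_T0", 1, "Float", "Pooled duplicate VAF before therapy")
    header.info.add("VAF_T1", 1, "Float", "Pooled duplicate VAF after therapy")
    header.info.add("Q95", 1, "Float", "Cohort buffycoat percentile VAF at this site")
    header.filters.add(
        "quantile_fail",
        None,
        None,
        "VAF not greater than multiplier x cohort buffycoat percentile VAF",
    )
    ordered = sorted(
        variants, key=lambda v: (chrom_sort_key(v.candidate.chrom), v.candidate.pos)
    )
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for v in ordered:
            c = v.candidate
            rec = vcf.new_record(
                contig=c.chrom,
                start=c.pos - 1,
                alleles=(c.ref, c.alt),
            )
            rec.info["GENE"] = c.gene or "."
            rec.info["CSQ"] = c.consequence or "."
            rec.info["VAF_T0"] = float(c.vaf_t0)
            rec.info["VAF_T1"] = float(c.vaf_t1)
            rec.info["Q95"] = float(v.q95)
            rec.filter.add("PASS" if v.passed else "quantile_fail")
            vcf.write(rec)
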