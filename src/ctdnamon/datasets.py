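"""Bundled study tables: published cfDNA masses and clinical annotations."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .variant_io import PatientRecord, PlasmaSample, read_clinical, read_manifest

__all__ = ["cfdna_manifest", "clinical_records", "fixture_path"]


def fixture_path(name: str) -> Path:
    """Path to a bundled data file."""
    return Path(resources.files("ctdnamon.data") / name)


def cfdna_manifest() -> tuple[list[PlasmaSample], dict[str, str]]:
    """The published per-patient cfDNA masses as a sample manifest.

    17 patients, two timepoints each, duplicate plasma libraries plus one
    buffycoat library per patient.  One patient's post-therapy mass is
    printed as 5.3 ng in the source table but 5.25 ng in the accompanying
    text; 5.25 is stored because it reproduces the published
    genome-equivalent counts.
    """
    return read_manifest(fixture_path("manifest_table3.tsv"))


def clinical_records() -> list[PatientRecord]:
    """Protocol, Dworak regression grade and downstaging per patient."""
    return read_clinical(fixture_path("clinical_table2.tsv"))
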