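"""cfDNA quantification: genome equivalents and the biological detection limit.

The amount of cell-free DNA recovered from a plasma draw bounds what any
assay can see: with ``m`` nanograms of cfDNA and an average diploid human
genome weighing 6.51 pg, the sample holds ``floor(1000*m / 6.51)`` diploid
genome copies, i.e. twice that many haploid copies.  A single tumor-derived
haploid genome among them is the smallest detectable signal, so the
biological limit of detection expressed as a variant allele frequency is
``100 / haploid_copies`` percent — independent of sequencing depth or
chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from statistics import median
from typing import Iterable, Mapping

from .variant_io import PlasmaSample, TIMEPOINTS

__all__ = [
    "GenomeConstants",
    "DetectionLimit",
    "UndefinedVAFError",
    "compute_vaf",
    "diploid_copies",
    "detection_limit",
    "summarize_masses",
]


@dataclass(frozen=True)
class GenomeConstants:
    """Physical constants for converting cfDNA mass to genome copies.

    6.51 pg is the average weight of one diploid female human genome.
    """

    diploid_genome_pg: float = 6.51

    def __post_init__(self) -> None:
        if not self.diploid_genome_pg > 0:
            raise ValueError("diploid_genome_pg must be positive")


DEFAULT_CONSTANTS = GenomeConstants()


@dataclass(frozen=True)
class DetectionLimit:
    """Biological limit of detection of one plasma sample.

    ``min_vaf_percent`` is the VAF of a single haploid tumor genome among
    all haploid genome copies in the sample, as a percentage rounded to two
    decimals.
    """

    diploid_copies: int
    haploid_copies: int
    min_vaf_percent: float


class UndefinedVAFError(ZeroDivisionError):
    """VAF is undefined at zero total depth; the caller must exclude the site."""


def compute_vaf(alt_reads: int, ref_reads: int) -> float:
    """Variant allele frequency ``alt / (alt + ref)`` as a fraction in [0, 1].

    Reads supporting neither the reference nor the variant allele are not
    part of the comparison and are ignored by construction.
    """
    depth = alt_reads + ref_reads
    if depth <= 0:
        raise UndefinedVAFError("VAF undefined at zero total depth")
    if alt_reads < 0 or ref_reads < 0:
        raise ValueError("read counts must be non-negative")
    return alt_reads / depth


def diploid_copies(mass_ng: float, constants: GenomeConstants = DEFAULT_CONSTANTS) -> int:
    """Number of whole diploid genome copies in ``mass_ng`` ng of cfDNA.

    Truncates (floor) rather than rounds: a fractional genome is not a
    detectable template.
    """
    if not mass_ng > 0:
        raise ValueError(f"cfDNA mass must be positive, got {mass_ng}")
    return int(mass_ng * 1000.0 / constants.diploid_genome_pg)


def _round_half_up(value: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def detection_limit(
    mass_ng: float, constants: GenomeConstants = DEFAULT_CONSTANTS
) -> DetectionLimit:
    """Biological limit of detection for a plasma sample of ``mass_ng`` ng."""
    dip = diploid_copies(mass_ng, constants)
    hap = 2 * dip
    return DetectionLimit(
        diploid_copies=dip,
        haploid_copies=hap,
        min_vaf_percent=_round_half_up(100.0 / hap, 2),
    )


def summarize_masses(
    samples: Iterable[PlasmaSample],
) -> dict[str, dict[str, float | int]]:
    """Per-timepoint min, max and median cfDNA mass.

    Returns, for each timepoint, the raw values in ng plus the
    nearest-integer-ng median (half-up), the form used in prose summaries.
    """
    by_tp: dict[str, list[float]] = {tp: [] for tp in TIMEPOINTS}
    for s in samples:
        by_tp[s.timepoint].append(s.cfdna_ng)
    out: dict[str, dict[str, float | int]] = {}
    for tp, masses in by_tp.items():
        if not masses:
            raise ValueError(f"no samples at timepoint {tp}")
        med = median(masses)
        out[tp] = {
            "n": len(masses),
            "min_ng": min(masses),
            "max_ng": max(masses),
            "median_ng": med,
            "median_ng_rounded": int(_round_half_up(med, 0)),
        }
    return out
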