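"""Synthetic cohort generator for ultradeep targeted cfDNA sequencing.

Emulates the data-generating process the downstream analysis assumes: a
cohort of rectal-cancer patients, each with duplicate plasma cfDNA
libraries before (t0) and after (t1) neoadjuvant radiotherapy plus one
buffycoat (leukocyte) library, sequenced over a targeted cancer-gene
panel.  Three biological variant classes are planted with truth labels:

* **tumor** — patient-private somatic mutations, expected VAF 0 in the
  buffycoat; t1 VAF scaled multiplicatively by the patient's response.
* **chip** — clonal-hematopoiesis variants at cohort-shared hotspot
  positions, with equal expected VAF in plasma and buffycoat.  Hotspots
  are shared because recurrent CHIP positions are what a cohort-wide
  buffycoat panel can recognise and remove.
* **germline** — heterozygous SNPs (VAF ~0.5 in every compartment) drawn
  per patient from a shared common-polymorphism pool.

Read counts are binomial: at each site the alternate-read count is drawn
with success probability equal to the compartment's expected VAF plus a
position-specific background error rate, at Poisson depth.  Error rates
are right-skewed across positions and constant across libraries at the
same position — the recurrent-artifact structure the quantile filter
targets.  Duplicate libraries are independent draws from the same
expectation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .variant_io import (
    CONSEQUENCE_CLASSES,
    COUNTS_COLUMNS,
    PatientRecord,
    PlasmaSample,
    read_clinical,
    read_counts_frame,
    read_manifest,
)

__all__ = [
    "PanelDesign",
    "SimConfig",
    "TrueVariant",
    "CohortTruth",
    "ConfigError",
    "generate_cohort",
    "generate_site_counts",
    "expected_vaf",
    "write_fixture",
    "read_truth",
]

PROTOCOLS = ("SCRT", "RAPIDO", "fRCT")

# Consequence mix of a colorectal-cancer mutation landscape
# (missense : frameshift : inframe indel : stop gained : essential splice).
CONSEQUENCE_WEIGHTS = (22, 13, 5, 2, 1)

_REAL_GENES = [
    "APC", "TP53", "KRAS", "FBXW7", "EP300", "TET2", "VHL", "PIK3CA",
    "SMAD4", "BRAF", "ATM", "NRAS", "CTNNB1", "PTEN", "ARID1A", "DNMT3A",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class PanelDesign:
    """The targeted capture panel being emulated.

    The real assay covers 127 TCGA cancer genes over 800 kb; the simulated
    site universe is a desk-scale stand-in of ``positions_per_gene``
    assayable positions per gene, each mapping to exactly one gene.
    """

    n_genes: int = 127
    target_size_bp: int = 800_000
    positions_per_gene: int = 2

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if self.target_size_bp < self.n_genes:
            raise ConfigError("target_size_bp must be >= n_genes")
        if self.positions_per_gene < 1:
            raise ConfigError("positions_per_gene must be >= 1")

    @property
    def n_sites(self) -> int:
        return self.n_genes * self.positions_per_gene


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic cohort.

    Defaults mirror the monitored study population: 17 patients split
    6 RAPIDO / 6 fRCT / 5 SCRT, ~9/17 Dworak responders, ~12/17 with
    detectable tumor variants whose t0 VAFs span 0.1-8.4%, duplicate
    10,000x libraries, and background error rates with mean 5e-4.
    ``response_effect`` is the multiplicative t1/t0 VAF factor for
    (responders, non-responders).
    """

    n_patients: int = 17
    protocol_mix: Mapping[str, float] = field(
        default_factory=lambda: {"RAPIDO": 6 / 17, "fRCT": 6 / 17, "SCRT": 5 / 17}
    )
    responder_fraction: float = 9 / 17
    ctdna_positive_fraction: float = 12 / 17
    tumor_variants_range: tuple[int, int] = (1, 4)
    vaf_range_t0: tuple[float, float] = (0.001, 0.084)
    response_effect: tuple[float, float] = (0.2, 1.5)
    vaf_jitter_sd: float = 0.5
    n_chip_variants_per_patient: int = 2
    chip_vaf_range: tuple[float, float] = (0.005, 0.03)
    germline_het_count: int = 3
    depth_mean: float = 10_000.0
    error_rate_mean: float = 5e-4
    error_rate_shape: float = 0.5
    error_rate_max: float = 5e-3
    mass_lognorm_mean_ng: float = 30.0
    mass_lognorm_sd: float = 0.8
    mass_range_ng: tuple[float, float] = (5.0, 370.0)
    seed: int = 0
    panel: PanelDesign = field(default_factory=PanelDesign)

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        for name in ("responder_fraction", "ctdna_positive_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if set(self.protocol_mix) - set(PROTOCOLS):
            raise ConfigError(f"unknown protocols {set(self.protocol_mix) - set(PROTOCOLS)}")
        if any(not 0 <= p <= 1 for p in self.protocol_mix.values()):
            raise ConfigError("protocol proportions must be in [0, 1]")
        if not math.isclose(sum(self.protocol_mix.values()), 1.0, abs_tol=1e-9):
            raise ConfigError("protocol_mix must sum to 1")
        for name in ("vaf_range_t0", "chip_vaf_range"):
            lo, hi = getattr(self, name)
            if not 0 <= lo <= hi <= 1:
                raise ConfigError(f"{name} must be an interval within [0, 1]")
        if self.depth_mean < 1:
            raise ConfigError("depth_mean must be >= 1")
        lo, hi = self.tumor_variants_range
        if not 1 <= lo <= hi:
            raise ConfigError("tumor_variants_range must be a positive interval")


@dataclass(frozen=True)
class TrueVariant:
    """A planted variant with its truth label."""

    patient_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    origin: str  # tumor | chip | germline
    vaf_t0: float
    vaf_t1: float

    @property
    def site(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class CohortTruth:
    """Everything the generator decided, before any sequencing noise."""

    config: SimConfig
    sites: pd.DataFrame  # chrom,pos,ref,alt,gene,consequence,error_rate
    patients: tuple[PatientRecord, ...]
    true_variants: tuple[TrueVariant, ...]
    samples: tuple[PlasmaSample, ...]  # 2 per patient (t0, t1)
    buffycoat_libraries: dict[str, str]  # patient -> library id

    def variants_of(self, patient_id: str) -> list[TrueVariant]:
        return [v for v in self.true_variants if v.patient_id == patient_id]


def _allocate_counts(mix: Mapping[str, float], n: int) -> dict[str, int]:
    """Largest-remainder proportional allocation, deterministic tie-break."""
    items = sorted(mix.items())
    floors = {k: int(math.floor(p * n)) for k, p in items}
    remainder = n - sum(floors.values())
    by_frac = sorted(items, key=lambda kv: (-(kv[1] * n - floors[kv[0]]), kv[0]))
    for k, _ in by_frac[:remainder]:
        floors[k] += 1
    return floors


_BASES = np.array(list("ACGT"))


def _site_alleles(rng: np.random.Generator, consequence: str) -> tuple[str, str]:
    ref_base = str(rng.choice(_BASES))
    if consequence in ("frameshift", "inframe_indel"):
        ins_len = 1 if consequence == "frameshift" else 3
        tail = "".join(rng.choice(_BASES, size=ins_len))
        if rng.random() < 0.5:  # insertion
            return ref_base, ref_base + tail
        return ref_base + tail, ref_base  # deletion
    alt = str(rng.choice(_BASES[_BASES != ref_base]))
    return ref_base, alt


def generate_cohort(config: SimConfig) -> CohortTruth:
    """Draw patient labels, the site universe and all true variants.

    Deterministic given ``config.seed``.  Protocols are allocated
    proportionally (largest remainder) and shuffled; responder and
    ctDNA-positive status are Bernoulli per patient; tumor t1 VAFs are the
    t0 VAFs scaled by the patient's response factor with per-variant
    lognormal jitter.
    """
    rng = np.random.default_rng(config.seed)
    panel = config.panel

    # --- site universe -------------------------------------------------
    genes = (_REAL_GENES + [f"GENE{i:03d}" for i in range(len(_REAL_GENES), panel.n_genes)])[
        : panel.n_genes
    ]
    spacing = max(panel.target_size_bp // max(panel.n_sites, 1), 1)
    csq_p = np.array(CONSEQUENCE_WEIGHTS, dtype=float)
    csq_p /= csq_p.sum()
    records = []
    for i in range(panel.n_sites):
        gene = genes[i // panel.positions_per_gene]
        chrom = f"chr{(i // panel.positions_per_gene) % 22 + 1}"
        pos = 1_000_000 + i * spacing  # unique even within one chromosome
        csq = str(rng.choice(CONSEQUENCE_CLASSES, p=csq_p))
        ref, alt = _site_alleles(rng, csq)
        records.append((chrom, pos, ref, alt, gene, csq))
    sites = pd.DataFrame(
        records, columns=["chrom", "pos", "ref", "alt", "gene", "consequence"]
    )
    err = rng.gamma(
        config.error_rate_shape,
        config.error_rate_mean / config.error_rate_shape,
        size=panel.n_sites,
    )
    sites["error_rate"] = np.minimum(err, config.error_rate_max)

    # --- reserved site groups ------------------------------------------
    n_chip = config.n_chip_variants_per_patient
    n_snp_pool = 3 * config.germline_het_count
    if n_chip + n_snp_pool >= panel.n_sites:
        raise ConfigError("site universe too small for CHIP hotspots and SNP pool")
    special = rng.choice(panel.n_sites, size=n_chip + n_snp_pool, replace=False)
    chip_sites = list(special[:n_chip])
    snp_pool = list(special[n_chip:])
    free_sites = [i for i in range(panel.n_sites) if i not in set(special)]
    rng.shuffle(free_sites)

    # --- patient labels -------------------------------------------------
    n = config.n_patients
    protocol_counts = _allocate_counts(config.protocol_mix, n)
    protocol_vec = [p for p, k in sorted(protocol_counts.items()) for _ in range(k)]
    protocol_vec = [str(p) for p in rng.permutation(protocol_vec)]
    responder = rng.random(n) < config.responder_fraction
    positive = rng.random(n) < config.ctdna_positive_fraction

    patients: list[PatientRecord] = []
    variants: list[TrueVariant] = []
    samples: list[PlasmaSample] = []
    buffycoat: dict[str, str] = {}
    free_cursor = 0

    def site_row(idx: int) -> pd.Series:
        return sites.iloc[idx]

    for i in range(n):
        pid = f"SIM{i + 1:03d}"
        trg = int(rng.choice([3, 4])) if responder[i] else 1
        cT = int(rng.choice([3, 4]))
        cN = int(rng.choice([1, 2]))
        if responder[i] or rng.random() < 0.5:
            ypT = int(rng.integers(0, cT))
            ypN = int(rng.integers(0, cN))
            ds = True
        else:
            ypT = cT
            ypN = int(rng.integers(0, cN + 1))
            ds = False
        patients.append(
            PatientRecord(
                patient_id=pid,
                protocol=protocol_vec[i],
                dworak_trg=trg,
                downstaging=ds,
                cT=cT,
                cN=cN,
                ypT=ypT,
                ypN=ypN,
            )
        )

        # tumor variants: private sites, loguniform t0 VAF, response-scaled t1
        if positive[i]:
            lo, hi = config.tumor_variants_range
            k = int(rng.integers(lo, hi + 1))
            if free_cursor + k > len(free_sites):
                raise ConfigError("site universe exhausted; enlarge the panel")
            factor = config.response_effect[0 if responder[i] else 1]
            for idx in free_sites[free_cursor : free_cursor + k]:
                row = site_row(idx)
                v_lo, v_hi = config.vaf_range_t0
                vaf0 = float(np.exp(rng.uniform(np.log(v_lo), np.log(v_hi))))
                jitter = float(np.exp(rng.normal(0.0, config.vaf_jitter_sd)))
                vaf1 = float(np.clip(vaf0 * factor * jitter, 0.0, 0.5))
                variants.append(
                    TrueVariant(
                        pid, row.chrom, int(row.pos), row.ref, row.alt,
                        row.gene, row.consequence, "tumor", vaf0, vaf1,
                    )
                )
            free_cursor += k

        # CHIP: every patient carries every hotspot at a patient-specific VAF
        for idx in chip_sites:
            row = site_row(idx)
            vaf = float(rng.uniform(*config.chip_vaf_range))
            variants.append(
                TrueVariant(
                    pid, row.chrom, int(row.pos), row.ref, row.alt,
                    row.gene, row.consequence, "chip", vaf, vaf,
                )
            )

        # germline heterozygous SNPs from the shared pool
        het = rng.choice(snp_pool, size=min(config.germline_het_count, len(snp_pool)),
                         replace=False)
        for idx in het:
            row = site_row(int(idx))
            variants.append(
                TrueVariant(
                    pid, row.chrom, int(row.pos), row.ref, row.alt,
                    row.gene, row.consequence, "germline", 0.5, 0.5,
                )
            )

        # library plan and plasma masses
        lo_m, hi_m = config.mass_range_ng
        for tp in ("t0", "t1"):
            mass = float(
                np.clip(
                    rng.lognormal(np.log(config.mass_lognorm_mean_ng), config.mass_lognorm_sd),
                    lo_m,
                    hi_m,
                )
            )
            samples.append(
                PlasmaSample(
                    patient_id=pid,
                    timepoint=tp,
                    cfdna_ng=round(mass, 1),
                    library_ids=(f"{pid}_{tp}_r1", f"{pid}_{tp}_r2"),
                )
            )
        buffycoat[pid] = f"{pid}_bc"

    return CohortTruth(
        config=config,
        sites=sites,
        patients=tuple(patients),
        true_variants=tuple(variants),
        samples=tuple(samples),
        buffycoat_libraries=buffycoat,
    )


def expected_vaf(
    truth: CohortTruth, patient_id: str, compartment: str, timepoint: str
) -> np.ndarray:
    """Expected VAF per panel site for one library, before background error.

    Tumor variants contribute nothing to the buffycoat; CHIP contributes
    equally to plasma and buffycoat; germline hets sit at 0.5 everywhere.
    """
    idx = {
        (r.chrom, int(r.pos), r.ref, r.alt): i
        for i, r in enumerate(truth.sites.itertuples(index=False))
    }
    out = np.zeros(len(truth.sites))
    for v in truth.variants_of(patient_id):
        if v.origin == "tumor":
            if compartment == "buffycoat":
                continue
            vaf = v.vaf_t0 if timepoint == "t0" else v.vaf_t1
        else:  # chip and germline are constant across compartments/timepoints
            vaf = v.vaf_t0
        out[idx[v.site]] += vaf
    return out


def generate_site_counts(
    truth: CohortTruth, config: SimConfig | None = None
) -> dict[str, pd.DataFrame]:
    """Draw read counts for every library of the cohort.

    Depth is Poisson around ``depth_mean``; alternate reads are binomial
    with success probability = expected compartment VAF + the site's
    background error rate.  Duplicate libraries are independent draws.
    Deterministic given the truth's seed.
    """
    config = config or truth.config
    rng = np.random.default_rng([config.seed, 104729])
    err = truth.sites["error_rate"].to_numpy()
    counts: dict[str, pd.DataFrame] = {}

    def draw(patient_id: str, compartment: str, timepoint: str, library_id: str) -> None:
        p = np.clip(expected_vaf(truth, patient_id, compartment, timepoint) + err, 0.0, 1.0)
        depth = rng.poisson(config.depth_mean, size=len(p))
        alt = rng.binomial(depth, p)
        df = truth.sites[["chrom", "pos", "ref", "alt", "gene", "consequence"]].copy()
        df["ref_reads"] = depth - alt
        df["alt_reads"] = alt
        df = df[COUNTS_COLUMNS]
        df.attrs["library_id"] = library_id
        counts[library_id] = df

    for s in truth.samples:
        for lib in s.library_ids:
            draw(s.patient_id, "plasma", s.timepoint, lib)
    for pid, lib in truth.buffycoat_libraries.items():
        draw(pid, "buffycoat", "t0", lib)
    return counts


def write_fixture(
    truth: CohortTruth, counts: Mapping[str, pd.DataFrame], directory: str | Path
) -> None:
    """Emit the cohort as the pipeline's external-interface files.

    ``manifest.tsv``, ``clinical.tsv``, ``cohort_truth.tsv`` and one
    ``counts/<library_id>.tsv`` per library.
    """
    directory = Path(directory)
    (directory / "counts").mkdir(parents=True, exist_ok=True)

    rows = []
    for s in truth.samples:
        for rep, lib in enumerate(s.library_ids, start=1):
            rows.append((s.patient_id, s.timepoint, lib, rep, "plasma", s.cfdna_ng))
    for pid, lib in truth.buffycoat_libraries.items():
        rows.append((pid, "t0", lib, 1, "buffycoat", ""))
    pd.DataFrame(
        rows,
        columns=["patient_id", "timepoint", "library_id", "replicate", "compartment", "cfdna_ng"],
    ).to_csv(directory / "manifest.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            (p.patient_id, p.protocol, p.dworak_trg,
             "yes" if p.downstaging else "no", p.cT, p.cN, p.ypT, p.ypN)
            for p in truth.patients
        ],
        columns=["patient_id", "protocol", "dworak_trg", "downstaging", "cT", "cN", "ypT", "ypN"],
    ).to_csv(directory / "clinical.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            (v.patient_id, v.chrom, v.pos, v.ref, v.alt, v.gene, v.consequence,
             v.origin, v.vaf_t0, v.vaf_t1)
            for v in truth.true_variants
        ],
        columns=["patient_id", "chrom", "pos", "ref", "alt", "gene", "consequence",
                 "origin", "vaf_t0", "vaf_t1"],
    ).to_csv(directory / "cohort_truth.tsv", sep="\t", index=False, float_format="%.17g")

    for lib, df in counts.items():
        df.to_csv(directory / "counts" / f"{lib}.tsv", sep="\t", index=False)


def read_truth(path: str | Path) -> list[TrueVariant]:
    """Read back a ``cohort_truth.tsv`` written by :func:`write_fixture`."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"chrom": str, "ref": str, "alt": str},
        float_precision="round_trip",
    )
    return [
        TrueVariant(
            r.patient_id, r.chrom, int(r.pos), r.ref, r.alt, r.gene,
            r.consequence, r.origin, float(r.vaf_t0), float(r.vaf_t1),
        )
        for r in df.itertuples(index=False)
    ]
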