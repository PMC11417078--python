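"""Per-patient ctDNA dynamics and their association with clinical response.

Each validated variant's pooled VAF trajectory between the pre-therapy (t0)
and post-radiation (t1) draw is classified as down, up or stable (within a
relative tolerance band).  A patient is then `decrease` if at least one
variant fell and none rose, `increase` in the mirror case, `mixed` when
both directions occur, and `ctdna_negative` without any validated variant.
Patients whose variants are all stable at nonzero VAF carry persistent
ctDNA — the non-clearing signal — and are grouped with `increase`, flagged
``stable_only``.

Clinical response is the Dworak tumor regression grade dichotomized at
TRG >= 3; downstaging is a post-therapy decrease in both T and N category.
The ctDNA-status-by-response association is tested with a two-tailed
Fisher's exact test computed by exact hypergeometric enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import Iterable, Mapping, Sequence

from .artifact_filter import ValidatedVariant
from .variant_io import PatientRecord

__all__ = [
    "VariantDelta",
    "ResponseCall",
    "ContingencyTable2x2",
    "responder_from_trg",
    "downstaging",
    "classify_variant_change",
    "classify_patient",
    "classify_cohort",
    "build_contingency",
    "fisher_exact_2x2",
]

RESPONSE_CLASSES = ("decrease", "increase", "mixed", "ctdna_negative")


@dataclass(frozen=True)
class VariantDelta:
    """One variant's VAF change between timepoints."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    vaf_t0: float
    vaf_t1: float
    direction: str  # down | up | stable


@dataclass(frozen=True)
class ResponseCall:
    """Per-patient ctDNA dynamic class with its per-variant evidence."""

    patient_id: str
    call_class: str  # decrease | increase | mixed | ctdna_negative
    deltas: tuple[VariantDelta, ...]
    stable_only: bool = False


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows: ctDNA-negative / ctDNA-positive; columns: responder / non-responder."""

    a: int  # negative, responder
    b: int  # negative, non-responder
    c: int  # positive, responder
    d: int  # positive, non-responder

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


def responder_from_trg(trg: int) -> bool:
    """Dworak responder dichotomy: TRG 3 or 4 is a responder."""
    if not 0 <= trg <= 4:
        raise ValueError(f"Dworak TRG must be in [0, 4], got {trg}")
    return trg >= 3


def downstaging(cT: int, cN: int, ypT: int, ypN: int) -> bool:
    """True iff both the T and the N category decreased after therapy."""
    for label, v in (("cT", cT), ("cN", cN), ("ypT", ypT), ("ypN", ypN)):
        if not isinstance(v, int) or v < 0:
            raise ValueError(f"{label} category {v!r} is not a valid stage code")
    return ypT < cT and ypN < cN


def classify_variant_change(
    vaf_t0: float, vaf_t1: float, stable_rel_tol: float = 0.10
) -> str:
    """Direction of one variant's VAF change: ``down``, ``up`` or ``stable``.

    Stable means the absolute change is within ``stable_rel_tol`` of the
    larger of the two VAFs (or both are zero) — a band for "nearly
    constant" trajectories that plain sign comparison would overcall.
    """
    if not (0 <= vaf_t0 <= 1 and 0 <= vaf_t1 <= 1):
        raise ValueError("VAFs must be in [0, 1]")
    larger = max(vaf_t0, vaf_t1)
    if larger == 0 or abs(vaf_t1 - vaf_t0) <= stable_rel_tol * larger:
        return "stable"
    return "down" if vaf_t1 < vaf_t0 else "up"


def classify_patient(
    patient_id: str,
    validated: Sequence[ValidatedVariant],
    stable_rel_tol: float = 0.10,
) -> ResponseCall:
    """Classify one patient's ctDNA dynamic from their validated variants.

    Only variants that passed the artifact filter count.  An all-stable
    patient keeps detectable ctDNA through therapy and is grouped with
    `increase`, marked ``stable_only``.
    """
    passed = [v for v in validated if v.passed]
    deltas = tuple(
        VariantDelta(
            chrom=v.candidate.chrom,
            pos=v.candidate.pos,
            ref=v.candidate.ref,
            alt=v.candidate.alt,
            gene=v.candidate.gene,
            vaf_t0=v.candidate.vaf_t0,
            vaf_t1=v.candidate.vaf_t1,
            direction=classify_variant_change(
                v.candidate.vaf_t0, v.candidate.vaf_t1, stable_rel_tol
            ),
        )
        for v in passed
    )
    if not deltas:
        return ResponseCall(patient_id, "ctdna_negative", deltas)
    downs = any(d.direction == "down" for d in deltas)
    ups = any(d.direction == "up" for d in deltas)
    if downs and ups:
        return ResponseCall(patient_id, "mixed", deltas)
    if downs:
        return ResponseCall(patient_id, "decrease", deltas)
    if ups:
        return ResponseCall(patient_id, "increase", deltas)
    return ResponseCall(patient_id, "increase", deltas, stable_only=True)


def classify_cohort(
    validated: Iterable[ValidatedVariant],
    patient_ids: Iterable[str],
    stable_rel_tol: float = 0.10,
) -> list[ResponseCall]:
    """One :class:`ResponseCall` per patient; patients without validated
    variants come out ``ctdna_negative``."""
    by_patient: dict[str, list[ValidatedVariant]] = {pid: [] for pid in patient_ids}
    for v in validated:
        by_patient.setdefault(v.patient_id, []).append(v)
    return [
        classify_patient(pid, vs, stable_rel_tol) for pid, vs in by_patient.items()
    ]


def build_contingency(
    calls: Sequence[ResponseCall], records: Sequence[PatientRecord]
) -> ContingencyTable2x2:
    """Cross-tabulate ctDNA status against Dworak responder status."""
    if not calls:
        raise ValueError("empty cohort: no response calls")
    responder = {r.patient_id: responder_from_trg(r.dworak_trg) for r in records}
    a = b = c = d = 0
    for call in calls:
        if call.patient_id not in responder:
            raise ValueError(f"no clinical record for patient {call.patient_id}")
        negative = call.call_class == "ctdna_negative"
        if responder[call.patient_id]:
            a, c = (a + 1, c) if negative else (a, c + 1)
        else:
            b, d = (b + 1, d) if negative else (b, d + 1)
    return ContingencyTable2x2(a, b, c, d)


def fisher_exact_2x2(table: ContingencyTable2x2 | Sequence[Sequence[int]]) -> float:
    """Two-tailed Fisher's exact test by exact hypergeometric enumeration.

    Sums, over all tables with the observed margins, the probabilities of
    those no more probable than the observed table (the probability-mass
    rule).  All arithmetic is on exact integers/rationals, so ties at the
    observed probability are decided exactly rather than to floating-point
    tolerance.
    """
    if isinstance(table, ContingencyTable2x2):
        a, b, c, d = table.cells
    else:
        (a, b), (c, d) = table
        if min(a, b, c, d) < 0:
            raise ValueError("contingency cells must be non-negative")
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("degenerate margins: every row and column must be positive")
    n = r1 + r2
    lo, hi = max(0, r1 - c2), min(r1, c1)
    # P(x) = C(c1,x) C(c2,r1-x) / C(n,r1); common denominator -> compare numerators
    observed = comb(c1, a) * comb(c2, r1 - a)
    numerator = sum(
        w for x in range(lo, hi + 1) if (w := comb(c1, x) * comb(c2, r1 - x)) <= observed
    )
    return float(Fraction(numerator, comb(n, r1)))
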