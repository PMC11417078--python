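"""VAF-dynamics classification and the Fisher exact association test."""

from collections import Counter
from math import comb

import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from ctdnamon.artifact_filter import ValidatedVariant
from ctdnamon.response import (
    ContingencyTable2x2,
    build_contingency,
    classify_cohort,
    classify_patient,
    classify_variant_change,
    downstaging,
    fisher_exact_2x2,
    responder_from_trg,
)
from ctdnamon.variant_io import PatientRecord
from conftest import make_candidate


def validated(vaf_t0, vaf_t1, patient_id="P1", passed=True, pos=100):
    c = make_candidate(vaf_t0, vaf_t1, patient_id=patient_id, pos=pos)
    return ValidatedVariant(
        candidate=c,
        q95=0.0,
        threshold=0.0,
        evaluated_vaf=max(vaf_t0, vaf_t1),
        passed=passed,
        passed_t0=passed,
        passed_t1=passed,
    )


class TestResponderRule:
    @pytest.mark.parametrize("trg,expected", [(4, True), (3, True), (2, False), (1, False), (0, False)])
    def test_dichotomy(self, trg, expected):
        assert responder_from_trg(trg) is expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            responder_from_trg(5)


class TestDownstaging:
    @pytest.mark.parametrize(
        "cT,cN,ypT,ypN,expected",
        [(4, 2, 3, 1, True), (3, 1, 3, 0, False), (4, 1, 2, 1, False)],
    )
    def test_both_categories_must_decrease(self, cT, cN, ypT, ypN, expected):
        assert downstaging(cT, cN, ypT, ypN) is expected

    def test_unparsable_category(self):
        with pytest.raises(ValueError):
            downstaging("T3", 1, 2, 0)


class TestVariantChange:
    @pytest.mark.parametrize(
        "t0,t1,expected",
        [
            (0.004, 0.000, "down"),
            (0.084, 0.158, "up"),
            (0.010, 0.0101, "stable"),
            (0.0, 0.0, "stable"),
        ],
    )
    def test_direction(self, t0, t1, expected):
        assert classify_variant_change(t0, t1, stable_rel_tol=0.10) == expected


class TestClassifyPatient:
    def test_all_down_is_decrease(self):
        call = classify_patient("P1", [validated(0.05, 0.01), validated(0.02, 0.0, pos=200)])
        assert call.call_class == "decrease" and not call.stable_only

    def test_down_and_up_is_mixed(self):
        call = classify_patient("P1", [validated(0.05, 0.01), validated(0.01, 0.05, pos=200)])
        assert call.call_class == "mixed"

    def test_no_validated_variants_is_negative(self):
        assert classify_patient("P1", []).call_class == "ctdna_negative"
        assert classify_patient("P1", [validated(0.05, 0.0, passed=False)]).call_class == "ctdna_negative"

    def test_all_stable_is_persistent_ctdna(self):
        """Stable nonzero VAF through therapy groups with `increase`."""
        call = classify_patient("P1", [validated(0.02, 0.0205)])
        assert call.call_class == "increase" and call.stable_only

    def test_class_counts_partition_cohort(self, pipeline_result, sim_truth):
        counts = Counter(c.call_class for c in pipeline_result.calls)
        assert sum(counts.values()) == len(sim_truth.patients)


class TestContingency:
    def _records(self, n_resp, n_nonresp):
        recs = [
            PatientRecord(f"R{i}", "SCRT", 4, True) for i in range(n_resp)
        ] + [
            PatientRecord(f"N{i}", "SCRT", 1, False) for i in range(n_nonresp)
        ]
        return recs

    def _calls(self, records, negatives):
        out = []
        for r in records:
            if r.patient_id in negatives:
                out.append(classify_patient(r.patient_id, []))
            else:
                out.append(classify_patient(r.patient_id, [validated(0.05, 0.01, patient_id=r.patient_id)]))
        return out

    def test_published_cohort_structure(self):
        """9 responders / 8 non-responders with 3 vs 2 ctDNA-negative gives
        the [[3,2],[6,6]] table."""
        records = self._records(9, 8)
        calls = self._calls(records, negatives={"R0", "R1", "R2", "N0", "N1"})
        table = build_contingency(calls, records)
        assert table.cells == (3, 2, 6, 6)

    def test_all_negative_cohort(self):
        records = self._records(2, 2)
        calls = self._calls(records, negatives={r.patient_id for r in records})
        assert build_contingency(calls, records).cells == (2, 2, 0, 0)

    def test_empty_cohort_is_an_error(self):
        with pytest.raises(ValueError):
            build_contingency([], [])


def enumeration_oracle(a, b, c, d):
    """Independent full enumeration: sum float hypergeometric probabilities of
    all tables whose (integer) support count is no larger than observed."""
    r1, c1, c2 = a + b, a + c, b + d
    n = a + b + c + d
    observed = comb(c1, a) * comb(c2, r1 - a)
    total = comb(n, r1)
    p = 0.0
    for x in range(max(0, r1 - c2), min(r1, c1) + 1):
        w = comb(c1, x) * comb(c2, r1 - x)
        if w <= observed:
            p += w / total
    return p


class TestFisherExact:
    @pytest.mark.parametrize(
        "table,expected",
        [
            (((3, 2), (6, 6)), 1.0),
            (((10, 0), (0, 10)), 2 / comb(20, 10)),
            (((1, 1), (1, 1)), 1.0),
        ],
    )
    def test_reference_tables(self, table, expected):
        assert fisher_exact_2x2(table) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_margins_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(((0, 0), (3, 4)))

    def test_against_scipy(self):
        for table in [((3, 2), (6, 6)), ((12, 3), (5, 9)), ((1, 7), (4, 2))]:
            _, p_scipy = scipy.stats.fisher_exact(table, alternative="two-sided")
            assert fisher_exact_2x2(table) == pytest.approx(p_scipy, rel=1e-9)

    @given(
        st.integers(min_value=0, max_value=50),
        st.integers(min_value=0, max_value=50),
        st.integers(min_value=0, max_value=50),
        st.integers(min_value=0, max_value=50),
    )
    @settings(derandomize=True, max_examples=500)
    def test_matches_enumeration_oracle(self, a, b, c, d):
        if min(a + b, c + d, a + c, b + d) == 0:
            return
        p = fisher_exact_2x2(((a, b), (c, d)))
        assert abs(p - enumeration_oracle(a, b, c, d)) <= 1e-12
        assert 0 <= p <= 1

    @given(
        st.integers(min_value=1, max_value=30),
        st.integers(min_value=1, max_value=30),
        st.integers(min_value=1, max_value=30),
        st.integers(min_value=1, max_value=30),
    )
    @settings(derandomize=True, max_examples=200)
    def test_symmetries(self, a, b, c, d):
        """Two-tailed p is invariant under row swap, column swap, transpose."""
        p = fisher_exact_2x2(((a, b), (c, d)))
        assert fisher_exact_2x2(((c, d), (a, b))) == pytest.approx(p, abs=1e-15)
        assert fisher_exact_2x2(((b, a), (d, c))) == pytest.approx(p, abs=1e-15)
        assert fisher_exact_2x2(((a, c), (b, d))) == pytest.approx(p, abs=1e-15)
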