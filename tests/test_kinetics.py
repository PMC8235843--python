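"""VAF_mean, its change, direction classification and emergent detection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ctdna_kinetics import PatientRecord, VariantCall
from ctdna_kinetics.kinetics import (
    compute_change_and_direction,
    compute_vaf_mean,
    detect_emergent,
    eligible_variants,
    marker_direction,
)
from ctdna_kinetics.variants import MutationType, ValidationError


def patient_from_vafs(baseline, week4, patient_id="P1"):
    """Build a two-panel patient from gene -> VAF dicts (0 = reported absent)."""

    def calls(timepoint, mapping):
        return [
            VariantCall(
                patient_id=patient_id, timepoint=timepoint, gene=gene,
                variant_class="SNV", hgvs_p="M1V", vaf=vaf,
            )
            for gene, vaf in mapping.items()
        ]

    return PatientRecord(
        patient_id=patient_id,
        baseline_calls=calls("baseline", baseline),
        week4_calls=calls("week4", week4),
    )


class TestEligibleVariants:
    def test_union_with_zero_substitution_and_double_zero_exclusion(
        self, worked_example
    ):
        table = eligible_variants(worked_example)
        assert sorted(table["gene"]) == ["GENEA", "GENEB", "GENEC"]
        row_c = table[table["gene"] == "GENEC"].iloc[0]
        assert (row_c["vaf_baseline"], row_c["vaf_week4"]) == (0.0, 2.0)

    def test_cnv_only_patient_has_empty_table(self):
        patient = PatientRecord(
            patient_id="P1",
            baseline_calls=[
                VariantCall(patient_id="P1", timepoint="baseline", gene="MYC",
                            variant_class="CNV", copy_number=5.0)
            ],
        )
        assert eligible_variants(patient).empty

    def test_all_zero_panels_empty(self):
        patient = patient_from_vafs({"A": 0.0}, {"A": 0.0})
        assert eligible_variants(patient).empty

    def test_germline_band_drops_the_whole_pair(self):
        patient = patient_from_vafs({"A": 2.0, "APC": 50.2},
                                    {"A": 1.0, "APC": 50.4})
        table = eligible_variants(patient)
        assert list(table["gene"]) == ["A"]
        kept = eligible_variants(patient, drop_germline=False)
        assert sorted(kept["gene"]) == ["A", "APC"]

    def test_germline_at_one_timepoint_still_drops_pair(self):
        # allele balance of a germline variant does not move with treatment,
        # so a single in-band observation marks the variant itself
        patient = patient_from_vafs({"A": 2.0, "B": 44.0}, {"A": 1.0, "B": 61.0})
        assert list(eligible_variants(patient)["gene"]) == ["A"]

    def test_gene_aggregation_takes_max_per_gene(self):
        patient = PatientRecord(
            patient_id="P1",
            baseline_calls=[
                VariantCall(patient_id="P1", timepoint="baseline", gene="TP53",
                            variant_class="SNV", hgvs_p="R175H", vaf=2.0),
                VariantCall(patient_id="P1", timepoint="baseline", gene="TP53",
                            variant_class="SNV", hgvs_p="L130F", vaf=7.5),
            ],
        )
        table = eligible_variants(patient, aggregation="gene")
        assert len(table) == 1
        assert table.iloc[0]["vaf_baseline"] == 7.5


class TestComputeVafMean:
    def test_worked_example_values(self, worked_example):
        table = eligible_variants(worked_example)
        assert compute_vaf_mean(table, "baseline") == 5.0
        assert compute_vaf_mean(table, "week4") == 6.0

    def test_empty_table_is_undefined(self):
        table = eligible_variants(patient_from_vafs({}, {}))
        assert compute_vaf_mean(table, "baseline") is None

    @given(st.floats(min_value=0, max_value=100), st.integers(2, 8))
    def test_constant_vafs_give_that_constant(self, vaf, n):
        if vaf == 0:
            return
        patient = patient_from_vafs({f"G{i}": vaf for i in range(n)}, {})
        table = eligible_variants(patient, drop_germline=False)
        assert compute_vaf_mean(table, "baseline") == pytest.approx(vaf)

    @given(
        st.lists(st.floats(min_value=0.01, max_value=100), min_size=1, max_size=20)
    )
    def test_matches_sum_count_oracle(self, vafs):
        patient = patient_from_vafs(
            {f"G{i}": v for i, v in enumerate(vafs)}, {}
        )
        table = eligible_variants(patient, drop_germline=False)
        assert compute_vaf_mean(table, "baseline") == pytest.approx(
            sum(vafs) / len(vafs), rel=1e-12
        )


class TestChangeAndDirection:
    def test_worked_example_change_plus_one_increase(self, worked_example):
        summary = compute_change_and_direction(worked_example)
        assert summary.vaf_mean_change == pytest.approx(1.0)
        assert summary.direction == "increase"
        assert summary.n_variants_used == 3

    def test_identical_panels_tie_goes_to_increase(self):
        patient = patient_from_vafs({"A": 3.0}, {"A": 3.0})
        summary = compute_change_and_direction(patient)
        assert summary.vaf_mean_change == 0.0
        assert summary.direction == "increase"

    def test_no_ctdna_at_either_timepoint_is_excluded(self):
        summary = compute_change_and_direction(patient_from_vafs({}, {}))
        assert summary.direction == "excluded"
        assert summary.vaf_mean_baseline is None
        assert summary.vaf_mean_change is None
        assert summary.n_variants_used == 0

    def test_per_type_changes_can_oppose_each_other(self):
        patient = PatientRecord(
            patient_id="P1",
            baseline_calls=[
                VariantCall(patient_id="P1", timepoint="baseline", gene="TP53",
                            variant_class="SNV", hgvs_c="c.97-1G>A", vaf=1.0),
                VariantCall(patient_id="P1", timepoint="baseline", gene="CTNNB1",
                            variant_class="SNV", hgvs_p="S45P", vaf=3.0),
            ],
            week4_calls=[
                VariantCall(patient_id="P1", timepoint="week4", gene="TP53",
                            variant_class="SNV", hgvs_c="c.97-1G>A", vaf=1.8),
                VariantCall(patient_id="P1", timepoint="week4", gene="CTNNB1",
                            variant_class="SNV", hgvs_p="S45P", vaf=1.0),
            ],
        )
        summary = compute_change_and_direction(patient)
        assert summary.per_type_change[MutationType.SPLICE_SITE] > 0
        assert summary.per_type_change[MutationType.MISSENSE] < 0
        assert summary.direction == "decrease"  # overall still falls

    @given(
        st.dictionaries(
            st.sampled_from([f"G{i}" for i in range(8)]),
            st.tuples(
                st.floats(min_value=0, max_value=50),
                st.floats(min_value=0, max_value=50),
            ),
            min_size=1,
            max_size=8,
        )
    )
    def test_double_zero_variant_never_changes_summary(self, vafs):
        baseline = {g: b for g, (b, _) in vafs.items()}
        week4 = {g: w for g, (_, w) in vafs.items()}
        patient = patient_from_vafs(baseline, week4)
        with_zero = patient_from_vafs(
            {**baseline, "ZERO": 0.0}, {**week4, "ZERO": 0.0}
        )
        a = compute_change_and_direction(patient)
        b = compute_change_and_direction(with_zero)
        assert (a.vaf_mean_baseline, a.vaf_mean_week4, a.direction,
                a.n_variants_used) == (
            b.vaf_mean_baseline, b.vaf_mean_week4, b.direction,
            b.n_variants_used,
        )

    @given(
        st.dictionaries(
            st.sampled_from([f"G{i}" for i in range(6)]),
            st.tuples(
                st.floats(min_value=0.01, max_value=30),
                st.floats(min_value=0.01, max_value=30),
            ),
            min_size=1,
            max_size=6,
        ),
        st.floats(min_value=0.1, max_value=3.0),
    )
    def test_change_is_homogeneous_in_vaf_scale(self, vafs, scale):
        patient = patient_from_vafs(
            {g: b for g, (b, _) in vafs.items()},
            {g: w for g, (_, w) in vafs.items()},
        )
        scaled = patient_from_vafs(
            {g: min(b * scale, 100.0) for g, (b, _) in vafs.items()},
            {g: min(w * scale, 100.0) for g, (_, w) in vafs.items()},
        )
        if any(b * scale > 100 or w * scale > 100 for b, w in vafs.values()):
            return  # clipping breaks exact homogeneity by construction
        a = compute_change_and_direction(patient, drop_germline=False)
        b = compute_change_and_direction(scaled, drop_germline=False)
        assert b.vaf_mean_change == pytest.approx(
            scale * a.vaf_mean_change, rel=1e-9, abs=1e-12
        )

    def test_per_type_sets_partition_the_eligible_set(self, fixture_cohort):
        for patient in fixture_cohort:
            table = eligible_variants(patient)
            if table.empty:
                continue
            summary = compute_change_and_direction(patient)
            total = sum(
                1
                for _, row in table.iterrows()
            )
            typed = 0
            from ctdna_kinetics.variants import classify_mutation_type

            counts = {}
            for _, row in table.iterrows():
                label = classify_mutation_type(row["hgvs_p"], row["hgvs_c"])
                counts[label] = counts.get(label, 0) + 1
            typed = sum(counts.values())
            assert typed == total == summary.n_variants_used
            # every non-empty type has a defined change; empty types undefined
            for mutation_type in MutationType:
                defined = summary.per_type_change[mutation_type] is not None
                assert defined == (mutation_type in counts)


class TestDetectEmergent:
    def test_novel_and_increased_statuses(self):
        patient = patient_from_vafs(
            {"DDR2": 0.0, "ATM": 0.10, "TP53": 2.0},
            {"DDR2": 0.60, "ATM": 0.19, "TP53": 1.0},
        )
        emergent = detect_emergent(patient)
        by_gene = {e.gene: e.status for e in emergent}
        assert by_gene == {"DDR2": "novelly_detected", "ATM": "increased"}

    def test_sorted_by_descending_week4_vaf(self):
        patient = patient_from_vafs(
            {"A": 0.0, "B": 0.0, "C": 0.0}, {"A": 0.2, "B": 0.9, "C": 0.5}
        )
        assert [e.gene for e in detect_emergent(patient)] == ["B", "C", "A"]

    def test_unchanged_vafs_give_empty_list(self):
        patient = patient_from_vafs({"A": 1.0}, {"A": 1.0})
        assert detect_emergent(patient) == []

    def test_min_increase_threshold_filters_small_rises(self):
        patient = patient_from_vafs({"A": 1.0}, {"A": 1.05})
        assert detect_emergent(patient, min_increase=0.1) == []
        assert len(detect_emergent(patient, min_increase=0.0)) == 1

    def test_invariants_of_statuses(self):
        patient = patient_from_vafs(
            {"A": 0.0, "B": 0.5}, {"A": 0.3, "B": 0.8}
        )
        for e in detect_emergent(patient):
            if e.status == "novelly_detected":
                assert e.vaf_baseline == 0.0 and e.vaf_week4 > 0
            else:
                assert 0 < e.vaf_baseline < e.vaf_week4


class TestMarkerDirection:
    @pytest.mark.parametrize(
        "baseline, week4, expected",
        [
            (221.0, 168.0, "decrease"),
            (3834.0, 1273.0, "decrease"),
            (10.0, 10.0, "increase"),  # tie mirrors the VAF convention
            (5.0, 9.0, "increase"),
        ],
    )
    def test_direction(self, baseline, week4, expected):
        assert marker_direction(baseline, week4) == expected

    def test_negative_input_rejected(self):
        with pytest.raises(ValidationError):
            marker_direction(-1.0, 5.0)
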