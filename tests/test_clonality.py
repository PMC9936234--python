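"""Clone assignment, richness, and entropy: examples, oracle, invariants."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from repclon import (
    CohortTable,
    SampleMetadata,
    assign_clones,
    compute_entropy,
    compute_expression,
    metrics_table,
    pairwise_identity,
)
from repclon.io_clonotypes import CELL_TYPES_22

from conftest import brute_force_clones, make_records, partition_sets, random_instance


class TestPairwiseIdentity:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACGTACGTAC", "ACGTACGTAC", 1.0),
            ("ACGTACGTAC", "ACGTACGTAG", 0.9),
            ("AAAA", "TTTT", 0.0),
        ],
    )
    def test_examples(self, a, b, expected):
        assert pairwise_identity(a, b) == pytest.approx(expected)

    def test_unequal_lengths_are_an_error(self):
        with pytest.raises(ValueError, match="equal lengths"):
            pairwise_identity("ACGT", "ACGTA")


# Length-10 CDR3s with identity(A,B) = identity(B,C) = 0.9 but
# identity(A,C) = 0.8: B differs from A at position 0, C from B at position 1.
_A = "ACGTACGTAC"
_B = "TCGTACGTAC"
_C = "TAGTACGTAC"


class TestAssignClones:
    def test_single_linkage_transitivity_at_bcr_threshold(self):
        recs = make_records([("V1", "J1", s, 1) for s in (_A, _B, _C)])
        a = assign_clones(recs, identity_threshold=0.90)
        assert a.n_clones == 1
        assert list(a.clone_read_counts) == [3]

    def test_tcr_threshold_splits_into_singletons(self):
        recs = make_records([("V1", "J1", s, 1) for s in (_A, _B, _C)], chain="TRB")
        a = assign_clones(recs, identity_threshold=0.95)
        assert a.n_clones == 3

    def test_different_j_gene_separates_identical_cdr3s(self):
        recs = make_records([("V1", "J1", _A, 2), ("V1", "J2", _A, 3)])
        a = assign_clones(recs)
        assert a.n_clones == 2
        assert sorted(a.clone_read_counts) == [2, 3]

    def test_empty_input_gives_empty_assignment(self):
        a = assign_clones(make_records([]))
        assert a.n_clones == 0

    def test_clone_ids_deterministic_by_first_member(self):
        recs = make_records(
            [("V2", "J1", "AAAATTTTCCCC", 1), ("V1", "J1", _A, 1), ("V2", "J1", "AAAATTTTCCCC", 4)]
        )
        a = assign_clones(recs)
        assert list(a.clone_ids) == [0, 1, 0]

    def test_agrees_with_brute_force_oracle(self, rng):
        for _ in range(40):
            n = int(rng.integers(1, 120))
            recs = random_instance(rng, n)
            for thr in (0.90, 0.95):
                got = partition_sets(assign_clones(recs, thr).clone_ids)
                assert got == brute_force_clones(recs, thr)

    def test_members_partition_the_records(self, rng):
        recs = random_instance(rng, 80)
        a = assign_clones(recs)
        members = a.members()
        flat = sorted(i for clone in members for i in clone)
        assert flat == list(range(len(recs)))


class TestExpression:
    @pytest.mark.parametrize(
        "m,total,expected",
        [(100, 1000, 0.1), (0, 10**6, 0.0), (41954, 10**8, 4.1954e-4)],
    )
    def test_arithmetic(self, m, total, expected):
        assert compute_expression(m, total) == pytest.approx(expected)

    def test_receptor_reads_exceeding_total_is_error(self):
        with pytest.raises(ValueError, match="exceed"):
            compute_expression(11, 10)

    @given(st.integers(0, 999))
    @settings(deadline=None)
    def test_monotone_in_receptor_reads(self, m):
        assert compute_expression(m, 1000) <= compute_expression(m + 1, 1000)


class TestEntropy:
    @pytest.mark.parametrize(
        "counts,expected",
        [([50], 0.0), ([25, 25, 25, 25], 2.0), ([2, 1, 1], 1.5)],
    )
    def test_examples(self, counts, expected):
        assert compute_entropy(counts) == pytest.approx(expected)

    def test_empty_is_undefined_not_zero(self):
        assert math.isnan(compute_entropy([]))

    @given(st.lists(st.integers(1, 500), min_size=1, max_size=30),
           st.integers(2, 9))
    @settings(deadline=None, max_examples=60)
    def test_permutation_and_scale_invariance(self, counts, scale):
        h = compute_entropy(counts)
        assert compute_entropy(counts[::-1]) == pytest.approx(h, abs=1e-12)
        assert compute_entropy([c * scale for c in counts]) == pytest.approx(h, abs=1e-9)

    @given(st.lists(st.integers(1, 500), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=60)
    def test_bounded_by_log2_n_clones(self, counts):
        assert -1e-12 <= compute_entropy(counts) <= math.log2(len(counts)) + 1e-12

    def test_splitting_a_clone_into_equal_halves_increases_entropy(self):
        base = [8, 4, 2]
        split = [4, 4, 4, 2]  # first clone split into equal halves
        assert compute_entropy(split) > compute_entropy(base)

    def test_merging_two_clones_decreases_entropy(self):
        assert compute_entropy([6, 2]) < compute_entropy([4, 2, 2])


def _meta(sample_id="S1", total_reads=1000):
    return SampleMetadata(
        sample_id=sample_id, subtype="LumP", total_reads=total_reads,
        age_years=60.0, sex="Male", region="Europe", stage="III",
        histology="Papillary", os_time=100.0, os_event=0, nsmr=1.0, smr=1.0,
        cell_fractions={c: 0.01 for c in CELL_TYPES_22},
    )


class TestMetricsTable:
    def test_records_in_one_chain_give_five_rows(self):
        recs = make_records([("V1", "J1", _A, 4)], chain="IGH")
        cohort = CohortTable(records=recs, metadata={"S1": _meta()})
        tbl = metrics_table(cohort)
        assert len(tbl) == 5
        assert (tbl["expression"] == 0).sum() == 4
        # undefined entropy for empty chains, not zero
        assert tbl.loc[tbl["chain"] != "IGH", "entropy"].isna().all()
        igh = tbl[tbl["chain"] == "IGH"].iloc[0]
        assert igh.expression == pytest.approx(4 / 1000)
        assert igh.entropy == pytest.approx(0.0)

    def test_two_samples_give_ten_rows(self):
        recs = pd.concat(
            [
                make_records([("V1", "J1", _A, 1)], sample_id="S1"),
                make_records([("V1", "J1", _A, 1)], sample_id="S2"),
            ],
            ignore_index=True,
        )
        cohort = CohortTable(records=recs, metadata={"S1": _meta("S1"), "S2": _meta("S2")})
        assert len(metrics_table(cohort)) == 10

    def test_composed_clustering_and_entropy(self):
        # three records collapse to one clone at 0.90; counts [2,1,1] over
        # two clones after a J-gene split -> 1.5 bits
        recs = make_records(
            [("V1", "J1", _A, 1), ("V1", "J1", _B, 1), ("V1", "J2", _A, 2)]
        )
        cohort = CohortTable(records=recs, metadata={"S1": _meta()})
        igh = metrics_table(cohort).query("chain == 'IGH'").iloc[0]
        assert igh.n_clones == 2
        assert igh.entropy == pytest.approx(1.0)  # counts [2, 2]
        recs2 = make_records(
            [("V1", "J1", _A, 2), ("V1", "J2", _A, 1), ("V2", "J1", _A, 1)]
        )
        cohort2 = CohortTable(records=recs2, metadata={"S1": _meta()})
        igh2 = metrics_table(cohort2).query("chain == 'IGH'").iloc[0]
        assert igh2.entropy == pytest.approx(1.5)
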