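from __future__ import annotations

import numpy as np
import pytest

from orthokmeans import (
    CoverageError,
    EmptyInputError,
    PairSet,
    UnknownIdError,
    adjusted_mutual_information,
    contingency,
    exact_match_percentage,
    f1_from_rates,
    family_completeness,
    group_scores,
    one_to_one_scores,
    pair_scores,
    reference_nm_pairs,
    reference_one_to_one_groups,
    round_sig,
)

from conftest import make_registry, random_partition_pair
from oracles import ami_direct, family_completeness_loop


def pairset(pairs):
    ps = PairSet()
    for a, b in pairs:
        ps.add(a, b, "x", "test")
    return ps


class TestReferencePairs:
    def test_single_species_group_yields_no_pairs(self):
        reg = make_registry([("a1", "A", "G1"), ("a2", "A", "G1"), ("b1", "B", "G2"),
                             ("b2", "B", "G2")])
        assert len(reference_nm_pairs(reg)) == 0

    def test_cross_species_pairs_within_group(self):
        reg = make_registry([("a1", "A", "G1"), ("a2", "A", "G1"), ("b1", "B", "G1")])
        ps = reference_nm_pairs(reg)
        assert ps.pairs == {("a1", "b1"), ("a2", "b1")}

    def test_one_to_one_groups_excluded_by_default(self):
        # groups over 2 species with per-species sizes (1+1), (2+1), (0+3)
        reg = make_registry(
            [("a1", "A", "G1"), ("b1", "B", "G1"),
             ("a2", "A", "G2"), ("a3", "A", "G2"), ("b2", "B", "G2"),
             ("b3", "B", "G3"), ("b4", "B", "G3"), ("b5", "B", "G3")]
        )
        excl = reference_nm_pairs(reg, exclude_one_to_one=True)
        assert excl.pairs == {("a2", "b2"), ("a3", "b2")}
        incl = reference_nm_pairs(reg, exclude_one_to_one=False)
        assert incl.pairs == excl.pairs | {("a1", "b1")}

    def test_ungrouped_protein_directs_to_singleton_policy(self):
        reg = make_registry([("a1", "A", "G1"), ("b1", "B")])
        with pytest.raises(UnknownIdError, match="singleton"):
            reference_nm_pairs(reg)


class TestPairScores:
    def test_perfect_prediction(self):
        ref = pairset([("a", "b"), ("c", "d")])
        rep = pair_scores(ref, ref)
        assert (rep.precision, rep.sensitivity, rep.f1) == (100.0, 100.0, 100.0)

    def test_half_right_quarter_found(self):
        predicted = pairset([("a", "b"), ("a", "x")])
        reference = pairset([("a", "b"), ("c", "d"), ("e", "f"), ("g", "h")])
        rep = pair_scores(predicted, reference)
        assert rep.precision == pytest.approx(50.0)
        assert rep.sensitivity == pytest.approx(25.0)
        assert round_sig(rep.f1) == pytest.approx(33.3)

    def test_empty_prediction_gives_undefined_sentinels(self):
        rep = pair_scores(pairset([]), pairset([("a", "b")]))
        assert rep.precision is None and rep.f1 is None
        assert rep.sensitivity == 0.0

    def test_f1_between_precision_and_sensitivity(self, rng):
        for _ in range(50):
            p, s = rng.uniform(1, 100, size=2)
            f1 = f1_from_rates(p, s)
            assert min(p, s) <= f1 <= max(p, s)

    @pytest.mark.parametrize(
        "p, s, expected",
        [(92.2, 60.4, 73.0), (94.8, 4.70, 8.96), (91.4, 3.13, 6.05), (71.3, 75.0, 73.1)],
    )
    def test_published_style_f1_arithmetic(self, p, s, expected):
        assert round_sig(f1_from_rates(p, s)) == pytest.approx(expected)


class TestContingency:
    def test_identical_partitions_one_entry_per_row(self):
        part = {f"p{i}": f"G{i % 3}" for i in range(9)}
        table = contingency(part, part)
        assert (np.count_nonzero(table.y, axis=1) == 1).all()
        assert table.y.sum() == 9

    def test_hand_tally(self):
        ref = {"p1": "A", "p2": "A", "p3": "A", "p4": "B", "p5": "B"}
        pred = {"p1": "c1", "p2": "c1", "p3": "c2", "p4": "c1", "p5": "c2"}
        table = contingency(ref, pred)
        np.testing.assert_array_equal(table.y, [[2, 1], [1, 1]])

    def test_marginals_match_counters_on_random_partitions(self, rng):
        ref, pred = random_partition_pair(rng, 30)
        table = contingency(ref, pred)
        from collections import Counter

        gsizes = Counter(ref.values())
        csizes = Counter(pred.values())
        for i, g in enumerate(table.group_labels):
            assert table.y[i].sum() == gsizes[g]
        for j, c in enumerate(table.cluster_labels):
            assert table.y[:, j].sum() == csizes[c]
        assert table.total == 30

    def test_coverage_mismatch_lists_difference(self):
        with pytest.raises(CoverageError, match="p2"):
            contingency({"p1": "A"}, {"p1": "c", "p2": "c"})


class TestFamilyCompleteness:
    def test_perfect_clustering_is_one(self):
        part = {f"p{i}": f"G{i % 4}" for i in range(12)}
        assert family_completeness(contingency(part, part)) == 1.0

    def test_hand_tally_toy(self):
        ref = {"p1": "A", "p2": "A", "p3": "A", "p4": "B", "p5": "B"}
        pred = {"p1": "c1", "p2": "c1", "p3": "c2", "p4": "c1", "p5": "c2"}
        assert family_completeness(contingency(ref, pred)) == pytest.approx(0.6)

    def test_all_singleton_clusters_give_i_over_t(self):
        ref = {f"p{i}": f"G{i % 3}" for i in range(9)}
        pred = {f"p{i}": i for i in range(9)}
        assert family_completeness(contingency(ref, pred)) == pytest.approx(3 / 9)

    def test_matches_loop_oracle_on_random_partitions(self, rng):
        for _ in range(30):
            ref, pred = random_partition_pair(rng, int(rng.integers(5, 30)))
            got = family_completeness(contingency(ref, pred))
            assert got == pytest.approx(family_completeness_loop(ref, pred))


class TestAMI:
    def test_identical_partitions_give_one(self):
        part = {f"p{i}": f"G{i % 3}" for i in range(10)}
        assert adjusted_mutual_information(part, part) == pytest.approx(1.0)

    def test_cluster_relabeling_invariance(self, rng):
        ref, pred = random_partition_pair(rng, 20)
        relabeled = {pid: f"renamed-{lab}" for pid, lab in pred.items()}
        assert adjusted_mutual_information(ref, pred) == pytest.approx(
            adjusted_mutual_information(ref, relabeled)
        )

    def test_symmetry(self, rng):
        ref, pred = random_partition_pair(rng, 18)
        assert adjusted_mutual_information(ref, pred) == pytest.approx(
            adjusted_mutual_information(pred, ref)
        )

    def test_matches_direct_summation_oracle(self, rng):
        ids = [f"p{i}" for i in range(12)]
        for _ in range(25):
            ref = {pid: int(rng.integers(2)) for pid in ids}
            pred = {pid: int(rng.integers(2)) for pid in ids}
            if len(set(ref.values())) < 2 or len(set(pred.values())) < 2:
                continue
            got = adjusted_mutual_information(ref, pred)
            want = ami_direct(
                [ref[p] for p in sorted(ref)], [pred[p] for p in sorted(pred)]
            )
            assert got == pytest.approx(want, abs=1e-9)

    def test_single_block_conventions(self):
        ids = ["p1", "p2", "p3"]
        one_block = {pid: "all" for pid in ids}
        assert adjusted_mutual_information(one_block, one_block) == pytest.approx(1.0)
        split = {"p1": 0, "p2": 1, "p3": 1}
        assert adjusted_mutual_information(one_block, split) == pytest.approx(0.0)


class TestExactMatch:
    def test_identical_partitions_are_all_exact(self):
        part = {f"p{i}": f"G{i % 3}" for i in range(9)}
        assert exact_match_percentage(part, part) == 100.0

    def test_toy_with_no_exact_cluster(self):
        ref = {"p1": "A", "p2": "A", "p3": "A", "p4": "B", "p5": "B"}
        pred = {"p1": "c1", "p2": "c1", "p3": "c2", "p4": "c1", "p5": "c2"}
        assert exact_match_percentage(ref, pred) == 0.0

    def test_one_exact_of_two_clusters(self):
        ref = {"p1": "A", "p2": "A", "p3": "B", "p4": "B"}
        pred = {"p1": "c1", "p2": "c1", "p3": "c2", "p4": "c3"}
        # c1 == A exactly; c2 and c3 are fragments of B
        assert exact_match_percentage(ref, pred) == pytest.approx(100 / 3)
        assert exact_match_percentage(ref, pred, denominator="groups") == pytest.approx(50.0)

    def test_full_exactness_implies_other_metrics_maxed(self, rng):
        # partition identity: exact-match 100 forces completeness 1 and AMI 1
        for trial in range(5):
            ref, _ = random_partition_pair(rng, 20)
            relabel = {g: i for i, g in enumerate(set(ref.values()))}
            pred = {pid: relabel[g] for pid, g in ref.items()}
            assert exact_match_percentage(ref, pred) == 100.0
            assert family_completeness(contingency(ref, pred)) == 1.0
            assert adjusted_mutual_information(ref, pred) == pytest.approx(1.0)


class TestOneToOneScores:
    def test_reference_set_definition(self):
        reg = make_registry(
            [("a1", "A", "G1"), ("b1", "B", "G1"),
             ("a2", "A", "G2"), ("a3", "A", "G2"), ("b2", "B", "G2"),
             ("a4", "A", "G3"), ("b3", "B", "G3")]
        )
        assert reference_one_to_one_groups(reg) == {
            frozenset({"a1", "b1"}), frozenset({"a4", "b3"})
        }

    def test_perfect_prediction(self):
        reg = make_registry([("a1", "A", "G1"), ("b1", "B", "G1"),
                             ("a2", "A", "G2"), ("b2", "B", "G2")])
        rep = one_to_one_scores(
            [frozenset({"a1", "b1"}), frozenset({"a2", "b2"})], reg
        )
        assert (rep.precision, rep.sensitivity) == (100.0, 100.0)

    def test_wrong_size_injection_counts_incorrect(self):
        reg = make_registry([("a1", "A", "G1"), ("b1", "B", "G1"), ("c1", "C", "G1")])
        rep = one_to_one_scores([frozenset({"a1", "b1"})], reg)  # size 2, S=3
        assert rep.n_correct == 0
        assert rep.precision == 0.0

    def test_no_predictions_gives_sentinel(self):
        reg = make_registry([("a1", "A", "G1"), ("b1", "B", "G1")])
        rep = one_to_one_scores([], reg)
        assert rep.precision is None and rep.f1 is None


class TestGroupScores:
    def test_bundles_all_three_metrics(self, rng):
        ref, pred = random_partition_pair(rng, 25)
        rep = group_scores(ref, pred)
        assert rep.family_completeness == pytest.approx(
            family_completeness(contingency(ref, pred))
        )
        assert rep.ami == pytest.approx(adjusted_mutual_information(ref, pred))
        assert rep.exact_match_pct == pytest.approx(exact_match_percentage(ref, pred))
        assert rep.n_proteins == 25

    def test_empty_partitions_rejected(self):
        with pytest.raises(EmptyInputError):
            group_scores({}, {})


class TestRounding:
    @pytest.mark.parametrize(
        "x, expected",
        [(72.983, 73.0), (8.9564, 8.96), (0.62648, 0.626), (None, None), (0.0, 0.0)],
    )
    def test_three_significant_figures_half_even(self, x, expected):
        assert round_sig(x) == expected
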