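"""Jaccard matching, recall, score matrices and co-location analysis."""

import numpy as np
import pytest

from tenec.interpret import MembershipMatrix
from tenec.validation import (
    GroundTruth,
    LocationFingerprints,
    colocation,
    jaccard,
    match_components,
    recall_and_coverage,
    reference_score_matrix,
    score_matrix,
)


def truth_from_sizes(sizes: dict[str, int], teachers: dict[str, str] | None = None):
    labels, roles = {}, {}
    for cls, size in sizes.items():
        for i in range(size):
            node = f"{cls}s{i:02d}"
            labels[node] = cls
            roles[node] = "student"
    for node, cls in (teachers or {}).items():
        labels[node] = cls
        roles[node] = "teacher"
    return GroundTruth(labels=labels, roles=roles)


def membership_from_sets(node_order, member_sets):
    values = np.zeros((len(node_order), len(member_sets)), dtype=int)
    pos = {n: i for i, n in enumerate(node_order)}
    for k, members in enumerate(member_sets):
        for n in members:
            values[pos[n], k] = 1
    return MembershipMatrix(values=values, nodes=tuple(node_order))


class TestJaccard:
    def test_identical_sets(self):
        assert jaccard({1, 2}, {1, 2}) == 1.0

    def test_half_overlap(self):
        assert jaccard({1, 2, 3}, {2, 3, 4}) == 0.5

    def test_disjoint_and_empty(self):
        assert jaccard({1}, {2}) == 0.0
        assert jaccard(set(), set()) == 0.0

    def test_symmetry(self, rng):
        a = set(rng.integers(0, 20, size=8).tolist())
        b = set(rng.integers(0, 20, size=8).tolist())
        assert jaccard(a, b) == jaccard(b, a)


class TestMatching:
    def test_exact_class_matches(self):
        truth = truth_from_sizes({"A": 3, "B": 4})
        m = membership_from_sets(sorted(truth.labels),
                                 [truth.class_members("A")])
        matches = match_components(m, truth)
        assert matches[0].matched_class == "A"
        assert matches[0].overlaps["A"] == 1.0

    def test_mixed_component_unmatched(self):
        truth = truth_from_sizes({"A": 3, "B": 3})
        mixed = set(truth.class_members("A")) | {"Bs00"}
        m = membership_from_sets(sorted(truth.labels), [mixed])
        assert match_components(m, truth)[0].matched_class is None

    def test_teachers_excluded_from_matching(self):
        truth = truth_from_sizes({"A": 3, "B": 3}, teachers={"tA": "A", "tB": "B"})
        # component = class A students + class B's teacher: with teachers
        # excluded the overlap vector has a single non-zero entry
        members = set(truth.class_members("A")) | {"tB"}
        m = membership_from_sets(sorted(truth.labels), [members])
        match = match_components(m, truth)[0]
        assert match.matched_class == "A"
        unmatched = match_components(m, truth, students_only=False)[0]
        assert unmatched.matched_class is None

    def test_planted_groups_matched_mixed_unmatched(self):
        truth = truth_from_sizes({"A": 4, "B": 4, "C": 4})
        sets = [truth.class_members("A"), truth.class_members("B"),
                truth.class_members("C"),
                set(truth.class_members("A")) | set(truth.class_members("B"))]
        m = membership_from_sets(sorted(truth.labels), sets)
        matches = match_components(m, truth)
        assert [x.matched_class for x in matches] == ["A", "B", "C", None]


class TestRecall:
    def test_single_class_fully_covered(self):
        truth = truth_from_sizes({"A": 25, "B": 20})
        m = membership_from_sets(sorted(truth.labels), [truth.class_members("A")])
        report = recall_and_coverage(match_components(m, truth), m, truth)
        assert (report.n_matched_classes, report.class_nodes,
                report.covered_nodes, report.recall) == (1, 25, 25, 1.0)

    def test_ten_classes_one_missing_student(self):
        # 231 students in 10 classes; one component misses one student of its
        # class -> 230 covered, recall 230/231
        sizes = dict(zip("ABCDEFGHIJ", [25, 22, 22, 24, 26, 22, 23, 21, 23, 23]))
        truth = truth_from_sizes(sizes)
        sets = []
        for cls in sizes:
            members = set(truth.class_members(cls))
            if cls == "B":
                members.discard("Bs00")
            sets.append(members)
        m = membership_from_sets(sorted(truth.labels), sets)
        report = recall_and_coverage(match_components(m, truth), m, truth)
        assert report.class_nodes == 231 and report.covered_nodes == 230
        assert report.recall == pytest.approx(0.99567, abs=5e-6)

    def test_one_deleted_member_counting_oracle(self):
        truth = truth_from_sizes({"A": 7})
        members = set(truth.class_members("A"))
        members.discard("As03")
        m = membership_from_sets(sorted(truth.labels), [members])
        report = recall_and_coverage(match_components(m, truth), m, truth)
        assert report.recall == pytest.approx(6 / 7)

    def test_no_matches_gives_absent_recall(self):
        truth = truth_from_sizes({"A": 3, "B": 3})
        mixed = set(truth.class_members("A")) | set(truth.class_members("B"))
        m = membership_from_sets(sorted(truth.labels), [mixed])
        report = recall_and_coverage(match_components(m, truth), m, truth)
        assert report.recall is None and report.n_matched_classes == 0

    def test_recall_monotone_in_correct_members(self):
        truth = truth_from_sizes({"A": 6, "B": 6})
        partial = set(list(truth.class_members("A"))[:4])
        fuller = partial | {sorted(truth.class_members("A") - partial)[0]}
        reports = []
        for members in (partial, fuller):
            m = membership_from_sets(sorted(truth.labels), [members])
            reports.append(recall_and_coverage(match_components(m, truth), m, truth))
        assert reports[1].recall >= reports[0].recall


class TestScoreMatrix:
    def test_truth_encoding_gives_diagonal(self):
        sizes = {"A": 4, "B": 6, "C": 5}
        truth = truth_from_sizes(sizes)
        sets = [truth.class_members(c) for c in sorted(sizes)]
        m = membership_from_sets(sorted(truth.labels), sets)
        got = score_matrix(m, truth)
        np.testing.assert_array_equal(got.values, np.diag([4, 6, 5]))
        np.testing.assert_array_equal(reference_score_matrix(truth).values,
                                      np.diag([4, 6, 5]))

    def test_empty_membership_gives_zero_matrix(self):
        truth = truth_from_sizes({"A": 3})
        m = membership_from_sets(sorted(truth.labels), [set(), set()])
        assert (score_matrix(m, truth).values == 0).all()

    def test_random_membership_double_loop_oracle(self, rng):
        truth = truth_from_sizes({"A": 5, "B": 4, "C": 6})
        nodes = sorted(truth.labels)
        values = (rng.random((len(nodes), 4)) < 0.4).astype(int)
        m = MembershipMatrix(values=values, nodes=tuple(nodes))
        got = score_matrix(m, truth)
        for ci, cls in enumerate(sorted({"A", "B", "C"})):
            for k in range(4):
                expected = sum(
                    1 for ni, n in enumerate(nodes)
                    if values[ni, k] == 1 and truth.labels[n] == cls
                )
                assert got.iloc[ci, k] == expected

    def test_column_sums_equal_student_component_sizes(self, rng):
        truth = truth_from_sizes({"A": 5, "B": 5}, teachers={"tA": "A"})
        nodes = sorted(truth.labels)
        values = (rng.random((len(nodes), 3)) < 0.5).astype(int)
        m = MembershipMatrix(values=values, nodes=tuple(nodes))
        got = score_matrix(m, truth)
        students = truth.students()
        for k in range(3):
            assert got.iloc[:, k].sum() == len(m.members(k) & students)


def make_fingerprints(counts_by_node, receivers, n_intervals):
    nodes = tuple(sorted(counts_by_node))
    counts = np.zeros((len(nodes), len(receivers), n_intervals), dtype=int)
    for ni, node in enumerate(nodes):
        for (receiver, m), value in counts_by_node[node].items():
            counts[ni, receivers.index(receiver), m] = value
    return LocationFingerprints(counts=counts, nodes=nodes, receivers=tuple(receivers))


class TestColocation:
    def test_product_of_counts(self):
        fp = make_fingerprints({"x": {("r", 0): 2}, "y": {("r", 0): 2}}, ["r"], 2)
        series = colocation({"x", "y"}, fp)
        assert series.series("r")[0] == 4.0

    def test_zero_iff_any_member_absent(self):
        fp = make_fingerprints({"x": {("r", 0): 3, ("r", 1): 3},
                                "y": {("r", 0): 5}}, ["r"], 2)
        series = colocation({"x", "y"}, fp)
        assert series.series("r")[0] == 15.0
        assert series.series("r")[1] == 0.0

    def test_binarized_and_log_variants(self):
        fp = make_fingerprints({"x": {("r", 0): 3}, "y": {("r", 0): 5}}, ["r"], 1)
        assert colocation({"x", "y"}, fp, binarize=True).series("r")[0] == 1.0
        log_series = colocation({"x", "y"}, fp, log_domain=True)
        assert log_series.series("r")[0] == pytest.approx(np.log(3) + np.log(5))

    def test_missing_member_warns_and_zeroes(self):
        fp = make_fingerprints({"x": {("r", 0): 3}}, ["r"], 1)
        with pytest.warns(UserWarning, match="without fingerprint"):
            series = colocation({"x", "ghost"}, fp)
        assert (series.values == 0).all()

    def test_planted_gathering_is_argmax(self, school_data):
        truth = school_data.truth
        members = (truth.class_members("G00") | truth.class_members("G01")
                   | truth.class_members("G02") | truth.class_members("G03"))
        series = colocation(members, school_data.fingerprints, log_domain=True)
        assert series.peak_interval("cafeteria") in (18, 19, 20, 21)

    def test_rescaled_max_one(self):
        fp = make_fingerprints({"x": {("r", 0): 2, ("r", 1): 4}}, ["r"], 2)
        scaled = colocation({"x"}, fp).rescaled()
        assert scaled.max() == 1.0
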