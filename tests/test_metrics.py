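"""Confusion metrics, ROC/PR curves, overlap/coverage and grouped tables."""

import math

import numpy as np
import pytest

from disvote.metrics import (ConfusionCounts, all_coverage, confusion_metrics,
                             grouped_balanced_accuracy, is_defined,
                             metrics_from_counts, overlap_coverage,
                             roc_pr_curves)
from disvote.score_io import Dataset, ScoreProfile


def concordance_auc(labels, scores):
    """O(n^2) all-pairs oracle: P(score+ > score-) + 0.5 P(tie)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        rep = metrics_from_counts(ConfusionCounts(tp=50, fp=0, tn=50, fn=0))
        assert (rep.sens, rep.spec, rep.acc, rep.acc_b, rep.mcc, rep.f1) == \
            (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)

    def test_degenerate_all_positive_calls(self):
        labels = np.repeat([1, 0], 20)
        rep = confusion_metrics(labels, np.ones(40, int))
        assert rep.sens == 1.0 and rep.spec == 0.0 and rep.acc_b == 0.5
        assert not is_defined(rep.mcc)

    def test_hand_arithmetic_example(self):
        rep = metrics_from_counts(ConfusionCounts(tp=30, fp=10, tn=50, fn=10))
        assert rep.sens == pytest.approx(0.75)
        assert rep.spec == pytest.approx(5 / 6)
        assert rep.acc == pytest.approx(0.8)
        assert rep.acc_b == pytest.approx((0.75 + 5 / 6) / 2)
        assert rep.mcc == pytest.approx(
            (30 * 50 - 10 * 10) / math.sqrt(40 * 40 * 60 * 60))
        assert rep.f1 == pytest.approx(2 * 0.75 * 0.75 / 1.5)

    def test_matches_formula_oracle_on_random_tables(self):
        """1000 random confusion tables agree with direct formulas."""
        rng = np.random.default_rng(21)
        for _ in range(1000):
            tp, fp, tn, fn = rng.integers(0, 40, 4)
            if tp + fp + tn + fn == 0:
                tp = 1
            rep = metrics_from_counts(ConfusionCounts(tp, fp, tn, fn))
            if tp + fn:
                assert rep.sens == pytest.approx(tp / (tp + fn), abs=1e-12)
            else:
                assert not is_defined(rep.sens)
            if tn + fp:
                assert rep.spec == pytest.approx(tn / (tn + fp), abs=1e-12)
            if is_defined(rep.sens) and is_defined(rep.spec):
                assert rep.acc_b == pytest.approx((rep.sens + rep.spec) / 2,
                                                  abs=1e-15)
            den = math.sqrt(float((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)))
            if den:
                assert rep.mcc == pytest.approx((tp * tn - fp * fn) / den,
                                                abs=1e-12)
            else:
                assert not is_defined(rep.mcc)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            confusion_metrics([], [])


class TestRocPr:
    def test_perfect_ranking(self):
        rep = roc_pr_curves([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert rep.auc_roc == 1.0 and rep.auc_pr == pytest.approx(1.0)

    def test_constant_scores_give_half_auc(self):
        rep = roc_pr_curves(np.repeat([0, 1], 25), np.full(50, 0.5))
        assert rep.auc_roc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_pr_curves([1, 1, 1], [0.1, 0.2, 0.3])

    def test_trapezoid_matches_concordance_oracle(self):
        """100 random instances (with ties) match the all-pairs statistic
        within 1e-9."""
        rng = np.random.default_rng(22)
        for _ in range(100):
            n = int(rng.integers(10, 301))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[:2] = [0, 1]
            # quantized scores force ties
            scores = np.round(rng.uniform(size=n), 2)
            rep = roc_pr_curves(labels, scores)
            assert rep.auc_roc == pytest.approx(
                concordance_auc(labels, scores), abs=1e-9)

    def test_auc_pr_equals_sklearn_average_precision(self):
        from sklearn.metrics import average_precision_score

        rng = np.random.default_rng(23)
        labels = rng.integers(0, 2, 500)
        labels[:2] = [0, 1]
        scores = np.round(rng.uniform(size=500), 2)
        rep = roc_pr_curves(labels, scores)
        assert rep.auc_pr == pytest.approx(
            average_precision_score(labels, scores), abs=1e-12)


class TestOverlapCoverage:
    def test_identical_predictors_collapse_to_sens_spec(self):
        rng = np.random.default_rng(24)
        labels = rng.integers(0, 2, 200)
        calls = rng.integers(0, 2, 200)
        rep = confusion_metrics(labels, calls)
        op, cp, on, cn = overlap_coverage(labels, calls, calls)
        assert op == cp == pytest.approx(rep.sens)
        assert on == cn == pytest.approx(rep.spec)

    def test_disjoint_correct_sets_cover_everything(self):
        labels = np.array([1, 1, 1, 1])
        a = np.array([1, 1, 0, 0])
        b = np.array([0, 0, 1, 1])
        op, cp, _, _ = overlap_coverage(labels, a, b)
        assert op == 0.0 and cp == 1.0

    def test_constructed_ten_residue_example(self):
        # positives at 0-4, negatives at 5-9
        labels = np.array([1] * 5 + [0] * 5)
        a = np.array([1, 1, 1, 0, 0, 0, 0, 1, 1, 1])
        b = np.array([0, 1, 1, 1, 0, 0, 1, 0, 1, 0])
        # TP_A={0,1,2}, TP_B={1,2,3}: overlap 2/5, union 4/5
        # TN_A={5,6}, TN_B={5,7,9}: overlap 1/5, union 4/5
        assert overlap_coverage(labels, a, b) == (0.4, 0.8, 0.2, 0.8)

    def test_no_negatives_marks_undefined(self):
        labels = np.ones(5, int)
        _, _, on, cn = overlap_coverage(labels, labels, labels)
        assert not is_defined(on) and not is_defined(cn)

    def test_overlap_le_individual_le_coverage(self):
        rng = np.random.default_rng(25)
        for _ in range(50):
            labels = rng.integers(0, 2, 100)
            labels[:2] = [0, 1]
            a, b = rng.integers(0, 2, (2, 100))
            rep_a = confusion_metrics(labels, a)
            rep_b = confusion_metrics(labels, b)
            op, cp, on, cn = overlap_coverage(labels, a, b)
            assert op <= min(rep_a.sens, rep_b.sens) + 1e-12
            assert max(rep_a.sens, rep_b.sens) <= cp + 1e-12
            assert on <= min(rep_a.spec, rep_b.spec) + 1e-12
            assert max(rep_a.spec, rep_b.spec) <= cn + 1e-12


class TestAllCoverage:
    def test_copies_equal_single_predictor(self):
        rng = np.random.default_rng(26)
        labels = rng.integers(0, 2, 100)
        labels[:2] = [0, 1]
        calls = rng.integers(0, 2, 100)
        rep = confusion_metrics(labels, calls)
        cp, cn = all_coverage(labels, [calls] * 4)
        assert cp == pytest.approx(rep.sens) and cn == pytest.approx(rep.spec)

    def test_complementary_predictors_reach_one(self):
        labels = np.array([1, 1, 0, 0])
        a = np.array([1, 0, 0, 1])
        b = np.array([0, 1, 1, 0])
        assert all_coverage(labels, [a, b]) == (1.0, 1.0)

    def test_union_count_oracle(self):
        rng = np.random.default_rng(27)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        calls = [rng.integers(0, 2, 50) for _ in range(4)]
        cp, cn = all_coverage(labels, calls)
        tp_union = set()
        tn_union = set()
        for c in calls:
            tp_union |= {i for i in range(50) if labels[i] == 1 and c[i] == 1}
            tn_union |= {i for i in range(50) if labels[i] == 0 and c[i] == 0}
        assert cp == len(tp_union) / (labels == 1).sum()
        assert cn == len(tn_union) / (labels == 0).sum()

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            all_coverage([0, 1], [np.array([0, 1])])


class TestGroupedBalancedAccuracy:
    def _dataset(self, L=60, n=4, seed=30):
        rng = np.random.default_rng(seed)
        profiles = []
        for i in range(n):
            labels = rng.integers(0, 2, L)
            labels[:2] = [0, 1]
            profiles.append(ScoreProfile(
                f"s{i}", "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), L)),
                rng.uniform(size=(L, 4)), labels=labels))
        return Dataset(profiles)

    def test_perfect_calls_give_unit_acc_b_everywhere(self):
        ds = self._dataset()
        calls = np.concatenate([p.labels for p in ds.profiles])
        for grouping in ("amino_acid", "n_terminal_distance",
                         "c_terminal_distance", "per_sequence"):
            table = grouped_balanced_accuracy(ds, calls, grouping)
            defined = table["acc_b"].dropna()
            assert (defined == 1.0).all()

    def test_per_sequence_single_profile_matches_global(self):
        ds = self._dataset(n=1)
        rng = np.random.default_rng(31)
        calls = rng.integers(0, 2, ds.n_residues)
        table = grouped_balanced_accuracy(ds, calls, "per_sequence")
        assert len(table) == 1
        global_rep = confusion_metrics(ds.profiles[0].labels, calls)
        assert table["acc_b"][0] == pytest.approx(global_rep.acc_b)
        assert table["disorder_fraction"][0] == ds.profiles[0].labels.mean()

    def test_terminal_range_is_5_to_25(self):
        ds = self._dataset()
        calls = np.zeros(ds.n_residues, int)
        table = grouped_balanced_accuracy(ds, calls, "n_terminal_distance")
        assert list(table["group"]) == list(range(5, 26))

    def test_single_class_group_kept_with_marker(self):
        profile = ScoreProfile("s", "AAAC", np.zeros((4, 4)),
                               labels=[1, 1, 1, 0])
        ds = Dataset([profile])
        table = grouped_balanced_accuracy(ds, np.array([1, 1, 0, 0]),
                                          "amino_acid")
        row_a = table[table["group"] == "A"].iloc[0]
        assert row_a["n"] == 3 and not is_defined(row_a["spec"])
        assert not is_defined(row_a["acc_b"])
        assert "C" in set(table["group"])

    def test_unknown_grouping_rejected(self):
        with pytest.raises(ValueError, match="grouping"):
            grouped_balanced_accuracy(self._dataset(),
                                      np.zeros(240, int), "bogus")
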