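"""Metric oracles and the repeated random-split protocol."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smitox import (binary_metrics, confusion_counts, label_binary,
                    micro_auc_multiclass, repeated_evaluation, roc_auc)
from smitox.data import ChemicalRecord


def pair_counting_auc(y, s):
    """Brute-force Mann-Whitney estimator over all positive-negative pairs."""
    y = np.asarray(y)
    s = np.asarray(s, dtype=float)
    pos = s[y == 1]
    neg = s[y == 0]
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestConfusionCounts:
    def test_direct_count(self):
        assert confusion_counts([1, 1, 0, 0], [1, 0, 0, 0]) == (1, 2, 0, 1)

    def test_perfect_prediction(self):
        tp, tn, fp, fn = confusion_counts([1, 0, 1], [1, 0, 1])
        assert fp == fn == 0

    def test_counts_sum_to_n_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(1, 30))
            y = rng.integers(0, 2, n)
            yhat = rng.integers(0, 2, n)
            assert sum(confusion_counts(y, yhat)) == n

    def test_length_mismatch_and_nonbinary_rejected(self):
        with pytest.raises(ValueError):
            confusion_counts([1, 0], [1])
        with pytest.raises(ValueError):
            confusion_counts([2, 0], [1, 0])


class TestRocAuc:
    def test_four_pair_example(self):
        assert roc_auc([1, 0, 1, 0], [0.9, 0.8, 0.4, 0.2]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1, 1], [0.1, 0.2, 0.3])

    def test_equals_pair_counting_estimator_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(4, 31))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            s = rng.choice([0.1, 0.25, 0.5, 0.75, 0.9], size=n)  # force ties
            assert roc_auc(y, s) == pytest.approx(pair_counting_auc(y, s),
                                                  abs=1e-12)

    @given(st.integers(min_value=0, max_value=2**16))
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_strictly_increasing_transform(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, 20)
        if len(np.unique(y)) < 2:
            return
        s = rng.standard_normal(20)
        assert roc_auc(y, s) == pytest.approx(
            roc_auc(y, np.exp(3 * s) + 1), abs=1e-12)

    def test_score_negation_complements_auc(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 30)
        s = rng.random(30)  # ties almost surely absent
        assert roc_auc(y, s) + roc_auc(y, -s) == pytest.approx(1.0, abs=1e-12)


class TestBinaryMetrics:
    def test_worked_threshold_example(self):
        m = binary_metrics([1, 1, 0, 0], [0.9, 0.4, 0.3, 0.1])
        assert m["accuracy"] == 0.75
        assert m["sensitivity"] == 0.5
        assert m["specificity"] == 1.0

    def test_perfect_classifier_all_ones(self):
        m = binary_metrics([1, 0, 1], [1.0, 0.0, 1.0])
        assert all(v == 1.0 for v in m.values())

    def test_agreement_with_confusion_formulas_on_random_cases(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(6, 40))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            p = rng.random(n)
            m = binary_metrics(y, p)
            tp, tn, fp, fn = confusion_counts(y, (p >= 0.5).astype(int))
            assert m["accuracy"] == pytest.approx((tp + tn) / n, abs=1e-9)
            if tp + fn:
                assert m["sensitivity"] == pytest.approx(tp / (tp + fn), abs=1e-9)
            if tn + fp:
                assert m["specificity"] == pytest.approx(tn / (tn + fp), abs=1e-9)
            if tp + fp:
                assert m["precision"] == pytest.approx(tp / (tp + fp), abs=1e-9)
            assert m["auc"] == pytest.approx(pair_counting_auc(y, p), abs=1e-9)

    def test_zero_denominator_returns_zero_with_warning(self):
        with pytest.warns(UserWarning, match="precision"):
            m = binary_metrics([1, 0], [0.1, 0.2])
        assert m["precision"] == 0.0

    def test_complementing_swaps_sensitivity_specificity(self):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, 40)
        p = rng.random(40)
        m = binary_metrics(y, p)
        m_flip = binary_metrics(1 - y, 1 - p)
        assert m["sensitivity"] == pytest.approx(m_flip["specificity"])
        assert m["specificity"] == pytest.approx(m_flip["sensitivity"])


class TestMicroAuc:
    def test_probabilities_equal_onehot_labels(self):
        y = np.eye(4)[[0, 1, 2, 3, 1]]
        assert micro_auc_multiclass(y, y) == 1.0

    def test_uniform_probabilities_give_half(self):
        y = np.eye(4)[[0, 1, 2, 3]]
        p = np.full((4, 4), 0.25)
        assert micro_auc_multiclass(y, p) == 0.5

    def test_random_instance_equals_flattened_pair_counting(self):
        rng = np.random.default_rng(11)
        y = np.eye(4)[rng.integers(0, 4, 20)]
        p = rng.random((20, 4))
        p /= p.sum(axis=1, keepdims=True)
        expected = pair_counting_auc(y.ravel(order="F"), p.ravel(order="F"))
        assert micro_auc_multiclass(y, p) == pytest.approx(expected, abs=1e-12)

    def test_two_class_complementary_columns_bounded_by_binary_auc_direction(self):
        """Flattening a 2-class problem keeps the ranking direction: micro
        AUC sits on the same side of 0.5 as the binary AUC (the two are
        not equal in general — cross-column comparisons enter the
        flattened pair count)."""
        rng = np.random.default_rng(13)
        y = rng.integers(0, 2, 30)
        p1 = np.where(y == 1, rng.uniform(0.5, 1, 30), rng.uniform(0, 0.5, 30))
        micro = micro_auc_multiclass(np.eye(2)[y], np.column_stack([1 - p1, p1]))
        assert micro > 0.5 and roc_auc(y, p1) > 0.5
        # and the perfect-prediction case coincides exactly
        exact = y.astype(float)
        if len(np.unique(y)) == 2:
            assert micro_auc_multiclass(
                np.eye(2)[y], np.column_stack([1 - exact, exact])) == \
                roc_auc(y, exact) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            micro_auc_multiclass(np.eye(3), np.ones((3, 4)))


def threshold_factory(train, seed):
    """Deterministic toy scorer: probability from the train toxic fraction."""
    toxic_rate = train.labels.mean()

    def scorer(test):
        p = np.array([min(1.0, toxic_rate * 1000.0 / r.ld50)
                      for r in test.records])
        return p[:, None]

    return scorer


def toy_dataset(n=200, seed=0):
    rng = np.random.default_rng(seed)
    records = [ChemicalRecord(id=f"c{i}", smiles="CCO",
                              ld50=float(10 ** rng.uniform(1, 4)))
               for i in range(n)]
    return label_binary(records, cutoff=500)


class TestRepeatedEvaluation:
    def test_ten_repeats_aggregate_is_arithmetic_mean(self):
        report = repeated_evaluation(toy_dataset(), threshold_factory,
                                     n_repeats=10, test_size=0.2, master_seed=1)
        assert report.n_repeats == 10
        for metric, agg in report.aggregate.items():
            vals = [run[metric] for run in report.per_run]
            assert agg["mean"] == pytest.approx(np.mean(vals), abs=1e-12)

    def test_single_repeat_aggregate_equals_run(self):
        report = repeated_evaluation(toy_dataset(), threshold_factory,
                                     n_repeats=1, master_seed=5)
        for metric, agg in report.aggregate.items():
            assert agg["mean"] == report.per_run[0][metric]
            assert agg["sd"] == 0.0

    def test_same_master_seed_identical_reports(self):
        a = repeated_evaluation(toy_dataset(), threshold_factory,
                                n_repeats=3, master_seed=9)
        b = repeated_evaluation(toy_dataset(), threshold_factory,
                                n_repeats=3, master_seed=9)
        assert a.to_json() == b.to_json()

    def test_failed_repeats_recorded_as_partial(self):
        calls = {"n": 0}

        def flaky_factory(train, seed):
            calls["n"] += 1
            if calls["n"] == 2:
                raise RuntimeError("boom")
            return threshold_factory(train, seed)

        report = repeated_evaluation(toy_dataset(), flaky_factory,
                                     n_repeats=3, master_seed=0)
        assert report.n_repeats == 2
        assert report.protocol["partial"] is True
        assert report.protocol["failures"][0]["repeat"] == 1

    def test_report_serialization(self, tmp_path):
        report = repeated_evaluation(toy_dataset(), threshold_factory,
                                     n_repeats=2, master_seed=0)
        report.to_json(tmp_path / "r.json")
        report.to_csv(tmp_path / "r.csv")
        import pandas as pd

        assert len(pd.read_csv(tmp_path / "r.csv")) == 2
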