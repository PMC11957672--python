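"""Metric formulas against exhaustive and library oracles."""

import itertools
import warnings

import numpy as np
import pytest
import sklearn.metrics as skm

from bindnode.evaluation import (
    ConfusionCounts,
    aggregate_per_protein,
    confusion,
    confusion_per_class,
    metric_defined,
    metrics,
    per_protein_ci,
    plddt_correlation,
    pr_roc_sweep,
    reliability_table,
)
from bindnode.prediction import to_binary


class TestConfusion:
    def test_perfect_and_inverted_predictions(self):
        labels = np.array([1, 1, 0, 0, 1])
        perfect = confusion(labels, labels)
        assert perfect.fp == perfect.fn == 0
        inverted = confusion(1 - labels, labels)
        assert inverted.tp == inverted.tn == 0

    def test_four_residue_enumeration(self):
        cc = confusion(np.array([1, 1, 0, 0]), np.array([1, 0, 1, 0]))
        assert (cc.tp, cc.fp, cc.fn, cc.tn) == (1, 1, 1, 1)

    def test_per_class_plus_binary(self):
        calls = np.array([[1, 0, 0], [0, 1, 1], [0, 0, 0]])
        labels = np.array([[1, 0, 0], [0, 0, 1], [1, 0, 0]])
        by = confusion_per_class(calls, labels)
        assert by["metal"].tp == 1 and by["metal"].fn == 1
        assert by["nucleic"].fp == 1
        assert by["binary"].tp == 2 and by["binary"].fn == 1

    def test_micro_counts_add_over_proteins(self, rng):
        calls = [rng.integers(0, 2, (n, 3)) for n in (5, 9, 4)]
        labels = [rng.integers(0, 2, (n, 3)) for n in (5, 9, 4)]
        summed = None
        for c, y in zip(calls, labels):
            cc = confusion(c, y)
            summed = cc if summed is None else summed + cc
        whole = confusion(np.vstack(calls), np.vstack(labels))
        assert summed == whole


class TestMetrics:
    def test_perfect_two_residue_case(self):
        ms = metrics(ConfusionCounts(tp=1, fp=0, tn=1, fn=0))
        assert ms.mcc == ms.f1 == ms.accuracy == 1.0

    def test_hand_computed_table(self):
        ms = metrics(ConfusionCounts(tp=3, fp=1, tn=4, fn=2))
        assert ms.precision == pytest.approx(0.75)
        assert ms.recall == pytest.approx(0.6)
        assert ms.f1 == pytest.approx(2 * 0.75 * 0.6 / 1.35)
        assert ms.accuracy == pytest.approx(0.7)
        assert ms.mcc == pytest.approx((3 * 4 - 2 * 1) / np.sqrt(4 * 5 * 5 * 6))

    def test_degenerate_tables_return_zero_not_error(self):
        ms = metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=0))
        assert ms.recall == 0.0 and ms.precision == 0.0
        assert ms.mcc == 0.0 and ms.f1 == 0.0

    def test_exhaustive_oracle_all_small_tables(self):
        """Direct formula evaluation over every table with entries <= 10."""
        for tp, fp, tn, fn in itertools.product(range(11), repeat=4):
            if tp + fp + tn + fn == 0:
                continue
            ms = metrics(ConfusionCounts(tp, fp, tn, fn))
            denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
            mcc = (tp * tn - fn * fp) / np.sqrt(denom) if denom else 0.0
            prec = tp / (tp + fp) if tp + fp else 0.0
            rec = tp / (tp + fn) if tp + fn else 0.0
            f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
            acc = (tp + tn) / (tp + fp + tn + fn)
            assert ms.mcc == pytest.approx(mcc, abs=1e-12)
            assert ms.precision == prec and ms.recall == rec
            assert ms.f1 == pytest.approx(f1, abs=1e-12)
            assert ms.accuracy == pytest.approx(acc, abs=1e-12)

    def test_against_sklearn_on_random_data(self, rng):
        calls = rng.integers(0, 2, 200)
        labels = rng.integers(0, 2, 200)
        ms = metrics(confusion(calls, labels))
        assert ms.mcc == pytest.approx(skm.matthews_corrcoef(labels, calls))
        assert ms.precision == pytest.approx(skm.precision_score(labels, calls))
        assert ms.recall == pytest.approx(skm.recall_score(labels, calls))
        assert ms.f1 == pytest.approx(skm.f1_score(labels, calls))
        assert ms.accuracy == pytest.approx(skm.accuracy_score(labels, calls))


class TestPerProteinCI:
    def test_zero_variance(self):
        mean, half, n = per_protein_ci([0.5, 0.5, 0.5])
        assert (mean, half, n) == (0.5, 0.0, 3)

    def test_closed_form_halfwidth(self):
        mean, half, _ = per_protein_ci([0.4, 0.5, 0.6])
        assert mean == pytest.approx(0.5)
        assert half == pytest.approx(1.96 * 0.1 / np.sqrt(3))

    def test_single_protein_flagged_zero(self):
        with pytest.warns(UserWarning):
            mean, half, n = per_protein_ci([0.7])
        assert (mean, half, n) == (0.7, 0.0, 1)

    def test_undefined_proteins_excluded_from_aggregation(self):
        counts = [
            {"metal": ConfusionCounts(1, 0, 4, 0), "nucleic": ConfusionCounts(0, 0, 5, 0),
             "small": ConfusionCounts(0, 0, 5, 0), "binary": ConfusionCounts(1, 0, 4, 0)},
            {"metal": ConfusionCounts(0, 0, 6, 0), "nucleic": ConfusionCounts(2, 1, 3, 0),
             "small": ConfusionCounts(0, 0, 6, 0), "binary": ConfusionCounts(2, 1, 3, 0)},
        ]
        table = aggregate_per_protein(counts)
        metal_n = table.query("task == 'metal' and metric == 'f1'").n.item()
        small_n = table.query("task == 'small' and metric == 'f1'").n.item()
        assert metal_n == 1 and small_n == 0  # undefined proteins dropped
        zero_fill = aggregate_per_protein(counts, undefined="zero")
        assert zero_fill.query("task == 'metal' and metric == 'f1'").n.item() == 2

    def test_metric_defined_rule(self):
        assert not metric_defined(ConfusionCounts(0, 0, 10, 0))
        assert metric_defined(ConfusionCounts(0, 1, 9, 0))
        assert metric_defined(ConfusionCounts(0, 0, 9, 1))


class TestCurves:
    def test_perfect_separation_has_unit_area(self):
        probs = np.zeros((100, 3))
        labels = np.zeros((100, 3), dtype=int)
        probs[:20, 0] = 0.99
        labels[:20, 0] = 1
        probs[20:, 0] = 0.01
        table = pr_roc_sweep(probs, labels)
        assert (table.precision.iloc[:-1] == 1.0).all()
        assert (table.recall == 1.0).all()
        assert (table.fpr == 0.0).all()

    def test_random_scores_give_half_auc(self):
        rng = np.random.default_rng(0)
        n = 20000
        probs = np.column_stack([rng.uniform(0, 1, n)] * 3) * [1.0, 0.5, 0.5]
        labels = np.zeros((n, 3), dtype=int)
        labels[rng.uniform(size=n) < 0.1, 0] = 1
        table = pr_roc_sweep(probs, labels, thresholds=np.linspace(0.01, 0.99, 99))
        fpr = np.concatenate([[1.0], table.fpr.to_numpy(), [0.0]])[::-1]
        tpr = np.concatenate([[1.0], table.tpr.to_numpy(), [0.0]])[::-1]
        auc = np.trapezoid(tpr, fpr)
        assert auc == pytest.approx(0.5, abs=0.02)

    def test_sweep_at_half_reproduces_confusion(self, rng):
        probs = rng.uniform(0, 1, (50, 3))
        labels = rng.integers(0, 2, (50, 3))
        table = pr_roc_sweep(probs, labels, thresholds=[0.5])
        calls, _ = to_binary(probs, 0.5)
        cc = confusion(calls, labels.any(axis=1))
        ms = metrics(cc)
        assert table.precision.item() == pytest.approx(ms.precision)
        assert table.recall.item() == pytest.approx(ms.recall)

    def test_reliability_coverage_and_precision(self):
        probs = np.array(
            [[0.95, 0, 0], [0.85, 0, 0], [0.6, 0, 0], [0.9, 0, 0], [0.2, 0, 0]]
        )
        labels = np.zeros((5, 3), dtype=int)
        labels[[0, 1, 2], 0] = 1  # three observed binding residues
        table = reliability_table(probs, labels, thresholds=[0.8])
        row = table.iloc[0]
        assert row.coverage == pytest.approx(2 / 3)  # 0.95 and 0.85 of the 3
        assert row.precision == pytest.approx(2 / 3)  # 0.9 is a false positive


class TestPlddtCorrelation:
    def test_exact_linear_relationships(self):
        x = np.linspace(50, 100, 30)
        assert plddt_correlation(x, (x - 50) / 50) == pytest.approx(1.0)
        assert plddt_correlation(x, (100 - x) / 50) == pytest.approx(-1.0)

    def test_constant_vector_is_nan_with_warning(self):
        with pytest.warns(UserWarning):
            r = plddt_correlation(np.full(10, 80.0), np.linspace(0, 1, 10))
        assert np.isnan(r)

    def test_accepts_probability_matrix(self, rng):
        plddt = rng.uniform(50, 100, 40)
        probs = rng.uniform(0, 1, (40, 3))
        r = plddt_correlation(plddt, probs)
        expected = np.corrcoef(plddt, probs.max(axis=1))[0, 1]
        assert r == pytest.approx(expected)
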