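"""Confusion counting, per-class metrics, macro averaging, error series."""

import numpy as np
import pandas as pd
import pytest

from spectraseg.metrics import (aggregate_seeds, confusion_counts,
                                hard_macro_dice, macro_average, metric_table,
                                per_class_metrics, slice_error_series)


def _brute_counts(pred, gt, n_classes):
    out = np.zeros((n_classes, 4), dtype=int)
    for c in range(n_classes):
        p = pred == c
        g = gt == c
        out[c] = [(p & g).sum(), (p & ~g).sum(), (~p & g).sum(),
                  (~p & ~g).sum()]
    return out


@pytest.mark.parametrize("trial", range(50))
def test_confusion_counts_match_brute_force(trial):
    rng = np.random.default_rng(trial)
    pred = rng.integers(0, 13, (10, 10))
    gt = rng.integers(0, 13, (10, 10))
    counts = confusion_counts(pred, gt)
    assert np.array_equal(counts, _brute_counts(pred, gt, 13))
    assert np.all(counts.sum(axis=1) == 100)


def test_perfect_prediction_has_no_errors(rng):
    gt = rng.integers(0, 13, (8, 8))
    counts = confusion_counts(gt, gt)
    assert np.all(counts[:, 1] == 0) and np.all(counts[:, 2] == 0)
    assert hard_macro_dice(gt[None], gt[None]) == 1.0


def test_counts_invariant_to_relabeling_other_classes(rng):
    pred = rng.integers(0, 5, (6, 6))
    gt = rng.integers(0, 5, (6, 6))
    c = 3
    before = confusion_counts(pred, gt, 5)[c]
    swap = {0: 1, 1: 4, 4: 0, 2: 2, 3: 3}
    pred2 = np.vectorize(swap.get)(pred)
    gt2 = np.vectorize(swap.get)(gt)
    assert np.array_equal(before, confusion_counts(pred2, gt2, 5)[c])


class TestPerClassMetrics:
    def test_worked_example(self):
        m = per_class_metrics(np.array([6, 2, 2, 90]), gt_present=True)
        assert np.isclose(m["dice"], 0.75)
        assert np.isclose(m["sensitivity"], 0.75)
        assert np.isclose(m["specificity"], 90 / 92)
        assert np.isclose(m["precision"], 0.75)
        assert np.isclose(m["iou"], 0.6)

    def test_absent_class_no_predictions_all_missing(self):
        m = per_class_metrics(np.array([0, 0, 0, 100]), gt_present=False)
        assert np.isnan(m["dice"]) and np.isnan(m["sensitivity"])
        assert np.isnan(m["precision"]) and np.isnan(m["iou"])
        assert m["specificity"] == 1.0

    def test_absent_class_with_false_positives_scores_zero(self):
        m = per_class_metrics(np.array([0, 4, 0, 96]), gt_present=False)
        assert m["precision"] == 0.0 and m["iou"] == 0.0
        assert np.isnan(m["dice"])

    def test_metric_identities_on_random_counts(self, rng):
        """IoU = Dice/(2-Dice); Sensitivity = Precision when FP == FN."""
        for _ in range(200):
            tp, fp, fn = rng.integers(1, 50, 3)
            tn = 200 - tp - fp - fn
            m = per_class_metrics(np.array([tp, fp, fn, tn]), True)
            assert np.isclose(m["iou"], m["dice"] / (2 - m["dice"]))
            m2 = per_class_metrics(np.array([tp, fp, fp, tn]), True)
            assert np.isclose(m2["sensitivity"], m2["precision"])


class TestMacroAverage:
    def test_omit_missing_slice_values(self):
        rows = []
        for z, d in enumerate([0.8, 0.6, np.nan]):
            rows.append({"slice": z, "class_id": 1, "dice": d,
                         "sensitivity": d, "specificity": 1.0,
                         "precision": d, "iou": d,
                         "gt_present": not np.isnan(d)})
        out = macro_average(pd.DataFrame(rows))
        assert np.isclose(out["per_class"]["dice"][1], 0.7)

    def test_background_and_absent_classes_excluded(self):
        rows = []
        for cid, d, present in [(0, 1.0, True), (1, 0.4, True),
                                (2, 0.8, True), (3, np.nan, False)]:
            rows.append({"slice": 0, "class_id": cid, "dice": d,
                         "sensitivity": d, "specificity": 1.0, "precision": d,
                         "iou": d, "gt_present": present})
        out = macro_average(pd.DataFrame(rows))
        assert np.isclose(out["macro"]["dice"], 0.6)
        assert out["present_classes"] == [1, 2]


class TestSliceErrorSeries:
    def _table(self, dices):
        rows = []
        for z, d in enumerate(dices):
            rows.append({"slice": z, "class_id": 1, "dice": d,
                         "gt_present": True})
        return pd.DataFrame(rows)

    def test_constant_series(self):
        out = slice_error_series(self._table([0.9] * 5), {"grp": {1}})
        assert np.allclose(out["grp"]["errors"], 0.1)
        assert out["grp"]["half_width"] == 0.0

    def test_arithmetic(self):
        out = slice_error_series(self._table([0.9, 0.8, 0.7]), {"grp": {1}})
        assert np.isclose(out["grp"]["mean"], 0.2)
        assert np.isclose(out["grp"]["half_width"], 1.96 * 0.1)

    def test_errors_in_unit_interval_and_empty_group_rejected(self, rng):
        dices = rng.uniform(0, 1, 20)
        out = slice_error_series(self._table(dices), {"grp": {1}})
        assert np.all((out["grp"]["errors"] >= 0)
                      & (out["grp"]["errors"] <= 1))
        with pytest.raises(ValueError):
            slice_error_series(self._table(dices), {"grp": set()})


class TestAggregateSeeds:
    def test_mean_and_sample_sd(self):
        mean, sd = aggregate_seeds([0.70, 0.72, 0.74])
        assert np.isclose(mean, 0.72) and np.isclose(sd, 0.02)

    def test_identical_values_and_permutation_invariance(self):
        assert aggregate_seeds([0.5, 0.5, 0.5])[1] == 0.0
        assert np.allclose(aggregate_seeds([0.1, 0.3, 0.2]),
                           aggregate_seeds([0.3, 0.2, 0.1]))

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            aggregate_seeds([0.7])


def test_metric_table_roundtrip_consistency(rng):
    """Recomputing metrics from the stored counts reproduces the table."""
    pred = rng.integers(0, 5, (3, 12, 12))
    gt = rng.integers(0, 5, (3, 12, 12))
    table = metric_table(pred, gt, n_classes=5)
    for _, row in table.iterrows():
        m = per_class_metrics(
            np.array([row.tp, row.fp, row.fn, row.tn]), row.gt_present)
        for k, v in m.items():
            assert (np.isnan(v) and np.isnan(row[k])) or np.isclose(v, row[k])
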