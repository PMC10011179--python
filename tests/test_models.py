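"""Splitting, classifier training and the evaluation report."""

import numpy as np
import pytest

import hsidrought as hd
from hsidrought.models import ModelReport, SplitSpec


class FixedPredictor:
    """Predicts a stored label sequence; lets tests realize any confusion matrix."""

    def __init__(self, calib_pred, pred_pred):
        self._c = np.asarray(calib_pred)
        self._p = np.asarray(pred_pred)

    def predict(self, X):
        return self._c if len(X) == len(self._c) else self._p


def table1_labels():
    """Per-class pair counts of the study design: 108/105/102."""
    return np.repeat([0, 1, 2], [108, 105, 102])


class TestSplit:
    def test_leaf_level_split_of_630_near_440_190(self):
        y = np.repeat(table1_labels(), 2)  # young + mature leaves
        cal, prd = hd.split(y, SplitSpec(seed=0, group_by_plant=False))
        assert cal.size + prd.size == 630
        assert abs(cal.size - 441) <= 3 and abs(prd.size - 189) <= 3
        for c in (0, 1, 2):
            n_c = np.sum(y == c)
            assert abs(np.sum(y[cal] == c) - 0.7 * n_c) <= 1

    def test_pair_level_split_of_315_near_220_95(self):
        y = table1_labels()
        plants = np.arange(y.size) // 3
        cal, prd = hd.split(y, SplitSpec(seed=1, unit="pair"), groups=plants)
        assert cal.size + prd.size == 315
        assert abs(cal.size - 220) <= 2 and abs(prd.size - 95) <= 2

    def test_groups_never_straddle_the_split(self):
        y = table1_labels()
        plants = np.arange(y.size) // 3
        cal, prd = hd.split(y, SplitSpec(seed=2), groups=plants)
        assert not (set(plants[cal]) & set(plants[prd]))

    def test_disjoint_seeds_give_different_partitions_of_same_size(self):
        y = table1_labels()
        cal1, _ = hd.split(y, SplitSpec(seed=0, group_by_plant=False))
        cal2, _ = hd.split(y, SplitSpec(seed=99, group_by_plant=False))
        assert cal1.size == cal2.size
        assert not np.array_equal(cal1, cal2)

    def test_singleton_class_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            hd.split(np.array([0, 0, 1]), SplitSpec())


class TestTrainers:
    def test_svm_fits_linearly_separable_toy_set(self, rng):
        X = np.vstack([rng.normal(-3, 0.2, (10, 2)), rng.normal(3, 0.2, (10, 2))])
        y = np.repeat([0, 1], 10)
        model = hd.train_svm(X, y)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_single_stump_forest_reproduces_best_split_rule(self, rng):
        # brute-force the optimal stump and compare predictions
        x = np.concatenate([rng.uniform(-2, -1, 10), rng.uniform(1, 2, 10)])
        y = np.repeat([0, 1], 10)
        X = x[:, None]
        model = hd.train_rf(X, y, n_estimators=1, max_depth=1, bootstrap=False, seed=0)
        cuts = np.sort(x)
        best = min(
            ((cut, np.sum((x > cut) != y)) for cut in (cuts[:-1] + cuts[1:]) / 2),
            key=lambda t: t[1])
        grid = np.linspace(-2, 2, 41)[:, None]
        assert np.array_equal(model.predict(grid),
                              (grid.ravel() > best[0]).astype(int))

    def test_densenet_trainer_outputs_three_class_scores(self):
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1, 2], 8)
        X = rng.normal(size=(24, 10)) + y[:, None]
        model = hd.train_densenet1d(X, y, epochs=3)
        assert model.decision_function(X).shape == (24, 3)

    def test_single_class_calibration_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            hd.train_svm(np.zeros((5, 2)), np.zeros(5, int))


class TestEvaluate:
    def test_perfect_predictions_give_all_100(self):
        y = np.repeat([0, 1, 2], 4)
        model = FixedPredictor(y, y)
        rep = hd.evaluate(model, (np.zeros((12, 1)), y), (np.ones((12, 1)), y))
        assert rep.acc_c == 100.0 and rep.acc_p == 100.0
        assert all(rep.f1[c] == 100.0 for c in (0, 1, 2))
        assert np.array_equal(np.diag(rep.confusion), [4, 4, 4])

    def test_two_class_worked_example(self):
        # confusion [[2,0],[1,1]]: precision0 = 2/3, recall0 = 1, F1 = 80%
        yp = np.array([0, 0, 1, 1])
        yhat = np.array([0, 0, 0, 1])
        yc = np.array([0, 1])
        model = FixedPredictor(yc, yhat)
        rep = hd.evaluate(model, (np.zeros((2, 1)), yc), (np.ones((4, 1)), yp))
        assert np.isclose(rep.precision[0], 200 / 3)
        assert rep.recall[0] == 100.0
        assert np.isclose(rep.f1[0], 80.0)

    def test_f1_is_harmonic_mean_identity(self, rng):
        for _ in range(10):
            yp = rng.integers(0, 3, 30)
            yhat = rng.integers(0, 3, 30)
            if np.unique(yp).size < 3:
                continue
            model = FixedPredictor(yp, yhat)
            rep = hd.evaluate(model, (np.zeros((30, 1)), yp), (np.ones((30, 1)), yp))
            for c, f in rep.f1.items():
                p, r = rep.precision[c], rep.recall[c]
                if f is None or p is None:
                    continue
                expected = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
                assert np.isclose(f, expected)

    def test_absent_class_flagged_not_zeroed(self):
        yc = np.repeat([0, 1, 2], 4)
        yp = np.repeat([0, 1], 3)  # class 2 missing from prediction set
        model = FixedPredictor(yc, yp)
        rep = hd.evaluate(model, (np.zeros((12, 1)), yc), (np.ones((6, 1)), yp),
                          classes=np.array([0, 1, 2]))
        assert rep.precision[2] is None
        assert any("class 2" in f for f in rep.flags)

    def test_random_scores_give_chance_auc(self):
        aucs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = rng.integers(0, 2, 60)

            class RandomScore:
                def predict(self, X):
                    return rng.integers(0, 2, len(X))

                def decision_function(self, X):
                    return rng.normal(size=len(X))

            rep = hd.evaluate(RandomScore(), (np.zeros((60, 1)), y),
                              (np.ones((60, 1)), y))
            if 1 in rep.roc:
                aucs.append(rep.roc[1]["auc"])
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_report_round_trips_through_json(self, tmp_path, rng):
        yp = np.repeat([0, 1, 2], 5)
        yhat = rng.integers(0, 3, 15)
        model = FixedPredictor(yp, yhat)
        rep = hd.evaluate(model, (np.zeros((15, 1)), yp), (np.ones((15, 1)), yp))
        path = tmp_path / "report.json"
        rep.to_json(str(path))
        import json

        back = ModelReport.from_dict(json.load(open(path)))
        assert back.acc_p == rep.acc_p
        assert np.array_equal(back.confusion, rep.confusion)
        assert back.precision == rep.precision

    def test_confusion_csv_matches_report(self, tmp_path):
        yp = np.repeat([0, 1, 2], 4)
        model = FixedPredictor(np.array([0, 1]), yp)
        rep = hd.evaluate(model, (np.zeros((2, 1)), np.array([0, 1])),
                          (np.ones((12, 1)), yp))
        rep.write_csvs(str(tmp_path / "rep"))
        import csv

        rows = list(csv.reader(open(tmp_path / "rep_confusion.csv")))
        body = np.array([[int(v) for v in r[1:]] for r in rows[1:]])
        assert np.array_equal(body, rep.confusion)
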