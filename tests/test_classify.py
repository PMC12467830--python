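"""Session-split classification: PCA, grids, mode voting, metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srk.classify import (
    CLASS_LABELS,
    ClassifierSpec,
    LeakageError,
    PredictionSeries,
    Session,
    SessionSplit,
    WindowVote,
    _grid,
    build_feature_matrix,
    evaluate,
    fit_pca,
    mode_vote,
    predict_epochs,
    tune_and_train,
)
from srk.spectral import ANALYSIS_BANDS, FeatureTable


def _table(rng, n_epochs, shift=0.0):
    values = rng.normal(shift, 1.0, (n_epochs, 366))
    from srk.montage import CHANNELS_61

    return FeatureTable(values=values, channel_labels=CHANNELS_61,
                        band_names=ANALYSIS_BANDS, units="z")


def _session(rng, sid="s", shift=1.0, n=40):
    tables = {"S1": _table(rng, n), "R1": _table(rng, n),
              "K1": _table(rng, n, shift=shift)}
    s = build_feature_matrix(tables)
    s.session_id = sid
    return s


class TestFeatureMatrix:
    def test_shape_and_labels(self, rng):
        s = _session(rng, n=40)
        assert s.X.shape == (120, 366)
        assert list(s.y[:80]) == ["SR"] * 80
        assert list(s.y[80:]) == ["K"] * 40

    def test_skill_and_rule_both_map_to_sr(self, rng):
        tables = {"S2": _table(rng, 5), "R2": _table(rng, 5)}
        s = build_feature_matrix(tables)
        assert set(s.y) == {"SR"}

    def test_unknown_condition_rejected(self, rng):
        with pytest.raises(ValueError):
            build_feature_matrix({"REF": _table(rng, 5)})


class TestPCA:
    def test_component_count_for_known_variance_shares(self, rng):
        # rank-3 data with variance shares exactly (0.7, 0.2, 0.1)
        n = 3000
        basis = np.linalg.qr(rng.standard_normal((10, 3)))[0]
        scores = rng.standard_normal((n, 3))
        scores = (scores - scores.mean(0)) / scores.std(0)
        scores *= np.sqrt(np.array([0.7, 0.2, 0.1]) * n / (n - 1))
        X = scores @ basis.T
        assert fit_pca(X, 0.90).n_components == 2
        assert fit_pca(X, 0.95).n_components == 3

    def test_threshold_one_keeps_rank(self, rng):
        X = rng.standard_normal((50, 4)) @ rng.standard_normal((4, 20))
        red = fit_pca(X, 1.0)
        assert red.n_components == np.linalg.matrix_rank(X - X.mean(0))

    def test_matches_bruteforce_eigendecomposition(self, rng):
        """Component count equals an explicit cumulative-variance scan."""
        for _ in range(10):
            X = rng.standard_normal((60, 15))
            Xc = X - X.mean(0)
            w = np.sort(np.linalg.eigvalsh(Xc.T @ Xc))[::-1]
            shares = np.cumsum(w) / w.sum()
            threshold = rng.uniform(0.5, 0.99)
            expected = int(np.searchsorted(shares, threshold - 1e-12) + 1)
            assert fit_pca(X, threshold).n_components == expected

    def test_invalid_threshold(self, rng):
        with pytest.raises(ValueError):
            fit_pca(rng.standard_normal((5, 3)), 1.5)


class TestGrids:
    def test_knn_grid_metrics(self):
        _, grid = _grid("KNN", 50, 0, None)
        assert set(grid["metric"]) == {"euclidean", "manhattan", "minkowski",
                                       "chebyshev"}
        assert set(grid["weights"]) == {"uniform", "distance"}

    def test_dt_criterion_options(self):
        _, grid = _grid("DT", 50, 0, None)
        assert set(grid["criterion"]) == {"gini", "entropy"}

    def test_rf_easy_tunes_only_estimators_and_depth(self):
        _, grid = _grid("RF-Easy", 50, 0, None)
        assert set(grid) == {"n_estimators", "max_depth"}

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            ClassifierSpec(family="SVM")


class TestTraining:
    def test_leakage_guard(self, rng):
        s = _session(rng, sid="same")
        with pytest.raises(LeakageError):
            SessionSplit(train=s, test=s)

    def test_single_class_training_rejected(self, rng):
        train = build_feature_matrix({"S1": _table(rng, 20)})
        train.session_id = "a"
        test = _session(rng, sid="b")
        red = fit_pca(train.X, 0.9)
        with pytest.raises(ValueError, match="one class"):
            tune_and_train(ClassifierSpec(family="KNN"),
                           SessionSplit(train=train, test=test), red)

    def test_separable_classes_predicted_accurately(self, rng):
        train = _session(rng, sid="a", shift=3.0)
        test = _session(rng, sid="b", shift=3.0)
        split = SessionSplit(train=train, test=test)
        red = fit_pca(train.X, 0.9)
        model = tune_and_train(ClassifierSpec(family="KNN", seed=0, n_iter=10),
                               split, red)
        series = predict_epochs(model, red, test)
        assert (series.predicted == series.true).mean() > 0.9
        assert len(series) == len(test.y)


# --- mode voting ------------------------------------------------------------


def brute_force_mode(labels):
    """Counting oracle with the most-recent-epoch tie rule."""
    counts = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    best = max(counts.values())
    for lab in reversed(labels):
        if counts[lab] == best:
            return lab


class TestModeVote:
    def test_window_one_is_identity(self, rng):
        pred = rng.choice(CLASS_LABELS, 50)
        s = PredictionSeries(predicted=pred, true=pred.copy())
        out = mode_vote(s, WindowVote(1))
        assert np.array_equal(out.predicted, s.predicted)

    def test_hand_example(self):
        s = PredictionSeries(predicted=np.array(["K", "K", "SR", "K", "SR"]),
                             true=np.array(["K"] * 5))
        out = mode_vote(s, WindowVote(3))
        assert list(out.predicted) == ["K", "K", "SR"]

    def test_output_length(self, rng):
        pred = rng.choice(CLASS_LABELS, 40)
        s = PredictionSeries(predicted=pred, true=pred.copy())
        for w in (1, 5, 35, 40):
            assert len(mode_vote(s, WindowVote(w))) == 40 - w + 1

    def test_window_longer_than_series_rejected(self, rng):
        pred = rng.choice(CLASS_LABELS, 10)
        s = PredictionSeries(predicted=pred, true=pred.copy())
        with pytest.raises(ValueError):
            mode_vote(s, WindowVote(11))

    def test_matches_bruteforce_oracle_on_random_series(self, rng):
        """1,000 random series against the counting oracle."""
        for _ in range(1000):
            n = int(rng.integers(2, 30))
            w = int(rng.integers(1, n + 1))
            pred = rng.choice(CLASS_LABELS, n)
            true = rng.choice(CLASS_LABELS, n)
            out = mode_vote(PredictionSeries(predicted=pred, true=true),
                            WindowVote(w))
            for i in range(n - w + 1):
                assert out.predicted[i] == brute_force_mode(list(pred[i:i + w]))
                assert out.true[i] == brute_force_mode(list(true[i:i + w]))


@given(st.lists(st.sampled_from(CLASS_LABELS), min_size=1, max_size=20),
       st.integers(1, 20))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_mode_vote_property(labels, w):
    if w > len(labels):
        return
    pred = np.array(labels, dtype=object)
    s = PredictionSeries(predicted=pred, true=pred.copy())
    out = mode_vote(s, WindowVote(w))
    assert out.predicted[0] == brute_force_mode(labels[:w])


# --- metrics ----------------------------------------------------------------


class TestEvaluate:
    def _series(self, tp, tn, fp, fn):
        pred = ["K"] * tp + ["SR"] * tn + ["K"] * fp + ["SR"] * fn
        true = ["K"] * tp + ["SR"] * tn + ["SR"] * fp + ["K"] * fn
        return PredictionSeries(predicted=np.array(pred), true=np.array(true))

    def test_hand_confusion_matrix(self):
        rep = evaluate(self._series(tp=4, tn=5, fp=1, fn=2))
        assert rep.accuracy == pytest.approx(0.75)
        assert rep.precision["K"] == pytest.approx(0.8)
        assert rep.recall["K"] == pytest.approx(2 / 3)
        assert rep.specificity["K"] == pytest.approx(rep.recall["SR"])
        assert (rep.tn, rep.fp, rep.fn, rep.tp) == (5, 1, 2, 4)

    def test_perfect_predictions(self):
        rep = evaluate(self._series(tp=5, tn=5, fp=0, fn=0))
        assert rep.accuracy == 1.0
        assert all(v == 1.0 for v in rep.f1.values())

    def test_class_role_symmetry(self):
        rep = evaluate(self._series(tp=4, tn=5, fp=1, fn=2))
        swapped = evaluate(self._series(tp=5, tn=4, fp=2, fn=1))
        assert rep.precision["K"] == pytest.approx(swapped.precision["SR"])
        assert rep.recall["K"] == pytest.approx(swapped.recall["SR"])

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            evaluate(PredictionSeries(predicted=np.array([]),
                                      true=np.array([])))

    def test_report_dict_has_table_fields(self):
        d = evaluate(self._series(tp=4, tn=5, fp=1, fn=2)).to_dict()
        for key in ("Precision 0", "Precision 1", "Recall 0", "Recall 1",
                    "Specificity 0", "Specificity 1", "F1-score 0",
                    "F1-score 1", "Accuracy"):
            assert key in d
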