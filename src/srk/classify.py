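"""Intra-subject (S+R) vs K classification with windowed mode voting.

Protocol: each subject contributes two session pairs (one S-R session
plus one K session each).  One pair trains and tunes the model, the
other is held out for testing — session-level disjointness rules out
temporal leakage.  Features (61 channels x 6 bands = 366 REF-z-scored
band powers per 1-s epoch) are reduced by PCA fitted on the training
pair at a cumulative-explained-variance threshold (default 0.90), then
classified by one of five model families tuned over their printed
hyperparameter grids.  Per-epoch predictions are smoothed by the mode
over overlapping windows of 1-35 epochs (step 1), and the confusion
matrix yields per-class precision/recall/specificity/F1 and overall
accuracy (class 0 = SR, class 1 = K).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats
from sklearn.base import clone
from sklearn.decomposition import PCA
from sklearn.model_selection import RandomizedSearchCV, StratifiedKFold

logger = logging.getLogger(__name__)

CLASS_LABELS = ("SR", "K")      # class 0, class 1
FAMILIES = ("DT", "RF", "RF-Easy", "KNN", "XGB")

_DEFAULT_N_ITER = {"DT": 40, "RF": 40, "RF-Easy": 20, "KNN": 30, "XGB": 40}
_MAX_N_ITER = 200               # hard cap on sampled grid points


class LeakageError(RuntimeError):
    """Train and test share a session — the protocol forbids this."""


@dataclass
class Session:
    """One recorded session's epoch features and labels, in epoch order."""

    X: np.ndarray                # (n_epochs, n_features)
    y: np.ndarray                # "SR" / "K" per epoch
    session_id: str

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=object)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("feature rows and labels differ in length")


@dataclass
class SessionSplit:
    """A train pair and a disjoint held-out test pair for one subject."""

    train: Session
    test: Session
    subject_id: str = ""

    def __post_init__(self):
        if self.train.session_id == self.test.session_id:
            raise LeakageError(
                f"train and test both use session {self.train.session_id!r}"
            )


@dataclass(frozen=True)
class ClassifierSpec:
    """Model family plus tuning settings (grids follow the printed tables)."""

    family: str = "KNN"
    n_iter: int | None = None
    cv_folds: int = 5
    seed: int = 0
    class_weight: str | None = None     # optional imbalance handling, off by default

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")


@dataclass
class PCAReducer:
    """PCA keeping the fewest components reaching the variance threshold."""

    threshold: float
    n_components: int
    mean_: np.ndarray
    components_: np.ndarray
    explained_variance_ratio_: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean_) @ self.components_.T


@dataclass
class PredictionSeries:
    """Per-epoch (or per-window) predicted and true labels, order preserved."""

    predicted: np.ndarray
    true: np.ndarray

    def __post_init__(self):
        self.predicted = np.asarray(self.predicted, dtype=object)
        self.true = np.asarray(self.true, dtype=object)
        if self.predicted.shape != self.true.shape:
            raise ValueError("prediction and truth lengths differ")

    def __len__(self) -> int:
        return self.predicted.size


@dataclass(frozen=True)
class WindowVote:
    """Overlapping mode-vote window: size w epochs, step 1, last-epoch ties."""

    size: int

    def __post_init__(self):
        if self.size < 1:
            raise ValueError("window size must be >= 1")


@dataclass
class MetricsReport:
    """Confusion matrix and classical per-class metrics (class 1 = K)."""

    tn: int
    fp: int
    fn: int
    tp: int
    accuracy: float
    precision: dict = field(default_factory=dict)    # per class label
    recall: dict = field(default_factory=dict)
    specificity: dict = field(default_factory=dict)
    f1: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {"TN": self.tn, "FP": self.fp, "FN": self.fn, "TP": self.tp,
               "Accuracy": self.accuracy}
        for name, d in (("Precision", self.precision), ("Recall", self.recall),
                        ("Specificity", self.specificity), ("F1-score", self.f1)):
            for cls_idx, cls in enumerate(CLASS_LABELS):
                out[f"{name} {cls_idx}"] = d[cls]
        return out


# ---------------------------------------------------------------------------
# feature assembly

def build_feature_matrix(features_by_condition: dict,
                         merge_skill_rule: bool = True) -> Session:
    """Stack per-condition feature tables into one labelled session matrix.

    ``features_by_condition`` maps condition name (e.g. "S1") to a
    :class:`~srk.spectral.FeatureTable`; Skill/Rule epochs are labelled
    "SR" and Knowledge epochs "K" (the binary protocol).  With
    ``merge_skill_rule=False`` the original three levels "S"/"R"/"K" are
    kept, which runs the same machinery as a 3-class problem.  All 61
    channels are expected on this path (no channel exclusion).
    """
    from .simulate import CLASS_OF_CONDITION

    blocks, labels = [], []
    n_feat = None
    for cond, table in features_by_condition.items():
        if cond not in CLASS_OF_CONDITION:
            raise ValueError(f"unknown condition {cond!r}")
        if n_feat is None:
            n_feat = table.n_features
        elif table.n_features != n_feat:
            raise ValueError("feature dimensionality differs across conditions")
        blocks.append(table.values)
        label = CLASS_OF_CONDITION[cond] if merge_skill_rule else cond[0]
        labels.extend([label] * table.values.shape[0])
    X = np.vstack(blocks)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values (degenerate features present?)")
    sid = "+".join(features_by_condition)
    return Session(X=X, y=np.array(labels, dtype=object), session_id=sid)


# ---------------------------------------------------------------------------
# PCA

def fit_pca(X_train: np.ndarray, threshold: float = 0.90) -> PCAReducer:
    """Fit PCA on training rows; keep the smallest k with cumvar >= threshold."""
    if not 0 < threshold <= 1:
        raise ValueError("variance threshold must lie in (0, 1]")
    if X_train.shape[0] < 2:
        raise ValueError("PCA needs at least 2 training rows")
    pca = PCA(svd_solver="full").fit(X_train)
    ratios = pca.explained_variance_ratio_
    cum = np.cumsum(ratios)
    k = int(np.searchsorted(cum, threshold - 1e-12) + 1)
    k = min(k, ratios.size)
    return PCAReducer(
        threshold=threshold,
        n_components=k,
        mean_=pca.mean_,
        components_=pca.components_[:k],
        explained_variance_ratio_=ratios[:k],
    )


# ---------------------------------------------------------------------------
# model zoo with the printed grids

def _grid(family: str, n_features: int, seed: int, class_weight):
    """Estimator + hyperparameter distributions per family."""
    rng_int = lambda lo, hi: _scipy_stats.randint(lo, hi + 1)
    if family == "DT":
        from sklearn.tree import DecisionTreeClassifier

        est = DecisionTreeClassifier(random_state=seed, class_weight=class_weight)
        grid = {
            "criterion": ["gini", "entropy"],
            "max_depth": rng_int(2, 100),
            "min_samples_split": rng_int(5, 300),
            "min_samples_leaf": rng_int(5, 200),
            "max_leaf_nodes": rng_int(2, 20),
            "max_features": rng_int(2, max(2, min(61, n_features))),
            "min_impurity_decrease": _scipy_stats.loguniform(5e-5, 0.01),
        }
    elif family in ("RF", "RF-Easy"):
        from sklearn.ensemble import RandomForestClassifier

        est = RandomForestClassifier(random_state=seed, class_weight=class_weight)
        grid = {
            "n_estimators": rng_int(1, 100),
            "max_depth": rng_int(2, 100),
        }
        if family == "RF":
            grid.update({
                "criterion": ["gini", "entropy"],
                "min_samples_split": rng_int(5, 100),
                "min_samples_leaf": rng_int(5, 100),
                "max_leaf_nodes": rng_int(2, 20),
                "max_features": rng_int(2, max(2, min(60, n_features))),
                "min_impurity_decrease": _scipy_stats.loguniform(5e-5, 0.01),
            })
    elif family == "KNN":
        from sklearn.neighbors import KNeighborsClassifier

        est = KNeighborsClassifier()
        grid = {
            "n_neighbors": rng_int(5, 100),
            "weights": ["uniform", "distance"],
            "leaf_size": rng_int(2, 150),
            "metric": ["euclidean", "manhattan", "minkowski", "chebyshev"],
        }
    elif family == "XGB":
        from xgboost import XGBClassifier

        est = XGBClassifier(random_state=seed, n_jobs=1, verbosity=0,
                            eval_metric="logloss")
        grid = {
            "learning_rate": _scipy_stats.loguniform(0.001, 0.3),
            "n_estimators": rng_int(2, 120),
            "booster": ["gbtree", "dart"],
            "gamma": _scipy_stats.uniform(0, 6),
            "subsample": _scipy_stats.uniform(0.1, 0.8),
            "colsample_bytree": _scipy_stats.uniform(0.1, 0.8),
            "reg_alpha": _scipy_stats.loguniform(5e-5, 100),
            "max_depth": rng_int(2, 20),
        }
    else:
        raise ValueError(f"unknown family {family!r}")
    return est, grid


def tune_and_train(spec: ClassifierSpec, split: SessionSplit,
                   reducer: PCAReducer):
    """Randomized search (stratified k-fold) on the training pair, then refit.

    Tuning never touches the test pair; the best configuration is refit
    on all training epochs in the reduced feature space.
    """
    y_train = split.train.y
    classes = np.unique(y_train.astype(str))
    if classes.size < 2:
        raise ValueError("degenerate split: training pair contains one class")
    Xt = reducer.transform(split.train.X)
    yt = np.searchsorted(classes, y_train.astype(str))
    est, grid = _grid(spec.family, Xt.shape[1], spec.seed, spec.class_weight)
    n_iter = min(spec.n_iter or _DEFAULT_N_ITER[spec.family], _MAX_N_ITER)
    cv = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True,
                         random_state=spec.seed)
    search = RandomizedSearchCV(
        est, grid, n_iter=n_iter, cv=cv, scoring="accuracy",
        random_state=spec.seed, n_jobs=1, error_score=0.0, refit=False,
    )
    search.fit(Xt, yt)
    logger.info("%s best CV accuracy %.3f with %s", spec.family,
                search.best_score_, search.best_params_)
    model = clone(est).set_params(**search.best_params_)
    model.fit(Xt, yt)
    model.srk_classes_ = classes
    return model


def predict_epochs(model, reducer: PCAReducer, test: Session) -> PredictionSeries:
    """Per-epoch predictions on the held-out session, chronological order."""
    Xr = reducer.transform(test.X)
    if Xr.shape[1] != reducer.n_components:
        raise ValueError("feature dimension mismatch after reduction")
    yhat = model.predict(Xr)
    classes = getattr(model, "srk_classes_", np.array(sorted(CLASS_LABELS)))
    predicted = np.array([classes[int(v)] for v in yhat], dtype=object)
    return PredictionSeries(predicted=predicted, true=test.y.copy())


# ---------------------------------------------------------------------------
# windowed voting and metrics

def _window_mode(labels: np.ndarray) -> object:
    """Most frequent label; ties go to the window's most recent epoch."""
    values, counts = np.unique(labels.astype(str), return_counts=True)
    best = counts.max()
    winners = set(values[counts == best])
    if len(winners) == 1:
        return next(iter(winners))
    for lab in labels[::-1]:
        if lab in winners:
            return lab
    raise AssertionError("unreachable")


def mode_vote(series: PredictionSeries, vote: WindowVote) -> PredictionSeries:
    """Mode-vote predictions (and truths) over overlapping windows, step 1."""
    w = vote.size
    n = len(series)
    if w > n:
        raise ValueError(f"window size {w} exceeds series length {n}")
    if w == 1:
        return PredictionSeries(predicted=series.predicted.copy(),
                                true=series.true.copy())
    pred = np.empty(n - w + 1, dtype=object)
    true = np.empty(n - w + 1, dtype=object)
    for i in range(n - w + 1):
        pred[i] = _window_mode(series.predicted[i:i + w])
        true[i] = _window_mode(series.true[i:i + w])
    return PredictionSeries(predicted=pred, true=true)


def evaluate(series: PredictionSeries) -> MetricsReport:
    """Confusion matrix and per-class metrics; class 0 = SR, class 1 = K."""
    if len(series) == 0:
        raise ValueError("empty prediction series")
    pos = CLASS_LABELS[1]
    t = series.true == pos
    p = series.predicted == pos
    tp = int(np.sum(t & p))
    tn = int(np.sum(~t & ~p))
    fp = int(np.sum(~t & p))
    fn = int(np.sum(t & ~p))
    n = tp + tn + fp + fn

    def _safe(num, den):
        return num / den if den else 0.0

    precision = {CLASS_LABELS[1]: _safe(tp, tp + fp),
                 CLASS_LABELS[0]: _safe(tn, tn + fn)}
    recall = {CLASS_LABELS[1]: _safe(tp, tp + fn),
              CLASS_LABELS[0]: _safe(tn, tn + fp)}
    specificity = {CLASS_LABELS[1]: recall[CLASS_LABELS[0]],
                   CLASS_LABELS[0]: recall[CLASS_LABELS[1]]}
    f1 = {c: _safe(2 * precision[c] * recall[c], precision[c] + recall[c])
          for c in CLASS_LABELS}
    return MetricsReport(tn=tn, fp=fp, fn=fn, tp=tp,
                         accuracy=_safe(tp + tn, n),
                         precision=precision, recall=recall,
                         specificity=specificity, f1=f1)


# ---------------------------------------------------------------------------
# full comparison protocol

def run_subject(pair_train: Session, pair_test: Session, family: str = "KNN",
                windows=range(1, 36), pca_threshold: float = 0.90,
                seed: int = 0, n_iter: int | None = None):
    """Train on one session pair, test on the other, sweep window sizes.

    Returns ``(accuracies, epoch_series, model, reducer)`` where
    ``accuracies`` maps window size to windowed accuracy.
    """
    split = SessionSplit(train=pair_train, test=pair_test)
    reducer = fit_pca(split.train.X, pca_threshold)
    spec = ClassifierSpec(family=family, seed=seed, n_iter=n_iter)
    model = tune_and_train(spec, split, reducer)
    series = predict_epochs(model, reducer, split.test)
    acc = {}
    for w in windows:
        if w > len(series):
            break
        acc[w] = evaluate(mode_vote(series, WindowVote(w))).accuracy
    return acc, series, model, reducer


def run_comparison(subjects: dict, families=FAMILIES, windows=range(1, 36),
                   pca_threshold: float = 0.90, seed: int = 0,
                   n_iter: int | None = None) -> pd.DataFrame:
    """Run the full protocol for every subject and family.

    ``subjects`` maps subject id to a ``(train_pair, test_pair)`` tuple of
    :class:`Session` objects.  Returns a long DataFrame with columns
    subject, family, window, accuracy; incomplete subjects are skipped
    with a warning.
    """
    rows = []
    for subject, pairs in subjects.items():
        if len(pairs) != 2 or pairs[0] is None or pairs[1] is None:
            logger.warning("subject %s incomplete; excluded", subject)
            continue
        for family in families:
            acc, *_ = run_subject(pairs[0], pairs[1], family=family,
                                  windows=windows, pca_threshold=pca_threshold,
                                  seed=seed, n_iter=n_iter)
            rows.extend({"subject": subject, "family": family,
                         "window": w, "accuracy": a} for w, a in acc.items())
    return pd.DataFrame(rows, columns=["subject", "family", "window", "accuracy"])


def window_means(surface: pd.DataFrame) -> pd.DataFrame:
    """Per-family, per-window mean accuracy over subjects."""
    return (surface.groupby(["family", "window"], as_index=False)["accuracy"]
            .mean())
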