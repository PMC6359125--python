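"""Supervised and unsupervised classifier benchmarking under
leave-one-out cross-validation (LOOCV).

Seven models: K-NN (Euclidean), CART decision tree (Gini), random
forest, Gaussian Naïve Bayes, SVM (linear or polynomial kernel), and —
unsupervised — 2-cluster K-means and a 2-component Gaussian mixture.
Every model sees z-score-standardized features, with the statistics
computed on the training fold only.  Unsupervised models are fit on the
training features without labels; their clusters are mapped to class
labels by the permutation maximizing training accuracy, and the held-out
record is assigned to the nearest centroid / max-responsibility
component.

K-NN ties (possible with even K) are broken by the label of the single
nearest neighbour, keeping predictions deterministic.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier
from sklearn.mixture import GaussianMixture
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .types import FeatureTable, ValidationError

__all__ = [
    "ClassifierSpec",
    "PredictionSet",
    "loocv_predict",
    "grid_search",
    "map_clusters",
    "under_sample",
    "SUPERVISED_MODELS",
    "UNSUPERVISED_MODELS",
]

SUPERVISED_MODELS = ("knn", "cart", "rf", "nb", "svm")
UNSUPERVISED_MODELS = ("kmeans", "gmm")


@dataclass
class ClassifierSpec:
    """A named model with its resolved hyperparameters.

    params keys by model: knn: ``k``; rf: ``n_trees``; svm: ``kernel``
    ("linear"/"poly"), ``degree``, ``C``; gmm: ``covariance``
    ("full"/"diag"); cart, nb, kmeans: none.
    """

    name: str
    params: dict = field(default_factory=dict)
    grid: dict | None = None     # param name -> iterable of candidate values
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in SUPERVISED_MODELS + UNSUPERVISED_MODELS:
            raise ValidationError(f"unknown classifier {self.name!r}")

    @property
    def is_supervised(self) -> bool:
        return self.name in SUPERVISED_MODELS


@dataclass
class PredictionSet:
    record_ids: list[str]
    y_true: np.ndarray
    y_pred: np.ndarray
    fold: np.ndarray
    manifest: list[dict] = field(default_factory=list)  # resolved params per fold

    def __post_init__(self) -> None:
        self.y_true = np.asarray(self.y_true)
        self.y_pred = np.asarray(self.y_pred)
        self.fold = np.asarray(self.fold, dtype=int)
        if not (len(self.record_ids) == self.y_true.size == self.y_pred.size == self.fold.size):
            raise ValidationError("prediction set arrays must share one length")

    @property
    def accuracy(self) -> float:
        """Proportion correct, in percent."""
        return float(100.0 * np.mean(self.y_true == self.y_pred))


def _standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (train - mu) / sd, (test - mu) / sd


def map_clusters(assignments: np.ndarray, labels: np.ndarray) -> dict[int, object]:
    """Best cluster→class bijection by training accuracy (brute force
    over permutations).  An empty cluster maps to the majority class."""
    assignments = np.asarray(assignments)
    labels = np.asarray(labels)
    clusters = np.unique(assignments)
    classes = list(np.unique(labels))
    majority = max(classes, key=lambda c: np.sum(labels == c))
    best_map, best_acc = None, -1.0
    for perm in itertools.permutations(classes):
        m = {int(c): perm[i % len(perm)] for i, c in enumerate(clusters)}
        acc = np.mean([m[int(a)] == l for a, l in zip(assignments, labels)])
        if acc > best_acc:
            best_acc, best_map = acc, m
    out = dict(best_map)
    for c in range(2):  # cover clusters absent from training assignments
        out.setdefault(c, majority)
    return out


def _predict_knn(Xtr, ytr, Xte, k: int) -> np.ndarray:
    nn = NearestNeighbors(n_neighbors=min(k, len(Xtr)), metric="euclidean").fit(Xtr)
    _, idx = nn.kneighbors(Xte)
    preds = []
    for row in idx:
        votes = ytr[row]
        classes, counts = np.unique(votes, return_counts=True)
        winners = classes[counts == counts.max()]
        preds.append(winners[0] if winners.size == 1 else votes[0])  # votes[0] = nearest
    return np.asarray(preds)


def _fit_predict(spec: ClassifierSpec, Xtr, ytr, Xte) -> np.ndarray:
    p = spec.params
    if spec.name == "knn":
        return _predict_knn(Xtr, ytr, Xte, int(p.get("k", 5)))
    if spec.name == "cart":
        m = DecisionTreeClassifier(criterion="gini", random_state=spec.seed)
    elif spec.name == "rf":
        m = RandomForestClassifier(n_estimators=int(p.get("n_trees", 100)),
                                   criterion="gini", random_state=spec.seed)
    elif spec.name == "nb":
        m = GaussianNB()
    elif spec.name == "svm":
        m = SVC(kernel=p.get("kernel", "linear"), degree=int(p.get("degree", 3)),
                C=float(p.get("C", 1.0)), gamma="scale", random_state=spec.seed)
    elif spec.name == "kmeans":
        km = KMeans(n_clusters=2, n_init=10, random_state=spec.seed).fit(Xtr)
        mapping = map_clusters(km.labels_, ytr)
        return np.asarray([mapping[int(c)] for c in km.predict(Xte)])
    elif spec.name == "gmm":
        cov = {"full": "full", "diag": "diag", "diagonal": "diag"}[p.get("covariance", "full")]
        gm = GaussianMixture(n_components=2, covariance_type=cov, n_init=5,
                             random_state=spec.seed, reg_covar=1e-6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gm.fit(Xtr)
            mapping = map_clusters(gm.predict(Xtr), ytr)
            return np.asarray([mapping[int(c)] for c in gm.predict(Xte)])
    else:  # pragma: no cover
        raise ValidationError(spec.name)
    m.fit(Xtr, ytr)
    return m.predict(Xte)


def loocv_predict(
    table: FeatureTable,
    spec: ClassifierSpec,
    features: Sequence[str] | None = None,
    grouping: str = "record",
    standardize: bool = True,
    feature_selector=None,
) -> PredictionSet:
    """Leave-one-out predictions.

    With ``grouping="record"`` each record is held out in turn; with
    ``"subject"`` all records of one subject are held out together
    (leakage-free subject-level evaluation).  ``feature_selector``, when
    given, is called per fold with the training-rows FeatureTable and
    returns the feature ids to use — nested, leakage-free selection;
    it overrides ``features``.
    """
    if grouping not in ("record", "subject"):
        raise ValidationError(f"unknown grouping {grouping!r}")
    df = table.data
    if len(df) < 3:
        raise ValidationError("LOOCV requires at least 3 records")
    y = table.y
    groups = df["subject_id"].to_numpy() if grouping == "subject" else df["record_id"].to_numpy()
    unique_groups = list(dict.fromkeys(groups))

    rec_ids, y_true, y_pred, folds, manifest = [], [], [], [], []
    for fold_i, g in enumerate(unique_groups):
        test = groups == g
        train = ~test
        if np.unique(y[train]).size < 2:
            raise ValidationError(
                f"training fold {fold_i} (held-out {g!r}) collapsed to one class"
            )
        fold_features = features
        if feature_selector is not None:
            fold_features = feature_selector(FeatureTable(df.loc[train].copy()))
        X = table.X(fold_features)
        Xtr, Xte = (X[train], X[test])
        if standardize:
            Xtr, Xte = _standardize(Xtr, Xte)
        preds = _fit_predict(spec, Xtr, y[train], Xte)
        rec_ids.extend(df.loc[test, "record_id"])
        y_true.extend(y[test])
        y_pred.extend(preds)
        folds.extend([fold_i] * int(test.sum()))
        manifest.append({"fold": fold_i, "held_out": str(g),
                         "model": spec.name, **spec.params, "seed": spec.seed,
                         "features": list(fold_features) if fold_features is not None else "all"})
    return PredictionSet(rec_ids, np.asarray(y_true), np.asarray(y_pred),
                         np.asarray(folds), manifest)


def _complexity_key(spec: ClassifierSpec) -> tuple:
    """Sort key preferring the simpler model on accuracy ties."""
    p = spec.params
    return (p.get("k", 0), p.get("n_trees", 0), p.get("degree", 0), p.get("C", 0))


def grid_search(
    table: FeatureTable,
    spec: ClassifierSpec,
    features: Sequence[str] | None = None,
    grouping: str = "record",
) -> tuple[ClassifierSpec, float]:
    """Exhaustive grid search maximizing LOOCV accuracy.

    Returns the winning spec (grid cleared, params resolved) and its
    accuracy in percent.  Ties go to the simpler model: smaller K,
    fewer trees, lower kernel degree.
    """
    if not spec.grid:
        raise ValidationError("grid_search requires a non-empty grid")
    names = sorted(spec.grid)
    candidates = []
    for values in itertools.product(*(spec.grid[n] for n in names)):
        params = dict(spec.params)
        params.update(dict(zip(names, values)))
        candidates.append(replace(spec, params=params, grid=None))
    candidates.sort(key=_complexity_key)
    best, best_acc = None, -1.0
    for cand in candidates:
        acc = loocv_predict(table, cand, features=features, grouping=grouping).accuracy
        if acc > best_acc:  # strict: first (simplest) winner kept on ties
            best, best_acc = cand, acc
    return best, best_acc


def under_sample(table: FeatureTable, seed: int = 0) -> FeatureTable:
    """Random under-sampling: every class is reduced (without
    replacement) to the minority-class count; row order is then
    shuffled deterministically."""
    df = table.data
    counts = df["label"].value_counts()
    if len(counts) < 2:
        raise ValidationError("under-sampling requires at least 2 classes")
    n_min = int(counts.min())
    rng = np.random.default_rng(seed)
    keep_idx = []
    for label in sorted(counts.index):
        idx = df.index[df["label"] == label].to_numpy()
        keep_idx.extend(rng.choice(idx, size=n_min, replace=False))
    keep_idx = np.asarray(keep_idx)
    rng.shuffle(keep_idx)
    return FeatureTable(df.loc[keep_idx].reset_index(drop=True))
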