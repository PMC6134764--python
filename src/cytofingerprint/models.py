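"""The four supervised classifiers and their cross-validation machinery.

Four algorithms are compared on fingerprint vectors behind one contract
(train / predict_proba / accuracy):

* GB  — gradient boosting machine (200 trees, max depth 5);
* DRF — random forest (200 trees, max depth 20);
* NB  — Gaussian naive Bayes with a variance floor;
* DL  — feed-forward network with three hidden layers (2000, 1000, 500),
  rectifier-with-dropout activation (input dropout 0.1, hidden dropouts
  0.2/0.2/0.1), L1 and L2 penalties of 1e-5, 10 epochs.

GB, DRF and NB are scikit-learn estimators configured to these defaults;
the DL network is implemented here in numpy so its layer weights are
directly available for variable-importance analysis.  Hyperparameters are
tuned by grid search under nested cross-validation (stratified 4-fold
outer / 3-fold inner): the inner loop selects a grid point per outer
partition, the outer folds provide unbiased accuracy estimates of those
selections, and the final choice is the grid point with the best mean
outer-fold accuracy (ties: smaller SD, then grid order).
"""

from __future__ import annotations

import itertools
import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB

from .fingerprint import LabeledDataset

logger = logging.getLogger("cytofingerprint")

ALGORITHMS = ("GB", "NB", "DRF", "DL")

DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "GB": {"n_trees": 200, "max_depth": 5, "learning_rate": 0.1},
    "DRF": {"n_trees": 200, "max_depth": 20},
    "NB": {"var_smoothing": 1e-9},
    "DL": {
        "hidden": (2000, 1000, 500),
        "input_dropout": 0.1,
        "hidden_dropout": (0.2, 0.2, 0.1),
        "epochs": 10,
        "l1": 1e-5,
        "l2": 1e-5,
        "learning_rate": 1e-3,
        "batch_size": 32,
    },
}


@dataclass(frozen=True)
class ModelSpec:
    algorithm: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; expected one of {ALGORITHMS}")

    def resolved(self) -> dict:
        params = dict(DEFAULT_HYPERPARAMETERS[self.algorithm])
        unknown = set(self.hyperparameters) - set(params)
        if unknown:
            raise ValueError(
                f"unknown hyperparameter(s) {sorted(unknown)} for {self.algorithm}"
            )
        params.update(self.hyperparameters)
        return params


@dataclass
class CVResult:
    fold_accuracies: list[float]
    best_params: dict

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def sd(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1)) if len(self.fold_accuracies) > 1 else 0.0


# ---------------------------------------------------------------------------
# Feed-forward network (three hidden layers, rectifier with dropout)
# ---------------------------------------------------------------------------

class FeedForwardClassifier:
    """Numpy multilayer perceptron: softmax output, cross-entropy loss,
    inverted dropout, elastic (L1+L2) weight penalties, Adam updates."""

    def __init__(
        self,
        hidden: Sequence[int] = (2000, 1000, 500),
        input_dropout: float = 0.1,
        hidden_dropout: Sequence[float] = (0.2, 0.2, 0.1),
        epochs: int = 10,
        l1: float = 1e-5,
        l2: float = 1e-5,
        learning_rate: float = 1e-3,
        batch_size: int = 32,
        seed: int = 0,
    ):
        if len(hidden_dropout) != len(hidden):
            raise ValueError("one dropout ratio per hidden layer required")
        self.hidden = tuple(int(h) for h in hidden)
        self.input_dropout = float(input_dropout)
        self.hidden_dropout = tuple(float(d) for d in hidden_dropout)
        self.epochs = int(epochs)
        self.l1, self.l2 = float(l1), float(l2)
        self.learning_rate = float(learning_rate)
        self.batch_size = int(batch_size)
        self.seed = int(seed)
        self.classes_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "FeedForwardClassifier":
        X = np.asarray(X, dtype=float)
        self.classes_ = np.array(sorted(set(y)))
        class_index = {c: i for i, c in enumerate(self.classes_)}
        yi = np.array([class_index[c] for c in y])
        n, d = X.shape
        k = len(self.classes_)

        self._mu = X.mean(axis=0)
        std = X.std(axis=0)
        self._sigma = np.where(std > 0, std, 1.0)
        Xs = (X - self._mu) / self._sigma

        rng = np.random.default_rng(self.seed)
        sizes = [d, *self.hidden, k]
        self.Ws = [
            rng.uniform(-s, s, size=(a, b))
            for a, b in zip(sizes[:-1], sizes[1:])
            for s in [np.sqrt(6.0 / (a + b))]
        ]
        self.bs = [np.zeros(b) for b in sizes[1:]]

        params = [*self.Ws, *self.bs]
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        dropout = [self.input_dropout, *self.hidden_dropout]
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                a = Xs[idx]
                targets = yi[idx]
                activations, preacts, masks = [a], [], []
                for layer, (W, b) in enumerate(zip(self.Ws, self.bs)):
                    if layer < len(dropout) and dropout[layer] > 0:
                        keep = 1.0 - dropout[layer]
                        mask = (rng.random(a.shape) < keep) / keep
                        a = a * mask
                        masks.append(mask)
                    else:
                        masks.append(None)
                    z = a @ W + b
                    preacts.append(z)
                    a = np.maximum(z, 0.0) if layer < len(self.Ws) - 1 else z
                    activations.append(a)
                logits = activations[-1]
                logits = logits - logits.max(axis=1, keepdims=True)
                expz = np.exp(logits)
                probs = expz / expz.sum(axis=1, keepdims=True)
                delta = probs
                delta[np.arange(len(targets)), targets] -= 1.0
                delta /= len(targets)

                gWs = [None] * len(self.Ws)
                gbs = [None] * len(self.bs)
                for layer in range(len(self.Ws) - 1, -1, -1):
                    inp = activations[layer]
                    if masks[layer] is not None:
                        inp = inp * masks[layer]
                    gWs[layer] = inp.T @ delta + self.l2 * 2 * self.Ws[layer] + self.l1 * np.sign(self.Ws[layer])
                    gbs[layer] = delta.sum(axis=0)
                    if layer > 0:
                        delta = delta @ self.Ws[layer].T
                        if masks[layer] is not None:
                            delta = delta * masks[layer]
                        delta = delta * (preacts[layer - 1] > 0)
                t += 1
                for p, g, mi, vi in zip(params, [*gWs, *gbs], m, v):
                    mi *= beta1
                    mi += (1 - beta1) * g
                    vi *= beta2
                    vi += (1 - beta2) * g * g
                    p -= self.learning_rate * (mi / (1 - beta1**t)) / (
                        np.sqrt(vi / (1 - beta2**t)) + eps
                    )
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        a = (np.asarray(X, dtype=float) - self._mu) / self._sigma
        for layer, (W, b) in enumerate(zip(self.Ws, self.bs)):
            z = a @ W + b
            a = np.maximum(z, 0.0) if layer < len(self.Ws) - 1 else z
        z = a - a.max(axis=1, keepdims=True)
        expz = np.exp(z)
        return expz / expz.sum(axis=1, keepdims=True)

    @property
    def layer_weights(self) -> list[np.ndarray]:
        """Weight matrices input->h1, h1->h2, ... (for variable importance)."""
        return list(self.Ws)


# ---------------------------------------------------------------------------
# The shared classifier contract
# ---------------------------------------------------------------------------

@dataclass
class TrainedClassifier:
    spec: ModelSpec
    classes_: np.ndarray  # lexicographic label order, fixed across reports
    backend: object
    n_features: int

    def predict_proba(self, data: LabeledDataset | np.ndarray) -> np.ndarray:
        X = data.X if isinstance(data, LabeledDataset) else np.asarray(data, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"expected (n, {self.n_features}) inputs, got {X.shape}"
            )
        # backend class order == lexicographic (np.unique / sorted) by construction
        return self.backend.predict_proba(X)

    def predict(self, data: LabeledDataset | np.ndarray) -> np.ndarray:
        probs = self.predict_proba(data)
        return self.classes_[np.argmax(probs, axis=1)]

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "wb") as fh:
            pickle.dump(self, fh)
        return path

    @staticmethod
    def load(path: str | Path) -> "TrainedClassifier":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def _make_backend(spec: ModelSpec):
    p = spec.resolved()
    if spec.algorithm == "GB":
        return GradientBoostingClassifier(
            n_estimators=p["n_trees"],
            max_depth=p["max_depth"],
            learning_rate=p["learning_rate"],
            random_state=spec.seed,
        )
    if spec.algorithm == "DRF":
        return RandomForestClassifier(
            n_estimators=p["n_trees"],
            max_depth=p["max_depth"],
            random_state=spec.seed,
            n_jobs=1,
        )
    if spec.algorithm == "NB":
        return GaussianNB(var_smoothing=p["var_smoothing"])
    return FeedForwardClassifier(
        hidden=p["hidden"],
        input_dropout=p["input_dropout"],
        hidden_dropout=p["hidden_dropout"],
        epochs=p["epochs"],
        l1=p["l1"],
        l2=p["l2"],
        learning_rate=p["learning_rate"],
        batch_size=p["batch_size"],
        seed=spec.seed,
    )


def train(spec: ModelSpec, train_ds: LabeledDataset) -> TrainedClassifier:
    """Fit one classifier on a labeled fingerprint dataset."""
    labels = train_ds.label_set
    if len(labels) < 2:
        raise ValueError(f"training needs >= 2 labels, got {labels}")
    backend = _make_backend(spec)
    y = train_ds.labels.astype(str)
    backend.fit(train_ds.X, y)
    return TrainedClassifier(
        spec=spec,
        classes_=np.array(labels),
        backend=backend,
        n_features=train_ds.n_features,
    )


def accuracy(
    model: TrainedClassifier,
    test: LabeledDataset,
    per_class_thresholds: Mapping[str, float] | None = None,
) -> tuple[float, dict[str, float]]:
    """Overall argmax accuracy and per-class recall on a test set.

    With ``per_class_thresholds``, a class's recall becomes the fraction of
    its vectors whose predicted probability for that class exceeds the
    class threshold (the fixed-threshold variant); overall accuracy is
    always argmax-based.
    """
    if len(test) == 0:
        raise ValueError("test dataset is empty")
    probs = model.predict_proba(test)
    pred = model.classes_[np.argmax(probs, axis=1)]
    truth = test.labels.astype(str)
    unseen = sorted(set(truth) - set(model.classes_))
    if unseen:
        logger.warning("test label(s) %s unseen in training; counted as errors", unseen)
    overall = float(np.mean(pred == truth))
    per_class: dict[str, float] = {}
    class_col = {c: j for j, c in enumerate(model.classes_)}
    for label in sorted(set(truth)):
        mask = truth == label
        if label not in class_col:
            per_class[label] = 0.0
        elif per_class_thresholds is not None and label in per_class_thresholds:
            per_class[label] = float(
                np.mean(probs[mask, class_col[label]] > per_class_thresholds[label])
            )
        else:
            per_class[label] = float(np.mean(pred[mask] == label))
    return overall, per_class


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def _expand_grid(grid: Mapping[str, Sequence] | Sequence[Mapping]) -> list[dict]:
    if isinstance(grid, Mapping):
        keys = list(grid)
        return [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]
    return [dict(g) for g in grid]


def nested_cv_grid_search(
    algorithm: str,
    grid: Mapping[str, Sequence] | Sequence[Mapping],
    train_ds: LabeledDataset,
    outer_folds: int = 4,
    inner_folds: int = 3,
    seed: int = 0,
) -> tuple[ModelSpec, CVResult]:
    """Stratified nested cross-validation grid search.

    For each outer partition, a 3-fold inner grid search on the outer
    training part selects the grid point with the best inner mean accuracy;
    that selection is then scored once on the disjoint outer fold.  The
    returned best spec is the grid point with the highest mean outer-fold
    accuracy among those selected (ties: smaller outer SD, then grid
    order), and the CVResult carries the outer-fold accuracies.
    """
    grid_points = _expand_grid(grid)
    if not grid_points:
        raise ValueError("hyperparameter grid is empty")
    if outer_folds < 2 or inner_folds < 2:
        raise ValueError("outer_folds and inner_folds must be >= 2")
    y = train_ds.labels.astype(str)
    counts = {l: int(np.sum(y == l)) for l in sorted(set(y))}
    too_small = {l: c for l, c in counts.items() if c < outer_folds}
    if too_small:
        raise ValueError(f"label(s) {too_small} have fewer vectors than outer_folds")

    outer = StratifiedKFold(n_splits=outer_folds, shuffle=True, random_state=seed)
    outer_acc: list[float] = []
    selected: list[int] = []
    for outer_train_idx, outer_test_idx in outer.split(train_ds.X, y):
        inner_ds = train_ds.subset(outer_train_idx)
        inner_y = inner_ds.labels.astype(str)
        inner = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed + 1)
        inner_means = []
        for params in grid_points:
            accs = []
            for tr_idx, va_idx in inner.split(inner_ds.X, inner_y):
                spec = ModelSpec(algorithm, dict(params), seed=seed)
                model = train(spec, inner_ds.subset(tr_idx))
                accs.append(accuracy(model, inner_ds.subset(va_idx))[0])
            inner_means.append(float(np.mean(accs)))
        best_g = int(np.argmax(inner_means))  # argmax keeps grid order on ties
        selected.append(best_g)
        spec = ModelSpec(algorithm, dict(grid_points[best_g]), seed=seed)
        model = train(spec, inner_ds)
        outer_acc.append(accuracy(model, train_ds.subset(outer_test_idx))[0])

    # Aggregate outer accuracies per selected grid point.
    stats = []
    for g in sorted(set(selected)):
        accs = [a for a, s in zip(outer_acc, selected) if s == g]
        sd = float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0
        stats.append((-float(np.mean(accs)), sd, g))
    stats.sort()
    best = stats[0][2]
    best_spec = ModelSpec(algorithm, dict(grid_points[best]), seed=seed)
    return best_spec, CVResult(fold_accuracies=outer_acc, best_params=dict(grid_points[best]))


def kfold_stability(
    spec: ModelSpec, ds: LabeledDataset, k: int = 5, seed: int = 0
) -> CVResult:
    """Stratified k-fold accuracies as an overfitting/stability check."""
    if k < 2:
        raise ValueError("k must be >= 2")
    y = ds.labels.astype(str)
    counts = {l: int(np.sum(y == l)) for l in sorted(set(y))}
    too_small = {l: c for l, c in counts.items() if c < k}
    if too_small:
        raise ValueError(f"label(s) {too_small} have fewer than k={k} vectors")
    folds = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs = []
    for tr_idx, te_idx in folds.split(ds.X, y):
        model = train(spec, ds.subset(tr_idx))
        accs.append(accuracy(model, ds.subset(te_idx))[0])
    return CVResult(fold_accuracies=accs, best_params=spec.resolved())
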