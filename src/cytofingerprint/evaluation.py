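"""Evaluation surfaces: one-vs-all ROC/AUC, confusion matrices,
class-probability summaries, and Gedeon variable importance.

The four-class problem is evaluated as four one-vs-all binary problems:
for each putative group the group's predicted probability is swept over
all thresholds to build a step-function ROC, and the AUC (trapezoidal) is
the probability that a random positive vector outranks a random negative
one, ties counted one half.  Variable importance for the feed-forward
network follows Gedeon's magnitude-propagation measure over the weights
into the first two hidden layers, aggregated into the three channel
blocks (V1-V1000 = FSC-A, V1001-V2000 = SSC-A, V2001-V3000 = AmCyan-A).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as _skm

from .fingerprint import ANALYSIS_CHANNELS
from .models import FeedForwardClassifier, TrainedClassifier


@dataclass
class ROCResult:
    class_label: str
    thresholds: np.ndarray  # descending
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class_label": self.class_label,
                "threshold": self.thresholds,
                "fpr": self.fpr,
                "tpr": self.tpr,
            }
        )


@dataclass
class ImportanceReport:
    per_variable: np.ndarray  # normalized to max 1
    per_block: dict[str, float]  # channel -> sum of its block's scores

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": [f"V{i}" for i in range(1, len(self.per_variable) + 1)],
                "score": self.per_variable,
            }
        )


def one_vs_all_roc(
    scores: np.ndarray,
    truth: Sequence[str],
    positive_class: str,
    classes: Sequence[str],
) -> ROCResult:
    """ROC for one class against the rest, from per-vector probability rows.

    ``scores`` has one row per vector and one column per label in
    ``classes``; the positive-class column is the ranking score.
    """
    truth = np.asarray(truth, dtype=object)
    classes = list(classes)
    if positive_class not in classes:
        raise ValueError(f"{positive_class!r} not among classes {classes}")
    if len(scores) != len(truth):
        raise ValueError("scores and truth must be parallel")
    y = (truth == positive_class).astype(int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError(
            f"class {positive_class!r} needs both positives and negatives in truth"
        )
    s = np.asarray(scores)[:, classes.index(positive_class)]
    fpr, tpr, thr = _skm.roc_curve(y, s, drop_intermediate=False)
    return ROCResult(
        class_label=positive_class,
        thresholds=thr,
        fpr=fpr,
        tpr=tpr,
        auc=float(_skm.auc(fpr, tpr)),
    )


def all_roc(
    scores: np.ndarray, truth: Sequence[str], classes: Sequence[str]
) -> dict[str, ROCResult]:
    return {c: one_vs_all_roc(scores, truth, c, classes) for c in classes}


def confusion_matrix(
    pred: Sequence[str], truth: Sequence[str]
) -> pd.DataFrame:
    """Rows = true label, columns = predicted label, entries = counts."""
    pred = np.asarray(pred, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if len(pred) != len(truth):
        raise ValueError("pred and truth must be parallel")
    labels = sorted(set(truth) | set(pred))
    counts = _skm.confusion_matrix(truth, pred, labels=labels)
    return pd.DataFrame(counts, index=pd.Index(labels, name="truth"),
                        columns=pd.Index(labels, name="predicted"))


def class_probability_summary(
    scores: np.ndarray, truth: Sequence[str], classes: Sequence[str]
) -> pd.DataFrame:
    """Five-number summaries behind the per-class probability box plots.

    One row per (true class, predicted class): the distribution of the
    predicted class's probability over vectors whose true label is the
    true class.
    """
    truth = np.asarray(truth, dtype=object)
    scores = np.asarray(scores)
    rows = []
    for t in sorted(set(truth)):
        mask = truth == t
        for j, c in enumerate(classes):
            col = scores[mask, j]
            q1, med, q3 = np.percentile(col, [25, 50, 75])
            rows.append(
                {
                    "true_class": t,
                    "predicted_class": c,
                    "min": float(col.min()),
                    "q1": float(q1),
                    "median": float(med),
                    "q3": float(q3),
                    "max": float(col.max()),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Gedeon variable importance
# ---------------------------------------------------------------------------

def gedeon_scores(W1: np.ndarray, W2: np.ndarray) -> np.ndarray:
    """Gedeon magnitude-propagation scores over two weight layers.

    score_i = sum_j P1_ij * sum_k P2_jk, where P1_ij = |w1_ij| / sum_i' |w1_i'j|
    and P2_jk = |w2_jk| / sum_j' |w2_j'k| — each input's share of each
    first-hidden unit, weighted by that unit's share of the second layer.
    """
    A1 = np.abs(W1)
    A2 = np.abs(W2)
    P1 = A1 / np.where(A1.sum(axis=0) > 0, A1.sum(axis=0), 1.0)
    P2 = A2 / np.where(A2.sum(axis=0) > 0, A2.sum(axis=0), 1.0)
    return P1 @ P2.sum(axis=1)


def gedeon_importance(
    model: TrainedClassifier, chunk_size: int | None = None
) -> ImportanceReport:
    """Per-variable and per-channel-block importance of the DL network."""
    if model.spec.algorithm != "DL" or not isinstance(model.backend, FeedForwardClassifier):
        raise TypeError(
            "variable importance is defined for the feed-forward (DL) model only"
        )
    W1, W2 = model.backend.layer_weights[0], model.backend.layer_weights[1]
    raw = gedeon_scores(W1, W2)
    top = raw.max()
    per_variable = raw / top if top > 0 else raw
    d = per_variable.size
    b = chunk_size if chunk_size is not None else d // len(ANALYSIS_CHANNELS)
    per_block = {
        ch: float(per_variable[i * b : (i + 1) * b].sum())
        for i, ch in enumerate(ANALYSIS_CHANNELS)
    }
    return ImportanceReport(per_variable=per_variable, per_block=per_block)


# ---------------------------------------------------------------------------
# Report tables (the Table-1 / Table-2 layouts) and plots
# ---------------------------------------------------------------------------

GROUP_ROW_NAMES = {
    "ACETO": "Acetogens",
    "ACIDO": "Acidogens",
    "HYDRO": "Hydrolyzers",
    "METHA": "Methanogens",
}


def accuracy_table(
    per_model: Mapping[str, tuple[float, Mapping[str, float]]]
) -> pd.DataFrame:
    """Rows = classes + Overall, columns = algorithms, values = accuracies."""
    algorithms = list(per_model)
    classes = sorted({c for _, per_class in per_model.values() for c in per_class})
    rows = {}
    for c in classes:
        rows[c] = [per_model[a][1].get(c, float("nan")) for a in algorithms]
    rows["Overall"] = [per_model[a][0] for a in algorithms]
    return pd.DataFrame(rows, index=algorithms).T.rename_axis("class")


def auc_table(per_model_roc: Mapping[str, Mapping[str, ROCResult]]) -> pd.DataFrame:
    algorithms = list(per_model_roc)
    classes = sorted({c for rocs in per_model_roc.values() for c in rocs})
    data = {a: [per_model_roc[a][c].auc if c in per_model_roc[a] else float("nan")
                for c in classes] for a in algorithms}
    return pd.DataFrame(data, index=pd.Index(classes, name="class"))


def plot_roc(rocs: Mapping[str, Mapping[str, ROCResult]], path: str | Path) -> Path:
    """One panel per class, one curve per algorithm."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    classes = sorted({c for r in rocs.values() for c in r})
    fig, axes = plt.subplots(1, len(classes), figsize=(4 * len(classes), 4),
                             squeeze=False)
    for ax, c in zip(axes[0], classes):
        for algo, r in rocs.items():
            if c in r:
                ax.plot(r[c].fpr, r[c].tpr, label=f"{algo} (AUC {r[c].auc:.3f})")
        ax.plot([0, 1], [0, 1], "k:", lw=0.8)
        ax.set_title(c)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
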