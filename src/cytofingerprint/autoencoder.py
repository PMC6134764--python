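"""Unsupervised anomaly screening with a single-hidden-layer autoencoder.

The autoencoder learns an approximation of the identity function on
fingerprint vectors from unperturbed/reference communities; a community
whose fingerprints it reconstructs poorly — large reconstruction mean
squared error (MSE) — does not fit the learned pattern and is flagged as
anomalous (perturbed).  The network is input_dim -> hidden_nodes ->
input_dim (default 2000 hidden units for 3000-dimensional fingerprints),
trained by Adam on mini-batches; inputs are standardized per feature on
the training set so that MSE thresholds are scale-free.

Thresholds are data-dependent: by default the 95th percentile of the
training samples' scores is used, and both the threshold and the
aggregation of vector scores into one score per sample (mean by default)
are configuration.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .fingerprint import LabeledDataset

Aggregate = Literal["mean", "median", "max"]
_AGGREGATORS = {"mean": np.mean, "median": np.median, "max": np.max}


@dataclass(frozen=True)
class AutoencoderConfig:
    hidden_nodes: int = 2000
    epochs: int = 10
    activation: str = "tanh"  # tanh | relu | linear
    learning_rate: float = 1e-3
    batch_size: int = 32
    seed: int = 0
    input_dim: int | None = None  # inferred from the training data if None
    standardize: bool = True
    per_coordinate_mean: bool = True  # False: unnormalized squared norm ||x-x'||^2

    def __post_init__(self) -> None:
        if self.hidden_nodes < 1 or self.epochs < 1:
            raise ValueError("hidden_nodes and epochs must be >= 1")
        if self.activation not in ("tanh", "relu", "linear"):
            raise ValueError(f"unknown activation {self.activation!r}")


@dataclass
class AnomalyReport:
    """Per-sample reconstruction-MSE scores with outlier flags."""

    per_sample: pd.DataFrame  # columns sample_id, mse, is_outlier
    threshold: float
    per_vector_mse: pd.DataFrame | None = None  # columns sample_id, chunk_index, mse

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        out = self.per_sample.copy()
        out["threshold"] = self.threshold
        out[["sample_id", "mse", "threshold", "is_outlier"]].to_csv(path, index=False)
        return path

    def plot(self, path: str | Path) -> Path:
        """MSE-vs-sample scatter with a horizontal threshold line."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(max(6, 0.25 * len(self.per_sample)), 4))
        x = np.arange(len(self.per_sample))
        colors = np.where(self.per_sample["is_outlier"], "tab:red", "tab:blue")
        ax.scatter(x, self.per_sample["mse"], c=colors, s=18)
        ax.axhline(self.threshold, color="red", lw=1,
                   label=f"threshold = {self.threshold:.4g}")
        ax.set_xticks(x)
        ax.set_xticklabels(self.per_sample["sample_id"], rotation=90, fontsize=6)
        ax.set_ylabel("reconstruction MSE")
        ax.legend()
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return Path(path)


class Autoencoder:
    """input_dim -> hidden -> input_dim network trained to reconstruct its input."""

    def __init__(self, cfg: AutoencoderConfig, input_dim: int):
        if cfg.input_dim is not None and cfg.input_dim != input_dim:
            raise ValueError(
                f"config input_dim={cfg.input_dim} does not match data ({input_dim})"
            )
        self.cfg = cfg
        self.input_dim = input_dim
        rng = np.random.default_rng(cfg.seed)
        h = cfg.hidden_nodes
        s1 = np.sqrt(6.0 / (input_dim + h))
        s2 = np.sqrt(6.0 / (h + input_dim))
        self.W1 = rng.uniform(-s1, s1, size=(input_dim, h))
        self.b1 = np.zeros(h)
        self.W2 = rng.uniform(-s2, s2, size=(h, input_dim))
        self.b2 = np.zeros(input_dim)
        self.scaler_mean = np.zeros(input_dim)
        self.scaler_std = np.ones(input_dim)
        self.loss_history: list[float] = []

    # -- forward -----------------------------------------------------------
    def _act(self, z: np.ndarray) -> np.ndarray:
        if self.cfg.activation == "tanh":
            return np.tanh(z)
        if self.cfg.activation == "relu":
            return np.maximum(z, 0.0)
        return z

    def _act_grad(self, h: np.ndarray, z: np.ndarray) -> np.ndarray:
        if self.cfg.activation == "tanh":
            return 1.0 - h * h
        if self.cfg.activation == "relu":
            return (z > 0).astype(float)
        return np.ones_like(z)

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.scaler_mean) / self.scaler_std

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        """Reconstructions in the standardized space, given raw inputs."""
        Xs = self._standardize(np.atleast_2d(X))
        h = self._act(Xs @ self.W1 + self.b1)
        return h @ self.W2 + self.b2

    def _dataset_mse(self, Xs: np.ndarray) -> float:
        h = self._act(Xs @ self.W1 + self.b1)
        out = h @ self.W2 + self.b2
        return float(np.mean((out - Xs) ** 2))

    # -- training ----------------------------------------------------------
    def fit(self, X: np.ndarray) -> "Autoencoder":
        cfg = self.cfg
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.input_dim:
            raise ValueError(f"expected {self.input_dim} features, got {X.shape[1]}")
        if cfg.standardize:
            self.scaler_mean = X.mean(axis=0)
            std = X.std(axis=0)
            self.scaler_std = np.where(std > 0, std, 1.0)
        Xs = self._standardize(X)

        rng = np.random.default_rng(cfg.seed + 1)
        params = [self.W1, self.b1, self.W2, self.b2]
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        n = len(Xs)
        self.loss_history = [self._dataset_mse(Xs)]  # loss at initialization
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                batch = Xs[order[start : start + cfg.batch_size]]
                z1 = batch @ self.W1 + self.b1
                h = self._act(z1)
                out = h @ self.W2 + self.b2
                # d(mean MSE)/d(out), per-coordinate mean over batch and dim
                d_out = 2.0 * (out - batch) / out.size
                gW2 = h.T @ d_out
                gb2 = d_out.sum(axis=0)
                d_h = d_out @ self.W2.T * self._act_grad(h, z1)
                gW1 = batch.T @ d_h
                gb1 = d_h.sum(axis=0)
                t += 1
                for p, g, mi, vi in zip(params, [gW1, gb1, gW2, gb2], m, v):
                    mi *= beta1
                    mi += (1 - beta1) * g
                    vi *= beta2
                    vi += (1 - beta2) * g * g
                    m_hat = mi / (1 - beta1**t)
                    v_hat = vi / (1 - beta2**t)
                    p -= cfg.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
            self.loss_history.append(self._dataset_mse(Xs))
        return self

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> Path:
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(path.suffix + ".npz")
        np.savez(
            path,
            W1=self.W1, b1=self.b1, W2=self.W2, b2=self.b2,
            scaler_mean=self.scaler_mean, scaler_std=self.scaler_std,
            loss_history=np.array(self.loss_history),
            config=np.frombuffer(
                json.dumps(asdict(self.cfg)).encode(), dtype=np.uint8
            ),
        )
        return path

    @classmethod
    def load(cls, path: str | Path) -> "Autoencoder":
        with np.load(path) as archive:
            cfg = AutoencoderConfig(**json.loads(bytes(archive["config"]).decode()))
            model = cls(cfg, input_dim=archive["W1"].shape[0])
            model.W1 = archive["W1"]
            model.b1 = archive["b1"]
            model.W2 = archive["W2"]
            model.b2 = archive["b2"]
            model.scaler_mean = archive["scaler_mean"]
            model.scaler_std = archive["scaler_std"]
            model.loss_history = archive["loss_history"].tolist()
        return model


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def train_autoencoder(train: LabeledDataset, cfg: AutoencoderConfig) -> Autoencoder:
    """Fit the autoencoder on a training dataset (labels are ignored)."""
    if len(train) == 0:
        raise ValueError("training dataset is empty")
    model = Autoencoder(cfg, input_dim=train.n_features)
    return model.fit(train.X)


def reconstruction_mse(model: Autoencoder, v: np.ndarray) -> float:
    """MSE between a vector and its reconstruction (standardized space).

    Per-coordinate mean ||x - x'||^2 / input_dim by default; the raw
    squared norm when the config sets ``per_coordinate_mean=False``.
    """
    v = np.asarray(v, dtype=float).ravel()
    if v.size != model.input_dim:
        raise ValueError(f"expected {model.input_dim} values, got {v.size}")
    xs = model._standardize(v[None, :])
    diff = model.reconstruct(v) - xs
    ss = float(np.sum(diff * diff))
    return ss / model.input_dim if model.cfg.per_coordinate_mean else ss


def _vector_mses(model: Autoencoder, X: np.ndarray) -> np.ndarray:
    Xs = model._standardize(X)
    diff = model.reconstruct(X) - Xs
    ss = np.sum(diff * diff, axis=1)
    return ss / model.input_dim if model.cfg.per_coordinate_mean else ss


def sample_scores(
    model: Autoencoder, ds: LabeledDataset, aggregate: Aggregate = "mean"
) -> pd.Series:
    """One score per sample_id: the chosen aggregate of its vector MSEs."""
    if len(ds) == 0:
        raise ValueError("dataset is empty")
    if ds.n_features != model.input_dim:
        raise ValueError(
            f"dataset has {ds.n_features} features, model expects {model.input_dim}"
        )
    agg = _AGGREGATORS[aggregate]
    mses = _vector_mses(model, ds.X)
    frame = pd.DataFrame(
        {"sample_id": ds.provenance["sample_id"].to_numpy(), "mse": mses}
    )
    return frame.groupby("sample_id", sort=True)["mse"].agg(lambda s: float(agg(s.to_numpy())))


def threshold_from_training(
    model: Autoencoder,
    train: LabeledDataset,
    percentile: float = 95.0,
    aggregate: Aggregate = "mean",
) -> float:
    """Default threshold policy: a percentile of training-sample scores."""
    return float(np.percentile(sample_scores(model, train, aggregate).to_numpy(), percentile))


def score_samples(
    model: Autoencoder,
    ds: LabeledDataset,
    threshold: float,
    aggregate: Aggregate = "mean",
) -> AnomalyReport:
    """Score every sample and flag outliers (score strictly above threshold)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    scores = sample_scores(model, ds, aggregate)
    per_sample = scores.reset_index()
    per_sample["is_outlier"] = per_sample["mse"] > threshold
    mses = _vector_mses(model, ds.X)
    per_vector = pd.DataFrame(
        {
            "sample_id": ds.provenance["sample_id"].to_numpy(),
            "chunk_index": ds.provenance["chunk_index"].to_numpy(),
            "mse": mses,
        }
    )
    return AnomalyReport(per_sample=per_sample, threshold=float(threshold),
                         per_vector_mse=per_vector)
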