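"""Fingerprint vectorization, putative-group clubbing, train/test splitting.

The fingerprint of a microbial community sample is built by chunking its
gated event stream into consecutive, non-overlapping runs of ``chunk_size``
events (default 1000) and concatenating the chunk's per-channel values into
one fixed-length vector of ``chunk_size * 3`` entries (default 3000), laid
out as contiguous channel blocks: V1..V1000 = FSC-A, V1001..V2000 = SSC-A,
V2001..V3000 = AmCyan-A.  A 100,000-event sample therefore yields 100
vectors, and a class acquired in triplicate over five time points yields
1500 vectors.  These vectors — distributions of events, not single cells —
are the unit of all downstream learning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_fcs import (
    ANALYSIS_CHANNELS,
    EventMatrix,
    GateConfig,
    apply_gate,
    read_events,
    read_manifest,
    select_channels,
)

DEFAULT_CHUNK_SIZE = 1000

#: Carbon-source label -> putative anaerobic-digestion functional group.
#: HYDRO = hydrolyzers (cellulose-fed), ACIDO = acidogens (glucose),
#: ACETO = syntrophic acetogens (propionate/butyrate), METHA = methanogens
#: (acetate, sludge, and unfed/blank communities).
DEFAULT_CLUBBING: dict[str, str] = {
    "CELL": "HYDRO",
    "GLUC": "ACIDO",
    "PROP": "ACETO",
    "BUTY": "ACETO",
    "ACET": "METHA",
    "SLUD": "METHA",
    "BLAN": "METHA",
    "NONE": "METHA",
}

PUTATIVE_GROUPS = ("ACETO", "ACIDO", "HYDRO", "METHA")


@dataclass
class FingerprintVector:
    """One chunk's concatenated channel-block vector."""

    values: np.ndarray  # length chunk_size * 3
    sample_id: str
    chunk_index: int
    label: str = ""

    def to_chunk(self, chunk_size: int = DEFAULT_CHUNK_SIZE) -> np.ndarray:
        """Invert the layout back to a (chunk_size, 3) event block."""
        n_channels = self.values.size // chunk_size
        return self.values.reshape(n_channels, chunk_size).T


@dataclass
class LabeledDataset:
    """Fingerprint vectors with labels and per-vector provenance."""

    X: np.ndarray  # (n_vectors, chunk_size * 3)
    labels: np.ndarray  # (n_vectors,) of str
    provenance: pd.DataFrame  # columns sample_id, replicate, timepoint, chunk_index
    chunk_size: int = DEFAULT_CHUNK_SIZE

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.X) != len(self.labels) or len(self.X) != len(self.provenance):
            raise ValueError("X, labels and provenance must be parallel")

    def __len__(self) -> int:
        return len(self.X)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def label_set(self) -> list[str]:
        return sorted(set(self.labels))

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(
            X=self.X[idx],
            labels=self.labels[idx],
            provenance=self.provenance.iloc[idx].reset_index(drop=True),
            chunk_size=self.chunk_size,
        )

    # -- CSV layout: V1..Vd value columns plus label/provenance columns ----
    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        d = self.X.shape[1]
        df = pd.DataFrame(self.X, columns=[f"V{i}" for i in range(1, d + 1)])
        df["label"] = self.labels
        for col in ("sample_id", "replicate", "timepoint", "chunk_index"):
            df[col] = self.provenance[col].to_numpy()
        df.to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path, chunk_size: int = DEFAULT_CHUNK_SIZE) -> "LabeledDataset":
        df = pd.read_csv(path)
        value_cols = [c for c in df.columns if c.startswith("V") and c[1:].isdigit()]
        value_cols.sort(key=lambda c: int(c[1:]))
        prov = df[["sample_id", "replicate", "timepoint", "chunk_index"]].reset_index(drop=True)
        return cls(
            X=df[value_cols].to_numpy(dtype=float),
            labels=df["label"].to_numpy(dtype=object),
            provenance=prov,
            chunk_size=chunk_size,
        )


# ---------------------------------------------------------------------------
# Vectorization
# ---------------------------------------------------------------------------

def vectorize(
    em: EventMatrix,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
    sort_within_chunk: bool = False,
    chunking: str = "consecutive",
    seed: int | None = None,
) -> list[FingerprintVector]:
    """Chunk a gated event matrix into fixed-length fingerprint vectors.

    Consecutive, non-overlapping runs of ``chunk_size`` events in
    acquisition order (the default) produce ``floor(N / chunk_size)``
    vectors; a trailing remainder is discarded.  Each vector is the
    channel-block concatenation [FSC block | SSC block | AmCyan block],
    with events in acquisition order inside each block.

    ``sort_within_chunk`` sorts each channel block ascending, making the
    fingerprint invariant to event permutations (off by default).
    ``chunking="random"`` draws the chunks from a seeded permutation of the
    events instead of consecutive runs.
    """
    if em.n_channels != len(ANALYSIS_CHANNELS) or list(em.channel_names) != list(
        ANALYSIS_CHANNELS
    ):
        raise ValueError(
            f"vectorize expects channels {list(ANALYSIS_CHANNELS)} in order, "
            f"got {em.channel_names}; run select_channels first"
        )
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    n_chunks = em.n_events // chunk_size
    events = em.events
    if chunking == "random":
        rng = np.random.default_rng(seed)
        events = events[rng.permutation(em.n_events)]
    elif chunking != "consecutive":
        raise ValueError(f"unknown chunking mode {chunking!r}")
    out = []
    for k in range(n_chunks):
        chunk = events[k * chunk_size : (k + 1) * chunk_size]
        blocks = chunk.T  # (3, chunk_size): channel blocks in canonical order
        if sort_within_chunk:
            blocks = np.sort(blocks, axis=1)
        out.append(
            FingerprintVector(
                values=blocks.reshape(-1).copy(),
                sample_id=em.sample_id,
                chunk_index=k,
            )
        )
    return out


def distribution_summary(
    em: EventMatrix, percentiles: Sequence[float] = (5, 25, 50, 75, 95)
) -> np.ndarray:
    """Optional distribution-statistics featurizer: per-channel mean, SD
    and percentiles, concatenated channel-by-channel."""
    parts = []
    for j in range(em.n_channels):
        col = em.events[:, j]
        parts.append([col.mean(), col.std(ddof=1)])
        parts.append(np.percentile(col, percentiles))
    return np.concatenate(parts)


def build_dataset(
    manifest: str | Path | pd.DataFrame,
    data_dir: str | Path | None = None,
    gate: GateConfig = GateConfig(),
    chunk_size: int = DEFAULT_CHUNK_SIZE,
    **vectorize_kwargs,
) -> LabeledDataset:
    """Read every manifest sample, gate it, and assemble the dataset."""
    if isinstance(manifest, (str, Path)):
        manifest_path = Path(manifest)
        df = read_manifest(manifest_path)
        data_dir = Path(data_dir) if data_dir is not None else manifest_path.parent
    else:
        df = manifest
        data_dir = Path(data_dir) if data_dir is not None else Path(".")
    X_rows, labels, prov = [], [], []
    for row in df.itertuples(index=False):
        path = Path(row.path)
        if not path.is_absolute():
            path = data_dir / path
        fmt = "csv" if path.suffix.lower() == ".csv" else "fcs"
        em = read_events(path, format=fmt, sample_id=str(row.sample_id))
        em = select_channels(em, ANALYSIS_CHANNELS)
        em = apply_gate(em, gate)
        for fv in vectorize(em, chunk_size=chunk_size, **vectorize_kwargs):
            X_rows.append(fv.values)
            labels.append(str(row.label))
            prov.append(
                {
                    "sample_id": str(row.sample_id),
                    "replicate": row.replicate,
                    "timepoint": row.timepoint_day,
                    "chunk_index": fv.chunk_index,
                }
            )
    if X_rows:
        X = np.vstack(X_rows)
    else:
        X = np.empty((0, chunk_size * len(ANALYSIS_CHANNELS)))
    return LabeledDataset(
        X=X,
        labels=np.array(labels, dtype=object),
        provenance=pd.DataFrame(
            prov, columns=["sample_id", "replicate", "timepoint", "chunk_index"]
        ),
        chunk_size=chunk_size,
    )


# ---------------------------------------------------------------------------
# Label clubbing and splitting
# ---------------------------------------------------------------------------

def club_labels(
    ds: LabeledDataset, mapping: Mapping[str, str] | None = None
) -> LabeledDataset:
    """Replace perturbation labels by putative functional-group labels."""
    mapping = DEFAULT_CLUBBING if mapping is None else mapping
    unmapped = sorted(set(ds.labels) - set(mapping))
    if unmapped:
        raise KeyError(f"label(s) {unmapped} have no clubbing-map entry")
    new_labels = np.array([mapping[l] for l in ds.labels], dtype=object)
    return LabeledDataset(
        X=ds.X,
        labels=new_labels,
        provenance=ds.provenance.copy(),
        chunk_size=ds.chunk_size,
    )


def split_train_test(
    ds: LabeledDataset,
    train_fraction: float = 0.75,
    seed: int = 0,
    by_replicate: bool = False,
) -> tuple[LabeledDataset, LabeledDataset]:
    """Per-label stratified random split (default 75% train / 25% test).

    Each label with n vectors contributes round-half-up(train_fraction * n)
    vectors to training.  ``by_replicate=True`` keeps all vectors of a
    (label, replicate) together — the leakage-controlled variant — choosing
    whole replicates per label to approximate the fraction.
    """
    if len(ds) == 0:
        raise ValueError("cannot split an empty dataset")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for label in ds.label_set:
        idx = np.flatnonzero(ds.labels == label)
        if idx.size < 2:
            raise ValueError(f"label {label!r} has {idx.size} vector(s); cannot stratify")
        if by_replicate:
            reps = ds.provenance["replicate"].to_numpy()[idx]
            unique_reps = np.array(sorted(pd.unique(reps)))
            if unique_reps.size < 2:
                raise ValueError(
                    f"label {label!r} has a single replicate; cannot split by replicate"
                )
            perm = rng.permutation(unique_reps.size)
            n_train_reps = max(1, min(unique_reps.size - 1,
                                      math.floor(train_fraction * unique_reps.size + 0.5)))
            chosen = set(unique_reps[perm[:n_train_reps]])
            mask = np.array([r in chosen for r in reps])
            train_idx.append(idx[mask])
            test_idx.append(idx[~mask])
        else:
            n_train = math.floor(train_fraction * idx.size + 0.5)  # half-up
            n_train = max(1, min(idx.size - 1, n_train))
            perm = rng.permutation(idx.size)
            train_idx.append(idx[perm[:n_train]])
            test_idx.append(idx[perm[n_train:]])
    train = ds.subset(np.sort(np.concatenate(train_idx)))
    test = ds.subset(np.sort(np.concatenate(test_idx)))
    return train, test


def wald_sample_size(margin: float = 0.03, confidence: float = 0.95) -> int:
    """Worst-case Wald sample size n = z^2 * 0.25 / margin^2 for a
    proportion estimated to +/- ``margin`` at the given confidence."""
    from statistics import NormalDist

    z = NormalDist().inv_cdf(0.5 + confidence / 2)
    return math.ceil(z * z * 0.25 / (margin * margin))
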