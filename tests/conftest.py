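"""Shared fixtures: small in-memory synthetic studies.

All fixtures are generated programmatically at test time; sizes are kept
desk-scale (a few thousand events per sample) so the suite runs in
minutes while preserving the study geometry (4 classes x 3 replicates x
several time points, 1000-event chunks, 3000-value fingerprints).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import cytofingerprint as cf


def make_dataset(
    classes,
    events_per_sample: int = 3000,
    replicates: int = 3,
    timepoints: int = 5,
    chunk_size: int = 1000,
    seed: int = 11,
) -> cf.LabeledDataset:
    """Assemble a LabeledDataset directly from simulated samples (no files)."""
    X_rows, labels, prov = [], [], []
    for ci, cd in enumerate(classes):
        for rep in range(1, replicates + 1):
            for tp in range(timepoints):
                em = cf.simulate_sample(
                    cd, tp, events_per_sample,
                    np.random.SeedSequence([seed, ci, rep, tp]),
                )
                sample_id = f"{cd.class_label}_r{rep}_t{tp}"
                for fv in cf.vectorize(em, chunk_size=chunk_size):
                    X_rows.append(fv.values)
                    labels.append(cd.class_label)
                    prov.append(
                        {"sample_id": sample_id, "replicate": rep,
                         "timepoint": tp, "chunk_index": fv.chunk_index}
                    )
    return cf.LabeledDataset(
        X=np.vstack(X_rows),
        labels=np.array(labels, dtype=object),
        provenance=pd.DataFrame(prov),
        chunk_size=chunk_size,
    )


#: Mean shift placing the anomaly >= 5 pooled SD from its base class in
#: every scatter channel (component SDs are 1500-1800).
ANOMALY_SHIFT = (9000.0, 9000.0, 2500.0)


@pytest.fixture(scope="session")
def four_class_dataset() -> cf.LabeledDataset:
    """Separable 4-class study: 3 vectors/sample, 45 vectors per class."""
    return make_dataset(cf.default_classes(), events_per_sample=3000)


@pytest.fixture(scope="session")
def anomaly_dataset() -> cf.LabeledDataset:
    """The 4 training classes plus one shifted anomaly class (PERT)."""
    classes = list(cf.default_classes())
    classes.append(cf.make_anomaly_class(classes[0], ANOMALY_SHIFT, "PERT"))
    return make_dataset(classes, events_per_sample=3000, seed=17)


@pytest.fixture(scope="session")
def split_4class(four_class_dataset):
    return cf.split_train_test(four_class_dataset, seed=1)


@pytest.fixture(scope="session")
def small_dl_model(split_4class):
    """A reduced feed-forward network trained on the 4-class study."""
    train_ds, _ = split_4class
    spec = cf.ModelSpec("DL", {"hidden": (200, 100, 50), "epochs": 5}, seed=0)
    return cf.train(spec, train_ds)
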