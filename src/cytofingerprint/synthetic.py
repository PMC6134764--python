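"""Class-conditional synthetic event clouds and study manifests.

The generator emulates the structure of a perturbation study on anaerobic
digester microbiomes observed by label-free flow cytometry: for each
perturbation class, triplicate reactors sampled over five time points, with
~100,000 events per sample in the three analysis channels (FSC-A, SSC-A,
AmCyan-A).  Each class draws its events from its own mixture of
truncated-at-zero Gaussians — distinct locations, scales and mixture
weights per class stand in for the distinct community morphologies — with
an optional additive per-day mean drift emulating slow community change
along the incubation.  Designated anomaly classes are built by shifting a
base class's component means, emulating a significantly perturbed
community that the anomaly screen should flag.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_fcs import ANALYSIS_CHANNELS, EventMatrix, write_events, write_manifest

N_CHANNELS = len(ANALYSIS_CHANNELS)


@dataclass(frozen=True)
class MixtureComponent:
    weight: float
    mean: tuple[float, float, float]
    sd: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.mean) != N_CHANNELS or len(self.sd) != N_CHANNELS:
            raise ValueError("mean and sd must be 3-vectors")
        if any(s <= 0 for s in self.sd):
            raise ValueError("all sd must be > 0")


@dataclass(frozen=True)
class ClassDistribution:
    """A perturbation class's event distribution: a truncated-Gaussian mixture."""

    class_label: str
    components: tuple[MixtureComponent, ...]
    drift_per_day: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("at least one mixture component required")
        total = sum(c.weight for c in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"component weights sum to {total}, not 1")


@dataclass(frozen=True)
class StudyDesign:
    classes: tuple[ClassDistribution, ...]
    replicates: int = 3
    timepoints: int = 5
    events_per_sample: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1 or self.timepoints < 1 or self.events_per_sample < 1:
            raise ValueError("replicates, timepoints and events_per_sample must be >= 1")


def _sample_seed(study_seed: int, class_label: str, replicate: int, timepoint: int) -> np.random.SeedSequence:
    # Deterministic per-sample stream: samples are mutually independent yet
    # reproducible from the study seed alone.
    label_key = int.from_bytes(class_label.encode("utf-8")[:8].ljust(8, b"\0"), "big")
    return np.random.SeedSequence([study_seed, label_key, replicate, timepoint])


def simulate_sample(
    cd: ClassDistribution,
    timepoint: int,
    n_events: int,
    seed: int | np.random.SeedSequence,
) -> EventMatrix:
    """Draw ``n_events`` events from ``cd`` at the given time point.

    Means are shifted by ``timepoint * drift_per_day``; negative draws are
    redrawn (truncation at zero) so all intensities are >= 0.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    rng = np.random.default_rng(seed)
    weights = np.array([c.weight for c in cd.components])
    assignment = rng.choice(len(cd.components), size=n_events, p=weights)
    drift = np.asarray(cd.drift_per_day) * timepoint
    events = np.empty((n_events, N_CHANNELS))
    for k, comp in enumerate(cd.components):
        idx = np.flatnonzero(assignment == k)
        if idx.size == 0:
            continue
        mean = np.asarray(comp.mean) + drift
        sd = np.asarray(comp.sd)
        draws = rng.normal(mean, sd, size=(idx.size, N_CHANNELS))
        for _ in range(100):
            neg = draws < 0
            if not neg.any():
                break
            redraw = rng.normal(np.broadcast_to(mean, draws.shape)[neg], np.broadcast_to(sd, draws.shape)[neg])
            draws[neg] = redraw
        np.clip(draws, 0.0, None, out=draws)
        events[idx] = draws
    sample_id = f"{cd.class_label}_t{timepoint}"
    return EventMatrix(
        sample_id=sample_id,
        events=events,
        channel_names=list(ANALYSIS_CHANNELS),
        metadata={"class_label": cd.class_label, "timepoint": str(timepoint)},
    )


def simulate_study(
    sd: StudyDesign, out_dir: str | Path, format: str = "csv"
) -> Path:
    """Write one event file per (class, replicate, timepoint) plus a manifest.

    Returns the manifest path.  Per class the total event count is
    ``replicates * timepoints * events_per_sample``.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create output directory {out_dir}: {exc}") from exc
    rows = []
    for cd in sd.classes:
        for rep in range(1, sd.replicates + 1):
            for tp in range(sd.timepoints):
                em = simulate_sample(
                    cd, tp, sd.events_per_sample,
                    _sample_seed(sd.seed, cd.class_label, rep, tp),
                )
                sample_id = f"{cd.class_label}_r{rep}_t{tp}"
                em = replace(em, sample_id=sample_id)
                fname = f"{sample_id}.{format}"
                write_events(em, out_dir / fname, format=format)
                rows.append(
                    {
                        "sample_id": sample_id,
                        "path": fname,
                        "label": cd.class_label,
                        "replicate": rep,
                        "timepoint_day": tp,
                    }
                )
    return write_manifest(rows, out_dir / "manifest.csv")


def make_anomaly_class(
    base: ClassDistribution, shift: Sequence[float], label: str
) -> ClassDistribution:
    """A copy of ``base`` with every component mean shifted and relabelled."""
    shift = tuple(float(s) for s in shift)
    if len(shift) != N_CHANNELS:
        raise ValueError("shift must be a 3-vector")
    shifted = tuple(
        MixtureComponent(
            weight=c.weight,
            mean=tuple(m + s for m, s in zip(c.mean, shift)),
            sd=c.sd,
        )
        for c in base.components
    )
    return ClassDistribution(
        class_label=label, components=shifted, drift_per_day=base.drift_per_day
    )


# ---------------------------------------------------------------------------
# Default study: four separable carbon-source classes
# ---------------------------------------------------------------------------

def default_classes() -> tuple[ClassDistribution, ...]:
    """Four carbon-source perturbation classes with well-separated,
    bimodal channel distributions.

    Labels follow the carbon-source naming (CELL = cellulose-fed, GLUC =
    glucose, PROP = propionate, ACET = acetate) so the putative-group
    clubbing map applies directly.  Component means are placed >= 5 pooled
    SD apart between classes in at least one channel, giving a study that
    is separable by construction; the per-class bimodality and a small
    positive drift mimic sub-populations and slow community change.
    """
    def bimodal(label, base, drift):
        b = np.asarray(base, dtype=float)
        return ClassDistribution(
            class_label=label,
            components=(
                MixtureComponent(0.6, tuple(b), (1500.0, 1200.0, 400.0)),
                MixtureComponent(0.4, tuple(b + np.array([4000.0, -2500.0, 800.0])), (1800.0, 1400.0, 500.0)),
            ),
            drift_per_day=drift,
        )

    return (
        bimodal("CELL", (52000.0, 30000.0, 5200.0), (60.0, 40.0, 5.0)),
        bimodal("GLUC", (20000.0, 42000.0, 2000.0), (40.0, -30.0, 4.0)),
        bimodal("PROP", (36000.0, 16000.0, 8000.0), (-30.0, 50.0, 6.0)),
        bimodal("ACET", (66000.0, 52000.0, 12500.0), (50.0, 30.0, -5.0)),
    )


def default_study(
    seed: int = 0,
    events_per_sample: int = 100_000,
    replicates: int = 3,
    timepoints: int = 5,
) -> StudyDesign:
    """The default four-class study design (triplicates over five days)."""
    return StudyDesign(
        classes=default_classes(),
        replicates=replicates,
        timepoints=timepoints,
        events_per_sample=events_per_sample,
        seed=seed,
    )
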