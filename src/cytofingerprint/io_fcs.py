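"""Per-event cytometry I/O: FCS 3.0/3.1 and CSV, channel selection, threshold gating.

An :class:`EventMatrix` is the raw unit of data: one sample's cloud of N
events (particles) by C channels (scatter / fluorescence pulse areas, in
arbitrary cytometer units).  Files are read and written in FCS list mode
(3.1 written, 3.0/3.1 accepted) or as plain CSV with a header row of
channel names.  Gating is axis-aligned thresholding: a per-channel lower
bound excludes low-signal background (debris / dead cells), and an upper
bound on forward scatter excludes putative doublets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: The three label-free analysis channels, in canonical order: forward
#: scatter area (cell size), side scatter area (granularity/morphology),
#: and 405 nm-excited autofluorescence area.
ANALYSIS_CHANNELS: tuple[str, ...] = ("FSC-A", "SSC-A", "AmCyan-A")


class FCSFormatError(ValueError):
    """Raised when a file does not parse as FCS list-mode data."""


@dataclass
class EventMatrix:
    """N events x C channels of finite, arbitrary-unit intensities."""

    sample_id: str
    events: np.ndarray  # shape (N, C), float
    channel_names: list[str]
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=float)
        if self.events.ndim != 2:
            raise ValueError("events must be a 2-D array of shape (N, C)")
        if self.events.shape[1] != len(self.channel_names):
            raise ValueError(
                f"{self.events.shape[1]} event columns but "
                f"{len(self.channel_names)} channel names"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("duplicate channel names")
        if self.events.size and not np.all(np.isfinite(self.events)):
            raise ValueError("non-finite intensity values")

    @property
    def n_events(self) -> int:
        return self.events.shape[0]

    @property
    def n_channels(self) -> int:
        return self.events.shape[1]


@dataclass(frozen=True)
class GateConfig:
    """Axis-aligned threshold gate.

    ``lower_bounds`` maps channel name -> background floor (events strictly
    below are excluded); ``fsc_upper_bound`` is the doublet ceiling on
    FSC-A (events strictly above are excluded).  The default is a no-op
    gate that retains every event.
    """

    lower_bounds: Mapping[str, float] = field(default_factory=dict)
    fsc_upper_bound: float = float("inf")
    fsc_channel: str = "FSC-A"

    def __post_init__(self) -> None:
        for name, bound in self.lower_bounds.items():
            if bound < 0:
                raise ValueError(f"lower bound for {name!r} must be >= 0")
        floor = self.lower_bounds.get(self.fsc_channel, 0.0)
        if not self.fsc_upper_bound > floor:
            raise ValueError("fsc_upper_bound must exceed the FSC-A floor")


# ---------------------------------------------------------------------------
# FCS reading
# ---------------------------------------------------------------------------

def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FCSFormatError("empty TEXT segment")
    delim = raw[0:1]
    body = raw[1:]
    if body.endswith(delim):
        body = body[:-1]
    # A doubled delimiter escapes a literal delimiter inside a value; split
    # on single occurrences only.
    sentinel = b"\x00\x01\x02"
    parts = body.replace(delim + delim, sentinel).split(delim)
    parts = [p.replace(sentinel, delim) for p in parts]
    if len(parts) % 2 != 0:
        # trailing empty value is tolerated
        if parts and parts[-1] == b"":
            parts = parts[:-1]
    if len(parts) % 2 != 0:
        raise FCSFormatError("TEXT segment has an odd number of tokens")
    text: dict[str, str] = {}
    for key, value in zip(parts[0::2], parts[1::2]):
        text[key.decode("utf-8", "replace").strip().upper()] = value.decode(
            "utf-8", "replace"
        )
    return text


def read_fcs(path: str | Path, sample_id: str | None = None) -> EventMatrix:
    """Read an FCS 3.0/3.1 list-mode file into an :class:`EventMatrix`."""
    path = Path(path)
    try:
        raw = path.read_bytes()
    except OSError as exc:
        raise IOError(f"cannot read FCS file {path}: {exc}") from exc
    if len(raw) < 58:
        raise FCSFormatError(f"{path}: too short to hold an FCS header")
    version = raw[0:6].decode("ascii", "replace")
    if version not in ("FCS3.0", "FCS3.1"):
        raise FCSFormatError(f"{path}: unsupported FCS version {version!r}")

    def _offset(lo: int, hi: int) -> int:
        s = raw[lo:hi].decode("ascii", "replace").strip()
        return int(s) if s else 0

    text_begin, text_end = _offset(10, 18), _offset(18, 26)
    data_begin, data_end = _offset(26, 34), _offset(34, 42)
    if text_end <= text_begin:
        raise FCSFormatError(f"{path}: missing TEXT segment")
    text = _parse_text_segment(raw[text_begin : text_end + 1])

    if "$PAR" not in text:
        raise FCSFormatError(f"{path}: $PAR (parameter count) not declared")
    n_par = int(text["$PAR"])
    n_tot = int(text.get("$TOT", 0))
    if data_begin == 0:
        data_begin = int(text.get("$BEGINDATA", 0))
        data_end = int(text.get("$ENDDATA", 0))
    datatype = text.get("$DATATYPE", "F").upper()
    mode = text.get("$MODE", "L").upper()
    if mode != "L":
        raise FCSFormatError(f"{path}: only list mode ($MODE L) is supported")
    byteord = text.get("$BYTEORD", "1,2,3,4")
    little = byteord.startswith("1")
    if datatype == "F":
        dtype = np.dtype("<f4" if little else ">f4")
    elif datatype == "D":
        dtype = np.dtype("<f8" if little else ">f8")
    else:
        raise FCSFormatError(f"{path}: unsupported $DATATYPE {datatype!r}")

    names = []
    for i in range(1, n_par + 1):
        names.append(text.get(f"$P{i}N", f"P{i}"))

    n_values = n_tot * n_par
    data = np.frombuffer(raw, dtype=dtype, count=n_values, offset=data_begin)
    if data.size != n_values:
        raise FCSFormatError(
            f"{path}: DATA segment holds {data.size} values, expected {n_values}"
        )
    events = data.reshape(n_tot, n_par).astype(float)
    metadata = dict(text)
    metadata["event_count"] = str(n_tot)
    return EventMatrix(
        sample_id=sample_id or path.stem,
        events=events,
        channel_names=names,
        metadata=metadata,
    )


# ---------------------------------------------------------------------------
# FCS writing (3.1, single dataset, list mode, 32-bit float, little-endian)
# ---------------------------------------------------------------------------

def write_fcs(em: EventMatrix, path: str | Path) -> Path:
    path = Path(path)
    n, c = em.events.shape
    data = em.events.astype("<f4").tobytes(order="C")

    def _text_segment(data_begin: int, data_end: int) -> bytes:
        pairs = [
            ("$BEGINANALYSIS", "0"),
            ("$ENDANALYSIS", "0"),
            ("$BEGINSTEXT", "0"),
            ("$ENDSTEXT", "0"),
            ("$BEGINDATA", str(data_begin)),
            ("$ENDDATA", str(data_end)),
            ("$BYTEORD", "1,2,3,4"),
            ("$DATATYPE", "F"),
            ("$MODE", "L"),
            ("$NEXTDATA", "0"),
            ("$PAR", str(c)),
            ("$TOT", str(n)),
        ]
        for i, name in enumerate(em.channel_names, start=1):
            rng = em.events[:, i - 1].max() if n else 262144.0
            pairs += [
                (f"$P{i}N", name),
                (f"$P{i}B", "32"),
                (f"$P{i}E", "0,0"),
                (f"$P{i}R", str(int(max(rng, 1)) + 1)),
            ]
        body = "/" + "".join(f"{k}/{v}/" for k, v in pairs)
        return body.encode("ascii")

    # The TEXT segment quotes the DATA offsets, whose widths depend on the
    # TEXT length; iterate until the offsets are self-consistent.
    header_len = 58
    text = _text_segment(0, 0)
    for _ in range(8):
        data_begin = header_len + len(text)
        data_end = data_begin + len(data) - 1 if data else 0
        new_text = _text_segment(data_begin, data_end)
        if len(new_text) == len(text):
            text = new_text
            break
        text = new_text
    data_begin = header_len + len(text)
    data_end = data_begin + len(data) - 1 if data else 0

    text_begin = header_len
    text_end = text_begin + len(text) - 1
    header = (
        b"FCS3.1    "
        + f"{text_begin:>8d}".encode()
        + f"{text_end:>8d}".encode()
        + (f"{data_begin:>8d}".encode() if data_end <= 99999999 else b"       0")
        + (f"{data_end:>8d}".encode() if data_end <= 99999999 else b"       0")
        + f"{0:>8d}".encode()
        + f"{0:>8d}".encode()
    )
    assert len(header) == header_len
    try:
        path.write_bytes(header + text + data)
    except OSError as exc:
        raise IOError(f"cannot write FCS file {path}: {exc}") from exc
    return path


# ---------------------------------------------------------------------------
# CSV and the public read/write surface
# ---------------------------------------------------------------------------

def read_csv_events(path: str | Path, sample_id: str | None = None) -> EventMatrix:
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read CSV file {path}: no such file")
    df = pd.read_csv(path)
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in column "
                f"{col!r}, data row {row}"
            )
        if numeric.isna().any():
            row = int(np.flatnonzero(numeric.isna().to_numpy())[0])
            raise ValueError(f"{path}: missing value in column {col!r}, data row {row}")
        values[:, j] = numeric.to_numpy()
    return EventMatrix(
        sample_id=sample_id or path.stem,
        events=values,
        channel_names=[str(c) for c in df.columns],
        metadata={"event_count": str(len(df))},
    )


def write_csv_events(em: EventMatrix, path: str | Path) -> Path:
    path = Path(path)
    try:
        pd.DataFrame(em.events, columns=em.channel_names).to_csv(path, index=False)
    except OSError as exc:
        raise IOError(f"cannot write CSV file {path}: {exc}") from exc
    return path


def read_events(path: str | Path, format: str = "fcs", sample_id: str | None = None) -> EventMatrix:
    """Read per-event data; ``format`` is ``"fcs"`` or ``"csv"``."""
    if format == "fcs":
        return read_fcs(path, sample_id=sample_id)
    if format == "csv":
        return read_csv_events(path, sample_id=sample_id)
    raise ValueError(f"unknown format {format!r}; expected 'fcs' or 'csv'")


def write_events(em: EventMatrix, path: str | Path, format: str = "fcs") -> Path:
    if format == "fcs":
        return write_fcs(em, path)
    if format == "csv":
        return write_csv_events(em, path)
    raise ValueError(f"unknown format {format!r}; expected 'fcs' or 'csv'")


# ---------------------------------------------------------------------------
# Channel selection and gating
# ---------------------------------------------------------------------------

def select_channels(
    em: EventMatrix, wanted: Sequence[str] = ANALYSIS_CHANNELS
) -> EventMatrix:
    """Subset/reorder columns to ``wanted`` (matched by $PnN short name)."""
    missing = [w for w in wanted if w not in em.channel_names]
    if missing:
        raise KeyError(
            f"channel(s) {missing} not present; available: {em.channel_names}"
        )
    idx = [em.channel_names.index(w) for w in wanted]
    return replace(
        em,
        events=em.events[:, idx].copy(),
        channel_names=list(wanted),
        metadata=dict(em.metadata),
    )


def apply_gate(em: EventMatrix, gate: GateConfig = GateConfig()) -> EventMatrix:
    """Retain events passing every threshold; order is preserved.

    An event is kept iff every gated channel is >= its lower bound and
    FSC-A (when present in the gate) is <= ``fsc_upper_bound``.
    """
    keep = np.ones(em.n_events, dtype=bool)
    for name, bound in gate.lower_bounds.items():
        if name not in em.channel_names:
            raise KeyError(f"gated channel {name!r} not in {em.channel_names}")
        keep &= em.events[:, em.channel_names.index(name)] >= bound
    if np.isfinite(gate.fsc_upper_bound):
        if gate.fsc_channel not in em.channel_names:
            raise KeyError(f"gated channel {gate.fsc_channel!r} not in {em.channel_names}")
        keep &= em.events[:, em.channel_names.index(gate.fsc_channel)] <= gate.fsc_upper_bound
    gated = replace(
        em, events=em.events[keep].copy(), metadata=dict(em.metadata)
    )
    gated.metadata["gated_event_count"] = str(gated.n_events)
    gated.metadata["excluded_event_count"] = str(em.n_events - gated.n_events)
    return gated


# ---------------------------------------------------------------------------
# Sample manifest
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["sample_id", "path", "label", "replicate", "timepoint_day"]


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} lacks column(s) {missing}")
    return df[MANIFEST_COLUMNS]


def write_manifest(rows: Iterable[Mapping[str, object]], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(list(rows), columns=MANIFEST_COLUMNS).to_csv(path, index=False)
    return path
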