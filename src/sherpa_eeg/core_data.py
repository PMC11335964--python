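"""Epochs container, time-grid conventions, channel layouts and spatial adjacency.

The package's common currency is :class:`EpochedData`: a ``trials x channels x
times`` block of preprocessed EEG amplitudes (microvolts) with per-trial
condition labels and subject identifiers.  Epochs are persisted as a directory
holding a raw little-endian float32 array plus a JSON sidecar — language
neutral, bit exact and diff-able.

Time-grid convention: sample ``i`` sits at ``t0 + i * 1000 / sfreq`` ms and
intervals are half-open ``[t_start, t_end)``, so an epoch cropped to
``[0, 1500)`` ms at 512 Hz has exactly 768 samples.
"""

from __future__ import annotations

import csv
import functools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ValidationError",
    "EpochedData",
    "ChannelLayout",
    "AdjacencyGraph",
    "load_epochs",
    "save_epochs",
    "crop",
    "index_to_time",
    "time_to_index",
    "build_adjacency",
    "auto_adjacency_max_dist",
    "biosemi128_layout",
    "fibonacci_layout",
    "map_1020_to_abc",
    "DEFAULT_SFREQ",
    "DEFAULT_ADJACENCY_MAX_DIST",
]

#: Packaged default sampling rate (Hz).  768 samples spanning [0, 1500) ms
#: imply a 1000/512 = 1.953125 ms sample period.
DEFAULT_SFREQ = 512.0

#: Frozen unit-sphere chord threshold for the default adjacency graph; gives
#: minimum degree 2 (mean 4.5) on the packaged 128-channel layout.
DEFAULT_ADJACENCY_MAX_DIST = 0.35

_TIME_ATOL_MS = 1e-9


class ValidationError(ValueError):
    """Raised when a container violates a structural invariant."""


# ---------------------------------------------------------------------------
# EpochedData
# ---------------------------------------------------------------------------


@dataclass
class EpochedData:
    """Epoched EEG: ``data[n_trials, n_channels, n_times]`` in microvolts."""

    data: np.ndarray
    labels: np.ndarray
    times: np.ndarray
    sfreq: float
    channels: list[str]
    subject_ids: np.ndarray
    conditions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=object)
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        self.times = np.asarray(self.times, dtype=np.float64)
        self.channels = [str(c) for c in self.channels]
        if not self.conditions:
            # declared conditions default to order of first appearance
            seen: dict[str, None] = {}
            for lab in self.labels:
                seen.setdefault(str(lab), None)
            self.conditions = list(seen)
        self.validate()

    # -- structural invariants ---------------------------------------------
    def validate(self) -> None:
        if self.data.ndim != 3:
            raise ValidationError(f"data must be 3-D, got shape {self.data.shape}")
        n_trials, n_channels, n_times = self.data.shape
        if len(self.labels) != n_trials:
            raise ValidationError(
                f"labels: expected {n_trials} entries, got {len(self.labels)}"
            )
        if len(self.subject_ids) != n_trials:
            raise ValidationError(
                f"subject_ids: expected {n_trials} entries, got {len(self.subject_ids)}"
            )
        if len(self.channels) != n_channels:
            raise ValidationError(
                f"channels: expected {n_channels} names, got {len(self.channels)}"
            )
        if len(set(self.channels)) != n_channels:
            raise ValidationError("channels: names must be unique")
        if len(self.times) != n_times:
            raise ValidationError(
                f"times: expected {n_times} entries, got {len(self.times)}"
            )
        if n_times > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValidationError("times: must be strictly increasing")
            if np.max(np.abs(dt - 1000.0 / self.sfreq)) > _TIME_ATOL_MS:
                raise ValidationError(
                    "times: grid spacing inconsistent with sfreq "
                    f"({np.unique(dt)} vs {1000.0 / self.sfreq})"
                )
        bad = sorted({str(x) for x in self.labels} - set(self.conditions))
        if bad:
            raise ValidationError(f"labels: {bad} not among conditions {self.conditions}")

    # -- convenience ---------------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def subset(self, idx) -> "EpochedData":
        """New container restricted to the given trial indices."""
        idx = np.asarray(idx)
        return EpochedData(
            data=self.data[idx],
            labels=self.labels[idx],
            times=self.times.copy(),
            sfreq=self.sfreq,
            channels=list(self.channels),
            subject_ids=self.subject_ids[idx],
            conditions=list(self.conditions),
        )

    def label_indices(self) -> np.ndarray:
        """Per-trial index into :attr:`conditions`."""
        lut = {c: i for i, c in enumerate(self.conditions)}
        return np.array([lut[str(x)] for x in self.labels], dtype=np.intp)


def save_epochs(epochs: EpochedData, path: str | Path) -> Path:
    """Write the directory container: ``data.f32`` + ``meta.json``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    arr = np.ascontiguousarray(epochs.data, dtype="<f4")
    arr.tofile(path / "data.f32")
    meta = {
        "shape": list(epochs.data.shape),
        "dtype": "float32-le",
        "sfreq": epochs.sfreq,
        "t0_ms": float(epochs.times[0]),
        "channels": list(epochs.channels),
        "conditions": list(epochs.conditions),
        "labels": [str(x) for x in epochs.labels],
        "subject_ids": [str(x) for x in epochs.subject_ids],
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    return path


def load_epochs(path: str | Path) -> EpochedData:
    """Load and validate an epochs container written by :func:`save_epochs`."""
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise ValidationError(f"missing metadata file {meta_path}")
    meta = json.loads(meta_path.read_text())
    for key in ("shape", "sfreq", "t0_ms", "channels", "labels", "subject_ids"):
        if key not in meta:
            raise ValidationError(f"metadata missing field '{key}'")
    shape = tuple(int(s) for s in meta["shape"])
    raw = np.fromfile(path / "data.f32", dtype="<f4")
    if raw.size != int(np.prod(shape)):
        raise ValidationError(
            f"data: file holds {raw.size} values, metadata shape {shape} "
            f"needs {int(np.prod(shape))}"
        )
    n_times = shape[2]
    times = meta["t0_ms"] + np.arange(n_times) * (1000.0 / meta["sfreq"])
    return EpochedData(
        data=raw.reshape(shape),
        labels=np.array(meta["labels"], dtype=object),
        times=times,
        sfreq=float(meta["sfreq"]),
        channels=list(meta["channels"]),
        subject_ids=np.array(meta["subject_ids"], dtype=object),
        conditions=list(meta.get("conditions", [])),
    )


# ---------------------------------------------------------------------------
# Time grid
# ---------------------------------------------------------------------------


def index_to_time(i: int, sfreq: float, t0: float = 0.0, n_times: int | None = None) -> float:
    """Latency (ms) of sample ``i`` on the grid ``t0 + i * 1000/sfreq``."""
    if i < 0 or (n_times is not None and i >= n_times):
        raise IndexError(f"sample index {i} out of range [0, {n_times})")
    return t0 + i * 1000.0 / sfreq


def time_to_index(t: float, sfreq: float, t0: float = 0.0, n_times: int | None = None) -> int:
    """Nearest-sample index of latency ``t`` ms (exact inverse on the grid)."""
    i = int(round((t - t0) * sfreq / 1000.0))
    if i < 0 or (n_times is not None and i >= n_times):
        raise IndexError(f"latency {t} ms maps to sample {i}, out of range [0, {n_times})")
    return i


def crop(epochs: EpochedData, t_start: float, t_end: float) -> EpochedData:
    """Keep samples with ``t_start <= t < t_end`` (half-open interval)."""
    if t_start >= t_end:
        raise ValueError(f"empty interval: t_start={t_start} >= t_end={t_end}")
    mask = (epochs.times >= t_start - _TIME_ATOL_MS) & (epochs.times < t_end - _TIME_ATOL_MS)
    if not mask.any():
        raise ValueError(f"crop [{t_start}, {t_end}) does not overlap the time axis")
    return EpochedData(
        data=epochs.data[:, :, mask],
        labels=epochs.labels,
        times=epochs.times[mask],
        sfreq=epochs.sfreq,
        channels=list(epochs.channels),
        subject_ids=epochs.subject_ids,
        conditions=list(epochs.conditions),
    )


# ---------------------------------------------------------------------------
# Channel layout and adjacency
# ---------------------------------------------------------------------------


@dataclass
class ChannelLayout:
    """Electrode names with unit-sphere 3-D head coordinates and a 2-D
    azimuthal projection used for topography exports."""

    names: list[str]
    pos3d: np.ndarray  # (n, 3)
    pos2d: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        self.names = [str(n) for n in self.names]
        self.pos3d = np.asarray(self.pos3d, dtype=float)
        self.pos2d = np.asarray(self.pos2d, dtype=float)
        if len(self.names) != len(set(self.names)):
            raise ValidationError("layout: duplicate channel names")
        if self.pos3d.shape != (len(self.names), 3):
            raise ValidationError("layout: pos3d must be (n_channels, 3)")
        if self.pos2d.shape != (len(self.names), 2):
            raise ValidationError("layout: pos2d must be (n_channels, 2)")

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def subset(self, names: list[str]) -> "ChannelLayout":
        idx = [self.names.index(n) for n in names]
        return ChannelLayout(list(names), self.pos3d[idx], self.pos2d[idx])

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["name", "x", "y", "z", "x2d", "y2d"])
            for name, p3, p2 in zip(self.names, self.pos3d, self.pos2d):
                w.writerow([name, *(f"{v:.9g}" for v in p3), *(f"{v:.9g}" for v in p2)])
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "ChannelLayout":
        names, p3, p2 = [], [], []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                names.append(row["name"])
                p3.append([float(row["x"]), float(row["y"]), float(row["z"])])
                p2.append([float(row["x2d"]), float(row["y2d"])])
        return cls(names, np.array(p3), np.array(p2))


def _project_2d(pos3d: np.ndarray) -> np.ndarray:
    """Azimuthal-equidistant projection of unit vectors (vertex at origin)."""
    x, y, z = pos3d.T
    theta = np.arccos(np.clip(z, -1.0, 1.0))
    phi = np.arctan2(y, x)
    return np.column_stack([theta * np.cos(phi), theta * np.sin(phi)])


@functools.lru_cache(maxsize=1)
def _biosemi128_positions() -> tuple[tuple[str, ...], bytes]:
    import mne

    montage = mne.channels.make_standard_montage("biosemi128")
    pos = montage.get_positions()["ch_pos"]
    names = tuple(pos)
    P = np.array([pos[n] for n in names])
    P /= np.linalg.norm(P, axis=1, keepdims=True)
    return names, P.tobytes()


def biosemi128_layout() -> ChannelLayout:
    """The packaged 128-electrode layout (ABC convention A1..D32), positions
    normalized to the unit sphere."""
    names, raw = _biosemi128_positions()
    P = np.frombuffer(raw, dtype=float).reshape(len(names), 3)
    return ChannelLayout(list(names), P, _project_2d(P))


def fibonacci_layout(n_channels: int, prefix: str = "E") -> ChannelLayout:
    """Synthetic cap layout: ``n_channels`` points of a Fibonacci lattice on
    the upper hemisphere.  Used by the simulator's reduced presets."""
    if n_channels < 2:
        raise ValueError("need at least 2 channels")
    k = np.arange(n_channels)
    z = 0.05 + (1.0 - 0.05) * (k + 0.5) / n_channels  # cap, not full sphere
    phi = k * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    r = np.sqrt(1.0 - z**2)
    P = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    names = [f"{prefix}{i + 1:02d}" for i in k]
    return ChannelLayout(names, P, _project_2d(P))


@dataclass
class AdjacencyGraph:
    """Symmetric channel-neighborhood graph (no self-loops)."""

    neighbors: dict[str, set[str]]

    def __post_init__(self) -> None:
        for a, nbrs in self.neighbors.items():
            if a in nbrs:
                raise ValidationError(f"adjacency: self-neighbor {a}")
            for b in nbrs:
                if a not in self.neighbors.get(b, set()):
                    raise ValidationError(f"adjacency: asymmetric pair ({a}, {b})")

    @property
    def channels(self) -> list[str]:
        return list(self.neighbors)

    def degree(self, name: str) -> int:
        return len(self.neighbors[name])

    def edges(self) -> list[tuple[str, str]]:
        out = []
        for a, nbrs in self.neighbors.items():
            for b in nbrs:
                if a < b:
                    out.append((a, b))
        return sorted(out)

    def to_edge_csv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["channel_a", "channel_b"])
            w.writerows(self.edges())
        return path


def auto_adjacency_max_dist(
    layout: ChannelLayout, min_degree: int = 2, pad: float = 1.05
) -> float:
    """Smallest distance threshold that guarantees every channel at least
    ``min_degree`` neighbors, padded by 5%.  On the packaged 128-channel
    layout this lands near the frozen default 0.35."""
    P = layout.pos3d
    D = np.linalg.norm(P[:, None, :] - P[None, :, :], axis=2)
    np.fill_diagonal(D, np.inf)
    kth = np.sort(D, axis=1)[:, min_degree - 1]
    return float(kth.max() * pad)


def build_adjacency(
    layout: ChannelLayout, max_dist: float | None = None
) -> AdjacencyGraph:
    """Channels are adjacent iff their Euclidean 3-D distance is <= max_dist.

    With ``max_dist=None`` the threshold comes from
    :func:`auto_adjacency_max_dist` (guaranteed minimum degree 2).
    """
    if max_dist is None:
        max_dist = auto_adjacency_max_dist(layout)
    if max_dist <= 0:
        raise ValueError(f"max_dist must be positive, got {max_dist}")
    P = layout.pos3d
    finite = np.isfinite(P).all(axis=1)
    if finite.sum() < 2:
        raise ValueError("need at least 2 channels with finite positions")
    D = np.linalg.norm(P[:, None, :] - P[None, :, :], axis=2)
    np.fill_diagonal(D, np.inf)
    D[~finite, :] = np.inf
    D[:, ~finite] = np.inf
    neighbors = {
        name: {layout.names[j] for j in np.nonzero(D[i] <= max_dist)[0]}
        for i, name in enumerate(layout.names)
    }
    return AdjacencyGraph(neighbors)


# ---------------------------------------------------------------------------
# 10-20 aliasing for the packaged BioSemi layout
# ---------------------------------------------------------------------------


@functools.lru_cache(maxsize=1)
def _standard_1005_positions() -> dict[str, tuple[float, float, float]]:
    import warnings

    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        montage = mne.channels.make_standard_montage("standard_1005")
    out = {}
    for name, p in montage.get_positions()["ch_pos"].items():
        p = np.asarray(p, dtype=float)
        n = np.linalg.norm(p)
        if np.isfinite(n) and n > 0:
            out[name] = tuple(p / n)
    return out


def map_1020_to_abc(names: list[str], layout: ChannelLayout | None = None) -> dict[str, str]:
    """Map 10-20/10-05 electrode names (e.g. ``P8``, ``PO7``) to the nearest
    BioSemi ABC channels by unit-sphere position, injectively (no two aliases
    share one ABC channel).  The study layout's manual equivalences are not
    published, so this positional matching is the packaged stand-in.
    """
    from scipy.optimize import linear_sum_assignment

    layout = layout or biosemi128_layout()
    std = _standard_1005_positions()
    unknown = [n for n in names if n not in std]
    if unknown:
        raise KeyError(
            f"unknown 10-20 electrode name(s) {unknown}; valid examples: "
            "P7, P8, PO7, PO8, P9, P10, O1, O2, Oz, Pz"
        )
    Q = np.array([std[n] for n in names])
    cost = np.linalg.norm(Q[:, None, :] - layout.pos3d[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(cost)
    return {names[i]: layout.names[j] for i, j in zip(rows, cols)}
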