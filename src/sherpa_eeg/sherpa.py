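"""SHERPA core: distill importance curves/matrices into peaks, 40-ms time
windows centered on them, and ranked electrode sets with quantile membership.

Peak policy: sample ``i`` is a local maximum iff its value strictly exceeds
every neighbor within ``extremum_order`` samples; endpoints are never peaks
and flat plateaus yield none (strict-inequality rule — neighbor-comparison
implementations that emit plateau edges will diverge here, by design).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.signal import argrelmax

from .attribute import (
    AttributionTensor,
    ImportanceCurve,
    ImportanceMatrix,
    aggregate_importance,
    class_importance_curve,
)
from .core_data import time_to_index

__all__ = [
    "SherpaConfig",
    "Peak",
    "Window",
    "WindowReport",
    "find_importance_peaks",
    "extract_window",
    "rank_electrodes",
    "sherpa_report",
    "report_to_json",
]


@dataclass
class SherpaConfig:
    extremum_order: int = 10  # neighborhood half-width, samples (~19.5 ms @ 512 Hz)
    window_length_ms: float = 40.0
    quantile_thresholds: tuple[float, ...] = (0.75, 0.9)
    top_k_peaks: int = 2
    trial_scope: str = "all_trials"

    def __post_init__(self) -> None:
        if self.extremum_order < 1:
            raise ValueError("extremum_order must be >= 1")
        if self.window_length_ms <= 0:
            raise ValueError("window_length_ms must be > 0")


@dataclass
class Peak:
    latency_ms: float
    index: int
    value: float


@dataclass
class Window:
    t_lo_ms: float
    t_hi_ms: float
    i_lo: int
    i_hi: int  # inclusive
    clipped: bool = False


@dataclass
class WindowReport:
    condition: str
    peak: Peak
    window: Window
    electrode_scores: dict[str, float]
    quantile_sets: dict[float, list[str]] = field(default_factory=dict)


def find_importance_peaks(curve: ImportanceCurve, cfg: SherpaConfig) -> list[Peak]:
    """Local maxima of the importance curve, strict within ``extremum_order``
    samples, sorted by descending value and truncated to ``top_k_peaks``."""
    vals = np.asarray(curve.values, dtype=float)
    if len(vals) <= 2 * cfg.extremum_order:
        raise ValueError(
            f"curve length {len(vals)} must exceed 2*extremum_order="
            f"{2 * cfg.extremum_order}"
        )
    (idx,) = argrelmax(vals, order=cfg.extremum_order, mode="clip")
    peaks = [Peak(latency_ms=float(curve.times[i]), index=int(i), value=float(vals[i]))
             for i in idx]
    peaks.sort(key=lambda p: (-p.value, p.index))
    return peaks[: cfg.top_k_peaks]


def extract_window(
    peak_latency_ms: float, window_length_ms: float, times: np.ndarray
) -> Window:
    """Window of the configured length with the peak at its exact center,
    clipped to the time grid if necessary (flagged)."""
    if window_length_ms <= 0:
        raise ValueError("window_length_ms must be > 0")
    times = np.asarray(times, dtype=float)
    half = window_length_ms / 2.0
    t_lo, t_hi = peak_latency_ms - half, peak_latency_ms + half
    clipped = False
    if t_lo < times[0]:
        t_lo, clipped = float(times[0]), True
    if t_hi > times[-1]:
        t_hi, clipped = float(times[-1]), True
    sfreq = 1000.0 / (times[1] - times[0])
    i_lo = time_to_index(t_lo, sfreq, t0=times[0], n_times=len(times))
    i_hi = time_to_index(t_hi, sfreq, t0=times[0], n_times=len(times))
    return Window(t_lo_ms=t_lo, t_hi_ms=t_hi, i_lo=i_lo, i_hi=i_hi, clipped=clipped)


def rank_electrodes(
    matrix: ImportanceMatrix,
    window: Window,
    cfg: SherpaConfig,
    condition: str = "",
    peak: Peak | None = None,
) -> WindowReport:
    """Mean importance per electrode over the window samples, plus the
    channels at or above each configured empirical quantile of those scores
    (the 0.9-set is nested inside the 0.75-set by construction)."""
    if window.i_hi < window.i_lo:
        raise ValueError("empty window")
    if window.i_hi >= matrix.values.shape[1]:
        raise ValueError("window exceeds the matrix time range")
    scores = matrix.values[:, window.i_lo : window.i_hi + 1].mean(axis=1)
    names = list(matrix.channels)
    qsets: dict[float, list[str]] = {}
    for q in sorted(cfg.quantile_thresholds):
        thr = np.quantile(scores, q)
        qsets[q] = [n for n, s in zip(names, scores) if s >= thr]
    return WindowReport(
        condition=condition,
        peak=peak or Peak(float("nan"), -1, float("nan")),
        window=window,
        electrode_scores={n: float(s) for n, s in zip(names, scores)},
        quantile_sets=qsets,
    )


def sherpa_report(
    attr: AttributionTensor,
    cfg: SherpaConfig | None = None,
    labels: np.ndarray | None = None,
) -> dict[str, list[WindowReport]]:
    """Full SHERPA distillation: per class, find importance peaks, cut a
    window around each retained peak, and rank electrodes in it against the
    trial-and-class aggregated importance matrix."""
    cfg = cfg or SherpaConfig()
    matrix = aggregate_importance(attr)
    report: dict[str, list[WindowReport]] = {}
    for cls in attr.class_names:
        curve = class_importance_curve(
            attr, cls, trial_scope=cfg.trial_scope, labels=labels
        )
        entries = []
        for peak in find_importance_peaks(curve, cfg):
            window = extract_window(peak.latency_ms, cfg.window_length_ms, curve.times)
            entries.append(rank_electrodes(matrix, window, cfg, condition=cls, peak=peak))
        report[cls] = entries
    return report


def report_to_json(report: dict[str, list[WindowReport]], path: str | Path | None = None) -> str:
    """Machine-readable report (JSON with sorted keys, so byte-stable)."""
    payload = {
        cls: [
            {
                "condition": wr.condition,
                "peak": asdict(wr.peak),
                "window": asdict(wr.window),
                "electrode_scores": wr.electrode_scores,
                "quantile_sets": {str(q): chs for q, chs in wr.quantile_sets.items()},
            }
            for wr in entries
        ]
        for cls, entries in report.items()
    }
    text = json.dumps(payload, indent=1, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text
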