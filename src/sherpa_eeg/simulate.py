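"""Synthetic epoched-ERP generator.

Builds datasets with the statistical structure the downstream analysis
assumes: a small number of Gaussian-timecourse components (a posterior P100,
an occipito-temporal N170, an optional late component) with per-condition
gains, trial-level amplitude/latency jitter, and pink + white sensor noise.
Everything is deterministic given the config seed, so the full pipeline is
testable without any recorded data.

Topographies are abstract weight maps on the electrode sphere (no dipole /
leadfield modeling).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core_data import (
    ChannelLayout,
    EpochedData,
    biosemi128_layout,
    build_adjacency,
    fibonacci_layout,
)

__all__ = [
    "ComponentSpec",
    "NoiseSpec",
    "SimulationConfig",
    "component_timecourse",
    "simulate_epochs",
    "null_dataset",
    "preset_desk",
    "preset_n170",
    "preset_null",
    "gaussian_topography",
]


@dataclass
class ComponentSpec:
    """One ERP component: Gaussian time course times a fixed topography.

    amplitude is the signed peak value in microvolts at the topography's
    maximum-weight channel; ``condition_gains`` multiply it per condition.
    """

    name: str
    latency_ms: float
    width_ms: float  # Gaussian SD of the time course
    amplitude_uv: float
    topography: np.ndarray  # per-channel weight in [-1, 1]
    condition_gains: dict[str, float]
    latency_jitter_sd_ms: float = 0.0
    amplitude_jitter_sd: float = 0.0  # fractional

    def __post_init__(self) -> None:
        if self.width_ms <= 0:
            raise ValueError(f"component {self.name}: width must be > 0")
        self.topography = np.asarray(self.topography, dtype=float)


@dataclass
class NoiseSpec:
    """Additive sensor noise: 1/f (pink) + white, optionally mixed across
    spatial neighbors."""

    pink_sd_uv: float = 1.0
    white_sd_uv: float = 0.5
    spatial_smoothing: float = 0.0  # neighbor-mixing coefficient in [0, 1)

    def __post_init__(self) -> None:
        if self.pink_sd_uv < 0 or self.white_sd_uv < 0:
            raise ValueError("noise SDs must be >= 0")
        if not 0.0 <= self.spatial_smoothing < 1.0:
            raise ValueError("spatial_smoothing must be in [0, 1)")


@dataclass
class SimulationConfig:
    conditions: list[str]
    n_subjects: int
    trials_per_condition: int  # per subject, balanced by construction
    layout: ChannelLayout
    components: list[ComponentSpec]
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    sfreq: float = 512.0
    t_start_ms: float = 0.0
    t_end_ms: float = 500.0
    seed: int = 0

    @property
    def n_times(self) -> int:
        return int(round((self.t_end_ms - self.t_start_ms) * self.sfreq / 1000.0))

    @property
    def times(self) -> np.ndarray:
        return self.t_start_ms + np.arange(self.n_times) * (1000.0 / self.sfreq)

    def validate(self) -> None:
        if self.n_subjects < 1 or self.trials_per_condition < 1:
            raise ValueError("need at least one subject and one trial per condition")
        if self.n_times < 2:
            raise ValueError("epoch span too short for the sampling rate")
        n_ch = self.layout.n_channels
        for comp in self.components:
            if comp.topography.shape != (n_ch,):
                raise ValueError(
                    f"component {comp.name}: topography has {comp.topography.shape} "
                    f"weights, layout has {n_ch} channels"
                )
            missing = set(self.conditions) - set(comp.condition_gains)
            if missing:
                raise ValueError(f"component {comp.name}: no gain for {sorted(missing)}")


def component_timecourse(spec: ComponentSpec, times: np.ndarray) -> np.ndarray:
    """Unit-peak Gaussian bump exp(-(t - latency)^2 / (2 width^2))."""
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("times grid is empty")
    return np.exp(-((times - spec.latency_ms) ** 2) / (2.0 * spec.width_ms**2))


def gaussian_topography(
    layout: ChannelLayout, centers: np.ndarray, sigma_rad: float = 0.5
) -> np.ndarray:
    """Per-channel weights exp(-angle^2 / (2 sigma^2)) to the nearest of the
    given unit-vector centers (bilateral maps use two centers)."""
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    centers = centers / np.linalg.norm(centers, axis=1, keepdims=True)
    cosang = np.clip(layout.pos3d @ centers.T, -1.0, 1.0)
    ang = np.arccos(cosang).min(axis=1)
    return np.exp(-(ang**2) / (2.0 * sigma_rad**2))


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], sd: float) -> np.ndarray:
    """1/f-amplitude noise along the last axis, unit SD per trace, scaled."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n)
    scale = np.zeros_like(f)
    scale[1:] = 1.0 / f[1:]
    x = np.fft.irfft(spec * scale, n=n, axis=-1)
    s = x.std(axis=-1, keepdims=True)
    np.maximum(s, 1e-12, out=s)
    return sd * x / s


def _smoothing_matrix(layout: ChannelLayout, coeff: float) -> np.ndarray:
    adj = build_adjacency(layout)
    n = layout.n_channels
    M = np.eye(n) * (1.0 - coeff)
    index = {name: i for i, name in enumerate(layout.names)}
    for a, nbrs in adj.neighbors.items():
        if nbrs:
            w = coeff / len(nbrs)
            for b in nbrs:
                M[index[a], index[b]] += w
    return M


def simulate_epochs(config: SimulationConfig, seed: int | None = None) -> EpochedData:
    """Draw one dataset: sum of jittered components plus pink + white noise.

    Trial order is subject-major, condition-minor; labels are balanced per
    subject by construction.  Deterministic given the seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    times = config.times
    n_ch, n_t = config.layout.n_channels, config.n_times
    n_trials_block = config.trials_per_condition
    smooth = (
        _smoothing_matrix(config.layout, config.noise.spatial_smoothing)
        if config.noise.spatial_smoothing > 0
        else None
    )

    blocks, labels, subjects = [], [], []
    for s in range(config.n_subjects):
        sid = f"S{s + 1:02d}"
        for cond in config.conditions:
            x = np.zeros((n_trials_block, n_ch, n_t), dtype=np.float64)
            for comp in config.components:
                gain = comp.condition_gains[cond]
                lat_jit = (
                    rng.normal(0.0, comp.latency_jitter_sd_ms, n_trials_block)
                    if comp.latency_jitter_sd_ms > 0
                    else np.zeros(n_trials_block)
                )
                amp_jit = (
                    rng.normal(0.0, comp.amplitude_jitter_sd, n_trials_block)
                    if comp.amplitude_jitter_sd > 0
                    else np.zeros(n_trials_block)
                )
                tc = np.exp(
                    -((times[None, :] - (comp.latency_ms + lat_jit)[:, None]) ** 2)
                    / (2.0 * comp.width_ms**2)
                )
                amp = gain * comp.amplitude_uv * (1.0 + amp_jit)
                x += amp[:, None, None] * comp.topography[None, :, None] * tc[:, None, :]
            noise = np.zeros_like(x)
            if config.noise.pink_sd_uv > 0:
                noise += _pink_noise(rng, x.shape, config.noise.pink_sd_uv)
            if config.noise.white_sd_uv > 0:
                noise += rng.normal(0.0, config.noise.white_sd_uv, x.shape)
            if smooth is not None:
                noise = np.einsum("ij,tjs->tis", smooth, noise)
            x += noise
            blocks.append(x.astype(np.float32))
            labels.extend([cond] * n_trials_block)
            subjects.extend([sid] * n_trials_block)

    return EpochedData(
        data=np.concatenate(blocks, axis=0),
        labels=np.array(labels, dtype=object),
        times=times,
        sfreq=config.sfreq,
        channels=list(config.layout.names),
        subject_ids=np.array(subjects, dtype=object),
        conditions=list(config.conditions),
    )


def null_dataset(config: SimulationConfig, seed: int | None = None) -> EpochedData:
    """As :func:`simulate_epochs` but with every component's condition gains
    replaced by their mean, so condition labels are exchangeable."""
    comps = []
    for comp in config.components:
        g = float(np.mean(list(comp.condition_gains.values())))
        comps.append(replace(comp, condition_gains={c: g for c in config.conditions}))
    return simulate_epochs(replace(config, components=comps), seed=seed)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

_CONDITIONS = ["face", "blurred", "scrambled"]


def _desk_components(layout: ChannelLayout, effect: str) -> list[ComponentSpec]:
    posterior = gaussian_topography(layout, np.array([[0.0, -0.8, 0.6]]), 0.5)
    lateral = gaussian_topography(
        layout, np.array([[0.7, -0.6, 0.4], [-0.7, -0.6, 0.4]]), 0.45
    )
    if effect == "strong":
        n170_amp, n170_gains = -8.0, {"face": 1.0, "blurred": 0.1, "scrambled": 0.5}
    elif effect == "standard":
        n170_amp, n170_gains = -5.0, {"face": 1.0, "blurred": 0.5, "scrambled": 0.9}
    else:
        raise ValueError(f"unknown effect level '{effect}'")
    return [
        ComponentSpec(
            "p100", 100.0, 12.0, 4.0, posterior,
            {c: 1.0 for c in _CONDITIONS},
            latency_jitter_sd_ms=4.0, amplitude_jitter_sd=0.1,
        ),
        ComponentSpec(
            "n170", 170.0, 15.0, n170_amp, lateral, n170_gains,
            latency_jitter_sd_ms=5.0, amplitude_jitter_sd=0.15,
        ),
        ComponentSpec(
            "late", 300.0, 25.0, -4.0, posterior,
            {"face": 1.0, "blurred": 0.2, "scrambled": 0.2},
            latency_jitter_sd_ms=8.0, amplitude_jitter_sd=0.15,
        ),
    ]


def preset_desk(effect: str = "strong", seed: int = 0) -> SimulationConfig:
    """Reduced preset for fast CPU runs: 3 conditions x 8 subjects x 30
    trials, 32 synthetic cap channels, 0-500 ms at 512 Hz (256 samples)."""
    layout = fibonacci_layout(32)
    return SimulationConfig(
        conditions=list(_CONDITIONS),
        n_subjects=8,
        trials_per_condition=30,
        layout=layout,
        components=_desk_components(layout, effect),
        noise=NoiseSpec(pink_sd_uv=1.0, white_sd_uv=0.5),
        sfreq=512.0,
        t_start_ms=0.0,
        t_end_ms=500.0,
        seed=seed,
    )


def preset_n170(
    n_subjects: int = 26, trials_per_condition: int = 60, seed: int = 0
) -> SimulationConfig:
    """Study-scale preset: 26 subjects x 60 trials x 3 conditions, the
    packaged 128-channel layout, epochs 0-1500 ms at 512 Hz (768 samples).

    Component gains (N170 weakest for blurred faces; late component
    face-specific) are fixture parameters chosen to mirror the ordering the
    analysis is meant to recover, not measured quantities.
    """
    layout = biosemi128_layout()
    idx = {n: i for i, n in enumerate(layout.names)}
    # Gaussian maps centered on occipito-temporal / occipital electrodes
    lateral = gaussian_topography(
        layout, layout.pos3d[[idx["B7"], idx["A10"]]], 0.4
    )
    posterior = gaussian_topography(layout, layout.pos3d[[idx["A22"]]], 0.5)
    components = [
        ComponentSpec(
            "p100", 100.0, 12.0, 5.0, posterior,
            {c: 1.0 for c in _CONDITIONS},
            latency_jitter_sd_ms=5.0, amplitude_jitter_sd=0.1,
        ),
        ComponentSpec(
            "n170", 170.0, 15.0, -6.0, lateral,
            {"face": 1.0, "blurred": 0.5, "scrambled": 0.9},
            latency_jitter_sd_ms=6.0, amplitude_jitter_sd=0.15,
        ),
        ComponentSpec(
            "late", 300.0, 30.0, -3.0, posterior,
            {"face": 1.0, "blurred": 0.2, "scrambled": 0.2},
            latency_jitter_sd_ms=10.0, amplitude_jitter_sd=0.2,
        ),
    ]
    return SimulationConfig(
        conditions=list(_CONDITIONS),
        n_subjects=n_subjects,
        trials_per_condition=trials_per_condition,
        layout=layout,
        components=components,
        noise=NoiseSpec(pink_sd_uv=2.0, white_sd_uv=1.0),
        sfreq=512.0,
        t_start_ms=0.0,
        t_end_ms=1500.0,
        seed=seed,
    )


def preset_null(
    n_subjects: int = 8,
    n_channels: int = 16,
    n_times: int = 64,
    trials_per_condition: int = 8,
    seed: int = 0,
) -> SimulationConfig:
    """Reduced-geometry exchangeable-null preset for type-I-error studies."""
    layout = fibonacci_layout(n_channels)
    posterior = gaussian_topography(layout, np.array([[0.0, -0.8, 0.6]]), 0.6)
    sfreq = 512.0
    comp = ComponentSpec(
        "p100", 60.0, 12.0, 3.0, posterior,
        {c: 1.0 for c in _CONDITIONS},
        latency_jitter_sd_ms=4.0, amplitude_jitter_sd=0.1,
    )
    return SimulationConfig(
        conditions=list(_CONDITIONS),
        n_subjects=n_subjects,
        trials_per_condition=trials_per_condition,
        layout=layout,
        components=[comp],
        noise=NoiseSpec(pink_sd_uv=1.0, white_sd_uv=0.5),
        sfreq=sfreq,
        t_start_ms=0.0,
        t_end_ms=n_times * 1000.0 / sfreq,
        seed=seed,
    )
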