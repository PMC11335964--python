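import numpy as np
import pytest

from sherpa_eeg import (
    ComponentSpec,
    EpochedData,
    NoiseSpec,
    SimulationConfig,
    fibonacci_layout,
)


def make_epochs(
    n_subjects=2,
    n_conditions=2,
    trials_per_condition=3,
    n_channels=4,
    n_times=16,
    sfreq=512.0,
    seed=0,
):
    """Small handmade epochs block with balanced labels."""
    rng = np.random.default_rng(seed)
    conds = [f"cond{i}" for i in range(n_conditions)]
    n_trials = n_subjects * n_conditions * trials_per_condition
    labels, subjects = [], []
    for s in range(n_subjects):
        for c in conds:
            labels += [c] * trials_per_condition
            subjects += [f"S{s:02d}"] * trials_per_condition
    return EpochedData(
        data=rng.normal(size=(n_trials, n_channels, n_times)).astype(np.float32),
        labels=np.array(labels, dtype=object),
        times=np.arange(n_times) * 1000.0 / sfreq,
        sfreq=sfreq,
        channels=[f"ch{i}" for i in range(n_channels)],
        subject_ids=np.array(subjects, dtype=object),
        conditions=conds,
    )


def tiny_simulation(seed=0, n_subjects=4, trials=8, n_channels=12, n_times=128,
                    noise=(0.8, 0.4)):
    """Separable 3-condition simulation small enough for seconds-scale training."""
    layout = fibonacci_layout(n_channels)
    topo = np.exp(
        -np.arccos(np.clip(layout.pos3d @ np.array([0.0, -0.8, 0.6]) / np.linalg.norm([0.0, -0.8, 0.6]), -1, 1)) ** 2
    )
    comp = ComponentSpec(
        "bump", 120.0, 15.0, -8.0, topo,
        {"face": 1.0, "blurred": 0.0, "scrambled": 0.5},
        latency_jitter_sd_ms=4.0, amplitude_jitter_sd=0.1,
    )
    return SimulationConfig(
        conditions=["face", "blurred", "scrambled"],
        n_subjects=n_subjects,
        trials_per_condition=trials,
        layout=layout,
        components=[comp],
        noise=NoiseSpec(pink_sd_uv=noise[0], white_sd_uv=noise[1]),
        sfreq=512.0,
        t_start_ms=0.0,
        t_end_ms=n_times * 1000.0 / 512.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
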