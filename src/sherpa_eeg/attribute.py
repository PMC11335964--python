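"""Expected-gradients (gradient SHAP) attribution and importance aggregation.

For a trial ``x`` and class output ``f_c`` (a softmax probability), the
attribution of feature ``i`` is the Monte-Carlo estimate

    E_{b ~ background, a ~ U(0,1)} [ d f_c / d x_i (b + a (x - b)) * (x_i - b_i) ]

i.e. integrated gradients averaged over a background distribution of
training trials.  Attributions are additive: summed over features they
approximate ``f_c(x) - E_b f_c(b)`` (the completeness property, which the
test suite checks against a trained network).

Aggregations mirror the reporting conventions of the analysis: absolute
values averaged over trials and summed over classes give the
channels x times :class:`ImportanceMatrix`; summed over channels they give
per-class :class:`ImportanceCurve` objects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "BackgroundSet",
    "AttributionTensor",
    "ImportanceMatrix",
    "ImportanceCurve",
    "GradientExplainer",
    "expected_gradients",
    "aggregate_importance",
    "class_importance_curve",
    "save_attribution",
    "load_attribution",
]


@dataclass
class BackgroundSet:
    """Reference trials the explainer integrates from."""

    samples: np.ndarray  # (n_bg, n_channels, n_times)
    seed: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float32)
        if self.samples.ndim != 3 or len(self.samples) < 1:
            raise ValueError("background needs >= 1 sample of shape (ch, times)")

    @classmethod
    def from_training_data(
        cls, X: np.ndarray, size: int = 100, seed: int = 0
    ) -> "BackgroundSet":
        """Default policy: ``size`` trials sampled uniformly from training."""
        rng = np.random.default_rng(seed)
        X = np.asarray(X)
        idx = rng.choice(len(X), size=min(size, len(X)), replace=False)
        return cls(samples=X[idx], seed=seed)


@dataclass
class AttributionTensor:
    """Signed per-trial, per-class attributions, in model-output probability
    units, with the same channel/time geometry as the input epochs."""

    values: np.ndarray  # (n_trials, n_classes, n_channels, n_times)
    class_names: list[str]
    channels: list[str]
    times: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 4:
            raise ValueError("attribution tensor must be 4-D")
        if not np.isfinite(self.values).all():
            raise ValueError("attribution tensor contains non-finite values")
        if self.values.shape[1] != len(self.class_names):
            raise ValueError("class axis does not match class_names")


@dataclass
class ImportanceMatrix:
    """Nonnegative channels x times aggregate of absolute attributions."""

    values: np.ndarray
    channels: list[str]
    times: np.ndarray
    aggregation: str = "mean_trials_sum_classes_abs"


@dataclass
class ImportanceCurve:
    """Per-time importance for one class, summed over electrodes."""

    class_name: str
    values: np.ndarray
    times: np.ndarray
    trial_scope: str = "all_trials"


class GradientExplainer:
    """shap-style interface: construct with (model, background), then call
    :meth:`shap_values` on the trials to explain.

    The model must expose ``predict_proba(X)`` and either
    ``class_input_gradients(X, class_indices)`` or
    ``output_input_gradient(X, class_index)`` returning d output_c / d input.
    """

    def __init__(self, model, background: BackgroundSet,
                 n_path_samples: int = 200, seed: int = 0, chunk: int = 64):
        if n_path_samples < 1:
            raise ValueError("n_path_samples must be >= 1")
        self.model = model
        self.background = background
        self.n_path_samples = n_path_samples
        self.seed = seed
        self.chunk = chunk

    def _grads(self, z: np.ndarray, class_indices: list[int]) -> np.ndarray:
        fn = getattr(self.model, "class_input_gradients", None)
        if fn is not None:
            return np.asarray(fn(z, class_indices))
        fn = getattr(self.model, "output_input_gradient", None)
        if fn is None:
            raise TypeError(
                "model provides no input-gradient method; a differentiable "
                "model exposing class_input_gradients or output_input_gradient "
                "is required"
            )
        return np.stack([np.asarray(fn(z, c)) for c in class_indices], axis=0)

    def shap_values(
        self, X: np.ndarray, class_names: list[str] | None = None,
        channels: list[str] | None = None, times: np.ndarray | None = None,
    ) -> AttributionTensor:
        X = np.asarray(X, dtype=np.float32)
        bg = self.background.samples
        if bg.shape[1:] != X.shape[1:]:
            raise ValueError(
                f"background geometry {bg.shape[1:]} != input geometry {X.shape[1:]}"
            )
        n_classes = np.asarray(self.model.predict_proba(X[:1])).shape[1]
        class_indices = list(range(n_classes))
        rng = np.random.default_rng(self.seed)
        m = self.n_path_samples
        out = np.zeros((len(X), n_classes) + X.shape[1:], dtype=np.float64)
        for t, x in enumerate(X):
            b_idx = rng.integers(0, len(bg), size=m)
            alpha = rng.uniform(0.0, 1.0, size=m).astype(np.float32)
            for lo in range(0, m, self.chunk):
                sel = slice(lo, min(lo + self.chunk, m))
                b = bg[b_idx[sel]]
                diff = x[None] - b
                z = b + alpha[sel, None, None] * diff
                g = self._grads(z, class_indices)  # (n_cls, chunk, C, T)
                out[t] += (g * diff[None]).sum(axis=1)
        out /= m
        n_t, n_ch, n_s = X.shape
        return AttributionTensor(
            values=out,
            class_names=class_names or [str(i) for i in class_indices],
            channels=channels or [f"ch{i}" for i in range(n_ch)],
            times=np.arange(n_s, dtype=float) if times is None else np.asarray(times),
            provenance={
                "n_path_samples": m,
                "seed": self.seed,
                "n_background": len(bg),
                "background_seed": self.background.seed,
                "model": type(self.model).__name__,
            },
        )


def expected_gradients(
    model, inputs: np.ndarray, background: BackgroundSet,
    n_path_samples: int = 200, seed: int = 0, **kw,
) -> AttributionTensor:
    """Functional wrapper over :class:`GradientExplainer`."""
    return GradientExplainer(
        model, background, n_path_samples=n_path_samples, seed=seed
    ).shap_values(inputs, **kw)


def aggregate_importance(attr: AttributionTensor) -> ImportanceMatrix:
    """Mean over trials of the class-summed absolute attributions."""
    if attr.values.shape[0] == 0:
        raise ValueError("attribution tensor has no trials")
    vals = np.abs(attr.values).sum(axis=1).mean(axis=0)
    return ImportanceMatrix(values=vals, channels=list(attr.channels),
                            times=np.asarray(attr.times))


def class_importance_curve(
    attr: AttributionTensor,
    class_name: str,
    trial_scope: str = "all_trials",
    labels: np.ndarray | None = None,
) -> ImportanceCurve:
    """Per-time importance for one class: mean over scoped trials of the
    channel-summed absolute attributions.

    ``trial_scope='class_trials'`` restricts the mean to trials whose label
    equals ``class_name`` (requires ``labels``).
    """
    if class_name not in attr.class_names:
        raise KeyError(f"unknown class {class_name!r}; have {attr.class_names}")
    c = attr.class_names.index(class_name)
    sel = np.abs(attr.values[:, c]).sum(axis=1)  # (n_trials, n_times)
    if trial_scope == "all_trials":
        curve = sel.mean(axis=0)
    elif trial_scope == "class_trials":
        if labels is None:
            raise ValueError("trial_scope='class_trials' requires labels")
        mask = np.array([str(x) for x in labels]) == class_name
        if not mask.any():
            raise ValueError(f"no trials labeled {class_name!r}")
        curve = sel[mask].mean(axis=0)
    else:
        raise ValueError("trial_scope must be 'all_trials' or 'class_trials'")
    return ImportanceCurve(class_name=class_name, values=curve,
                           times=np.asarray(attr.times), trial_scope=trial_scope)


# ---------------------------------------------------------------------------
# Persistence (epochs-container style: raw f32 + JSON sidecar)
# ---------------------------------------------------------------------------


def save_attribution(attr: AttributionTensor, path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.ascontiguousarray(attr.values, dtype="<f4").tofile(path / "data.f32")
    meta = {
        "shape": list(attr.values.shape),
        "dtype": "float32-le",
        "class_names": list(attr.class_names),
        "channels": list(attr.channels),
        "times": [float(t) for t in attr.times],
        "provenance": attr.provenance,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    return path


def load_attribution(path: str | Path) -> AttributionTensor:
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    shape = tuple(meta["shape"])
    vals = np.fromfile(path / "data.f32", dtype="<f4").reshape(shape)
    return AttributionTensor(
        values=vals.astype(np.float64),
        class_names=meta["class_names"],
        channels=meta["channels"],
        times=np.array(meta["times"]),
        provenance=meta.get("provenance", {}),
    )
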