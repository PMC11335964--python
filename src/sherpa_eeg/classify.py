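"""CNN epoch classifier: model/training configuration, subject-aware data
splitting, five-fold cross-validated training and test-set evaluation.

``EpochClassifier`` is a scikit-learn style estimator (``fit`` /
``predict`` / ``predict_proba``, fitted attributes with trailing
underscores) wrapping the numpy network in :mod:`sherpa_eeg._network`.

Protocol notes, matching the training recipe this pipeline validates:
early stopping monitors *validation loss* with a patience counter, while
the checkpoint that is kept is the epoch with the best *validation
accuracy* — two different metrics, on purpose.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold

from ._network import Adam, ConvNet
from .core_data import EpochedData

__all__ = [
    "ModelSpec",
    "TrainingConfig",
    "EvaluationReport",
    "EpochClassifier",
    "split_data",
    "train_crossval",
    "evaluate",
]


@dataclass
class ModelSpec:
    """Architecture hyperparameters.

    Defaults are the full-scale network: four conv layers with ascending
    filter counts 16..128, kernel 50 samples, GELU, L2 regularization,
    max-pooling, then three hidden dense layers 128/64/32 with ReLU and a
    softmax output.
    """

    conv_filters: tuple[int, ...] = (16, 32, 64, 128)
    kernel_size: int = 50
    pool_size: int = 2
    dense_units: tuple[int, ...] = (128, 64, 32)
    l2: float = 1e-4
    n_classes: int = 3

    @classmethod
    def desk(cls) -> "ModelSpec":
        """Reduced spec for 256-sample epochs: kernel scaled 50*(256/768)~17,
        filter/dense widths halved, so CPU training stays in minutes."""
        return cls(
            conv_filters=(8, 16, 32, 64),
            kernel_size=17,
            dense_units=(64, 32, 16),
        )


@dataclass
class TrainingConfig:
    batch_size: int = 64
    max_epochs: int = 200
    early_stop_patience: int = 50  # epochs without val-loss improvement
    n_folds: int = 5
    learning_rate: float = 1e-3
    test_fraction: float = 0.2
    holdout_subjects: int = 2  # subjects fully excluded from training
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")


@dataclass
class EvaluationReport:
    per_fold_val_accuracy: list[float]
    per_fold_test_accuracy: list[float]
    test_accuracy_mean: float
    test_accuracy_sd: float
    confusion: np.ndarray  # row-normalized, rows = true class
    classes: list[str]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        d = asdict(self)
        d["confusion"] = self.confusion.tolist()
        path.write_text(json.dumps(d, indent=1))
        return path


class EpochClassifier(BaseEstimator, ClassifierMixin):
    """CNN classifier over epochs ``X[n_trials, n_channels, n_times]``.

    Parameters mirror :class:`ModelSpec` plus the optimizer settings; the
    fitted network lives in ``net_`` and per-epoch metrics in ``history_``.
    """

    def __init__(
        self,
        spec: ModelSpec | None = None,
        learning_rate: float = 1e-3,
        batch_size: int = 64,
        max_epochs: int = 200,
        early_stop_patience: int = 50,
        random_state: int = 0,
    ):
        self.spec = spec
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.early_stop_patience = early_stop_patience
        self.random_state = random_state

    # -- estimator API -------------------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None):
        """Train with Adam on categorical cross-entropy.

        With validation data, early stopping (patience on val loss) and
        best-val-accuracy checkpointing are active; without it the model
        trains for ``max_epochs`` and keeps the final weights.
        """
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        spec = self.spec or ModelSpec(n_classes=len(self.classes_))
        if len(self.classes_) != spec.n_classes:
            spec = ModelSpec(**{**asdict(spec), "n_classes": len(self.classes_)})
        net = ConvNet(
            n_channels=X.shape[1],
            n_times=X.shape[2],
            n_classes=spec.n_classes,
            conv_filters=spec.conv_filters,
            kernel_size=spec.kernel_size,
            pool_size=spec.pool_size,
            dense_units=spec.dense_units,
            l2=spec.l2,
            seed=self.random_state,
        )
        opt = Adam(net.layers, lr=self.learning_rate)
        rng = np.random.default_rng(self.random_state)
        Y = np.eye(spec.n_classes, dtype=np.float32)[y_idx]
        have_val = X_val is not None
        if have_val:
            X_val = np.asarray(X_val, dtype=np.float32)
            yv_idx = np.searchsorted(self.classes_, np.asarray(y_val))
            Yv = np.eye(spec.n_classes, dtype=np.float32)[yv_idx]

        history: list[dict] = []
        best_val_loss, best_val_acc = np.inf, -np.inf
        best_weights = None
        since_best_loss = 0
        for epoch in range(self.max_epochs):
            order = rng.permutation(len(X))
            train_loss = 0.0
            for i in range(0, len(X), self.batch_size):
                sel = order[i : i + self.batch_size]
                train_loss += net.loss_and_param_grads(X[sel], Y[sel]) * len(sel)
                opt.step()
            entry = {"epoch": epoch, "train_loss": train_loss / len(X)}
            if have_val:
                val_loss, val_acc = net.evaluate_loss(X_val, Yv)
                entry.update(val_loss=val_loss, val_accuracy=val_acc)
                if val_acc > best_val_acc:
                    best_val_acc = val_acc
                    best_weights = net.get_weights()
                if val_loss < best_val_loss - 1e-12:
                    best_val_loss = val_loss
                    since_best_loss = 0
                else:
                    since_best_loss += 1
            history.append(entry)
            if have_val and since_best_loss >= self.early_stop_patience:
                break
        if best_weights is not None:
            net.set_weights(best_weights)
        self.net_ = net
        self.history_ = history
        self.best_val_accuracy_ = best_val_acc if have_val else None
        return self

    def predict_proba(self, X):
        return self.net_.predict_proba(np.asarray(X, dtype=np.float32))

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def score(self, X, y):
        return float(np.mean(self.predict(X) == np.asarray(y)))

    # -- attribution support -------------------------------------------------
    def class_input_gradients(self, X, class_indices):
        return self.net_.class_input_gradients(
            np.asarray(X, dtype=np.float32), class_indices
        )

    def output_input_gradient(self, X, class_index):
        return self.net_.output_input_gradient(
            np.asarray(X, dtype=np.float32), class_index
        )

    # -- persistence ----------------------------------------------------------
    def save(self, path: str | Path) -> Path:
        path = Path(path)
        self.net_.save(path)
        path.with_suffix(path.suffix + ".classes.json").write_text(
            json.dumps([str(c) for c in self.classes_])
        )
        return path

    @classmethod
    def load(cls, path: str | Path) -> "EpochClassifier":
        path = Path(path)
        est = cls()
        est.net_ = ConvNet.load(path)
        classes_file = path.with_suffix(path.suffix + ".classes.json")
        est.classes_ = np.array(json.loads(classes_file.read_text()), dtype=object)
        est.history_ = []
        return est


# ---------------------------------------------------------------------------
# Splitting, cross-validation, evaluation
# ---------------------------------------------------------------------------


def split_data(
    epochs: EpochedData, cfg: TrainingConfig
) -> tuple[EpochedData, EpochedData]:
    """Hold-out split: all trials of ``holdout_subjects`` randomly chosen
    subjects plus a stratified trial sample from the remaining subjects,
    together ~``test_fraction`` of all trials.  Deterministic given seed."""
    subjects = np.array(sorted({str(s) for s in epochs.subject_ids}))
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects to split")
    if cfg.holdout_subjects >= len(subjects):
        raise ValueError(
            f"holdout_subjects={cfg.holdout_subjects} must be < n_subjects={len(subjects)}"
        )
    rng = np.random.default_rng(cfg.seed)
    held = set(rng.choice(subjects, size=cfg.holdout_subjects, replace=False))
    subj = np.array([str(s) for s in epochs.subject_ids])
    test_mask = np.isin(subj, list(held))
    target = int(round(cfg.test_fraction * epochs.n_trials))
    need = target - int(test_mask.sum())
    if need > 0:
        rest = np.nonzero(~test_mask)[0]
        labels_rest = np.array([str(x) for x in epochs.labels])[rest]
        # proportional (stratified) sample per condition from the rest
        extra: list[np.ndarray] = []
        conds = epochs.conditions
        quota = [need // len(conds) + (1 if i < need % len(conds) else 0)
                 for i in range(len(conds))]
        for cond, q in zip(conds, quota):
            pool = rest[labels_rest == cond]
            q = min(q, len(pool))
            extra.append(rng.choice(pool, size=q, replace=False))
        test_mask[np.concatenate(extra).astype(int)] = True
    train_idx = np.nonzero(~test_mask)[0]
    test_idx = np.nonzero(test_mask)[0]
    return epochs.subset(train_idx), epochs.subset(test_idx)


def train_crossval(
    spec: ModelSpec, train: EpochedData, cfg: TrainingConfig
) -> list[EpochClassifier]:
    """Stratified k-fold cross-validated training (data shuffled prior to
    splitting into folds); returns one best-epoch model per fold."""
    if train.n_trials == 0:
        raise ValueError("training set is empty")
    y = np.array([str(x) for x in train.labels])
    skf = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed)
    models: list[EpochClassifier] = []
    for fold, (tr, va) in enumerate(skf.split(np.zeros(len(y)), y)):
        est = EpochClassifier(
            spec=spec,
            learning_rate=cfg.learning_rate,
            batch_size=cfg.batch_size,
            max_epochs=cfg.max_epochs,
            early_stop_patience=cfg.early_stop_patience,
            random_state=cfg.seed + fold,
        )
        est.fit(
            train.data[tr], y[tr], X_val=train.data[va], y_val=y[va]
        )
        models.append(est)
    return models


def evaluate(models: list, test: EpochedData) -> EvaluationReport:
    """Mean/SD of per-model test accuracy; confusion matrix (row-normalized)
    from the last fold's model."""
    if not models:
        raise ValueError("need at least one model state")
    y_true = np.array([str(x) for x in test.labels])
    last = models[-1]
    classes = [str(c) for c in last.classes_]
    if not set(y_true) <= set(classes):
        raise ValueError(
            f"test labels {sorted(set(y_true))} not covered by model classes {classes}"
        )
    accs = [float(np.mean(np.asarray(m.predict(test.data)).astype(str) == y_true))
            for m in models]
    pred = np.asarray(last.predict(test.data)).astype(str)
    k = len(classes)
    lut = {c: i for i, c in enumerate(classes)}
    conf = np.zeros((k, k))
    for t, p in zip(y_true, pred):
        conf[lut[t], lut[p]] += 1
    rows = conf.sum(axis=1, keepdims=True)
    conf = np.divide(conf, rows, out=np.zeros_like(conf), where=rows > 0)
    val_accs = [
        float(m.best_val_accuracy_)
        if getattr(m, "best_val_accuracy_", None) is not None
        else float("nan")
        for m in models
    ]
    return EvaluationReport(
        per_fold_val_accuracy=val_accs,
        per_fold_test_accuracy=accs,
        test_accuracy_mean=float(np.mean(accs)),
        test_accuracy_sd=float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
        confusion=conf,
        classes=classes,
    )
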