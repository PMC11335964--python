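"""End-to-end orchestration: simulate (or load) epochs, train the classifier,
attribute, distill the SHERPA report, run both comparator analyses, and write
every artifact plus a cross-method comparison table into a run directory.

A single global seed fans out to named per-stage substreams (stage name ->
derived seed), so each stage is independently reproducible and two runs with
the same seed produce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .attribute import (
    BackgroundSet,
    GradientExplainer,
    aggregate_importance,
    class_importance_curve,
    load_attribution,
    save_attribution,
)
from .classify import ModelSpec, TrainingConfig, evaluate, split_data, train_crossval
from .comparators import (
    PermConfig,
    cluster_permutation_test,
    conventional_analysis,
    subject_condition_averages,
)
from .core_data import EpochedData, build_adjacency, load_epochs, save_epochs
from .sherpa import SherpaConfig, report_to_json, sherpa_report
from .simulate import SimulationConfig, preset_desk, preset_n170, simulate_epochs

__all__ = ["RunConfig", "derive_seed", "run_pipeline", "export_figure_data"]

logger = logging.getLogger("sherpa_eeg")


def derive_seed(global_seed: int, stage: str) -> int:
    """Named-substream scheme: stable per-stage seed below 2**31."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


@dataclass
class AttributionSettings:
    background_size: int = 100
    n_path_samples: int = 200
    max_explain_trials: int | None = None  # cap on test trials to explain


@dataclass
class ConventionalSettings:
    electrodes: list[str] | None = None  # None -> literature N170 set (10-20 names)
    window_ms: tuple[float, float] | None = None


@dataclass
class RunConfig:
    simulation: SimulationConfig | None = None  # or load epochs from input_path
    input_path: str | None = None
    model: ModelSpec = field(default_factory=ModelSpec.desk)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    attribution: AttributionSettings = field(default_factory=AttributionSettings)
    sherpa: SherpaConfig = field(default_factory=SherpaConfig)
    permutation: PermConfig = field(default_factory=PermConfig)
    conventional: ConventionalSettings = field(default_factory=ConventionalSettings)
    adjacency_max_dist: float | None = None  # None -> auto (min degree 2)
    seed: int = 0

    @classmethod
    def desk(cls, seed: int = 0, effect: str = "strong") -> "RunConfig":
        return cls(simulation=preset_desk(effect=effect), seed=seed)

    @classmethod
    def study_scale(cls, seed: int = 0) -> "RunConfig":
        return cls(simulation=preset_n170(), model=ModelSpec(), seed=seed)


def _config_digest(cfg: RunConfig) -> str:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return str(o)

    blob = json.dumps(dataclasses.asdict(cfg), default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _provenance(outdir: Path, cfg: RunConfig, stages: dict) -> None:
    (outdir / "provenance.json").write_text(
        json.dumps(
            {
                "package_version": __version__,
                "config_hash": _config_digest(cfg),
                "global_seed": cfg.seed,
                "stage_seeds": {s: derive_seed(cfg.seed, s) for s in stages},
                "stage_seconds": stages,
            },
            indent=1,
            sort_keys=True,
        )
    )


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> Path:
    """Execute every stage; artifacts land in ``outdir``.  Any stage failure
    raises with the stage name, leaving earlier artifacts on disk."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "log.txt")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    stage_seconds: dict[str, float] = {}

    def stage(name):
        class _Timer:
            def __enter__(self):
                logger.info("stage %s: start", name)
                self.t0 = time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                stage_seconds[name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None:
                    logger.error("stage %s: FAILED: %s", name, exc)
                    _provenance(outdir, cfg, stage_seconds)
                    raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
                logger.info("stage %s: done in %.1fs", name, stage_seconds[name])

        return _Timer()

    try:
        with stage("simulate"):
            if cfg.simulation is not None:
                epochs = simulate_epochs(cfg.simulation, seed=derive_seed(cfg.seed, "simulate"))
                save_epochs(epochs, outdir / "epochs")
            elif cfg.input_path is not None:
                epochs = load_epochs(cfg.input_path)
            else:
                raise ValueError("RunConfig needs a simulation config or an input_path")
            layout = cfg.simulation.layout if cfg.simulation is not None else None

        with stage("split"):
            tcfg = dataclasses.replace(cfg.training, seed=derive_seed(cfg.seed, "split"))
            train, test = split_data(epochs, tcfg)

        with stage("train"):
            tcfg = dataclasses.replace(tcfg, seed=derive_seed(cfg.seed, "train"))
            models = train_crossval(cfg.model, train, tcfg)
            for i, m in enumerate(models):
                m.save(outdir / f"model_fold{i}.npz")

        with stage("evaluate"):
            report = evaluate(models, test)
            report.to_json(outdir / "evaluation.json")
            np.savetxt(
                outdir / "confusion.csv",
                report.confusion,
                delimiter=",",
                header=",".join(report.classes),
                comments="",
            )

        with stage("attribute"):
            background = BackgroundSet.from_training_data(
                train.data,
                size=cfg.attribution.background_size,
                seed=derive_seed(cfg.seed, "background"),
            )
            cap = cfg.attribution.max_explain_trials
            explain = test if cap is None or test.n_trials <= cap else test.subset(
                np.sort(
                    np.random.default_rng(derive_seed(cfg.seed, "explain_subset"))
                    .choice(test.n_trials, size=cap, replace=False)
                )
            )
            explainer = GradientExplainer(
                models[-1],
                background,
                n_path_samples=cfg.attribution.n_path_samples,
                seed=derive_seed(cfg.seed, "attribute"),
            )
            attr = explainer.shap_values(
                explain.data,
                class_names=[str(c) for c in models[-1].classes_],
                channels=epochs.channels,
                times=epochs.times,
            )
            save_attribution(attr, outdir / "attributions")
            (outdir / "explained_labels.json").write_text(
                json.dumps([str(x) for x in explain.labels])
            )

        with stage("sherpa"):
            matrix = aggregate_importance(attr)
            _write_matrix_csv(outdir / "importance_matrix.csv", matrix)
            for cls in attr.class_names:
                curve = class_importance_curve(
                    attr, cls, trial_scope=cfg.sherpa.trial_scope,
                    labels=explain.labels,
                )
                _write_curve_csv(outdir / f"importance_curve_{cls}.csv", curve)
            s_report = sherpa_report(attr, cfg.sherpa, labels=explain.labels)
            report_to_json(s_report, outdir / "sherpa_report.json")

        with stage("permtest"):
            adjacency = build_adjacency(layout, cfg.adjacency_max_dist) if layout else None
            if adjacency is None:
                raise ValueError("cluster test needs a channel layout (simulated runs provide one)")
            erp = subject_condition_averages(epochs)
            pcfg = dataclasses.replace(cfg.permutation, seed=derive_seed(cfg.seed, "permtest"))
            cluster_result = cluster_permutation_test(erp, pcfg, adjacency)
            cluster_result.to_json(outdir / "cluster_result.json")
            _write_cluster_mask(outdir / "cluster_mask.csv", cluster_result, epochs)

        with stage("anova"):
            electrodes = cfg.conventional.electrodes
            window = cfg.conventional.window_ms
            if electrodes is None:
                # literature names only resolve on the 128-channel montage;
                # on synthetic layouts default to the strongest N170-window channels
                if set(["A1", "B1"]) <= set(epochs.channels):
                    electrodes = None  # conventional_analysis resolves aliases
                else:
                    electrodes = _default_synthetic_electrodes(epochs)
            anova = conventional_analysis(epochs, electrodes, window)
            anova.to_json(outdir / "anova.json")

        with stage("compare"):
            comparison = _comparison_table(s_report, cluster_result, anova, cfg)
            (outdir / "comparison.json").write_text(
                json.dumps(comparison, indent=1, sort_keys=True)
            )

        _provenance(outdir, cfg, stage_seconds)
        return outdir
    finally:
        logger.removeHandler(handler)
        handler.close()


def _default_synthetic_electrodes(epochs: EpochedData, k: int = 6) -> list[str]:
    """Strongest grand-average |amplitude| channels in the 165-205 ms window."""
    mask = (epochs.times >= 165.0) & (epochs.times <= 205.0)
    if not mask.any():
        mask = np.ones(len(epochs.times), dtype=bool)
    score = np.abs(epochs.data[:, :, mask].mean(axis=0)).mean(axis=1)
    order = np.argsort(score)[::-1][:k]
    return [epochs.channels[i] for i in sorted(order)]


def _comparison_table(s_report, cluster_result, anova, cfg: RunConfig) -> dict:
    """Cross-method agreement: top SHERPA window + its 0.75-quantile
    electrodes vs significant-cluster channels vs conventional electrodes."""
    best = None
    for entries in s_report.values():
        for wr in entries:
            if best is None or wr.peak.value > best.peak.value:
                best = wr
    sig = cluster_result.significant(cfg.permutation.test_alpha)
    q = max(cfg.sherpa.quantile_thresholds)
    q_lo = min(cfg.sherpa.quantile_thresholds)
    sherpa_set = set(best.quantile_sets[q_lo]) if best else set()
    cluster_set = set().union(*(c.channels for c in sig)) if sig else set()
    conventional_set = set(anova.electrodes)
    return {
        "sherpa_top_window_ms": [best.window.t_lo_ms, best.window.t_hi_ms] if best else None,
        "sherpa_top_condition": best.condition if best else None,
        "sherpa_quantile": q_lo,
        "sherpa_electrodes": sorted(sherpa_set),
        "significant_clusters": len(sig),
        "min_cluster_p": min((c.p_value for c in cluster_result.clusters), default=None),
        "cluster_electrodes": sorted(cluster_set),
        "anova": {"F": anova.F, "df": [anova.df_num, anova.df_den], "p": anova.p,
                  "eta_sq_partial": anova.eta_sq_partial},
        "conventional_electrodes": sorted(conventional_set),
        "conventional_window_ms": list(anova.window_ms),
        "sherpa_cluster_overlap": sorted(sherpa_set & cluster_set),
        "sherpa_conventional_overlap": sorted(sherpa_set & conventional_set),
    }


def _write_matrix_csv(path: Path, matrix) -> None:
    import pandas as pd

    pd.DataFrame(
        matrix.values, index=matrix.channels, columns=[f"{t:.6g}" for t in matrix.times]
    ).to_csv(path, index_label="channel")


def _write_curve_csv(path: Path, curve) -> None:
    import pandas as pd

    pd.DataFrame(
        {"class": curve.class_name, "time_ms": curve.times, "value": curve.values}
    ).to_csv(path, index=False)


def _write_cluster_mask(path: Path, result, epochs: EpochedData) -> None:
    import pandas as pd

    rows = []
    for ci, c in enumerate(result.clusters):
        for ch, t in c.members:
            rows.append((ci, ch, t, float(epochs.times[t]), c.p_value))
    pd.DataFrame(
        rows, columns=["cluster", "channel", "time_index", "time_ms", "p_value"]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Figure-data exports
# ---------------------------------------------------------------------------


def export_figure_data(run_dir: str | Path, outdir: str | Path | None = None) -> Path:
    """Emit figure-ready CSV bundles from a completed run directory: the
    contour matrix, per-class curves, per-window topography tables, and
    grand-average ERP traces for the quantile electrode sets."""
    import pandas as pd

    run_dir = Path(run_dir)
    outdir = Path(outdir) if outdir else run_dir / "figures"
    for artifact in ("attributions", "sherpa_report.json", "epochs"):
        if not (run_dir / artifact).exists():
            raise FileNotFoundError(f"run directory missing artifact '{artifact}'")
    outdir.mkdir(parents=True, exist_ok=True)

    attr = load_attribution(run_dir / "attributions")
    matrix = aggregate_importance(attr)
    _write_matrix_csv(outdir / "contour_matrix.csv", matrix)

    curves = []
    for cls in attr.class_names:
        curve = class_importance_curve(attr, cls)
        curves.append(
            pd.DataFrame({"class": cls, "time_ms": curve.times, "value": curve.values})
        )
    pd.concat(curves, ignore_index=True).to_csv(outdir / "class_curves.csv", index=False)

    report = json.loads((run_dir / "sherpa_report.json").read_text())
    epochs = load_epochs(run_dir / "epochs")
    grand = {}
    labs = np.array([str(x) for x in epochs.labels])
    for cond in epochs.conditions:
        grand[cond] = epochs.data[labs == cond].mean(axis=0)  # (C, T)

    for cls, entries in sorted(report.items()):
        for w, entry in enumerate(entries):
            topo = pd.DataFrame(
                sorted(entry["electrode_scores"].items()),
                columns=["channel", "importance"],
            )
            topo.to_csv(outdir / f"topography_{cls}_w{w}.csv", index=False)
            for q, chans in sorted(entry["quantile_sets"].items()):
                idx = [epochs.channels.index(c) for c in chans]
                df = pd.DataFrame({"time_ms": epochs.times})
                for cond in epochs.conditions:
                    df[cond] = grand[cond][idx].mean(axis=0)
                df.to_csv(outdir / f"erp_{cls}_w{w}_q{q}.csv", index=False)
    return outdir
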