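"""Validation analyses: spatiotemporal cluster-based permutation test with a
dependent (repeated-measures) F statistic, and the conventional
researcher-driven rmANOVA on mean amplitudes in a literature window.

Permutation scheme: condition labels are relabeled independently within each
subject — the exchangeability-preserving scheme for a within-subject design.
The Monte-Carlo p-value includes the observed statistic in the null,
p = (1 + #{null >= observed}) / (1 + n_permutations), so it is never below
1/(n_permutations + 1).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import sparse, stats

from .core_data import AdjacencyGraph, EpochedData, map_1020_to_abc

__all__ = [
    "SubjectConditionERP",
    "PermConfig",
    "ClusterResult",
    "AnovaResult",
    "subject_condition_averages",
    "repeated_measures_f",
    "dependent_f_map",
    "form_clusters",
    "cluster_permutation_test",
    "conventional_analysis",
    "N170_ELECTRODES",
    "N170_WINDOW_MS",
]

#: Literature defaults for the researcher-driven N170 analysis.
N170_ELECTRODES = ["P8", "P7", "PO8", "PO7", "P10", "P9"]
N170_WINDOW_MS = (165.0, 205.0)


@dataclass
class SubjectConditionERP:
    """Per-subject condition-average amplitudes (complete within-subject
    design): ``means[n_subjects, n_conditions, n_channels, n_times]``."""

    means: np.ndarray
    subjects: list[str]
    conditions: list[str]
    channels: list[str]
    times: np.ndarray


@dataclass
class PermConfig:
    cluster_alpha: float = 0.05  # sample-level threshold
    test_alpha: float = 0.05
    n_permutations: int = 500
    min_channel_neighbors: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.cluster_alpha < 1 and 0 < self.test_alpha < 1):
            raise ValueError("alphas must be in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


@dataclass
class Cluster:
    members: list[tuple[str, int]]  # (channel, time index)
    mass: float
    channels: list[str]
    time_range: tuple[int, int]
    p_value: float = float("nan")


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    null_distribution: np.ndarray
    threshold: float
    df: tuple[int, int]

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value <= alpha]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "threshold": self.threshold,
            "df": list(self.df),
            "null_distribution": self.null_distribution.tolist(),
            "clusters": [asdict(c) for c in self.clusters],
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        return path


@dataclass
class AnovaResult:
    F: float
    df_num: int
    df_den: int
    p: float
    eta_sq_partial: float
    pairwise: list[dict] = field(default_factory=list)
    cell_means: np.ndarray | None = None  # (n_subjects, n_conditions)
    conditions: list[str] = field(default_factory=list)
    electrodes: list[str] = field(default_factory=list)
    window_ms: tuple[float, float] = (float("nan"), float("nan"))

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        d = asdict(self)
        if self.cell_means is not None:
            d["cell_means"] = self.cell_means.tolist()
        path.write_text(json.dumps(d, indent=1, sort_keys=True))
        return path


# ---------------------------------------------------------------------------
# Subject-level averaging and the dependent F statistic
# ---------------------------------------------------------------------------


def subject_condition_averages(epochs: EpochedData) -> SubjectConditionERP:
    """Per-cell mean over each subject's trials of each condition; errors on
    an incomplete design (within-subject tests need every cell)."""
    subjects = sorted({str(s) for s in epochs.subject_ids})
    conds = list(epochs.conditions)
    subj = np.array([str(s) for s in epochs.subject_ids])
    labs = np.array([str(x) for x in epochs.labels])
    means = np.zeros(
        (len(subjects), len(conds), epochs.n_channels, epochs.n_times), dtype=np.float64
    )
    missing = []
    for i, s in enumerate(subjects):
        for j, c in enumerate(conds):
            sel = (subj == s) & (labs == c)
            if not sel.any():
                missing.append((s, c))
                continue
            means[i, j] = epochs.data[sel].mean(axis=0)
    if missing:
        raise ValueError(f"incomplete design; missing (subject, condition) cells: {missing}")
    return SubjectConditionERP(
        means=means,
        subjects=subjects,
        conditions=conds,
        channels=list(epochs.channels),
        times=epochs.times.copy(),
    )


def repeated_measures_f(y: np.ndarray) -> tuple[np.ndarray, tuple[int, int], np.ndarray]:
    """One-way repeated-measures F over the first two axes of
    ``y[n_subjects, n_conditions, ...]``.

    F = MS_condition / MS_(condition x subject), df (k-1, (k-1)(n-1)).
    Where both effect and error sums of squares vanish (all cells equal),
    F is defined as 0.  Returns (F, df, partial eta^2).
    """
    y = np.asarray(y, dtype=np.float64)
    n, k = y.shape[:2]
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 conditions")
    grand = y.mean(axis=(0, 1))
    cond_mean = y.mean(axis=0)  # (k, ...)
    subj_mean = y.mean(axis=1)  # (n, ...)
    ss_cond = n * ((cond_mean - grand) ** 2).sum(axis=0)
    # exact zero where every condition mean is bitwise identical (degenerate
    # identical-conditions input would otherwise leave ~1e-17 rounding dust)
    ss_cond = np.where((cond_mean == cond_mean[0]).all(axis=0), 0.0, ss_cond)
    ss_subj = k * ((subj_mean - grand) ** 2).sum(axis=0)
    ss_tot = ((y - grand) ** 2).sum(axis=(0, 1))
    ss_err = np.maximum(ss_tot - ss_cond - ss_subj, 0.0)
    df = (k - 1, (k - 1) * (n - 1))
    ms_cond = ss_cond / df[0]
    ms_err = ss_err / df[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(
            ms_err > 0,
            ms_cond / np.where(ms_err > 0, ms_err, 1.0),
            np.where(ms_cond > 0, np.inf, 0.0),
        )
        denom = ss_cond + ss_err
        eta = np.where(denom > 0, ss_cond / np.where(denom > 0, denom, 1.0), 0.0)
    return F, df, eta


def dependent_f_map(erp: SubjectConditionERP) -> tuple[np.ndarray, tuple[int, int]]:
    """Sample-level dependent F over channels x times."""
    F, df, _ = repeated_measures_f(erp.means)
    return F, df


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


def _adjacency_index_pairs(
    adjacency: AdjacencyGraph, channels: list[str]
) -> np.ndarray:
    if set(adjacency.channels) != set(channels):
        raise ValueError(
            "adjacency channels do not match the map channels; "
            f"only in adjacency: {sorted(set(adjacency.channels) - set(channels))[:5]}, "
            f"only in map: {sorted(set(channels) - set(adjacency.channels))[:5]}"
        )
    index = {c: i for i, c in enumerate(channels)}
    pairs = [
        (index[a], index[b]) for a, b in adjacency.edges()
    ]
    return np.array(pairs, dtype=np.intp).reshape(-1, 2)


def _passes_spatial_rule(
    member_mask: np.ndarray, neighbor_idx: list[np.ndarray], min_channel_neighbors: int
) -> bool:
    """A cluster is retained iff at some time point it contains a channel
    together with at least ``min_channel_neighbors - 1`` of that channel's
    spatial neighbors (i.e. it spans >= min_channel_neighbors adjacent
    channels at one latency)."""
    if min_channel_neighbors <= 1:
        return True
    chs = np.nonzero(member_mask.any(axis=1))[0]
    for t in np.nonzero(member_mask.any(axis=0))[0]:
        col = member_mask[:, t]
        for ch in chs:
            if col[ch] and col[neighbor_idx[ch]].sum() >= min_channel_neighbors - 1:
                return True
    return False


def form_clusters(
    fmap: np.ndarray,
    df: tuple[int, int],
    cfg: PermConfig,
    adjacency: AdjacencyGraph,
    channels: list[str],
    _pairs: np.ndarray | None = None,
    _neighbor_idx: list[np.ndarray] | None = None,
) -> list[Cluster]:
    """Group supra-threshold samples by temporal (t +- 1 within a channel)
    and spatial (adjacent channels at the same t) connectivity; drop clusters
    failing the min-neighboring-channels rule; mass = sum of member F values.
    """
    threshold = float(stats.f.isf(cfg.cluster_alpha, *df))
    pairs = _adjacency_index_pairs(adjacency, channels) if _pairs is None else _pairs
    if _neighbor_idx is None:
        index = {c: i for i, c in enumerate(channels)}
        _neighbor_idx = [
            np.array(sorted(index[b] for b in adjacency.neighbors[c]), dtype=np.intp)
            for c in channels
        ]
    n_ch, n_t = fmap.shape
    supra = fmap > threshold
    if not supra.any():
        return []
    flat = np.nonzero(supra.ravel())[0]
    compact = -np.ones(n_ch * n_t, dtype=np.intp)
    compact[flat] = np.arange(len(flat))
    rows, cols = [], []
    # temporal edges
    tmask = supra[:, :-1] & supra[:, 1:]
    ch_i, t_i = np.nonzero(tmask)
    rows.extend(compact[ch_i * n_t + t_i])
    cols.extend(compact[ch_i * n_t + t_i + 1])
    # spatial edges
    if len(pairs):
        both = supra[pairs[:, 0]] & supra[pairs[:, 1]]  # (n_pairs, n_t)
        p_i, t_i = np.nonzero(both)
        rows.extend(compact[pairs[p_i, 0] * n_t + t_i])
        cols.extend(compact[pairs[p_i, 1] * n_t + t_i])
    g = sparse.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(flat), len(flat))
    )
    n_comp, labels_ = sparse.csgraph.connected_components(g, directed=False)
    clusters: list[Cluster] = []
    for comp in range(n_comp):
        nodes = flat[labels_ == comp]
        member_mask = np.zeros((n_ch, n_t), dtype=bool)
        member_mask.ravel()[nodes] = True
        if not _passes_spatial_rule(member_mask, _neighbor_idx, cfg.min_channel_neighbors):
            continue
        ch_i, t_i = np.nonzero(member_mask)
        clusters.append(
            Cluster(
                members=[(channels[c], int(t)) for c, t in zip(ch_i, t_i)],
                mass=float(fmap[member_mask].sum()),
                channels=sorted({channels[c] for c in ch_i}),
                time_range=(int(t_i.min()), int(t_i.max())),
            )
        )
    clusters.sort(key=lambda c: -c.mass)
    return clusters


def cluster_permutation_test(
    erp: SubjectConditionERP,
    cfg: PermConfig,
    adjacency: AdjacencyGraph,
    seed: int | None = None,
) -> ClusterResult:
    """Monte-Carlo cluster test: relabel conditions independently within each
    subject, recompute the dependent-F map, cluster, and record the maximum
    cluster mass (0 if none) as the permutation null."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    F, df, _ = repeated_measures_f(erp.means)
    pairs = _adjacency_index_pairs(adjacency, erp.channels)
    index = {c: i for i, c in enumerate(erp.channels)}
    neighbor_idx = [
        np.array(sorted(index[b] for b in adjacency.neighbors[c]), dtype=np.intp)
        for c in erp.channels
    ]
    threshold = float(stats.f.isf(cfg.cluster_alpha, *df))
    observed = form_clusters(
        F, df, cfg, adjacency, erp.channels, _pairs=pairs, _neighbor_idx=neighbor_idx
    )
    n, k = erp.means.shape[:2]
    perms = np.array(list(itertools.permutations(range(k))))
    null = np.zeros(cfg.n_permutations)
    shape = erp.means.shape
    for b in range(cfg.n_permutations):
        pick = rng.integers(0, len(perms), size=n)
        Yp = erp.means[np.arange(n)[:, None], perms[pick], ...]
        Fp, _, _ = repeated_measures_f(Yp.reshape(shape))
        cl = form_clusters(
            Fp, df, cfg, adjacency, erp.channels, _pairs=pairs, _neighbor_idx=neighbor_idx
        )
        null[b] = cl[0].mass if cl else 0.0
    for c in observed:
        c.p_value = float((1 + np.sum(null >= c.mass)) / (1 + cfg.n_permutations))
    return ClusterResult(
        clusters=observed, null_distribution=null, threshold=threshold, df=df
    )


# ---------------------------------------------------------------------------
# Conventional researcher-driven analysis
# ---------------------------------------------------------------------------


def conventional_analysis(
    epochs: EpochedData,
    electrodes: list[str] | None = None,
    window_ms: tuple[float, float] | None = None,
) -> AnovaResult:
    """Mean amplitude per subject x condition over the given electrodes and
    latency window, one-way rmANOVA (factor: condition) plus all pairwise
    paired t tests (df = n - 1).

    Electrode names may be 10-20 labels (e.g. ``P8``); on a BioSemi ABC
    montage they are resolved through positional aliasing.
    """
    electrodes = list(electrodes or N170_ELECTRODES)
    lo, hi = window_ms or N170_WINDOW_MS
    missing = [e for e in electrodes if e not in epochs.channels]
    if missing:
        try:
            alias = map_1020_to_abc(missing)
        except KeyError as err:
            raise KeyError(
                f"unknown electrode name(s) {missing}: not in the data channels "
                f"and not 10-20 aliases ({err})"
            ) from None
        still = [e for e in missing if alias[e] not in epochs.channels]
        if still:
            raise KeyError(f"electrode alias target(s) not in data: {still}")
        electrodes = [e if e in epochs.channels else alias[e] for e in electrodes]
    ch_idx = [epochs.channels.index(e) for e in electrodes]
    t_mask = (epochs.times >= lo) & (epochs.times <= hi)
    if not t_mask.any():
        raise ValueError(f"window [{lo}, {hi}] ms outside the epoch time range")
    erp = subject_condition_averages(epochs)
    cell = erp.means[:, :, ch_idx][:, :, :, t_mask].mean(axis=(2, 3))  # (n, k)
    F, df, eta = repeated_measures_f(cell)
    p = float(stats.f.sf(F, *df))
    pairwise = []
    for i, j in itertools.combinations(range(len(erp.conditions)), 2):
        if np.all(cell[:, i] == cell[:, j]):
            t, pt = 0.0, 1.0  # identical conditions: no effect by definition
        else:
            t, pt = stats.ttest_rel(cell[:, i], cell[:, j])
        pairwise.append(
            {
                "pair": [erp.conditions[i], erp.conditions[j]],
                "t": float(t),
                "df": cell.shape[0] - 1,
                "p": float(pt),
            }
        )
    return AnovaResult(
        F=float(F),
        df_num=df[0],
        df_den=df[1],
        p=p,
        eta_sq_partial=float(eta),
        pairwise=pairwise,
        cell_means=cell,
        conditions=list(erp.conditions),
        electrodes=list(electrodes),
        window_ms=(float(lo), float(hi)),
    )
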