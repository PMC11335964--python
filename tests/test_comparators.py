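"""Dependent-F arithmetic against longhand and pingouin oracles, cluster
formation against a flood-fill reference, permutation-test mechanics, and the
conventional rmANOVA."""

import itertools

import numpy as np
import pytest
from scipy import stats

from sherpa_eeg import (
    AdjacencyGraph,
    PermConfig,
    cluster_permutation_test,
    conventional_analysis,
    dependent_f_map,
    repeated_measures_f,
    subject_condition_averages,
)
from sherpa_eeg.comparators import form_clusters

from conftest import make_epochs


def longhand_rm_anova(table):
    """Textbook two-way (subject x condition) sum-of-squares decomposition,
    written as explicit loops — the independent arithmetic oracle."""
    n, k = table.shape
    grand = sum(table[i][j] for i in range(n) for j in range(k)) / (n * k)
    ss_cond = n * sum((sum(table[i][j] for i in range(n)) / n - grand) ** 2
                      for j in range(k))
    ss_subj = k * sum((sum(table[i][j] for j in range(k)) / k - grand) ** 2
                      for i in range(n))
    ss_tot = sum((table[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    return (ss_cond / df1) / (ss_err / df2), (df1, df2)


def flood_fill_clusters(supra, adjacency_pairs):
    """Brute-force connected components over (channel, time) samples."""
    nodes = {tuple(x) for x in np.argwhere(supra)}
    pairs = set(adjacency_pairs) | {(b, a) for a, b in adjacency_pairs}
    clusters = []
    while nodes:
        stack = [nodes.pop()]
        comp = set(stack)
        while stack:
            c, t = stack.pop()
            cand = [(c, t - 1), (c, t + 1)] + [
                (c2, t) for (c1, c2) in pairs if c1 == c
            ]
            for nb in cand:
                if nb in nodes:
                    nodes.remove(nb)
                    comp.add(nb)
                    stack.append(nb)
        clusters.append(comp)
    return clusters


def chain_adjacency(names):
    nbrs = {n: set() for n in names}
    for a, b in zip(names, names[1:]):
        nbrs[a].add(b)
        nbrs[b].add(a)
    return AdjacencyGraph(nbrs)


class TestSubjectConditionAverages:
    def test_identical_trials_average_to_the_trial(self):
        ep = make_epochs(trials_per_condition=3, seed=1)
        ep.data[:] = ep.data[0]
        erp = subject_condition_averages(ep)
        for i in range(len(erp.subjects)):
            for j in range(len(erp.conditions)):
                np.testing.assert_allclose(erp.means[i, j], ep.data[0], atol=1e-6)

    def test_trial_order_invariance(self, rng):
        ep = make_epochs(seed=2)
        perm = rng.permutation(ep.n_trials)
        shuffled = ep.subset(perm)
        a = subject_condition_averages(ep)
        b = subject_condition_averages(shuffled)
        np.testing.assert_allclose(a.means, b.means, atol=1e-6)

    def test_two_trial_hand_computation(self):
        ep = make_epochs(n_subjects=2, n_conditions=2, trials_per_condition=2,
                         n_channels=1, n_times=3, seed=0)
        erp = subject_condition_averages(ep)
        sel = (ep.subject_ids == "S00") & (ep.labels == "cond1")
        hand = (ep.data[sel][0] + ep.data[sel][1]) / 2.0
        np.testing.assert_allclose(erp.means[0, 1], hand, rtol=1e-6)

    def test_incomplete_design_rejected(self):
        ep = make_epochs(n_subjects=2, n_conditions=2)
        keep = ~((ep.subject_ids == "S01") & (ep.labels == "cond1"))
        with pytest.raises(ValueError, match="missing"):
            subject_condition_averages(ep.subset(np.nonzero(keep)[0]))


class TestRepeatedMeasuresF:
    def test_identical_conditions_give_zero(self):
        y = np.tile(np.random.default_rng(0).normal(size=(6, 1)), (1, 3))
        F, df, eta = repeated_measures_f(y)
        assert F == 0.0
        assert eta == 0.0

    def test_longhand_oracle_on_random_tables(self, rng):
        for _ in range(20):
            table = rng.normal(size=(8, 3))
            F, df, _ = repeated_measures_f(table)
            F_ref, df_ref = longhand_rm_anova(table)
            assert df == df_ref
            assert F == pytest.approx(F_ref, abs=1e-10)

    def test_pingouin_cross_check(self, rng):
        import pandas as pd
        import pingouin as pg

        table = rng.normal(size=(10, 4))
        F, df, eta = repeated_measures_f(table)
        d = pd.DataFrame({
            "y": table.ravel(),
            "subj": np.repeat(np.arange(10), 4),
            "cond": np.tile(np.arange(4), 10),
        })
        res = pg.rm_anova(data=d, dv="y", within="cond", subject="subj",
                          detailed=True, effsize="np2")
        assert F == pytest.approx(float(res["F"][0]), rel=1e-9)
        assert eta == pytest.approx(float(res["np2"][0]), rel=1e-9)
        assert (df[0], df[1]) == (int(res["DF"][0]), int(res["DF"][1]))

    def test_subject_offset_invariance(self, rng):
        y = rng.normal(size=(7, 3, 2, 4))
        offsets = rng.normal(size=(7, 1, 1, 1)) * 50
        F1, _, _ = repeated_measures_f(y)
        F2, _, _ = repeated_measures_f(y + offsets)
        np.testing.assert_allclose(F1, F2, atol=1e-6)

    def test_study_design_degrees_of_freedom(self, rng):
        _, df, _ = repeated_measures_f(rng.normal(size=(26, 3)))
        assert df == (2, 50)

    def test_fmap_equals_scalar_anova_per_sample(self, rng):
        ep = make_epochs(n_subjects=5, n_conditions=3, n_channels=2, n_times=4)
        erp = subject_condition_averages(ep)
        fmap, df = dependent_f_map(erp)
        F_scalar, df_s, _ = repeated_measures_f(erp.means[:, :, 1, 2])
        assert df == df_s
        assert fmap[1, 2] == pytest.approx(F_scalar, abs=1e-10)


class TestFormClusters:
    def test_critical_value_for_study_dfs(self):
        assert stats.f.isf(0.05, 2, 50) == pytest.approx(3.1826, abs=1e-3)

    def test_toy_chain_cluster_and_mass(self):
        adj = chain_adjacency(["A", "B", "C"])
        df = (2, 14)
        thr = stats.f.isf(0.05, *df)
        fmap = np.zeros((3, 12))
        fmap[0, 5:8] = thr + 2.0
        fmap[1, 5:8] = thr + 1.0
        clusters = form_clusters(fmap, df, PermConfig(), adj, ["A", "B", "C"])
        assert len(clusters) == 1
        assert len(clusters[0].members) == 6
        assert clusters[0].mass == pytest.approx(fmap[fmap > thr].sum())

    def test_isolated_channel_discarded_by_spatial_rule(self):
        adj = chain_adjacency(["A", "B", "C"])
        df = (2, 14)
        fmap = np.zeros((3, 12))
        fmap[2, 4] = 100.0  # C supra, but alone at that latency
        assert form_clusters(fmap, df, PermConfig(min_channel_neighbors=2),
                             adj, ["A", "B", "C"]) == []
        assert len(form_clusters(fmap, df, PermConfig(min_channel_neighbors=1),
                                 adj, ["A", "B", "C"])) == 1

    def test_matches_flood_fill_on_random_maps(self, rng):
        names = [f"c{i}" for i in range(6)]
        adj = chain_adjacency(names)
        pairs = [(i, i + 1) for i in range(5)]
        df = (2, 10)
        thr = stats.f.isf(0.05, *df)
        cfg = PermConfig(min_channel_neighbors=1)  # compare pure connectivity
        for _ in range(50):
            fmap = rng.exponential(scale=thr / 1.2, size=(6, 20))
            got = form_clusters(fmap, df, cfg, adj, names)
            ref = flood_fill_clusters(fmap > thr, pairs)
            got_sets = sorted(
                sorted((names.index(c), t) for c, t in cl.members) for cl in got
            )
            ref_sets = sorted(sorted(cl) for cl in ref)
            assert got_sets == ref_sets

    def test_channel_mismatch_rejected(self):
        adj = chain_adjacency(["A", "B"])
        with pytest.raises(ValueError, match="adjacency"):
            form_clusters(np.zeros((3, 4)), (2, 10), PermConfig(), adj, ["A", "B", "X"])


class TestPermutationTest:
    def _erp(self, rng, effect=0.0, n=6, k=3, c=4, t=16):
        from sherpa_eeg.comparators import SubjectConditionERP

        means = rng.normal(size=(n, k, c, t))
        means[:, 0, 1:3, 6:9] += effect  # two adjacent channels: passes the spatial rule
        return SubjectConditionERP(
            means, [f"S{i}" for i in range(n)], [f"cond{j}" for j in range(k)],
            [f"c{i}" for i in range(c)], np.arange(t, dtype=float),
        )

    def test_p_values_bounded_and_deterministic(self, rng):
        erp = self._erp(rng, effect=4.0)
        adj = chain_adjacency([f"c{i}" for i in range(4)])
        cfg = PermConfig(n_permutations=100, seed=8)
        a = cluster_permutation_test(erp, cfg, adj)
        b = cluster_permutation_test(erp, cfg, adj)
        assert a.clusters, "strong effect should form at least one cluster"
        for c in a.clusters:
            assert 1 / 101 <= c.p_value <= 1.0
        np.testing.assert_array_equal(a.null_distribution, b.null_distribution)
        assert [c.p_value for c in a.clusters] == [c.p_value for c in b.clusters]

    def test_channel_relabeling_invariance(self, rng):
        erp = self._erp(rng, effect=3.0)
        names = [f"c{i}" for i in range(4)]
        adj = chain_adjacency(names)
        res = cluster_permutation_test(erp, PermConfig(n_permutations=50, seed=1), adj)
        # consistent renaming of channels in both data and adjacency
        renamed = {n: f"x_{n}" for n in names}
        from sherpa_eeg.comparators import SubjectConditionERP

        erp2 = SubjectConditionERP(erp.means, erp.subjects, erp.conditions,
                                   [renamed[n] for n in names], erp.times)
        adj2 = AdjacencyGraph({renamed[a]: {renamed[b] for b in nbrs}
                               for a, nbrs in adj.neighbors.items()})
        res2 = cluster_permutation_test(erp2, PermConfig(n_permutations=50, seed=1), adj2)
        np.testing.assert_array_equal(res.null_distribution, res2.null_distribution)
        assert [c.mass for c in res.clusters] == [c.mass for c in res2.clusters]


class TestConventionalAnalysis:
    def test_study_design_dfs_and_pairwise(self):
        ep = make_epochs(n_subjects=26, n_conditions=3, trials_per_condition=2,
                         n_channels=4, n_times=128, seed=5)
        res = conventional_analysis(ep, ["ch0", "ch1"], (165.0, 205.0))
        assert (res.df_num, res.df_den) == (2, 50)
        assert all(pw["df"] == 25 for pw in res.pairwise)
        assert len(res.pairwise) == 3

    def test_identical_conditions_give_null_statistics(self):
        ep = make_epochs(n_subjects=5, n_conditions=3, trials_per_condition=1,
                         n_channels=2, n_times=128, seed=6)
        # make all conditions of each subject identical
        for s in set(ep.subject_ids):
            sel = np.nonzero(ep.subject_ids == s)[0]
            ep.data[sel] = ep.data[sel[0]]
        res = conventional_analysis(ep, ["ch0"], (100.0, 200.0))
        assert res.F == 0.0
        for pw in res.pairwise:
            assert pw["t"] == pytest.approx(0.0, abs=1e-9)

    def test_longhand_oracle_via_cell_means(self, rng):
        ep = make_epochs(n_subjects=8, n_conditions=3, trials_per_condition=2,
                         n_channels=3, n_times=128, seed=7)
        res = conventional_analysis(ep, ["ch0", "ch2"], (50.0, 150.0))
        F_ref, df_ref = longhand_rm_anova(res.cell_means)
        assert res.F == pytest.approx(F_ref, abs=1e-10)
        assert (res.df_num, res.df_den) == df_ref

    def test_unknown_electrode_rejected(self):
        ep = make_epochs(n_times=128)
        with pytest.raises(KeyError, match="electrode"):
            conventional_analysis(ep, ["NotAnElectrode"], (50.0, 100.0))

    def test_1020_aliases_resolve_on_biosemi_montage(self):
        from sherpa_eeg import biosemi128_layout

        lay = biosemi128_layout()
        ep = make_epochs(n_subjects=3, n_conditions=3, trials_per_condition=1,
                         n_channels=128, n_times=128, seed=8)
        ep = type(ep)(ep.data, ep.labels, ep.times, ep.sfreq, lay.names,
                      ep.subject_ids, ep.conditions)
        res = conventional_analysis(ep)  # literature defaults: P8/P7 etc.
        assert len(res.electrodes) == 6
        assert all(e in lay.names for e in res.electrodes)
        assert res.window_ms == (165.0, 205.0)
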