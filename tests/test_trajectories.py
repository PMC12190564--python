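import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from qeegflow.preprocess import TIMEPOINTS
from qeegflow.trajectories import (
    ClusterSolution,
    TrajectoryMatrix,
    build_trajectories,
    flag_distinct,
    kmeans_trajectories,
    spearman,
)


def _feature_df(traj_by_key):
    rows = []
    for (subject, channel), vals in traj_by_key.items():
        for tp, v in zip(TIMEPOINTS, vals):
            rows.append((subject, channel, tp, "m", "b", v))
    return pd.DataFrame(rows, columns=["subject", "channel", "timepoint",
                                       "metric", "band", "value"])


def _tm(rows_array):
    idx = pd.MultiIndex.from_tuples(
        [("S1", f"c{i}") for i in range(len(rows_array))], names=["subject", "channel"]
    )
    return TrajectoryMatrix(pd.DataFrame(rows_array, index=idx, columns=TIMEPOINTS),
                            "m", "b")


class TestBuildTrajectories:
    def test_fold_change_vs_baseline(self):
        raw = (0.2, 0.2, 0.3, 0.3, 0.3, 0.3, 0.3, 0.3)
        df = _feature_df({("S1", "Cz"): raw})
        tm = build_trajectories(df, "m", "b")
        fold = np.array([1, 1, 1.5, 1.5, 1.5, 1.5, 1.5, 1.5])
        z = (fold - fold.mean()) / fold.std()
        np.testing.assert_allclose(tm.values[0], z, atol=1e-12)

    def test_constant_trajectory_all_zero_row(self):
        df = _feature_df({("S1", "Cz"): (0.4,) * 8})
        tm = build_trajectories(df, "m", "b")
        assert np.all(tm.values[0] == 0)

    def test_complete_cohort_gives_114_rows(self, feature_table):
        tm = build_trajectories(feature_table, "rel_power", "theta")
        assert len(tm.data) == 114  # 6 subjects x 19 channels

    def test_standardized_rows(self, feature_table):
        tm = build_trajectories(feature_table, "rel_power", "theta")
        v = tm.values
        np.testing.assert_allclose(v.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(v.std(axis=1), 1.0, atol=1e-9)

    def test_missing_timepoint_drops_row(self, feature_table):
        ft = feature_table[~((feature_table.subject == "S01")
                             & (feature_table.channel == "Cz")
                             & (feature_table.timepoint == "3h"))]
        tm = build_trajectories(ft, "rel_power", "theta")
        assert len(tm.data) == 113
        assert ("S01", "Cz") not in tm.data.index

    def test_nonpositive_baseline_drops_row(self, feature_table):
        ft = feature_table.copy()
        m = ((ft.subject == "S02") & (ft.channel == "Fz") & (ft.timepoint == "baseline"))
        ft.loc[m, "value"] = 0.0
        tm = build_trajectories(ft, "rel_power", "theta")
        assert ("S02", "Fz") not in tm.data.index


class TestSpearman:
    def test_hand_rank_formula(self):
        rho, p = spearman([1, 2, 3, 4], [1, 3, 2, 4])
        assert rho == pytest.approx(1 - 6 * 2 / (4 * 15))  # = 0.8

    def test_perfect_monotone(self):
        x = np.arange(8.0)
        assert spearman(x, x) == (1.0, 0.0)
        assert spearman(x, x[::-1]) == (-1.0, 0.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_exact_permutation_p(self, rng):
        # exact p = share of the 6! rank orderings at least as extreme
        x = rng.standard_normal(6)
        y = rng.standard_normal(6)
        rho_t, _ = spearman(x, y)
        rho_e, p_e = spearman(x, y, exact=True)
        assert rho_e == rho_t
        assert 0.0 < p_e <= 1.0
        # perfectly monotone: only the 2 extreme orderings out of 6!
        _, p_mono = spearman(np.arange(6.0), np.arange(6.0) ** 3, exact=True)
        assert p_mono == pytest.approx(2 / 720)


class TestKmeans:
    def test_recovers_well_separated_templates(self, rng):
        templates = np.array([
            np.linspace(-1.5, 1.5, 8),
            np.linspace(1.5, -1.5, 8),
            np.concatenate([np.linspace(-1, 1.5, 4), np.linspace(1.5, -1, 4)]),
            np.sin(np.linspace(0, np.pi, 8)) * 2 - 1,
            np.zeros(8),
        ])
        labels_true, rows = [], []
        for i, tpl in enumerate(templates):
            for _ in range(20):
                rows.append(tpl + 0.1 * tpl.std() * rng.standard_normal(8)
                            if tpl.std() > 0 else tpl + 0.05 * rng.standard_normal(8))
                labels_true.append(i)
        sol = kmeans_trajectories(_tm(np.array(rows)), k=5, seed=0)
        assert adjusted_rand_score(labels_true, sol.assignments.to_numpy()) >= 0.9

    def test_identical_rows_zero_inertia(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sol = kmeans_trajectories(_tm(np.zeros((10, 8))), k=5, seed=0, n_init=5)
        assert sol.inertia == 0.0

    def test_deterministic_given_seed(self, rng):
        rows = rng.standard_normal((30, 8))
        a = kmeans_trajectories(_tm(rows), k=5, seed=7)
        b = kmeans_trajectories(_tm(rows), k=5, seed=7)
        assert (a.assignments == b.assignments).all()

    def test_k_larger_than_rows_rejected(self, rng):
        with pytest.raises(ValueError):
            kmeans_trajectories(_tm(rng.standard_normal((3, 8))), k=5)


def _sol_from_profiles(profiles):
    profiles = np.asarray(profiles, dtype=float)
    k = len(profiles)
    idx = pd.MultiIndex.from_tuples([("S1", f"c{i}") for i in range(k)],
                                    names=["subject", "channel"])
    return ClusterSolution(
        k=k, assignments=pd.Series(range(k), index=idx),
        mean_profiles=profiles, sem_profiles=np.zeros_like(profiles),
        inertia=0.0, seed=0, n_init=1,
    )


class TestFlagDistinct:
    def test_monotone_increase_is_distinct(self):
        sol = flag_distinct(_sol_from_profiles(
            [(-1.5, -1, -0.5, 0, 0.5, 1, 1.25, 1.5)]))
        assert sol.distinct == [True]
        assert sol.spearman[0][0] == pytest.approx(1.0)

    def test_flat_jitter_not_distinct(self):
        jitter = (0.01, -0.01, 0.01, -0.01, 0.0, 0.01, -0.01, 0.0)
        sol = flag_distinct(_sol_from_profiles([jitter]))
        assert sol.distinct == [False]

    def test_rise_then_fall_not_distinct(self):
        sol = flag_distinct(_sol_from_profiles([(0, 0, 1, 2, 1.5, 1, 0.5, 0)]))
        assert sol.distinct == [False]

    def test_constant_profile_not_distinct(self):
        sol = flag_distinct(_sol_from_profiles([(0.0,) * 8]))
        assert sol.distinct == [False]

    def test_direction_sign_must_match(self):
        # decreasing overall but day-1 above baseline: sign mismatch
        profile = (1.5, -1.5, -1.2, -1.0, -0.9, -0.95, -1.0, -1.1)
        sol = flag_distinct(_sol_from_profiles([profile]))
        assert sol.distinct == [False]


class TestPlantedRecovery:
    def test_monotone_clusters_recovered(self, rng):
        dec = np.linspace(1.0, 0.6, 8)
        inc = np.linspace(1.0, 1.4, 8)
        flat = np.ones(8)
        rows, kinds = [], []
        for tpl, kind, n in ((dec, "dec", 40), (inc, "inc", 40), (flat, "flat", 34)):
            for _ in range(n):
                traj = tpl + 0.3 * tpl.std() * rng.standard_normal(8) if tpl.std() else \
                       tpl + 0.3 * dec.std() * rng.standard_normal(8)
                z = (traj - traj.mean()) / traj.std()
                rows.append(z)
                kinds.append(kind)
        sol = kmeans_trajectories(_tm(np.array(rows)), k=5, seed=0)
        kinds = np.array(kinds)
        rho = np.array([s[0] for s in sol.spearman])
        dec_clusters = [c for c in range(5) if sol.distinct[c] and rho[c] < 0]
        inc_clusters = [c for c in range(5) if sol.distinct[c] and rho[c] > 0]
        assert dec_clusters and inc_clusters
        labels = sol.assignments.to_numpy()
        captured = np.isin(labels, dec_clusters + inc_clusters)
        monotone = kinds != "flat"
        assert captured[monotone].mean() >= 0.8
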