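import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from qeegflow.preprocess import TIMEPOINTS
from qeegflow.stats import (
    NON_BASELINE,
    bh_adjust,
    delta_from_baseline,
    fit_lmm,
    friedman_test,
    load_rating_table,
    weighted_kappa,
    wilcoxon_posthoc,
)


def _global_features(values_by_subject):
    rows = []
    for subject, vals in values_by_subject.items():
        for tp, v in zip(TIMEPOINTS, vals):
            rows.append((subject, "GLOBAL", tp, "m", "b", v))
    return pd.DataFrame(rows, columns=["subject", "channel", "timepoint",
                                       "metric", "band", "value"])


def _delta_df(deltas_by_subject):
    rows = []
    for subject, vals in deltas_by_subject.items():
        for tp, v in zip(NON_BASELINE, vals):
            rows.append((subject, tp, "m", "b", v))
    return pd.DataFrame(rows, columns=["subject", "timepoint", "metric", "band", "delta"])


class TestDelta:
    def test_simple_subtraction(self):
        vals = (0.28, 0.30, 0.25, 0.27, 0.29, 0.31, 0.30, 0.26)
        d = delta_from_baseline(_global_features({"S1": vals}))
        got = d.set_index("timepoint")["delta"]
        assert got["1h"] == pytest.approx(-0.05)
        assert got["pre2h"] == pytest.approx(-0.02)
        assert len(d) == 7

    def test_no_change_all_zero(self):
        d = delta_from_baseline(_global_features({"S1": (0.3,) * 8}))
        assert np.allclose(d.delta, 0.0)

    def test_six_subjects_give_42_rows(self):
        feats = _global_features({f"S{i}": tuple(np.linspace(0.2, 0.4, 8))
                                  for i in range(6)})
        assert len(delta_from_baseline(feats)) == 42


class TestBH:
    def test_hand_step_up(self):
        adj = bh_adjust([0.005, 0.01, 0.03, 0.04])
        np.testing.assert_allclose(adj, [0.02, 0.02, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_all_equal(self):
        np.testing.assert_allclose(bh_adjust([0.02] * 5), [0.02] * 5)

    def test_adjusted_at_least_raw(self, rng):
        p = rng.random(20)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        assert (adj <= 1.0).all()

    def test_order_restored(self, rng):
        p = rng.random(9)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestFriedman:
    def test_monotone_three_by_three(self):
        v = np.array([[1, 2, 3], [4, 5, 6], [1.5, 2.5, 3.5]])
        res = friedman_test(v)
        assert res.statistic == pytest.approx(6.0)
        assert res.p == pytest.approx(0.0498, abs=5e-4)
        assert res.extra["rank_sums"] == [3, 6, 9]

    def test_all_tied_is_null(self):
        res = friedman_test(np.ones((4, 5)))
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_row_permutation_invariant(self, rng):
        v = rng.standard_normal((6, 4))
        a = friedman_test(v).statistic
        b = friedman_test(v[::-1]).statistic
        assert a == pytest.approx(b)

    def test_monotone_per_subject_transform_invariant(self, rng):
        v = rng.standard_normal((5, 4))
        w = np.array([np.exp(3 * row) + i for i, row in enumerate(v)])
        assert friedman_test(v).statistic == pytest.approx(friedman_test(w).statistic)

    def test_matches_scipy_without_ties(self, rng):
        v = rng.standard_normal((8, 5))
        stat, p = sps.friedmanchisquare(*(v[:, j] for j in range(5)))
        res = friedman_test(v)
        assert res.statistic == pytest.approx(stat)
        assert res.p == pytest.approx(p)


def wilcoxon_enumeration(x):
    """Exact two-sided signed-rank p by enumerating all 2^n sign patterns."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    ranks = sps.rankdata(np.abs(x))
    w_obs = ranks[x > 0].sum()
    total = ranks.sum()
    w_all = [np.dot(signs, ranks) for signs in itertools.product([0, 1], repeat=n)]
    w_all = np.array(w_all)
    lo = min(w_obs, total - w_obs)
    p = np.mean((w_all <= lo) | (w_all >= total - lo))
    return min(1.0, p)


class TestWilcoxon:
    def test_all_positive_six_subjects(self):
        d = _delta_df({f"S{i}": (0.1 * (i + 1),) * 7 for i in range(6)})
        res = wilcoxon_posthoc(d, "m", "b")
        for r in res:
            assert r.p == pytest.approx(2 / 64)

    def test_balanced_signs_null(self):
        d = _delta_df({f"S{i}": ((1.0 + i) * (1 if i < 3 else -1),) * 7
                       for i in range(6)})
        # magnitudes 1,2,3 up and 4,5,6 down -> not balanced; build symmetric:
        d = _delta_df({"S0": (1.0,) * 7, "S1": (-1.0,) * 7,
                       "S2": (2.0,) * 7, "S3": (-2.0,) * 7,
                       "S4": (3.0,) * 7, "S5": (-3.0,) * 7})
        res = wilcoxon_posthoc(d, "m", "b")
        assert res[0].p == pytest.approx(1.0)

    def test_single_subject_cannot_be_significant(self):
        res = wilcoxon_posthoc(_delta_df({"S1": (0.5,) * 7}), "m", "b")
        assert res[0].p == pytest.approx(1.0)

    def test_all_zero_deltas(self):
        res = wilcoxon_posthoc(_delta_df({"S1": (0.0,) * 7, "S2": (0.0,) * 7}),
                               "m", "b")
        assert res[0].p == 1.0

    @pytest.mark.parametrize("n", [4, 6, 8, 10])
    def test_exact_p_equals_enumeration(self, n, rng):
        x = rng.standard_normal(n)
        x[x == 0] = 0.1
        d = _delta_df({f"S{i}": (x[i],) * 7 for i in range(n)})
        res = wilcoxon_posthoc(d, "m", "b")
        assert res[0].p == pytest.approx(wilcoxon_enumeration(x), abs=1e-12)


def _rating_df(pairs):
    return pd.DataFrame([("S1", f"t{i}", a, b, a) for i, (a, b) in enumerate(pairs)],
                        columns=["subject", "timepoint", "rater1", "rater2", "consensus"])


class TestWeightedKappa:
    def test_perfect_agreement(self):
        df = _rating_df([(0, 0), (1, 1), (2, 2), (1, 1), (0, 0)])
        assert weighted_kappa(df, "linear").statistic == pytest.approx(1.0)
        assert weighted_kappa(df, "quadratic").statistic == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # pairs (0,0),(1,1),(2,2),(0,2): P_o,w = 0.75, P_e,w = 0.5 -> kappa 0.5
        df = _rating_df([(0, 0), (1, 1), (2, 2), (0, 2)])
        assert weighted_kappa(df, "linear").statistic == pytest.approx(0.5)

    def test_two_categories_weighting_irrelevant(self):
        pairs = [(0, 0), (0, 1), (1, 1), (1, 0), (1, 1), (0, 0), (1, 1)]
        df = _rating_df(pairs)
        lin = weighted_kappa(df, "linear").statistic
        quad = weighted_kappa(df, "quadratic").statistic
        from sklearn.metrics import cohen_kappa_score
        simple = cohen_kappa_score(df.rater1, df.rater2)
        assert lin == pytest.approx(simple)
        assert quad == pytest.approx(simple)

    def test_packaged_table_reproduces_printed_agreement(self):
        table = load_rating_table()
        assert len(table) == 36
        lin = weighted_kappa(table, "linear").statistic
        quad = weighted_kappa(table, "quadratic").statistic
        assert lin == pytest.approx(0.6786, abs=1e-4)
        assert quad == pytest.approx(0.7483, abs=1e-4)

    def test_bad_weighting_rejected(self):
        with pytest.raises(ValueError):
            weighted_kappa(_rating_df([(0, 0)] * 3), "cubic")


class TestLMM:
    def _sim(self, rng, effect_1d=0.0, bsd=0.05, rsd=0.02):
        rows = []
        for s in range(6):
            b = bsd * rng.standard_normal()
            for tp in NON_BASELINE:
                eff = effect_1d if tp == "1d" else 0.0
                rows.append((f"S{s}", tp, "m", "b",
                             eff + b + rsd * rng.standard_normal()))
        return pd.DataFrame(rows, columns=["subject", "timepoint", "metric",
                                           "band", "delta"])

    def test_all_zero_deltas(self, rng):
        res = fit_lmm(self._sim(rng, bsd=0.0, rsd=0.0), "m", "b")
        assert np.allclose(res.table.estimate, 0.0)
        assert res.subject_var == pytest.approx(0.0, abs=1e-10)
        assert res.singular

    def test_effect_estimate_reasonable(self, rng):
        ests = []
        for _ in range(20):
            res = fit_lmm(self._sim(rng, effect_1d=-0.10), "m", "b")
            ests.append(res.table.set_index("timepoint").loc["1d", "estimate"])
        assert np.mean(ests) == pytest.approx(-0.10, abs=0.02)

    def test_bh_applied_within_family(self, rng):
        res = fit_lmm(self._sim(rng, effect_1d=-0.10), "m", "b")
        assert len(res.table) == 7
        assert (res.table.p_bh >= res.table.p - 1e-12).all()

    def test_pre2h_is_a_model_level(self, rng):
        res = fit_lmm(self._sim(rng), "m", "b")
        assert "pre2h" in set(res.table.timepoint)
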