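"""PCA, aggregation, random-forest regression and Welch t-test checks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ramanod import aggregate_profiles, group_ttest, pca_scores, rfr_train_eval
from ramanod.datatypes import ConcentrationProfile

COMPONENTS = ["protein", "PHB", "cytochrome", "DNA", "metabolite", "lipid"]
SMALL_GRID = {"n_estimators": [100], "max_depth": [None, 6], "min_samples_leaf": [1, 2]}


def make_profile(values, phases=None, sizes=None, nodules=None):
    n = values.shape[0]
    meta = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n)],
            "nodule_id": nodules if nodules is not None else ["n1"] * n,
            "phase": phases if phases is not None else ["Nod"] * n,
            "size_group": sizes if sizes is not None else ["G1"] * n,
        }
    )
    return ConcentrationProfile(values=values, components=COMPONENTS[: values.shape[1]],
                                metadata=meta, standardized=True)


class TestPCA:
    def test_single_varying_feature_owns_pc1(self, rng):
        X = np.tile([1.0, 0.5, 0.3, 0.2, 0.1, 0.4], (30, 1))
        X[:, 1] += rng.normal(0, 0.3, 30)  # only PHB varies
        res = pca_scores(make_profile(X), group_by="size_group")["G1"]
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)
        loading = res.loadings[0]
        assert loading[1] == pytest.approx(1.0, abs=1e-9)  # sign fixed positive
        np.testing.assert_allclose(np.delete(loading, 1), 0.0, atol=1e-9)

    def test_explained_variance_matches_covariance_eigenvalues(self, rng):
        X = rng.normal(size=(50, 6))
        res = pca_scores(make_profile(X))["G1"]
        cov = np.cov(X, rowvar=False)
        evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        explained = res.explained_variance_ratio * evals.sum()
        np.testing.assert_allclose(explained, evals, atol=1e-10)
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0)
        assert np.all(np.diff(res.explained_variance_ratio) <= 1e-12)

    def test_scores_are_centered(self, rng):
        X = rng.normal(size=(40, 6))
        res = pca_scores(make_profile(X))["G1"]
        np.testing.assert_allclose(res.scores.mean(axis=0), 0.0, atol=1e-12)

    def test_too_few_cells_raises(self, rng):
        with pytest.raises(ValueError, match="cells"):
            pca_scores(make_profile(rng.normal(size=(2, 6))))


class TestAggregate:
    def test_single_cell_unit_is_that_cell(self, rng):
        X = rng.uniform(0, 1, (1, 6))
        agg = aggregate_profiles(make_profile(X), level="nodule")
        np.testing.assert_allclose(agg[COMPONENTS].to_numpy()[0], X[0])
        assert agg["n_cells"].iloc[0] == 1

    def test_two_cell_mean(self, rng):
        X = rng.uniform(0, 1, (2, 6))
        agg = aggregate_profiles(make_profile(X), level="nodule")
        np.testing.assert_allclose(agg[COMPONENTS].to_numpy()[0], X.mean(axis=0), rtol=1e-15)

    def test_matches_loop_mean_oracle(self, rng):
        X = rng.uniform(0, 1, (100, 6))
        nodules = [f"n{rng.integers(10)}" for _ in range(100)]
        agg = aggregate_profiles(make_profile(X, nodules=nodules), level="nodule").set_index("nodule_id")
        for nod in set(nodules):
            rows = [i for i, n in enumerate(nodules) if n == nod]
            oracle = sum(X[i] for i in rows) / len(rows)
            np.testing.assert_allclose(agg.loc[nod, COMPONENTS].to_numpy(dtype=float), oracle, atol=1e-12)
            assert agg.loc[nod, "n_cells"] == len(rows)

    def test_bad_level_raises(self, rng):
        with pytest.raises(ValueError, match="level"):
            aggregate_profiles(make_profile(rng.uniform(0, 1, (4, 6))), level="pot")


class TestRFR:
    def test_planted_phb_target_recovered_over_seeds(self):
        """ara = 2*PHB + tiny noise: high held-out R^2 with PHB ranked first."""
        r2_ok = imp_ok = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.uniform(0, 1, (60, 6)), columns=COMPONENTS)
            signal = 2.0 * X["PHB"]
            y = signal + rng.normal(0, 0.01 * signal.std(), 60)
            report = rfr_train_eval(X, y, "G1", grid=SMALL_GRID, seed=seed)
            r2_ok += report.test_r2 >= 0.9
            imp_ok += max(report.importances, key=report.importances.get) == "PHB"
            assert sum(report.importances.values()) == pytest.approx(1.0, abs=1e-9)
            assert all(v >= 0 for v in report.importances.values())
        assert r2_ok >= 9
        assert imp_ok >= 9

    def test_no_signal_control_has_low_r2(self):
        r2s = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X = pd.DataFrame(rng.uniform(0, 1, (60, 6)), columns=COMPONENTS)
            y = rng.normal(0, 1, 60)
            r2s.append(rfr_train_eval(X, y, "G1", grid=SMALL_GRID, seed=seed).test_r2)
        assert np.mean(r2s) <= 0.2

    def test_seed_determinism(self, rng):
        X = pd.DataFrame(rng.uniform(0, 1, (40, 6)), columns=COMPONENTS)
        y = 2 * X["PHB"] + 0.1 * rng.normal(size=40)
        a = rfr_train_eval(X, y, "G1", grid=SMALL_GRID, seed=7)
        b = rfr_train_eval(X, y, "G1", grid=SMALL_GRID, seed=7)
        assert a.to_dict() == b.to_dict()

    def test_constant_target_raises(self, rng):
        X = pd.DataFrame(rng.uniform(0, 1, (20, 6)), columns=COMPONENTS)
        with pytest.raises(ValueError, match="degenerate"):
            rfr_train_eval(X, np.ones(20), "G1", grid=SMALL_GRID, seed=0)

    def test_excess_folds_raise(self, rng):
        X = pd.DataFrame(rng.uniform(0, 1, (10, 6)), columns=COMPONENTS)
        y = X["PHB"] + rng.normal(0, 0.1, 10)
        with pytest.raises(ValueError, match="cv_folds"):
            rfr_train_eval(X, y, "G1", grid=SMALL_GRID, cv_folds=20, seed=0)

    def test_too_few_observations_raise(self, rng):
        X = pd.DataFrame(rng.uniform(0, 1, (5, 6)), columns=COMPONENTS)
        with pytest.raises(ValueError, match=">= 8"):
            rfr_train_eval(X, np.arange(5.0), "G1", seed=0)


def make_ara(g1_values, g3_values, phase="Nod"):
    rows = []
    for group, values in (("G1", g1_values), ("G3", g3_values)):
        for i, v in enumerate(values):
            rows.append(
                {
                    "phase": phase,
                    "size_group": group,
                    "replicate_id": f"r{i}",
                    "ara_total": v,
                    "ara_per_weight": v,
                    "nodule_weight": 1.0,
                }
            )
    return pd.DataFrame(rows)


class TestGroupTTest:
    def test_identical_groups_give_t0_p1(self):
        ara = make_ara([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        res = group_ttest(ara)
        # same values: t exactly 0, p exactly 1
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue == pytest.approx(1.0, abs=1e-12)

    def test_matches_hand_welch_computation(self):
        ara = make_ara(g1_values=[1, 2, 3, 4], g3_values=[5, 6, 7, 8])
        res = group_ttest(ara, contrast=("G3", "G1"), within="Nod")
        # by-hand Welch: equal variances 5/3, n=4 each
        se = np.sqrt(5 / 3 / 4 + 5 / 3 / 4)
        t_hand = (6.5 - 2.5) / se
        df_hand = (5 / 3 / 4 + 5 / 3 / 4) ** 2 / (
            (5 / 3 / 4) ** 2 / 3 + (5 / 3 / 4) ** 2 / 3
        )
        p_hand = 2 * stats.t.sf(abs(t_hand), df_hand)
        assert res.statistic == pytest.approx(t_hand, abs=1e-9)
        assert res.df == pytest.approx(df_hand, abs=1e-9)
        assert res.pvalue == pytest.approx(p_hand, abs=1e-9)

    def test_three_sd_shift_detected_in_80_percent_of_draws(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(1000):
            a = rng.normal(5.0, 1.0, 4)
            b = rng.normal(8.0, 1.0, 4)
            hits += group_ttest(make_ara(a, b)).pvalue < 0.05
        assert hits / 1000 >= 0.80

    def test_single_replicate_raises(self):
        ara = make_ara([1.0], [2.0])
        with pytest.raises(ValueError, match="replicates"):
            group_ttest(ara)
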