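"""Classifier harness contracts: NZV, splitting, AUC/F1, RFE, planted/null signal."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from autosig import model_suite as ms
from autosig.errors import (
    ConfigurationError,
    EmptyFeatureError,
    EvaluationError,
    InsufficientDataError,
)
from conftest import SINGLE_POINT_GRIDS


def brute_force_nzv(col: np.ndarray, freq_cut=19.0, uniq_cut=0.10) -> bool:
    """Direct evaluation of both caret criteria for one feature."""
    values, counts = np.unique(col, return_counts=True)
    if len(values) == 1:
        return True
    top2 = np.sort(counts)[::-1][:2]
    return (top2[0] / top2[1] > freq_cut) and (len(values) / len(col) < uniq_cut)


def brute_force_auc(y: np.ndarray, s: np.ndarray) -> float:
    """Pairwise concordance count over all (positive, negative) pairs."""
    pos = s[y == 1]
    neg = s[y == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestNearZeroVariance:
    def test_constant_feature_removed(self):
        m = pd.DataFrame({"const": np.zeros(20), "ok": np.arange(20.0)})
        _, removed = ms.remove_near_zero_variance(m)
        assert removed == ["const"]

    def test_many_distinct_values_kept(self):
        rng = np.random.default_rng(0)
        col = np.concatenate([np.zeros(50), rng.random(50)])  # 51 distinct / 100
        m = pd.DataFrame({"x": col, "y": np.arange(100.0)})
        _, removed = ms.remove_near_zero_variance(m)
        assert removed == []

    def test_sparse_low_cardinality_removed(self):
        col = np.concatenate([np.zeros(97), [1.0, 2.0, 3.0]])  # ratio 97 > 19, 4/100 < 0.1
        m = pd.DataFrame({"x": col, "y": np.arange(100.0)})
        _, removed = ms.remove_near_zero_variance(m)
        assert removed == ["x"]

    def test_all_removed_is_error(self):
        with pytest.raises(EmptyFeatureError):
            ms.remove_near_zero_variance(pd.DataFrame({"a": np.zeros(5)}))

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 60)
        cols = {}
        for j in range(6):
            kind = rng.integers(3)
            if kind == 0:
                cols[f"c{j}"] = rng.choice([0.0, 1.0], n, p=[0.95, 0.05])
            elif kind == 1:
                cols[f"c{j}"] = rng.random(n)
            else:
                cols[f"c{j}"] = np.zeros(n)
        m = pd.DataFrame(cols)
        expected = [c for c in m.columns if brute_force_nzv(m[c].to_numpy())]
        if len(expected) == m.shape[1]:
            with pytest.raises(EmptyFeatureError):
                ms.remove_near_zero_variance(m)
        else:
            _, removed = ms.remove_near_zero_variance(m)
            assert removed == expected


class TestSplit:
    def test_90_10_split_sizes(self):
        x = pd.DataFrame(np.random.default_rng(0).random((200, 3)),
                         index=[f"s{i}" for i in range(200)])
        y = pd.Series(["a"] * 100 + ["b"] * 100, index=x.index)
        xtr, ytr, xte, yte = ms.split_train_test(x, y, test_fraction=0.10, seed=1)
        assert len(xtr) == 180 and len(xte) == 20
        assert (yte == "a").sum() == 10 and (yte == "b").sum() == 10

    def test_train_test_disjoint_and_deterministic(self):
        x = pd.DataFrame(np.random.default_rng(1).random((40, 2)),
                         index=[f"s{i}" for i in range(40)])
        y = pd.Series(["a"] * 25 + ["b"] * 15, index=x.index)
        a = ms.split_train_test(x, y, seed=7)
        b = ms.split_train_test(x, y, seed=7)
        assert not (set(a[0].index) & set(a[2].index))
        assert list(a[2].index) == list(b[2].index)

    def test_tiny_class_rejected(self):
        x = pd.DataFrame(np.ones((3, 2)), index=["a", "b", "c"])
        y = pd.Series(["x", "x", "y"], index=x.index)
        with pytest.raises(InsufficientDataError):
            ms.split_train_test(x, y, test_fraction=0.5)


class TestAucAndF1:
    def test_perfect_ordering_gives_one(self):
        assert ms.auc_score(np.array([0, 0, 1, 1]), np.array([0.1, 0.2, 0.8, 0.9])) == 1.0

    def test_hand_example_with_ties(self):
        # 5 pos x 5 neg = 25 pairs; construct 2 discordant and 1 tied pair
        y = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        s = np.array([0.9, 0.8, 0.7, 0.6, 0.35, 0.5, 0.4, 0.65, 0.3, 0.2])
        # discordant: (0.35 vs 0.5), (0.35 vs 0.4); no other inversions; tie: none yet
        s[4] = 0.4  # now one tie (0.4 vs 0.4) and one discordant (0.4 < 0.5, 0.4<0.65 x2?)
        expected = brute_force_auc(y, s)
        assert ms.auc_score(y, s) == pytest.approx(expected)

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_matches_pairwise_concordance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        y = np.zeros(n, dtype=int)
        y[: int(rng.integers(1, n))] = 1
        rng.shuffle(y)
        if y.sum() in (0, n):
            y[0] = 1 - y[0]
        s = rng.choice(np.linspace(0, 1, 7), n)  # coarse grid to force ties
        assert ms.auc_score(y, s) == pytest.approx(brute_force_auc(y, s))

    def test_exact_predictions_give_macro_f1_one(self):
        y = np.array([0, 1, 0, 1])
        assert ms.macro_f1_score(y, y) == 1.0

    def test_never_predicted_class_scores_zero(self):
        y = np.array([0, 0, 1, 1])
        pred = np.zeros(4, dtype=int)
        # class 1: F1=0; class 0: precision 0.5, recall 1 -> F1 = 2/3
        assert ms.macro_f1_score(y, pred) == pytest.approx((2 / 3) / 2)


class TestSvmRfe:
    def make_train(self, rng, n=40, p=6, informative=0):
        x = rng.random((n, p))
        y = np.array([0, 1] * (n // 2))
        if informative is not None:
            x[:, informative] += y * 2.0
        return pd.DataFrame(x, columns=[f"f{j}" for j in range(p)]), y

    def test_elimination_path_and_unique_ranks(self):
        rng = np.random.default_rng(0)
        x, y = self.make_train(rng, p=6)
        spec = ms.ModelSpec("svm_rfe", rfe_step=2, seed=0)
        ranking, best, path = ms.svm_rfe(x, y, spec)
        assert [size for size, _ in path] == [6, 4, 2, 1]
        assert sorted(ranking.to_numpy()) == [1, 2, 3, 4, 5, 6]
        assert set(best) <= set(x.columns)

    def test_informative_feature_ranked_first(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x, y = self.make_train(rng, n=60, p=6, informative=2)
            ranking, _, _ = ms.svm_rfe(x, y, ms.ModelSpec("svm_rfe", seed=seed))
            hits += ranking["f2"] == 1
        assert hits >= 18  # >= 90% of replicates

    def test_step_larger_than_remaining(self):
        rng = np.random.default_rng(1)
        x, y = self.make_train(rng, p=5)
        ranking, _, path = ms.svm_rfe(x, y, ms.ModelSpec("svm_rfe", rfe_step=10, seed=0))
        assert [size for size, _ in path] == [5, 1]

    def test_too_few_features_rejected(self):
        rng = np.random.default_rng(2)
        x, y = self.make_train(rng, p=3, informative=None)
        with pytest.raises(InsufficientDataError):
            ms.svm_rfe(x, y, ms.ModelSpec("svm_rfe"))


@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(5)
    n = 60
    x = pd.DataFrame(rng.random((n, 8)), columns=[f"f{j}" for j in range(8)],
                     index=[f"s{i}" for i in range(n)])
    y = (x["f3"] > 0.5).astype(int).to_numpy()
    x["f3"] = x["f3"] + y  # make f3 fully determine the class, with margin
    return x, y


class TestFitModel:
    @pytest.mark.parametrize("algo", ms.ALGORITHMS)
    def test_dominant_feature_has_max_importance(self, separable, algo):
        x, y = separable
        spec = ms.ModelSpec(algo, hyperparameter_grid=SINGLE_POINT_GRIDS[algo],
                            cv_folds=3, cv_repeats=1, seed=0)
        fit = ms.fit_model(spec, x, y)
        assert fit.importance.idxmax() == "f3"
        assert (fit.importance >= 0).all()
        assert set(fit.importance.index) == set(x.columns)

    def test_single_point_grid_is_reported_as_tuned(self):
        rng = np.random.default_rng(0)
        x = pd.DataFrame(rng.random((30, 5)))
        y = np.array([0, 1] * 15)
        spec = ms.ModelSpec("random_forest",
                            hyperparameter_grid={"max_features": ["sqrt"], "n_estimators": [50]},
                            seed=0)
        fit = ms.fit_model(spec, x, y)
        assert fit.tuned_parameters == {"max_features": "sqrt", "n_estimators": 50}

    def test_grid_search_selects_from_grid(self):
        rng = np.random.default_rng(3)
        x = pd.DataFrame(rng.random((40, 4)))
        y = np.array([0, 1] * 20)
        spec = ms.ModelSpec("ridge_logistic",
                            hyperparameter_grid={"logit__C": [0.01, 1.0]},
                            cv_folds=2, cv_repeats=1, seed=0)
        fit = ms.fit_model(spec, x, y)
        assert fit.tuned_parameters["logit__C"] in (0.01, 1.0)

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ConfigurationError):
            ms.ModelSpec("deep_net")


class TestEvaluate:
    def test_single_class_test_set_rejected(self):
        rng = np.random.default_rng(0)
        x = pd.DataFrame(rng.random((20, 4)), index=[f"s{i}" for i in range(20)])
        y = np.array([0, 1] * 10)
        fit = ms.fit_model(
            ms.ModelSpec("random_forest", hyperparameter_grid={"n_estimators": [20]}, seed=0),
            x, y,
        )
        x_test = pd.DataFrame(rng.random((3, 4)), index=["t0", "t1", "t2"])
        with pytest.raises(EvaluationError):
            ms.evaluate(fit, x_test, np.array([1, 1, 1]))

    def test_null_labels_give_chance_level_auc(self):
        """Mean held-out AUC over 10 seeds is in [0.4, 0.6] for every
        algorithm when labels are independent of the features."""
        means = {a: [] for a in ms.ALGORITHMS}
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = pd.DataFrame(rng.random((80, 10)), index=[f"s{i}" for i in range(80)],
                             columns=[f"f{j}" for j in range(10)])
            y = pd.Series(rng.permutation(["a"] * 40 + ["b"] * 40), index=x.index)
            fits, _ = ms.run_model_suite(
                x, y, "a", test_fraction=0.2, seed=seed, grids=SINGLE_POINT_GRIDS
            )
            for a, f in fits.items():
                means[a].append(f.auc)
        for a, vals in means.items():
            assert 0.4 <= np.mean(vals) <= 0.6, (a, np.mean(vals))
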