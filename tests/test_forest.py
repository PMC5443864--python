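"""Forest contract: purity, bootstrap law, votes, OOB, importances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mvbc.forest import (
    ForestParams,
    bootstrap_indices,
    expected_absent_fraction,
    feature_importances,
    oob_accuracy,
    predict_labels,
    predict_votes,
    purity,
    train_forest,
    votes_to_labels,
)


def separable_toy(n=20, p=2, seed=0):
    """Two linearly separable Gaussian clouds."""
    rng = np.random.default_rng(seed)
    half = n // 2
    X = np.vstack(
        [
            rng.normal(0.0, 0.3, size=(half, p)),
            rng.normal(3.0, 0.3, size=(n - half, p)),
        ]
    )
    y = np.array(["a"] * half + ["b"] * (n - half), dtype=object)
    return X, y


class TestPurity:
    @pytest.mark.parametrize(
        "criterion,props,expected",
        [
            ("gini", (1.0, 0.0, 0.0), 0.0),
            ("gini", (0.5, 0.5), 0.5),
            ("gini", (0.25, 0.75), 2 * 0.25 * 0.75),
            ("entropy", (1 / 3, 1 / 3, 1 / 3), np.log(3)),
            ("entropy", (1.0, 0.0), 0.0),
        ],
    )
    def test_printed_formula_values(self, criterion, props, expected):
        assert purity(criterion, props) == pytest.approx(expected, abs=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="negative"):
            purity("gini", (-0.1, 1.1))
        with pytest.raises(ValueError, match="sum"):
            purity("gini", (0.4, 0.4))
        with pytest.raises(ValueError, match="criterion"):
            purity("misclass", (0.5, 0.5))

    @given(st.integers(2, 5), st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_zero_iff_pure_and_max_at_uniform(self, k, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(k))
        for crit in ("gini", "entropy"):
            uniform = purity(crit, np.full(k, 1.0 / k))
            val = purity(crit, p)
            assert val >= -1e-12
            if np.max(p) < 1.0 - 1e-9:
                assert val > 0
            assert val <= uniform + 1e-9
            pure = np.zeros(k)
            pure[0] = 1.0
            assert purity(crit, pure) == 0.0


class TestBootstrap:
    def test_exclusion_law_at_n121(self):
        bags = bootstrap_indices(121, 10_000, seed=1)
        absent = 1.0 - np.mean(
            [np.isin(np.arange(121), row).mean() for row in bags]
        )
        assert abs(absent - expected_absent_fraction(121)) < 0.01

    def test_closed_form_approaches_inverse_e(self):
        vals = [expected_absent_fraction(n) for n in (10, 121, 10_000)]
        errs = [abs(v - 1 / np.e) for v in vals]
        assert errs == sorted(errs, reverse=True)
        assert errs[1] < 0.002  # N=121 already within 0.002 of 1/e


class TestTraining:
    def test_separable_data_trains_to_perfect_accuracy(self):
        X, y = separable_toy()
        model = train_forest(X, y, ForestParams(n_trees=100, seed=0))
        assert np.mean(predict_labels(model, X) == y) == 1.0

    def test_same_seed_is_deterministic_per_tree(self):
        X, y = separable_toy(seed=2)
        m1 = train_forest(X, y, ForestParams(n_trees=25, seed=7))
        m2 = train_forest(X, y, ForestParams(n_trees=25, seed=7))
        assert np.array_equal(m1.in_bag, m2.in_bag)
        assert np.array_equal(m1.tree_predictions(X), m2.tree_predictions(X))

    def test_single_class_is_rejected(self):
        X = np.zeros((5, 2))
        with pytest.raises(ValueError, match="single class"):
            train_forest(X, ["a"] * 5, ForestParams(n_trees=2))

    def test_mtry_validation(self):
        X, y = separable_toy()
        with pytest.raises(ValueError, match="mtry"):
            train_forest(X, y, ForestParams(n_trees=2, mtry=99))


class TestVotes:
    def test_counts_conserve_tree_total(self):
        X, y = separable_toy(n=14, seed=3)
        model = train_forest(X, y, ForestParams(n_trees=33, seed=1))
        votes = predict_votes(model, X)
        assert np.all(votes.sum(axis=1) == 33)
        assert votes.sum() == 33 * len(X)

    def test_tie_breaks_to_earlier_configured_class(self):
        votes = np.array([[5, 5], [2, 8], [8, 2]])
        labels = votes_to_labels(votes, ("a", "b"))
        assert labels.tolist() == ["a", "b", "a"]
        # reversed configured order flips the tie only
        labels2 = votes_to_labels(votes[:, ::-1], ("b", "a"))
        assert labels2.tolist() == ["b", "b", "a"]

    def test_column_misalignment_errors(self):
        X, y = separable_toy()
        model = train_forest(X, y, ForestParams(n_trees=3))
        with pytest.raises(ValueError, match="align"):
            predict_votes(model, X[:, :1])


class TestOOB:
    def test_single_tree_scores_only_its_oob_subjects(self):
        X, y = separable_toy(n=12, seed=5)
        model = train_forest(X, y, ForestParams(n_trees=1, seed=5))
        n_absent = int((~model.in_bag_mask()[0]).sum())
        res = oob_accuracy(model, X, y)
        assert res.n_evaluated == n_absent
        assert len(res.excluded) == 12 - n_absent

    def test_separable_oob_is_high(self):
        X, y = separable_toy(n=30, seed=6)
        model = train_forest(X, y, ForestParams(n_trees=500, seed=2))
        assert oob_accuracy(model, X, y).accuracy >= 0.9

    def test_oob_tracks_cross_validation(self):
        # noisy two-class problem, 200 subjects: OOB within 0.1 of 5-fold CV
        rng = np.random.default_rng(8)
        n = 200
        X = rng.normal(size=(n, 10))
        y = np.where(X[:, 0] + X[:, 1] + rng.normal(0, 1.2, n) > 0, "a", "b")
        y = y.astype(object)
        params = ForestParams(n_trees=300, seed=3)
        model = train_forest(X, y, params)
        oob = oob_accuracy(model, X, y).accuracy
        from sklearn.model_selection import KFold

        accs = []
        for tr, te in KFold(5, shuffle=True, random_state=0).split(X):
            m = train_forest(X[tr], y[tr], params)
            accs.append(np.mean(predict_labels(m, X[te]) == y[te]))
        assert abs(oob - np.mean(accs)) < 0.1


class TestImportances:
    def test_informative_feature_dominates_noise(self):
        rng = np.random.default_rng(4)
        n, p = 80, 51
        X = rng.normal(size=(n, p))
        y = np.where(X[:, 17] > 0, "a", "b").astype(object)
        model = train_forest(X, y, ForestParams(n_trees=100, seed=0))
        imp = feature_importances(model)
        assert imp.argmax() == 17
        assert imp.sum() == pytest.approx(1.0, abs=1e-8)
        assert (imp >= 0).all()

    def test_constant_feature_never_selected(self):
        X, y = separable_toy(n=24, seed=9)
        Xc = np.column_stack([X, np.zeros(len(X))])
        model = train_forest(Xc, y, ForestParams(n_trees=50, seed=1))
        assert feature_importances(model)[-1] == 0.0


def test_forest_archive_roundtrip(tmp_path):
    from mvbc.forest import load_forest, save_forest

    X, y = separable_toy(n=16, seed=12)
    model = train_forest(X, y, ForestParams(n_trees=12, seed=4))
    save_forest(model, tmp_path / "forest.pkl")
    back = load_forest(tmp_path / "forest.pkl")
    assert back.params == model.params and back.classes == model.classes
    np.testing.assert_array_equal(back.in_bag, model.in_bag)
    np.testing.assert_array_equal(
        back.tree_predictions(X), model.tree_predictions(X)
    )


def test_accuracy_non_decreasing_in_n_trees():
    """Ensemble accuracy grows (within MC tolerance) with forest size."""
    mean_acc = {}
    for n_trees in (10, 100, 1000):
        accs = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n = 80
            X = rng.normal(size=(n, 8))
            logit = X[:, 0] - X[:, 1] + rng.normal(0, 1.5, n)
            y = np.where(logit > 0, "a", "b").astype(object)
            tr, te = np.arange(0, n, 2), np.arange(1, n, 2)
            m = train_forest(X[tr], y[tr], ForestParams(n_trees=n_trees, seed=seed))
            accs.append(np.mean(predict_labels(m, X[te]) == y[te]))
        mean_acc[n_trees] = np.mean(accs)
    assert mean_acc[100] >= mean_acc[10] - 0.03
    assert mean_acc[1000] >= mean_acc[100] - 0.03
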