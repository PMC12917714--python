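"""Split stratification, gamma resolution, grid search, calibration,
prediction and persistence."""

import numpy as np
import pandas as pd
import pytest

from gpcrscreen.classifier import (
    DEFAULT_GRID,
    HyperParams,
    SplitSpec,
    confidence_percentiles,
    cv_accuracy,
    fit_final,
    fit_platt,
    grid_search_cv,
    load_model,
    predict,
    resolve_gamma,
    save_model,
    stratified_split,
)


def _separable(n=40, d=6, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, d))
    X[:, 0] += 4.0 * y + noise * rng.normal(size=n)
    m = pd.DataFrame(X, index=[f"l{i}" for i in range(n)],
                     columns=[f"f{j}" for j in range(d)])
    return m, y


class TestStratifiedSplit:
    def test_144_rows_split_115_29(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(size=(144, 4)))
        y = np.array([0] * 66 + [1] * 78)
        tr, te = stratified_split(m, y, SplitSpec(test_fraction=0.2, seed=42))
        assert (len(tr), len(te)) == (115, 29)

    def test_small_balanced_split_one_each(self):
        m = pd.DataFrame(np.arange(20).reshape(10, 2))
        y = np.array([0, 1] * 5)
        tr, te = stratified_split(m, y, SplitSpec(test_fraction=0.2, seed=1))
        assert len(te) == 2 and set(y[te]) == {0, 1}

    def test_same_seed_reproduces(self):
        m, y = _separable()
        a = stratified_split(m, y, SplitSpec(seed=5))
        b = stratified_split(m, y, SplitSpec(seed=5))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_disjoint_exhaustive_and_proportional(self):
        m, y = _separable(n=60)
        tr, te = stratified_split(m, y, SplitSpec())
        assert sorted(np.concatenate([tr, te]).tolist()) == list(range(60))
        pop = y.mean()
        assert abs(y[te].mean() - pop) <= 1.0 / len(te)

    def test_tiny_class_rejected(self):
        m = pd.DataFrame(np.zeros((5, 2)))
        with pytest.raises(ValueError, match="fewer than 2"):
            stratified_split(m, np.array([0, 0, 0, 0, 1]), SplitSpec())


class TestResolveGamma:
    def test_auto_is_inverse_dimension(self):
        X = np.random.default_rng(0).normal(size=(10, 2054))
        assert resolve_gamma("auto", X) == pytest.approx(1 / 2054)

    def test_scale_on_unit_variance_matrix(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(4000, 20))
        X = (X - X.mean()) / X.std()
        assert resolve_gamma("scale", X) == pytest.approx(1 / 20, rel=1e-6)

    def test_constant_matrix_rejected_for_scale(self):
        with pytest.raises(ValueError, match="variance"):
            resolve_gamma("scale", np.ones((5, 3)))


class TestGridSearch:
    def test_grid_has_six_points(self):
        assert len(DEFAULT_GRID) == 6
        assert {(p.C, p.gamma) for p in DEFAULT_GRID} == {
            (c, g) for c in (0.1, 1.0, 10.0) for g in ("scale", "auto")
        }

    def test_separable_data_reaches_perfect_cv(self):
        m, y = _separable(n=50, d=3)
        m.iloc[:, 0] = m.iloc[:, 0] * 0.2 + 8.0 * y  # wide-margin separation
        best, acc = grid_search_cv(m, y, DEFAULT_GRID, k=5, seed=0)
        assert acc == 1.0

    def test_shuffled_labels_near_chance(self):
        m, y = _separable(n=60)
        rng = np.random.default_rng(3)
        accs = [
            grid_search_cv(m, rng.permutation(y), DEFAULT_GRID, k=5, seed=0)[1]
            for _ in range(3)
        ]
        # grid-search maximum over 6 points on null data: above 0.5 but
        # within a few binomial standard errors of the majority rate
        assert np.mean(accs) < 0.5 + 3 * np.sqrt(0.25 / 60) + 0.15

    def test_class_smaller_than_k_rejected(self):
        m, y = _separable(n=8)
        with pytest.raises(ValueError, match="fewer members"):
            grid_search_cv(m, y, DEFAULT_GRID, k=5)


class TestFitPredict:
    def test_deterministic_refit(self):
        m, y = _separable(n=50, noise=2.0)
        p1 = predict(fit_final(m, y, HyperParams(C=1.0), seed=9), m)
        p2 = predict(fit_final(m, y, HyperParams(C=1.0), seed=9), m)
        assert [r.prob_antagonist for r in p1] == [r.prob_antagonist for r in p2]

    def test_training_accuracy_at_least_cv_accuracy(self):
        m, y = _separable(n=60, noise=3.0, seed=4)
        params = HyperParams(C=1.0)
        cv = cv_accuracy(m, y, params, k=5, seed=0)
        model = fit_final(m, y, params, seed=0)
        train_acc = np.mean([p.predicted_class for p in predict(model, m)] == y)
        assert train_acc >= cv - 1e-9

    def test_margin_violations_nonincreasing_in_C(self):
        m, y = _separable(n=60, noise=4.0, seed=8)
        def violations(C):
            model = fit_final(m, y, HyperParams(C=C), seed=0)
            f = model.decision_function(m)
            margins = np.where(y == 1, f, -f)
            return int(np.sum(margins < 1.0 - 1e-12))
        assert violations(10.0) <= violations(0.1)

    def test_probabilities_sum_to_one(self, trained_model):
        model, matrix = trained_model["model"], trained_model["matrix"]
        proba = model.predict_proba(matrix.iloc[:10])
        assert np.allclose(proba.sum(axis=1), 1.0)
        preds = predict(model, matrix.iloc[:10])
        for p in preds:
            assert 0 <= p.probability <= 1
            assert p.probability >= 0.5  # probability of the *predicted* class

    def test_duplicated_row_gets_identical_record(self, trained_model):
        model, matrix = trained_model["model"], trained_model["matrix"]
        dup = pd.concat([matrix.iloc[[3]], matrix.iloc[[3]]])
        a, b = predict(model, dup)
        assert a.prob_antagonist == b.prob_antagonist
        assert a.predicted_class == b.predicted_class

    def test_single_class_training_rejected(self):
        m, _ = _separable(n=20)
        with pytest.raises(ValueError, match="single class"):
            fit_final(m, np.zeros(20, dtype=int), HyperParams())

    def test_column_mismatch_is_named(self, trained_model):
        model, matrix = trained_model["model"], trained_model["matrix"]
        wrong = matrix.rename(columns={"MW": "weight"})
        with pytest.raises(ValueError, match="weight"):
            predict(model, wrong)

    def test_scaler_independent_of_test_rows(self, trained_model):
        """No leakage: scaler statistics come from training rows only."""
        matrix, labels = trained_model["matrix"], trained_model["labels"]
        tr = trained_model["train_idx"]
        best = trained_model["best"]
        m1 = fit_final(matrix.iloc[tr], labels[tr], best, seed=42)
        perturbed = matrix.copy()
        te = trained_model["test_idx"]
        perturbed.iloc[te] = perturbed.iloc[te].to_numpy() * 100 + 7
        m2 = fit_final(perturbed.iloc[tr], labels[tr], best, seed=42)
        assert np.array_equal(m1.scaler_mean, m2.scaler_mean)
        assert np.array_equal(m1.scaler_std, m2.scaler_std)


class TestPlatt:
    def test_recovers_generating_sigmoid(self):
        rng = np.random.default_rng(0)
        f = rng.normal(size=4000)
        a_true, b_true = -3.0, 0.5
        p = 1 / (1 + np.exp(a_true * f + b_true))
        y = (rng.random(4000) < p).astype(int)
        a, b = fit_platt(f, y, prior_correction=False)
        assert a == pytest.approx(a_true, abs=0.3)
        assert b == pytest.approx(b_true, abs=0.2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_platt([0.1, 0.2], [1, 1])


class TestConfidencePercentiles:
    def test_distinct_scores_weak_rank(self):
        pct = confidence_percentiles([0.1, 0.5, 0.9])
        assert np.allclose(pct, [1 / 3, 2 / 3, 1.0])

    def test_all_tied_share_top(self):
        assert np.allclose(confidence_percentiles([0.7] * 5), 1.0)

    def test_monotone_in_score(self):
        rng = np.random.default_rng(2)
        s = rng.random(50)
        pct = confidence_percentiles(s)
        order = np.argsort(s)
        assert np.all(np.diff(pct[order]) >= 0)


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, trained_model):
        model, matrix = trained_model["model"], trained_model["matrix"]
        path = tmp_path / "model.bin"
        save_model(model, path)
        loaded = load_model(path)
        a = [p.prob_antagonist for p in predict(model, matrix.iloc[:8])]
        b = [p.prob_antagonist for p in predict(loaded, matrix.iloc[:8])]
        assert a == b
        assert loaded.feature_columns == model.feature_columns
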