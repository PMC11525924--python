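"""Classifier contracts: risk score closed forms, decision rule, solver
optimality on small instances, CV coefficient averaging, sparsity vs lambda."""

import math
from dataclasses import replace

import numpy as np
import pytest

from evmir import (FitConfig, LogisticEnsemble, classify, cv_attribute_selection,
                   fit_l1_penalized, lambda_path, objective_value, predict_risk,
                   risk_scores)
from evmir.errors import (DegenerateLabelError, InvalidInputError,
                          MissingFeatureError, StratificationError)


def grid_search_min(X, y, lam, objective="squared_error", span=6.0,
                    n_points=21, n_zoom=4):
    """Independent coarse-to-fine dense grid search over (beta..., alpha).

    Returns the best objective value found on the final grid.
    """
    p = X.shape[1]
    centers = np.zeros(p + 1)
    half = span
    best_val = np.inf
    for _ in range(n_zoom):
        axes = [np.linspace(c - half, c + half, n_points) for c in centers]
        mesh = np.meshgrid(*axes, indexing="ij")
        flat = np.stack([m.ravel() for m in mesh], axis=1)   # (G, p+1)
        z = X @ flat[:, :p].T + flat[:, p]                   # (n, G)
        s = 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
        if objective == "squared_error":
            fit = ((s - y[:, None]) ** 2).sum(axis=0)
        else:
            fit = (np.logaddexp(0.0, z) - y[:, None] * z).sum(axis=0)
        total = fit + lam * np.abs(flat[:, :p]).sum(axis=1)
        k = int(np.argmin(total))
        best_val = min(best_val, float(total[k]))
        centers = flat[k]
        half = half * 2.0 / (n_points - 1) * 2.0    # shrink around the best cell
    return best_val


class TestPredictRisk:
    def test_zero_model_gives_half(self):
        m = LogisticEnsemble(beta={}, alpha=0.0, lam=1.0, feature_ids=["a"])
        assert predict_risk(m, {"a": 3.0}) == 0.5

    def test_log_three_gives_three_quarters(self):
        m = LogisticEnsemble(beta={"a": 1.0}, alpha=0.0, lam=1.0, feature_ids=["a"])
        assert predict_risk(m, {"a": math.log(3)}) == pytest.approx(0.75)

    def test_saturation_toward_zero(self):
        m = LogisticEnsemble(beta={}, alpha=-800.0, lam=1.0, feature_ids=[])
        assert predict_risk(m, {}) == pytest.approx(0.0, abs=1e-300)

    def test_missing_feature_named(self):
        m = LogisticEnsemble(beta={"miR-0007": 1.0}, alpha=0.0, lam=1.0,
                             feature_ids=["miR-0007"])
        with pytest.raises(MissingFeatureError, match="miR-0007"):
            predict_risk(m, {"miR-0001": 1.0})


class TestClassify:
    @pytest.mark.parametrize("score,expected", [
        (0.49, "noncancer"), (0.5, "cancer"), (1.0, "cancer"), (0.0, "noncancer"),
    ])
    def test_decision_rule_boundary_inclusive(self, score, expected):
        assert classify(score) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidInputError):
            classify(1.2)


class TestFitL1:
    def _random_problem(self, rng, n=None, p=None):
        n = n or int(rng.integers(6, 21))
        p = p or int(rng.integers(1, 3))
        X = rng.normal(0, 2, size=(n, p))
        y = (rng.random(n) < 0.5).astype(float)
        if y.sum() == 0:
            y[0] = 1.0
        if y.sum() == n:
            y[0] = 0.0
        return X, y

    def test_large_lambda_zeroes_beta_and_centers_intercept(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 3))
        y = np.array([0.0, 1.0] * 10)
        b, a, _ = fit_l1_penalized(X, y, FitConfig(lam=1e4))
        assert np.all(b == 0.0)
        # balanced classes: intercept-only squared-error min at sigmoid(a)=0.5
        assert a == pytest.approx(0.0, abs=1e-4)

    def test_single_class_rejected(self):
        X = np.ones((4, 1))
        with pytest.raises(DegenerateLabelError):
            fit_l1_penalized(X, np.ones(4))

    def test_monotone_descent(self):
        rng = np.random.default_rng(1)
        X, y = self._random_problem(rng, n=30, p=2)
        _, _, info = fit_l1_penalized(X, y, FitConfig(lam=0.5))
        assert np.all(np.diff(info["history"]) <= 0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_objective_beats_grid_search(self, seed):
        rng = np.random.default_rng(seed)
        X, y = self._random_problem(rng)
        lam = float(rng.uniform(0.1, 2.0))
        b, a, info = fit_l1_penalized(X, y, FitConfig(lam=lam))
        assert info["objective"] == pytest.approx(
            objective_value(b, a, X, y, lam))
        assert info["objective"] <= grid_search_min(X, y, lam) + 1e-6

    def test_log_loss_unpenalized_matches_sklearn(self):
        sklearn = pytest.importorskip("sklearn.linear_model")
        rng = np.random.default_rng(7)
        n = 200
        X = rng.normal(size=(n, 2))
        logit = 0.8 * X[:, 0] - 0.5 * X[:, 1] + 0.3
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
        b, a, _ = fit_l1_penalized(
            X, y, FitConfig(lam=0.0, objective="log_loss", tol=1e-12))
        ref = sklearn.LogisticRegression(C=np.inf, tol=1e-10, max_iter=10000)
        ref.fit(X, y)
        assert np.allclose(b, ref.coef_.ravel(), atol=1e-3)
        assert a == pytest.approx(float(ref.intercept_[0]), abs=1e-3)


class TestCvSelection:
    def _toy(self, seed=0, n=60, p=30, n_signal=4):
        rng = np.random.default_rng(seed)
        X = rng.normal(3, 1, size=(n, p))
        y = np.r_[np.ones(n // 2), np.zeros(n - n // 2)]
        X[y == 1, :n_signal] += 1.5
        ids = [f"miR-{j:04d}" for j in range(1, p + 1)]
        return X, y, ids

    def test_deterministic_under_seed(self):
        X, y, ids = self._toy()
        cfg = FitConfig(n_folds=5, seed=3)
        m1 = cv_attribute_selection(X, y, ids, cfg)
        m2 = cv_attribute_selection(X, y, ids, cfg)
        assert m1.beta == m2.beta
        assert m1.alpha == m2.alpha
        assert np.array_equal(m1.trace.fold_assignments, m2.trace.fold_assignments)

    def test_trace_counts_and_averages(self):
        X, y, ids = self._toy()
        cfg = FitConfig(n_folds=5, n_repeats=2, seed=3)
        m = cv_attribute_selection(X, y, ids, cfg)
        assert m.trace.n_fits == 10
        assert np.allclose(m.trace.mean_beta, m.trace.betas.mean(axis=0))
        assert m.trace.mean_alpha == pytest.approx(m.trace.alphas.mean())
        # selected ids are exactly the mean coefficients above threshold
        above = {ids[j] for j in np.flatnonzero(
            np.abs(m.trace.mean_beta) > cfg.coef_threshold)}
        assert set(m.beta) == above

    def test_infinite_threshold_gives_intercept_only(self):
        X, y, ids = self._toy()
        m = cv_attribute_selection(X, y, ids,
                                   FitConfig(n_folds=5, coef_threshold=np.inf))
        assert m.beta == {}
        scores = risk_scores(m, X, ids)
        assert np.allclose(scores, scores[0])

    def test_feature_reordering_invariance(self):
        # column order only enters through floating-point summation order,
        # so coefficients agree to solver tolerance and the selected set
        # can differ only at features sitting on the threshold
        X, y, ids = self._toy()
        cfg = FitConfig(n_folds=5, seed=3)
        m1 = cv_attribute_selection(X, y, ids, cfg)
        perm = np.random.default_rng(1).permutation(len(ids))
        m2 = cv_attribute_selection(X[:, perm], y, [ids[j] for j in perm], cfg)
        slack = 2e-3
        mean1 = dict(zip(ids, m1.trace.mean_beta))
        mean2 = {ids[j]: m2.trace.mean_beta[k] for k, j in enumerate(perm)}
        for k in ids:
            assert mean2[k] == pytest.approx(mean1[k], abs=slack)
        for k in set(m1.beta) ^ set(m2.beta):
            assert abs(abs(mean1[k]) - cfg.coef_threshold) < slack

    def test_too_many_folds_raises(self):
        X, y, ids = self._toy(n=10)
        with pytest.raises(StratificationError):
            cv_attribute_selection(X, y, ids, FitConfig(n_folds=20))

    def test_recovery_improves_with_n_and_effect(self):
        """Planted-species recall rises along n in {30, 60} per class and
        |log2 FC| in {0.75, 1.5} (mean over 3 seeds per cell, reduced
        feature count)."""
        from evmir import CohortSpec, generate_cohort, preprocess
        from evmir.matrix import to_design

        def recall(n_per_class, effect, seed):
            spec = CohortSpec(
                n_cancer=n_per_class, n_noncancer=n_per_class, n_species=150,
                core_fraction=0.4, target_median_detected=100, n_up=6, n_down=2,
                effect_log2fc=effect,
                stage_fractions={"I": 0.25, "II": 0.25, "III": 0.25, "IV": 0.25},
                seed=seed)
            cohort = generate_cohort(spec)
            _, l2 = preprocess(cohort.matrix)
            X, y, ids, _ = to_design(l2, cohort.labels)
            m = cv_attribute_selection(X, y, ids, FitConfig(n_folds=5, seed=2))
            planted = set(cohort.truth.planted_ids)
            return len(set(m.beta) & planted) / len(planted)

        grid = {(n, e): np.mean([recall(n, e, s) for s in (17, 18, 19)])
                for n in (30, 60) for e in (0.75, 1.5)}
        slack = 0.05    # one borderline species in 8 across 3 seeds
        assert grid[(60, 0.75)] >= grid[(30, 0.75)] - slack
        assert grid[(60, 1.5)] >= grid[(30, 1.5)] - slack
        assert grid[(30, 1.5)] >= grid[(30, 0.75)] - slack
        assert grid[(60, 1.5)] >= grid[(60, 0.75)] - slack
        assert grid[(60, 1.5)] >= 0.75


class TestLambdaPath:
    def test_invalid_paths_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 2))
        y = np.r_[np.ones(10), np.zeros(10)]
        with pytest.raises(InvalidInputError):
            lambda_path(X, y, ["a", "b"], [1.0, 1.0])     # duplicates
        with pytest.raises(InvalidInputError):
            lambda_path(X, y, ["a", "b"], [2.0, 1.0])     # decreasing
        with pytest.raises(InvalidInputError):
            lambda_path(X, y, ["a", "b"], [1.0])          # single value

    def test_penalty_limits(self):
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, size=(40, 5))
        y = np.r_[np.ones(20), np.zeros(20)]
        X[y == 1, 0] += 2.0
        counts = lambda_path(X, y, [f"f{j}" for j in range(5)],
                             [0.01, 1e4], FitConfig(n_folds=4, seed=0))
        assert counts.iloc[0] >= counts.iloc[-1]
        assert counts.iloc[-1] == 0
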