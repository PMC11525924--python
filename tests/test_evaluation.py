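"""Evaluation contracts: AUROC identities, ROC geometry, DeLong CI,
confusion metrics, stage-I hold-out hygiene."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from evmir import (FitConfig, auroc, auroc_confint, confusion_at_threshold,
                   cv_attribute_selection, one_vs_rest_multiclass, preprocess,
                   roc_points, stage_holdout_protocol)
from evmir.errors import DegenerateLabelError, ProtocolError
from evmir.matrix import to_design
from evmir.screening import mann_whitney_u


class TestAuroc:
    def test_brute_force_pair_count(self):
        scores = [0.9, 0.8, 0.4, 0.7, 0.3, 0.2]
        labels = [1, 1, 1, 0, 0, 0]
        assert auroc(scores, labels) == pytest.approx(8 / 9)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateLabelError):
            auroc([0.1, 0.2], [1, 1])

    def test_equals_normalized_u_statistic(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[0], labels[1] = 0, 1
        u, _ = mann_whitney_u(scores[labels == 1], scores[labels == 0])
        n1, n2 = (labels == 1).sum(), (labels == 0).sum()
        assert auroc(scores, labels) == pytest.approx(u / (n1 * n2))

    @given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=4, max_size=30))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_score_negation_complements(self, scores):
        n = len(scores)
        labels = np.arange(n) % 2
        s = np.asarray(scores)
        assert auroc(s, labels) + auroc(-s, labels) == pytest.approx(1.0)


class TestRocPoints:
    def test_single_positive_single_negative(self):
        r = roc_points([1.0, 0.0], [1, 0])
        assert list(r.fpr) == [0.0, 0.0, 1.0]
        assert list(r.tpr) == [0.0, 1.0, 1.0]
        assert r.auroc == 1.0

    def test_trapezoid_equals_pair_count(self):
        rng = np.random.default_rng(2)
        scores = rng.choice(np.linspace(0, 1, 20), size=60)  # forces ties
        labels = rng.integers(0, 2, size=60)
        labels[:2] = [0, 1]
        assert roc_points(scores, labels).auroc == pytest.approx(
            auroc(scores, labels), abs=1e-12)

    def test_reversed_scores_mirror_area(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        a = roc_points(scores, labels).auroc
        b = roc_points(-scores, labels).auroc
        assert a + b == pytest.approx(1.0)

    def test_curve_monotone_from_origin_to_corner(self):
        rng = np.random.default_rng(4)
        r = roc_points(rng.normal(size=30), np.arange(30) % 2)
        assert r.tpr[0] == r.fpr[0] == 0.0
        assert r.tpr[-1] == r.fpr[-1] == 1.0
        assert np.all(np.diff(r.tpr) >= 0) and np.all(np.diff(r.fpr) >= 0)


class TestConfint:
    def test_delong_hand_computed_small_sample(self):
        # pos = (0.9, 0.8, 0.4), neg = (0.7, 0.3, 0.2)
        pos, neg = [0.9, 0.8, 0.4], [0.7, 0.3, 0.2]
        scores = pos + neg
        labels = [1, 1, 1, 0, 0, 0]
        # structural components by hand:
        # V10 = (3/3, 3/3, 2/3), V01 = (2/3, 3/3, 3/3); theta = 8/9
        # s10 = s01 = var([1, 1, 2/3], ddof=1) = 1/27
        # var = 1/27/3 + 1/27/3 = 2/81
        theta = 8 / 9
        half = 1.959963984540054 * np.sqrt(2 / 81)
        lo, hi = auroc_confint(scores, labels, method="delong")
        assert lo == pytest.approx(max(0.0, theta - half), abs=1e-9)
        assert hi == pytest.approx(min(1.0, theta + half), abs=1e-9)

    def test_delong_upper_clipped_on_separable_data(self):
        scores = np.r_[np.ones(50), np.zeros(50)]
        labels = np.r_[np.ones(50), np.zeros(50)]
        lo, hi = auroc_confint(scores, labels, method="delong")
        assert hi == 1.0
        assert 0.0 <= lo <= 1.0

    def test_bootstrap_deterministic_under_seed(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=60)
        labels = np.arange(60) % 2
        a = auroc_confint(scores, labels, method="bootstrap", seed=42)
        b = auroc_confint(scores, labels, method="bootstrap", seed=42)
        assert a == b


class TestConfusion:
    def test_perfect_scores(self):
        c = confusion_at_threshold([1.0, 1.0, 0.0], [1, 1, 0])
        assert c.sensitivity == c.specificity == c.accuracy == 1.0

    def test_boundary_half_is_called_cancer(self):
        c = confusion_at_threshold([0.5, 0.5], [1, 0])
        assert c.sensitivity == 1.0
        assert c.specificity == 0.0

    def test_counts_match_hand_recount(self):
        rng = np.random.default_rng(6)
        scores = rng.random(40)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        c = confusion_at_threshold(scores, labels, threshold=0.6)
        tp = sum(1 for s, l in zip(scores, labels) if s >= 0.6 and l == 1)
        fp = sum(1 for s, l in zip(scores, labels) if s >= 0.6 and l == 0)
        assert (c.tp, c.fp) == (tp, fp)
        assert c.tp + c.fp + c.tn + c.fn == 40


class TestStageHoldout:
    CFG = FitConfig(n_folds=5, seed=1)

    def test_split_sizes_and_id_audit(self, small_cohort):
        _, l2 = preprocess(small_cohort.matrix)
        res = stage_holdout_protocol(l2, small_cohort.labels, self.CFG, seed=3)
        stages = small_cohort.labels.stage
        cancer = small_cohort.labels.is_cancer
        n_stage1 = int(((stages == "I") & cancer).sum())
        assert res.n_test_cancer == n_stage1
        assert res.n_train_cancer == int(cancer.sum()) - n_stage1
        assert res.n_test_noncancer == round(0.25 * (~cancer).sum())
        # no test subject may appear in training
        assert not (set(res.train_ids) & set(res.test_ids))
        assert sorted(res.train_ids + res.test_ids) == sorted(
            small_cohort.labels.sample_ids)
        # stage-I cancers all in the test set
        stage1_ids = set(stages.index[(stages == "I") & cancer])
        assert stage1_ids <= set(res.test_ids)

    def test_no_stage_one_raises(self, small_cohort):
        labels = small_cohort.labels
        labels.table.loc[labels.is_cancer, "stage"] = "II"
        _, l2 = preprocess(small_cohort.matrix)
        with pytest.raises(ProtocolError):
            stage_holdout_protocol(l2, labels, self.CFG)

    def test_whole_cohort_cv_beats_holdout_on_average(self):
        """Generalization sanity: over 10 seeds, the mean within-cohort
        AUROC of the deployed CV-averaged model (scored on the subjects it
        was selected on — the optimistic protocol) is >= the mean stage-I
        hold-out test AUROC (the honest protocol)."""
        from evmir import CohortSpec, generate_cohort, risk_scores

        cv_auc, ho_auc = [], []
        for seed in range(10):
            spec = CohortSpec(
                n_cancer=30, n_noncancer=30, n_species=150, core_fraction=0.4,
                target_median_detected=100, n_up=5, n_down=2, effect_log2fc=1.0,
                stage_fractions={"I": 0.25, "II": 0.25, "III": 0.25, "IV": 0.25},
                seed=100 + seed)
            cohort = generate_cohort(spec)
            _, l2 = preprocess(cohort.matrix)
            X, y, ids, _ = to_design(l2, cohort.labels)
            cfg = FitConfig(n_folds=5, seed=seed)
            model = cv_attribute_selection(X, y, ids, cfg)
            cv_auc.append(auroc(risk_scores(model, X, ids), y))
            res = stage_holdout_protocol(l2, cohort.labels, cfg, seed=seed)
            ho_auc.append(res.roc.auroc)
        assert np.mean(cv_auc) >= np.mean(ho_auc)


class TestOneVsRest:
    def test_three_separated_classes(self):
        rng = np.random.default_rng(8)
        n = 30
        X = rng.normal(0, 0.5, size=(3 * n, 4))
        X[:n, 0] += 4
        X[n:2 * n, 1] += 4
        X[2 * n:, 2] += 4
        labels = np.array(["a"] * n + ["b"] * n + ["c"] * n)
        ids = [f"f{j}" for j in range(4)]
        models, pred = one_vs_rest_multiclass(
            X, labels, ids, FitConfig(lam=0.1, n_folds=3, seed=0))
        assert set(models) == {"a", "b", "c"}
        assert (pred == labels).mean() >= 0.9

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateLabelError):
            one_vs_rest_multiclass(np.ones((4, 1)), ["a"] * 4, ["f0"])
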