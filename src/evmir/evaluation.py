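"""Risk-score evaluation: ROC curves, AUROC with confidence intervals,
threshold metrics, and the stage-I hold-out protocol.

AUROC is the probability that a random positive scores above a random
negative, ties counted 1/2 — identical to the normalized Mann-Whitney U and
to the trapezoidal area under the ROC polygon. An AUROC of 0.5 is a test
with no discriminating ability, 1.0 complete discrimination. Confidence
intervals default to DeLong's method; a stratified bootstrap is available.

The stage-I hold-out trains the ensemble on all non-stage-I cancer subjects
plus a seeded random subset of noncancer subjects, and evaluates on the
held-out stage-I cancers plus the remaining noncancer subjects — probing
whether the signal generalizes to the earliest disease stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ensemble import FitConfig, LogisticEnsemble, cv_attribute_selection, risk_scores
from .errors import DegenerateLabelError, InvalidInputError, ProtocolError
from .matrix import IntensityMatrix, CohortLabels, to_design


def _check_two_class(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels, dtype=float).ravel()
    pos = labels == 1
    if pos.all() or not pos.any():
        raise DegenerateLabelError("both classes are required")
    return pos, ~pos


def auroc(scores, labels) -> float:
    """Pair-counting AUROC with ties counted 1/2 (rank formulation)."""
    scores = np.asarray(scores, dtype=float).ravel()
    pos, neg = _check_two_class(labels)
    n1, n2 = int(pos.sum()), int(neg.sum())
    ranks = stats.rankdata(scores)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n2))


@dataclass
class ROCResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auroc: float
    ci: tuple | None = None
    ci_method: str | None = None


def roc_points(scores, labels) -> ROCResult:
    """ROC polygon: one vertex per distinct score plus the (0,0) endpoint.

    The trapezoidal area equals the pair-counting AUROC exactly.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    pos, neg = _check_two_class(labels)
    n1, n2 = int(pos.sum()), int(neg.sum())
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    is_pos = pos[order]
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted) != 0), s_sorted.size - 1]
    tp = np.cumsum(is_pos)[distinct]
    fp = np.cumsum(~is_pos)[distinct]
    tpr = np.r_[0.0, tp / n1]
    fpr = np.r_[0.0, fp / n2]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    area = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auroc=area)


def _delong_variance(scores, labels):
    """DeLong structural-component variance of the AUROC estimator."""
    scores = np.asarray(scores, dtype=float).ravel()
    pos, neg = _check_two_class(labels)
    x, yv = scores[pos], scores[neg]
    m, n = x.size, yv.size
    if m < 2 or n < 2:
        raise InvalidInputError("DeLong CI needs >= 2 samples per class")
    psi = (x[:, None] > yv[None, :]).astype(float) \
        + 0.5 * (x[:, None] == yv[None, :])
    theta = psi.mean()
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    s10 = v10.var(ddof=1)
    s01 = v01.var(ddof=1)
    return theta, s10 / m + s01 / n


def auroc_confint(scores, labels, level: float = 0.95, method: str = "delong",
                  n_boot: int = 2000, seed: int = 0) -> tuple[float, float]:
    """CI for the AUROC, clipped to [0, 1].

    ``delong`` uses the asymptotic normal interval from DeLong structural
    components; ``bootstrap`` a stratified percentile bootstrap (seeded).
    """
    if method == "delong":
        theta, var = _delong_variance(scores, labels)
        z = stats.norm.ppf(0.5 + level / 2.0)
        half = z * np.sqrt(max(var, 0.0))
        return (float(np.clip(theta - half, 0, 1)), float(np.clip(theta + half, 0, 1)))
    if method == "bootstrap":
        scores = np.asarray(scores, dtype=float).ravel()
        pos, neg = _check_two_class(labels)
        xp, xn = scores[pos], scores[neg]
        rng = np.random.default_rng(seed)
        vals = np.empty(n_boot)
        for b in range(n_boot):
            sp = rng.choice(xp, size=xp.size, replace=True)
            sn = rng.choice(xn, size=xn.size, replace=True)
            vals[b] = auroc(np.r_[sp, sn], np.r_[np.ones(sp.size), np.zeros(sn.size)])
        lo, hi = np.quantile(vals, [(1 - level) / 2, 0.5 + level / 2])
        return (float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1)))
    raise InvalidInputError(f"unknown CI method {method!r}")


@dataclass
class ConfusionMetrics:
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.fp + self.tn + self.fn)


def confusion_at_threshold(scores, labels, threshold: float = 0.5) -> ConfusionMetrics:
    """Confusion counts with the >= threshold -> cancer convention."""
    scores = np.asarray(scores, dtype=float).ravel()
    pos, neg = _check_two_class(labels)
    call = scores >= threshold
    return ConfusionMetrics(
        threshold=threshold,
        tp=int((call & pos).sum()), fp=int((call & neg).sum()),
        tn=int((~call & neg).sum()), fn=int((~call & pos).sum()),
    )


@dataclass
class StageHoldoutResult:
    model: LogisticEnsemble
    roc: ROCResult
    confusion: ConfusionMetrics
    train_ids: list
    test_ids: list
    n_train_cancer: int
    n_train_noncancer: int
    n_test_cancer: int
    n_test_noncancer: int


def stage_holdout_protocol(log2_matrix: IntensityMatrix, labels: CohortLabels,
                           config: FitConfig | None = None,
                           noncancer_test_fraction: float = 0.25,
                           seed: int = 0,
                           ci_method: str = "delong") -> StageHoldoutResult:
    """Train on non-stage-I cancers + a noncancer subset; test on stage-I
    cancers + the remaining noncancer subjects.

    With a 100+100 cohort carrying 24 stage-I cancers and the default
    noncancer test fraction of 0.25 this reproduces the 76+75 train /
    24+25 test split design.
    """
    log2_matrix.require_state("log2")
    config = config or FitConfig()
    X, y, probe_ids, sample_ids = to_design(log2_matrix, labels)
    stage = labels.stage.reindex(log2_matrix.sample_ids)
    is_ca = labels.is_cancer.reindex(log2_matrix.sample_ids).to_numpy()

    stage_one = (stage == "I").to_numpy() & is_ca
    if not stage_one.any():
        raise ProtocolError("cohort contains no stage-I cancer subjects")

    rng = np.random.default_rng(seed)
    nc_idx = np.flatnonzero(~is_ca)
    n_test_nc = int(round(noncancer_test_fraction * nc_idx.size))
    test_nc = set(rng.choice(nc_idx, size=n_test_nc, replace=False).tolist())

    test_mask = stage_one.copy()
    for i in test_nc:
        test_mask[i] = True
    train_mask = ~test_mask

    model = cv_attribute_selection(X[train_mask], y[train_mask], probe_ids, config)
    test_scores = risk_scores(model, X[test_mask], probe_ids)
    roc = roc_points(test_scores, y[test_mask])
    roc.ci = auroc_confint(test_scores, y[test_mask], method=ci_method, seed=seed)
    roc.ci_method = ci_method
    confusion = confusion_at_threshold(test_scores, y[test_mask])
    ids = np.array(sample_ids)
    return StageHoldoutResult(
        model=model, roc=roc, confusion=confusion,
        train_ids=ids[train_mask].tolist(), test_ids=ids[test_mask].tolist(),
        n_train_cancer=int((is_ca & train_mask).sum()),
        n_train_noncancer=int((~is_ca & train_mask).sum()),
        n_test_cancer=int((is_ca & test_mask).sum()),
        n_test_noncancer=int((~is_ca & test_mask).sum()),
    )


def one_vs_rest_multiclass(X: np.ndarray, class_labels, feature_ids,
                           config: FitConfig | None = None):
    """One binary ensemble per class; predicted class = argmax risk score.

    Ties broken by fixed (sorted) class order. Returns
    ``(models: dict, predictions: np.ndarray of class labels)``.
    """
    config = config or FitConfig()
    class_labels = np.asarray(class_labels)
    classes = sorted(set(class_labels.tolist()))
    if len(classes) < 2:
        raise DegenerateLabelError("need >= 2 classes")
    models = {}
    score_mat = np.zeros((X.shape[0], len(classes)))
    for k, cls in enumerate(classes):
        y_bin = (class_labels == cls).astype(float)
        models[cls] = cv_attribute_selection(X, y_bin, feature_ids, config)
        score_mat[:, k] = risk_scores(models[cls], X, feature_ids)
    pred = np.array([classes[k] for k in score_mat.argmax(axis=1)])
    return models, pred
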