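"""The miRNA-ensemble classifier: a logistic risk score

    Y = 1 / (1 + exp(-(beta . x + alpha)))

fitted by minimizing a least-squares error term through the sigmoid plus an
L1 penalty,

    F(beta, alpha) = sum_i (sigmoid(beta . x_i + alpha) - y_i)^2
                     + lambda * ||beta||_1

with the intercept unpenalized (a log-loss objective is available as an
option). lambda trades data fit against sparsity: larger lambda drives more
coefficients exactly to zero and shrinks the ensemble.

Attribute selection runs the fit once per cross-validation training subset
(n_folds x n_repeats fits, stratified folds), averages beta and alpha over
all fits, and keeps features whose mean |beta_j| exceeds a threshold
(0.01 by default). The deployed model uses the thresholded averaged
coefficients plus the mean intercept; an optional refit on the selected
features is available but off by default.

Solver: proximal gradient descent with soft-thresholding and a backtracking
line search. The objective is non-convex (least squares through a sigmoid),
so the contract is monotone descent to a stationary point, not global
optimality; small instances are cross-checked against a dense grid search
in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (ConvergenceError, DegenerateLabelError, InvalidInputError,
                     InvalidSpecError, MissingFeatureError, StratificationError)

DEFAULT_LAMBDA = 1.0
DEFAULT_N_FOLDS = 20
DEFAULT_COEF_THRESHOLD = 0.01


@dataclass
class FitConfig:
    """Hyperparameters of the fit and of the CV attribute selection."""

    lam: float = DEFAULT_LAMBDA
    n_folds: int = DEFAULT_N_FOLDS
    n_repeats: int = 1
    coef_threshold: float = DEFAULT_COEF_THRESHOLD
    objective: str = "squared_error"      # or "log_loss"
    max_iter: int = 20000
    tol: float = 1e-9   # relative objective-drop tolerance (10-iteration window)
    seed: int = 0
    refit: bool = False

    def validate(self) -> None:
        if self.lam < 0:
            raise InvalidSpecError("lambda must be nonnegative")
        if self.n_folds < 2:
            raise InvalidSpecError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise InvalidSpecError("n_repeats must be >= 1")
        if self.coef_threshold < 0:
            raise InvalidSpecError("coef_threshold must be nonnegative")
        if self.objective not in ("squared_error", "log_loss"):
            raise InvalidSpecError(f"unknown objective {self.objective!r}")


@dataclass
class SelectionTrace:
    """Per-fold fits and their average — the audit trail of the selection."""

    betas: np.ndarray             # (n_fits, p)
    alphas: np.ndarray            # (n_fits,)
    fold_assignments: np.ndarray  # (n_repeats, n) fold index per sample
    mean_beta: np.ndarray
    mean_alpha: float
    oof_scores: np.ndarray        # (n,) out-of-fold risk scores, repeat-averaged
    seed: int

    @property
    def n_fits(self) -> int:
        return self.betas.shape[0]


@dataclass
class LogisticEnsemble:
    """Deployed miRNA ensemble: sparse weights over probe ids + intercept."""

    beta: dict                    # probe id -> weight (nonzero entries only)
    alpha: float
    lam: float
    feature_ids: list = field(repr=False)
    trace: SelectionTrace | None = field(default=None, repr=False)

    @property
    def selected_ids(self) -> list:
        return sorted(self.beta)

    def beta_vector(self, feature_ids=None) -> np.ndarray:
        ids = self.feature_ids if feature_ids is None else list(feature_ids)
        return np.array([self.beta.get(f, 0.0) for f in ids])


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def predict_risk(model: LogisticEnsemble, x) -> float:
    """Risk score Y in (0,1) for one subject's log2 intensity profile.

    ``x`` is a mapping / pandas Series keyed by probe id and must cover
    every selected feature.
    """
    z = model.alpha
    for pid, w in model.beta.items():
        if pid not in x:
            raise MissingFeatureError(f"feature {pid!r} missing from input profile")
        z += w * float(x[pid])
    return float(_sigmoid(np.array([z]))[0])


def risk_scores(model: LogisticEnsemble, X: np.ndarray, feature_ids) -> np.ndarray:
    """Vectorized risk scores for a samples x features design matrix."""
    ids = list(feature_ids)
    idx = {f: j for j, f in enumerate(ids)}
    missing = [f for f in model.beta if f not in idx]
    if missing:
        raise MissingFeatureError(f"features missing from design matrix: {missing[:5]}")
    b = np.zeros(len(ids))
    for f, w in model.beta.items():
        b[idx[f]] = w
    return _sigmoid(X @ b + model.alpha)


def classify(y_score: float) -> str:
    """Decision rule: Y < 0.5 -> noncancer; Y >= 0.5 -> cancer."""
    if not (0.0 <= y_score <= 1.0):
        raise InvalidInputError(f"risk score {y_score} outside [0, 1]")
    return "cancer" if y_score >= 0.5 else "noncancer"


def _smooth_value(beta, alpha, X, y, objective):
    z = X @ beta + alpha
    if objective == "squared_error":
        r = _sigmoid(z) - y
        return float(r @ r)
    # log-loss: sum_i log(1+exp(z_i)) - y_i z_i, numerically stable
    return float(np.sum(np.logaddexp(0.0, z) - y * z))


def _soft(v: np.ndarray, t: float) -> np.ndarray:
    return np.sign(v) * np.maximum(np.abs(v) - t, 0.0)


def objective_value(beta, alpha, X, y, lam, objective="squared_error") -> float:
    """Full penalized objective F(beta, alpha)."""
    return _smooth_value(beta, alpha, X, y, objective) + lam * float(np.abs(beta).sum())


def fit_l1_penalized(X: np.ndarray, y: np.ndarray, config: FitConfig | None = None,
                     beta0=None, alpha0=None):
    """Minimize the L1-penalized objective by proximal gradient descent.

    Returns ``(beta, alpha, info)`` where ``info`` has the objective history
    (monotone non-increasing), iteration count and convergence flag.

    Raises
    ------
    DegenerateLabelError
        If only one class is present.
    ConvergenceError
        If the relative objective change has not fallen below ``tol``
        within ``max_iter`` iterations; carries the final objective.
    """
    config = config or FitConfig()
    config.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise InvalidInputError("X must be samples x features matching y")
    classes = np.unique(y)
    if classes.size < 2:
        raise DegenerateLabelError("both classes are required to fit the classifier")
    if not set(classes) <= {0.0, 1.0}:
        raise InvalidInputError("labels must be 0/1")

    n, p = X.shape
    xb = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    mean_y = float(np.clip(y.mean(), 1e-6, 1 - 1e-6))
    xa = float(np.log(mean_y / (1 - mean_y))) if alpha0 is None else float(alpha0)
    lam, obj = config.lam, config.objective

    def grad(b, a):
        s = _sigmoid(X @ b + a)
        if obj == "squared_error":
            w = 2.0 * (s - y) * s * (1.0 - s)
        else:
            w = s - y
        return X.T @ w, float(w.sum())

    # monotone FISTA: accelerated proximal gradient with backtracking;
    # the safeguard keeps the iterate sequence's objective non-increasing
    yb, ya = xb.copy(), xa
    F = _smooth_value(xb, xa, X, y, obj) + lam * np.abs(xb).sum()
    history = [F]
    t = 1.0
    tk = 1.0
    converged = False
    n_flat = 0
    it = -1
    for it in range(config.max_iter):
        f_y = _smooth_value(yb, ya, X, y, obj)
        gb, ga = grad(yb, ya)
        while True:
            zb = _soft(yb - t * gb, t * lam)
            za = ya - t * ga
            db, da = zb - yb, za - ya
            f_z = _smooth_value(zb, za, X, y, obj)
            bound = f_y + gb @ db + ga * da + (db @ db + da * da) / (2.0 * t)
            if f_z <= bound + 1e-12 * max(1.0, abs(f_y)):
                break
            t *= 0.5
            if t < 1e-16:
                break
        Fz = f_z + lam * np.abs(zb).sum()
        tk_new = (1.0 + np.sqrt(1.0 + 4.0 * tk * tk)) / 2.0
        if Fz <= F:
            yb = zb + ((tk - 1.0) / tk_new) * (zb - xb)
            ya = za + ((tk - 1.0) / tk_new) * (za - xa)
            xb, xa, F_new = zb, za, Fz
        else:
            # reject the step but keep momentum pointed at it
            yb = xb + (tk / tk_new) * (zb - xb)
            ya = xa + (tk / tk_new) * (za - xa)
            F_new = F
        rel_drop = (F - F_new) / max(1.0, abs(F))
        F = F_new
        tk = tk_new
        history.append(F)
        t = min(t * 1.1, 1e6)
        if rel_drop <= config.tol:
            n_flat += 1
            if n_flat >= 10:
                converged = True
                break
        else:
            n_flat = 0
    beta, alpha = xb, xa
    info = {"objective": F, "history": np.array(history),
            "n_iter": it + 1, "converged": converged}
    if not converged:
        raise ConvergenceError(
            f"proximal gradient did not converge in {config.max_iter} iterations "
            f"(final objective {F:.6g})", objective=F)
    return beta, float(alpha), info


def _stratified_folds(y: np.ndarray, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Fold index per sample; each class spread round-robin over folds."""
    y = np.asarray(y)
    folds = np.empty(y.size, dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if idx.size < n_folds:
            raise StratificationError(
                f"class {cls} has {idx.size} samples, fewer than {n_folds} folds")
        perm = rng.permutation(idx)
        folds[perm] = np.arange(perm.size) % n_folds
    return folds


def cv_attribute_selection(X: np.ndarray, y: np.ndarray, feature_ids,
                           config: FitConfig | None = None) -> LogisticEnsemble:
    """Cross-validated coefficient-averaging attribute selection.

    For each of ``n_folds x n_repeats`` training subsets an L1-penalized
    fit is run; beta and alpha are averaged over all fits, and features
    whose |mean beta_j| exceeds ``coef_threshold`` form the ensemble. The
    deployed model uses the thresholded averaged coefficients and the mean
    intercept (``config.refit=True`` refits on the selected features
    instead). Out-of-fold risk scores (repeat-averaged) are kept in the
    trace.
    """
    config = config or FitConfig()
    config.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    feature_ids = list(feature_ids)
    if X.shape[1] != len(feature_ids):
        raise InvalidInputError("feature_ids length must match X columns")

    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n, p = X.shape
    betas, alphas = [], []
    assignments = np.empty((config.n_repeats, n), dtype=int)
    oof = np.zeros((config.n_repeats, n))
    for rep in range(config.n_repeats):
        folds = _stratified_folds(y, config.n_folds, rng)
        assignments[rep] = folds
        for f_id in range(config.n_folds):
            train = folds != f_id
            if np.unique(y[train]).size < 2:
                raise StratificationError(f"fold {f_id} training set lost a class")
            b, a, _ = fit_l1_penalized(X[train], y[train], config)
            betas.append(b)
            alphas.append(a)
            test = ~train
            oof[rep, test] = _sigmoid(X[test] @ b + a)
    betas = np.array(betas)
    alphas = np.array(alphas)
    mean_beta = betas.mean(axis=0)
    mean_alpha = float(alphas.mean())
    selected = np.abs(mean_beta) > config.coef_threshold

    if config.refit and selected.any():
        b_sel, a_fit, _ = fit_l1_penalized(X[:, selected], y, config)
        deployed = np.zeros(p)
        deployed[selected] = b_sel
        alpha_out = a_fit
    else:
        deployed = np.where(selected, mean_beta, 0.0)
        alpha_out = mean_alpha

    trace = SelectionTrace(
        betas=betas, alphas=alphas, fold_assignments=assignments,
        mean_beta=mean_beta, mean_alpha=mean_alpha,
        oof_scores=oof.mean(axis=0), seed=config.seed,
    )
    beta_map = {feature_ids[j]: float(deployed[j])
                for j in np.flatnonzero(deployed != 0.0)}
    return LogisticEnsemble(beta=beta_map, alpha=float(alpha_out), lam=config.lam,
                            feature_ids=feature_ids, trace=trace)


def lambda_path(X: np.ndarray, y: np.ndarray, feature_ids, lambdas,
                config: FitConfig | None = None) -> pd.Series:
    """Selected-feature count per lambda along a strictly increasing path.

    Each lambda runs the full CV attribute selection; the count is expected
    to be non-increasing in lambda (up to solver tolerance).
    """
    lambdas = list(lambdas)
    if len(lambdas) < 2 or any(b <= a for a, b in zip(lambdas, lambdas[1:])):
        raise InvalidInputError("lambdas must be a strictly increasing list of >= 2 values")
    config = config or FitConfig()
    counts = []
    for lam in lambdas:
        model = cv_attribute_selection(X, y, feature_ids, replace(config, lam=lam))
        counts.append(len(model.beta))
    return pd.Series(counts, index=pd.Index(lambdas, name="lambda"),
                     name="n_selected")
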