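"""The four comparator classifiers and Sequential Forward Selection.

All baselines follow the same Model/Results shape as the GMDH engine: a model
is bound to a training table + labels, ``fit(seed)`` returns a results object
exposing ``predict_scores`` / ``predict``, so the validation drivers run
unmodified on every method.

* Logistic regression: ridge-stabilized IRLS on z-scored features; the
  decision rule is p >= 0.5.  Optionally drops features with small
  standardized coefficients and refits once.
* Poisson-link GLM: the 0/1 label is treated as a count and regressed with a
  log link; predictions are rates, thresholded at 0.5.
* RBF-kernel SVM: SMO-family solver (libsvm); the kernel width gamma and
  soft-margin C are tuned by internal stratified 3-fold CV maximizing MCC
  over a grid.
* RBF network: K-means prototypes, a shared width (median inter-center
  distance), and a linear output layer (one node per class) fitted by least
  squares; prediction is the argmax class score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.special import expit
from sklearn.cluster import KMeans
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .data import FeatureTable, check_labels
from .metrics import metric_set

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    pass


def _standardizer(X: np.ndarray):
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    sds = np.where(sds > 0, sds, 1.0)
    return means, sds


class _BaseModel:
    def __init__(self, table: FeatureTable, labels):
        self.table = table
        self.labels = check_labels(labels, table)
        if min(np.sum(self.labels == 0), np.sum(self.labels == 1)) < 1:
            raise ValueError("both classes must be present")


@dataclass
class _BaseResults:
    feature_names: list
    means: np.ndarray
    sds: np.ndarray

    def _matrix(self, table: FeatureTable) -> np.ndarray:
        cols = [table.column_index(n) for n in self.feature_names]
        return (table.values[:, cols] - self.means) / self.sds

    def predict(self, table: FeatureTable) -> np.ndarray:
        raise NotImplementedError

    def predict_scores(self, table: FeatureTable) -> np.ndarray:
        raise NotImplementedError


# ---------------------------------------------------------------------------
# Logistic regression
# ---------------------------------------------------------------------------

def _irls_logistic(X: np.ndarray, y: np.ndarray, ridge: float,
                   max_iter: int = 100, tol: float = 1e-8):
    """IRLS for logit(p) = b0 + X b with an L2 ridge on the slopes."""
    n, f = X.shape
    Xa = np.column_stack([np.ones(n), X])
    beta = np.zeros(f + 1)
    penalty = np.diag(np.r_[0.0, np.full(f, ridge)])
    trace = []
    for it in range(1, max_iter + 1):
        eta = np.clip(Xa @ beta, -30, 30)
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        XtW = Xa.T * w
        new = np.linalg.solve(XtW @ Xa + penalty, XtW @ z)
        if not np.isfinite(new).all():
            raise ConvergenceError(f"IRLS diverged at iteration {it}: {trace}")
        delta = np.max(np.abs(new - beta))
        trace.append(float(delta))
        beta = new
        if delta < tol:
            return beta, it, True
    return beta, max_iter, False


class LogisticRegressionClassifier(_BaseModel):
    """log(p/(1-p)) = b0 + sum_j b_j x_j; classify DT when p >= 0.5."""

    def __init__(self, table, labels, ridge: float = 1e-6,
                 weight_threshold: float | None = None):
        super().__init__(table, labels)
        self.ridge = ridge
        self.weight_threshold = weight_threshold

    def fit(self, seed: int = 0) -> "LogisticResults":
        X = self.table.values
        means, sds = _standardizer(X)
        Xz = (X - means) / sds
        y = self.labels.astype(float)
        beta, n_iter, converged = _irls_logistic(Xz, y, self.ridge)
        kept = list(range(X.shape[1]))
        if self.weight_threshold is not None:
            kept = [j for j in kept if abs(beta[j + 1]) >= self.weight_threshold]
            if not kept:
                kept = [int(np.argmax(np.abs(beta[1:])))]
            beta_k, n_iter, converged = _irls_logistic(Xz[:, kept], y, self.ridge)
            beta = np.r_[beta_k[0], np.zeros(X.shape[1])]
            beta[np.asarray(kept) + 1] = beta_k[1:]
        return LogisticResults(
            feature_names=list(self.table.feature_names), means=means, sds=sds,
            intercept=float(beta[0]), coefficients=beta[1:],
            kept_features=kept, n_iterations=n_iter, converged=converged)


@dataclass
class LogisticResults(_BaseResults):
    intercept: float = 0.0
    coefficients: np.ndarray = None
    kept_features: list = field(default_factory=list)
    n_iterations: int = 0
    converged: bool = True

    def predict_scores(self, table):
        return expit(np.clip(self.intercept + self._matrix(table) @ self.coefficients, -30, 30))

    def predict(self, table):
        return (self.predict_scores(table) >= 0.5).astype(int)

    def summary(self) -> str:
        rows = [f"logistic regression (IRLS, {self.n_iterations} iterations, "
                f"converged={self.converged})", f"intercept: {self.intercept:+.4f}"]
        rows += [f"  {n}: {c:+.4f}" for n, c in zip(self.feature_names, self.coefficients)]
        return "\n".join(rows)


# ---------------------------------------------------------------------------
# Poisson-link GLM
# ---------------------------------------------------------------------------

class PoissonGlmClassifier(_BaseModel):
    """GLM with log link treating the 0/1 label as a count; rule: rate >= 0.5."""

    def fit(self, seed: int = 0) -> "PoissonGlmResults":
        X = self.table.values
        means, sds = _standardizer(X)
        Xz = sm.add_constant((X - means) / sds, has_constant="add")
        fit = sm.GLM(self.labels.astype(float), Xz, family=sm.families.Poisson()).fit(maxiter=200)
        if not np.isfinite(fit.params).all():
            raise ConvergenceError("Poisson GLM produced non-finite parameters")
        return PoissonGlmResults(
            feature_names=list(self.table.feature_names), means=means, sds=sds,
            params=np.asarray(fit.params))


@dataclass
class PoissonGlmResults(_BaseResults):
    params: np.ndarray = None

    def predict_scores(self, table):
        """Predicted Poisson rates (may exceed 1)."""
        eta = self.params[0] + self._matrix(table) @ self.params[1:]
        return np.exp(np.clip(eta, -30, 30))

    def predict(self, table):
        return (self.predict_scores(table) >= 0.5).astype(int)

    def summary(self) -> str:
        return ("Poisson-link GLM on binary labels; rates thresholded at 0.5\n"
                + "\n".join(f"  {n}: {c:+.4f}" for n, c in
                            zip(["(intercept)"] + self.feature_names, self.params)))


# ---------------------------------------------------------------------------
# RBF-kernel SVM
# ---------------------------------------------------------------------------

DEFAULT_C_GRID = (0.1, 1.0, 10.0, 100.0)
DEFAULT_GAMMA_GRID = (0.01, 0.1, 1.0, 10.0)


class RbfSvmClassifier(_BaseModel):
    """RBF-kernel SVM; (C, gamma) tuned by internal 3-fold CV MCC."""

    def __init__(self, table, labels, c_grid=DEFAULT_C_GRID,
                 gamma_grid=DEFAULT_GAMMA_GRID, cv: int = 3):
        super().__init__(table, labels)
        if not c_grid or not gamma_grid:
            raise ValueError("tuning grid must be non-empty")
        self.c_grid = tuple(c_grid)
        self.gamma_grid = tuple(gamma_grid)
        self.cv = cv

    def fit(self, seed: int = 0) -> "RbfSvmResults":
        X = self.table.values
        means, sds = _standardizer(X)
        Xz = (X - means) / sds
        y = self.labels
        best = None
        if len(self.c_grid) * len(self.gamma_grid) > 1 and min(np.bincount(y)) >= self.cv:
            skf = StratifiedKFold(self.cv, shuffle=True, random_state=seed % (2**31))
            folds = list(skf.split(Xz, y))
            for C in self.c_grid:
                for gamma in self.gamma_grid:
                    mccs = []
                    for tr, te in folds:
                        svc = SVC(C=C, gamma=gamma, kernel="rbf")
                        svc.fit(Xz[tr], y[tr])
                        mccs.append(metric_set(y[te], svc.predict(Xz[te])).mcc)
                    score = float(np.mean(mccs))
                    if best is None or score > best[0]:
                        best = (score, C, gamma)
            _, C, gamma = best
        else:
            C, gamma = self.c_grid[0], self.gamma_grid[0]
        svc = SVC(C=C, gamma=gamma, kernel="rbf")
        svc.fit(Xz, y)
        return RbfSvmResults(feature_names=list(self.table.feature_names),
                             means=means, sds=sds, svc=svc, C=C, gamma=gamma)


@dataclass
class RbfSvmResults(_BaseResults):
    svc: SVC = None
    C: float = 1.0
    gamma: float = 1.0

    def predict_scores(self, table):
        """Signed decision-function values (not probabilities)."""
        return self.svc.decision_function(self._matrix(table))

    def predict(self, table):
        return self.svc.predict(self._matrix(table)).astype(int)

    def summary(self) -> str:
        return (f"RBF-SVM: C={self.C}, gamma={self.gamma}, "
                f"{len(self.svc.support_)} support vectors")


# ---------------------------------------------------------------------------
# RBF network
# ---------------------------------------------------------------------------

class RbfnClassifier(_BaseModel):
    """RBF network: K-means prototypes + linear two-node output layer."""

    def __init__(self, table, labels, n_centers: int = 10):
        super().__init__(table, labels)
        if n_centers < 1:
            raise ValueError("K must be >= 1")
        if n_centers > table.n_samples:
            raise ValueError(f"K={n_centers} exceeds {table.n_samples} fitting samples")
        self.n_centers = n_centers

    def fit(self, seed: int = 0) -> "RbfnResults":
        X = self.table.values
        means, sds = _standardizer(X)
        Xz = (X - means) / sds
        km = KMeans(n_clusters=self.n_centers, n_init=10, random_state=seed % (2**31))
        km.fit(Xz)
        centers = km.cluster_centers_
        if len(centers) > 1:
            d = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=2)
            width = float(np.median(d[np.triu_indices(len(centers), k=1)]))
        else:
            width = 1.0
        width = width if width > 0 else 1.0
        phi = _rbf_activations(Xz, centers, width)
        onehot = np.column_stack([(self.labels == 0), (self.labels == 1)]).astype(float)
        W, *_ = np.linalg.lstsq(phi, onehot, rcond=None)
        return RbfnResults(feature_names=list(self.table.feature_names),
                           means=means, sds=sds, centers=centers, width=width, W=W)


def _rbf_activations(X, centers, width):
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return np.column_stack([np.exp(-d2 / (2 * width ** 2)), np.ones(len(X))])


@dataclass
class RbfnResults(_BaseResults):
    centers: np.ndarray = None
    width: float = 1.0
    W: np.ndarray = None

    def _class_scores(self, table):
        return _rbf_activations(self._matrix(table), self.centers, self.width) @ self.W

    def predict_scores(self, table):
        """Discriminant: class-1 output minus class-0 output."""
        s = self._class_scores(table)
        return s[:, 1] - s[:, 0]

    def predict(self, table):
        return np.argmax(self._class_scores(table), axis=1).astype(int)

    def summary(self) -> str:
        return f"RBF network: K={len(self.centers)} prototypes, width={self.width:.4f}"


# ---------------------------------------------------------------------------
# Functional wrappers (fit on an explicit subset of rows)
# ---------------------------------------------------------------------------

def _subset(table, labels, fitting_indices):
    labels = check_labels(labels, table)
    if fitting_indices is None:
        return table, labels
    idx = np.asarray(fitting_indices, dtype=int)
    return table.subset_rows(idx), labels[idx]


def fit_logistic(table, labels, fitting_indices=None, weight_threshold=None,
                 seed: int = 0) -> LogisticResults:
    t, y = _subset(table, labels, fitting_indices)
    return LogisticRegressionClassifier(t, y, weight_threshold=weight_threshold).fit(seed)


def fit_glm_poisson(table, labels, fitting_indices=None, seed: int = 0) -> PoissonGlmResults:
    t, y = _subset(table, labels, fitting_indices)
    return PoissonGlmClassifier(t, y).fit(seed)


def fit_rbf_svm(table, labels, fitting_indices=None, c_grid=DEFAULT_C_GRID,
                gamma_grid=DEFAULT_GAMMA_GRID, seed: int = 0) -> RbfSvmResults:
    t, y = _subset(table, labels, fitting_indices)
    return RbfSvmClassifier(t, y, c_grid=c_grid, gamma_grid=gamma_grid).fit(seed)


def fit_rbfn(table, labels, fitting_indices=None, n_centers: int = 10,
             seed: int = 0) -> RbfnResults:
    t, y = _subset(table, labels, fitting_indices)
    return RbfnClassifier(t, y, n_centers=n_centers).fit(seed)


# ---------------------------------------------------------------------------
# Sequential forward selection
# ---------------------------------------------------------------------------

def sequential_forward_selection(trainer, table: FeatureTable, labels,
                                 criterion: str = "mcc",
                                 max_features: int | None = None,
                                 seed: int = 0, cv: int = 3) -> list:
    """Greedy wrapper selection: repeatedly add the feature that most improves
    the internal stratified 3-fold CV *criterion*; stop when nothing improves
    or ``max_features`` is reached.  Ties break toward the lower feature index.

    ``trainer`` is any callable (table, labels, seed) -> results with a
    ``predict`` method.
    """
    labels = check_labels(labels, table)
    n_f = table.n_features
    max_features = n_f if max_features is None else max_features
    if max_features > n_f:
        raise ValueError("max_features exceeds the number of features")
    skf = StratifiedKFold(cv, shuffle=True, random_state=seed % (2**31))
    folds = list(skf.split(table.values, labels))

    def cv_score(cols):
        sub = table.select_columns(cols)
        vals = []
        for k, (tr, te) in enumerate(folds):
            res = trainer(sub.subset_rows(tr), labels[tr], seed + k)
            vals.append(metric_set(labels[te], res.predict(sub.subset_rows(te)))[criterion])
        return float(np.mean(vals))

    selected: list = []
    best_score = -np.inf
    while len(selected) < max_features:
        candidates = [j for j in range(n_f) if j not in selected]
        scores = [(cv_score(selected + [j]), j) for j in candidates]
        step_best, j_best = max(scores, key=lambda t: (t[0], -t[1]))
        if step_best <= best_score:
            break
        selected.append(j_best)
        best_score = step_best
    return selected
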