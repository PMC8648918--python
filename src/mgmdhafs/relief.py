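"""I-RELIEF feature weighting and weight-based feature selection.

Iterated Relief scores each feature by its ability to discriminate between
neighboring patterns: under the current weighted L1 distance, every sample is
compared against a kernel-weighted expectation of its hits (same class) and
misses (other class); the per-feature expected margin (miss distance minus hit
distance) becomes the new weight vector after truncating negatives to zero and
renormalizing onto the probability simplex.  Iteration continues to a fixed
point.

Continuous features are z-scored (fitting-set mean/sd) before any distance is
computed; binary features enter as 0/1.  For cost control the expectation can
be taken over a class-stratified subsample (``max_samples``) since each
iteration is O(n^2 * n_features).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data import FeatureTable, check_labels

logger = logging.getLogger(__name__)


@dataclass
class ReliefWeights:
    weights: np.ndarray       # nonnegative, sums to 1
    feature_names: list
    n_iterations: int
    converged: bool
    kernel_width: float

    def to_json_dict(self) -> dict:
        return {name: float(w) for name, w in zip(self.feature_names, self.weights)}


def _standardize_continuous(table: FeatureTable) -> np.ndarray:
    X = table.values.astype(float).copy()
    for j, kind in enumerate(table.feature_kinds):
        if kind == "continuous":
            sd = X[:, j].std()
            X[:, j] = (X[:, j] - X[:, j].mean()) / (sd if sd > 0 else 1.0)
    return X


def _stratified_subsample(labels: np.ndarray, cap: int, seed: int) -> np.ndarray:
    n = len(labels)
    if cap is None or n <= cap:
        return np.arange(n)
    rng = np.random.default_rng(seed)
    keep = []
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        k = max(2, int(round(cap * len(idx) / n)))
        keep.append(rng.choice(idx, size=min(k, len(idx)), replace=False))
    return np.sort(np.concatenate(keep))


def irelief_weights(table: FeatureTable, labels, kernel_width: float = 1.0,
                    max_iterations: int = 50, tolerance: float = 1e-4,
                    max_samples: int | None = 600, seed: int = 0) -> ReliefWeights:
    """Iterated Relief weights on the probability simplex.

    Degenerate input (all features constant, or classes indistinguishable so
    that every margin is <= 0) yields uniform weights with a warning.
    """
    if kernel_width <= 0 or tolerance <= 0:
        raise ValueError("kernel_width and tolerance must be positive")
    labels = check_labels(labels, table)
    if min(np.sum(labels == 0), np.sum(labels == 1)) < 2:
        raise ValueError("need >= 2 samples per class")
    if any(k == "categorical" for k in table.feature_kinds):
        raise ValueError("encode categorical features before Relief weighting")
    X = _standardize_continuous(table)
    sub = _stratified_subsample(labels, max_samples, seed)
    X, y = X[sub], labels[sub]
    n, f = X.shape
    w = np.full(f, 1.0 / f)
    same = y[:, None] == y[None, :]
    np.fill_diagonal(same, False)       # a sample is not its own hit
    diff = ~same
    np.fill_diagonal(diff, False)
    converged = False
    it = 0
    chunk = max(1, int(2**22 / max(n * f, 1)))  # keep the |x_i - x_j| block ~32 MB
    for it in range(1, max_iterations + 1):
        margins = np.zeros(f)
        for start in range(0, n, chunk):
            stop = min(start + chunk, n)
            block = np.abs(X[start:stop, None, :] - X[None, :, :])  # (b, n, f)
            dist = block @ w                                        # (b, n)
            kern = np.exp(-dist / kernel_width)
            hit_k = np.where(same[start:stop], kern, 0.0)
            miss_k = np.where(diff[start:stop], kern, 0.0)
            hit_sum = hit_k.sum(axis=1, keepdims=True)
            miss_sum = miss_k.sum(axis=1, keepdims=True)
            hit_p = np.divide(hit_k, hit_sum, out=np.zeros_like(hit_k), where=hit_sum > 0)
            miss_p = np.divide(miss_k, miss_sum, out=np.zeros_like(miss_k), where=miss_sum > 0)
            margins += np.einsum("bn,bnf->f", miss_p - hit_p, block)
        margins /= n
        pos = np.clip(margins, 0.0, None)
        total = pos.sum()
        if total <= 0:
            logger.warning("all Relief margins non-positive; returning uniform weights")
            return ReliefWeights(np.full(f, 1.0 / f), list(table.feature_names),
                                 it, False, kernel_width)
        w_new = pos / total
        delta = np.linalg.norm(w_new - w)
        w = w_new
        if delta < tolerance:
            converged = True
            break
    return ReliefWeights(w, list(table.feature_names), it, converged, kernel_width)


def select_features(weights: ReliefWeights, top_m: int | None = None,
                    min_weight: float | None = None) -> list:
    """Feature indices selected by Relief weight.

    ``top_m`` keeps the m largest weights (ties -> lower feature index);
    ``min_weight`` keeps every feature with weight >= threshold.  The result
    is never empty (falls back to the single best feature).
    """
    w = np.asarray(weights.weights)
    if (top_m is None) == (min_weight is None):
        raise ValueError("give exactly one of top_m or min_weight")
    if top_m is not None:
        if top_m < 1:
            raise ValueError("top_m must be >= 1")
        if top_m > len(w):
            logger.warning("top_m=%d exceeds %d features; keeping all", top_m, len(w))
            top_m = len(w)
        order = np.argsort(-w, kind="stable")  # stable: ties keep lower index first
        return sorted(int(i) for i in order[:top_m])
    selected = [int(i) for i in np.flatnonzero(w >= min_weight)]
    if not selected:
        selected = [int(np.argmax(w))]
    return selected


def default_min_weight(n_features: int) -> float:
    """Default selection threshold: half the uniform weight."""
    return 1.0 / (2.0 * n_features)
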