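"""Model-assessment protocol: hold-out and k-fold drivers, the label
permutation test, and Cochran's Q + McNemar post-hoc with Bonferroni
correction for comparing classifiers on a shared test set.

A *trainer* is any callable ``(table, labels, seed) -> results`` whose result
exposes ``predict`` (hard 0/1 labels) and ``predict_scores``; every classifier
in this package provides one through :func:`make_trainer`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import FeatureTable, check_labels, kfold_indices, stratified_holdout_split
from .metrics import ConfusionCounts, MetricSet, compute_metrics, confusion, metric_set

PERMUTATION_METRICS = ("sensitivity", "specificity", "precision", "accuracy", "mcc", "auc")


def make_trainer(model_class, **config):
    """Wrap a Model class into the shared trainer interface."""
    def trainer(table, labels, seed):
        return model_class(table, labels, **config).fit(seed=seed)
    trainer.__name__ = f"trainer_{model_class.__name__}"
    return trainer


@dataclass
class HoldoutResult:
    metrics: MetricSet
    y_test: np.ndarray
    predictions: np.ndarray
    scores: np.ndarray
    test_indices: np.ndarray
    seed: int


def evaluate_holdout(trainer, table: FeatureTable, labels,
                     train_fraction: float = 0.7, seed: int = 0,
                     stratified: bool = True) -> HoldoutResult:
    """Stratified hold-out evaluation; all fitting is confined to the training
    partition, metrics are computed on the test partition only."""
    labels = check_labels(labels, table)
    split = stratified_holdout_split(labels, train_fraction, seed, stratified=stratified)
    tr, te = split["train"], split["test"]
    results = trainer(table.subset_rows(tr), labels[tr], seed)
    test_table = table.subset_rows(te)
    preds = np.asarray(results.predict(test_table)).astype(int)
    scores = np.asarray(results.predict_scores(test_table), dtype=float)
    metrics = metric_set(labels[te], preds, scores=scores)
    return HoldoutResult(metrics, labels[te], preds, scores, te, seed)


@dataclass
class KfoldResult:
    per_fold: list
    pooled: MetricSet
    y_out: np.ndarray
    predictions: np.ndarray
    scores: np.ndarray
    seed: int


def evaluate_kfold(trainer, table: FeatureTable, labels, k: int = 4,
                   seed: int = 0) -> KfoldResult:
    """k-fold cross-validation; pooled metrics come from the concatenated
    out-of-fold predictions (pooled counts = sum of per-fold counts)."""
    labels = check_labels(labels, table)
    split = kfold_indices(labels, k, seed)
    per_fold, ys, ps, ss = [], [], [], []
    for name in sorted(split.partitions, key=lambda s: int(s.split("_")[1])):
        te = split[name]
        tr = np.setdiff1d(np.arange(table.n_samples), te)
        results = trainer(table.subset_rows(tr), labels[tr], seed)
        test_table = table.subset_rows(te)
        preds = np.asarray(results.predict(test_table)).astype(int)
        scores = np.asarray(results.predict_scores(test_table), dtype=float)
        per_fold.append(metric_set(labels[te], preds, scores=scores))
        ys.append(labels[te]); ps.append(preds); ss.append(scores)
    y_out = np.concatenate(ys)
    preds = np.concatenate(ps)
    scores = np.concatenate(ss)
    pooled = metric_set(y_out, preds, scores=scores)
    return KfoldResult(per_fold, pooled, y_out, preds, scores, seed)


@dataclass
class PermutationReport:
    real: MetricSet
    permuted: list
    p_values: dict
    n_permutations: int
    seed: int


def permutation_test(trainer, table: FeatureTable, labels,
                     n_permutations: int = 10, seed: int = 0,
                     train_fraction: float = 0.7,
                     metrics: tuple = PERMUTATION_METRICS) -> PermutationReport:
    """Re-run the full pipeline on label sets permuted uniformly (the 1/0
    ratio is preserved exactly) and report the empirical p-value of each
    index: p = (1 + #{permuted >= real}) / (n_permutations + 1)."""
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    labels = check_labels(labels, table)
    real = evaluate_holdout(trainer, table, labels, train_fraction, seed).metrics
    permuted = []
    for i in range(1, n_permutations + 1):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(997, i)))
        shuffled = labels[rng.permutation(len(labels))]
        permuted.append(
            evaluate_holdout(trainer, table, shuffled, train_fraction, seed).metrics)
    p_values = {}
    for m in metrics:
        real_v = real[m]
        if real_v is None or not np.isfinite(real_v):
            p_values[m] = None
            continue
        exceed = sum(1 for ms in permuted
                     if ms[m] is not None and np.isfinite(ms[m]) and ms[m] >= real_v)
        p_values[m] = (1 + exceed) / (n_permutations + 1)
    return PermutationReport(real, permuted, p_values, n_permutations, seed)


# ---------------------------------------------------------------------------
# Classifier comparison tests
# ---------------------------------------------------------------------------

def correctness_matrix(y_true, predictions: dict):
    """Binary samples x classifiers matrix (1 = classifier correct) plus the
    column order."""
    y = check_labels(y_true)
    names = list(predictions)
    cols = [(np.asarray(predictions[n]).astype(int) == y).astype(int) for n in names]
    return np.column_stack(cols), names


@dataclass
class CochranQResult:
    statistic: float  # nan when undefined
    df: int
    p_value: float
    undefined: bool = False


def cochran_q(matrix) -> CochranQResult:
    """Cochran's Q over k >= 2 classifiers:
    Q = k(k-1) sum_j (C_j - Cbar)^2 / (k sum_i R_i - sum_i R_i^2),
    chi-square distributed with k-1 df under the null of equal accuracies."""
    M = np.asarray(matrix)
    if M.ndim != 2 or M.shape[1] < 2 or M.shape[0] < 2:
        raise ValueError("need a samples x classifiers matrix with >= 2 of each")
    if not np.isin(M, (0, 1)).all():
        raise ValueError("correctness entries must be 0/1")
    n, k = M.shape
    col = M.sum(axis=0)
    row = M.sum(axis=1)
    denom = k * row.sum() - np.sum(row ** 2)
    df = k - 1
    if denom == 0:
        # every row constant (all classifiers agree on every sample): the
        # column sums coincide, so the numerator vanishes too; report Q = 0
        # with the undefined flag and p = 1
        return CochranQResult(0.0, df, 1.0, undefined=True)
    q = k * (k - 1) * np.sum((col - col.mean()) ** 2) / denom
    return CochranQResult(float(q), df, float(stats.chi2.sf(q, df)))


@dataclass
class McnemarResult:
    statistic: float       # chi-square statistic; nan for the exact branch
    p_value: float
    b: int                 # first classifier correct, second wrong
    c: int                 # first wrong, second correct
    exact: bool


def mcnemar(correct_a, correct_b, exact_threshold: int = 25) -> McnemarResult:
    """McNemar's test on two correctness vectors.

    Exact two-sided binomial p when b + c < *exact_threshold*, otherwise the
    continuity-corrected chi-square (|b-c|-1)^2 / (b+c)."""
    a = np.asarray(correct_a).astype(int)
    bvec = np.asarray(correct_b).astype(int)
    if a.shape != bvec.shape:
        raise ValueError("correctness vectors must have equal length")
    b = int(np.sum((a == 1) & (bvec == 0)))
    c = int(np.sum((a == 0) & (bvec == 1)))
    n = b + c
    if n == 0:
        return McnemarResult(0.0, 1.0, b, c, exact=True)
    if n < exact_threshold:
        p = min(1.0, 2.0 * stats.binom.cdf(min(b, c), n, 0.5))
        return McnemarResult(float("nan"), float(p), b, c, exact=True)
    statistic = (abs(b - c) - 1) ** 2 / n
    return McnemarResult(float(statistic), float(stats.chi2.sf(statistic, 1)), b, c, exact=False)


def bonferroni(p_values, m: int | None = None) -> list:
    """Adjusted p-values: min(1, p * m); m defaults to the list length."""
    p_values = list(p_values)
    if any(p < 0 or p > 1 for p in p_values):
        raise ValueError("p-values must lie in [0,1]")
    m = len(p_values) if m is None else m
    return [min(1.0, p * m) for p in p_values]


def compare_classifiers(y_true, predictions: dict, reference: str) -> dict:
    """Cochran's Q across all classifiers, then pairwise McNemar of the
    reference method against every other, Bonferroni-adjusted."""
    matrix, names = correctness_matrix(y_true, predictions)
    q = cochran_q(matrix)
    ref_col = matrix[:, names.index(reference)]
    pairwise = {}
    raw_p = []
    others = [n for n in names if n != reference]
    for name in others:
        res = mcnemar(ref_col, matrix[:, names.index(name)])
        pairwise[name] = res
        raw_p.append(res.p_value)
    adjusted = bonferroni(raw_p, m=len(others))
    return {
        "cochran_q": q,
        "mcnemar": pairwise,
        "adjusted_p": dict(zip(others, adjusted)),
        "reference": reference,
    }
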