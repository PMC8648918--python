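"""Categorical-to-interval logistic encoding.

Each categorical feature is expanded to a one-hot (binary) design and a
univariate logistic regression of the label on that design is fitted by
iteratively reweighted least squares; every category code is then mapped to
its fitted positive-class probability.  Because the one-hot design is
saturated, the MLE per category equals the empirical positive proportion, so
the encoding is a form of non-linear data normalization: categories are placed
on the (0,1) interval ordered by how enriched they are in drug targets.

Values are clipped to [1e-6, 1 - 1e-6] (complete separation drives the MLE to
the boundary).  Categories unseen at fit time map to the positive-class
prevalence of the fitting set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .data import FeatureTable, check_labels
from .metrics import EPS

logger = logging.getLogger(__name__)


@dataclass
class EncoderDiagnostics:
    iterations: int
    converged: bool


@dataclass
class CategoricalEncoder:
    mappings: dict            # feature name -> {category code -> value in (0,1)}
    fallback: float           # positive-class prevalence of the fitting set
    feature_names: list
    diagnostics: dict = field(default_factory=dict)
    n_fallbacks_applied: int = 0

    def to_json_dict(self) -> dict:
        return {
            "mappings": {k: {str(int(c)): v for c, v in m.items()} for k, m in self.mappings.items()},
            "fallback": self.fallback,
            "feature_names": list(self.feature_names),
        }

    @classmethod
    def from_json_dict(cls, obj: dict) -> "CategoricalEncoder":
        mappings = {k: {int(c): float(v) for c, v in m.items()} for k, m in obj["mappings"].items()}
        return cls(mappings, float(obj["fallback"]), list(obj["feature_names"]))


def _irls_category_probs(codes: np.ndarray, y: np.ndarray):
    """Fitted P(y=1 | category) via one-hot IRLS logistic fit; falls back to
    empirical proportions when IRLS misbehaves (e.g. complete separation)."""
    cats = np.unique(codes)
    onehot = (codes[:, None] == cats[None, :]).astype(float)
    props = {int(c): float(y[codes == c].mean()) for c in cats}
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(y, onehot, family=sm.families.Binomial()).fit(maxiter=100)
        probs = 1.0 / (1.0 + np.exp(-np.clip(fit.params, -50, 50)))
        if not np.isfinite(probs).all():
            raise ValueError("non-finite IRLS parameters")
        mapping = {int(c): float(p) for c, p in zip(cats, probs)}
        diag = EncoderDiagnostics(int(getattr(fit, "fit_history", {}).get("iteration", 0) or 0),
                                  bool(getattr(fit, "converged", True)))
        # guard: the saturated MLE must reproduce the empirical proportions
        if any(abs(mapping[c] - props[c]) > 1e-4 for c in mapping):
            raise ValueError("IRLS drifted from the saturated MLE")
    except Exception as exc:  # separation / non-convergence -> proportions
        logger.warning("IRLS fallback to empirical proportions (%s)", exc)
        mapping, diag = props, EncoderDiagnostics(0, False)
    return {c: float(np.clip(v, EPS, 1 - EPS)) for c, v in mapping.items()}, diag


def fit_categorical_encoder(table: FeatureTable, labels, fitting_indices=None) -> CategoricalEncoder:
    """Fit per-category interval values on the fitting subset only."""
    labels = check_labels(labels, table)
    if fitting_indices is None:
        fitting_indices = np.arange(table.n_samples)
    idx = np.asarray(fitting_indices, dtype=int)
    if len(idx) == 0:
        raise ValueError("fitting_indices must be non-empty")
    y = labels[idx].astype(float)
    mappings, diagnostics = {}, {}
    for j, kind in enumerate(table.feature_kinds):
        if kind != "categorical":
            continue
        codes = table.values[idx, j].astype(int)
        mappings[table.feature_names[j]], diagnostics[table.feature_names[j]] = \
            _irls_category_probs(codes, y)
    return CategoricalEncoder(
        mappings=mappings,
        fallback=float(np.clip(y.mean(), EPS, 1 - EPS)),
        feature_names=list(table.feature_names),
        diagnostics=diagnostics,
    )


def apply_encoder(encoder: CategoricalEncoder, table: FeatureTable) -> FeatureTable:
    """Replace categorical columns by their encoded interval values (retagged
    continuous); binary/continuous columns pass through unchanged."""
    for name in encoder.mappings:
        if name not in table.feature_names:
            raise ValueError(f"encoder knows feature {name!r} absent from the table")
    values = table.values.copy()
    kinds = list(table.feature_kinds)
    n_fallbacks = 0
    for name, mapping in encoder.mappings.items():
        j = table.column_index(name)
        codes = values[:, j].astype(int)
        encoded = np.full(len(codes), encoder.fallback)
        for code, val in mapping.items():
            encoded[codes == code] = val
        n_fallbacks += int(np.sum(~np.isin(codes, list(mapping))))
        values[:, j] = encoded
        kinds[j] = "continuous"
    if n_fallbacks:
        logger.info("applied fallback encoding to %d unseen category cells", n_fallbacks)
    encoder.n_fallbacks_applied = n_fallbacks
    return FeatureTable(list(table.sample_ids), list(table.feature_names), values, kinds)
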