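"""The mGMDH-AFS classifier core.

A Group Method of Data Handling (GMDH) network grows layer by layer; every
neuron models the pairwise interaction of two inputs (original features at
layer 1, previous-layer neuron outputs afterwards) through a matrix of
nonlinear, non-convex basis functions (quadratic, exponential, sinusoid and
logarithmic forms) squashed by a logistic so that every neuron output lies in
(0, 1).  Because the basis is non-convex, neuron coefficients are estimated by
particle swarm optimization instead of least squares, with the Matthews
correlation coefficient (robust to heavy class imbalance) as the fitness.

Training pipeline of :class:`GmdhAfs` (all fitting is confined to the data
the model was constructed with — give it the training partition only):

1. categorical features -> interval values (logistic encoding);
2. continuous features z-scored on the fitting set;
3. I-RELIEF feature weighting + automatic feature selection;
4. minority oversampling of the training rows to a 1:1 ratio;
5. stratified split of the oversampled set into estimation and validation
   subsets (fit vs. neuron ranking / early stopping);
6. layers of PSO-fitted pairwise neurons; the top ``top_k`` (default 10) per
   layer survive, ranked by validation MCC; growth stops as soon as a new
   layer fails to improve the best validation MCC;
7. the decision cutoff is the Youden-optimal point of the ROC of the
   training-set scores.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.special import expit

from . import relief as relief_mod
from .data import (FeatureTable, check_labels, estimation_validation_split,
                   oversample_minority)
from .encoding import CategoricalEncoder, apply_encoder, fit_categorical_encoder
from .metrics import metric_set, optimal_cutoff
from .pso import PsoConfig, pso_maximize

logger = logging.getLogger(__name__)

EXP_CLAMP = 20.0

#: the matrix of basis functions available to a neuron on inputs (u, v)
BASIS_FUNCTIONS = {
    "const": lambda u, v: np.ones_like(u),
    "u": lambda u, v: u,
    "v": lambda u, v: v,
    "uv": lambda u, v: u * v,
    "u2": lambda u, v: u * u,
    "v2": lambda u, v: v * v,
    "sin_u": lambda u, v: np.sin(u),
    "sin_v": lambda u, v: np.sin(v),
    "exp_u": lambda u, v: np.exp(np.clip(u, -EXP_CLAMP, EXP_CLAMP)),
    "exp_v": lambda u, v: np.exp(np.clip(v, -EXP_CLAMP, EXP_CLAMP)),
    "log_u": lambda u, v: np.log1p(np.abs(u)),
    "log_v": lambda u, v: np.log1p(np.abs(v)),
}

DEFAULT_BASIS = tuple(BASIS_FUNCTIONS)


def validate_basis(basis) -> tuple:
    basis = tuple(basis)
    if "const" not in basis:
        raise ValueError("the constant term must be part of the basis")
    if len(set(basis)) != len(basis):
        raise ValueError("basis tags must be unique")
    for tag in basis:
        if tag not in BASIS_FUNCTIONS:
            raise ValueError(f"unknown basis tag {tag!r}")
    return basis


def basis_matrix(u, v, basis) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    return np.column_stack([BASIS_FUNCTIONS[tag](u, v) for tag in basis])


@dataclass
class GmdhNeuron:
    inputs: tuple                 # two distinct input indices (feature or previous-layer neuron)
    basis: tuple
    coefficients: np.ndarray
    estimation_mcc: float = 0.0
    validation_mcc: float = 0.0
    degenerate: bool = False

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.inputs) != 2 or self.inputs[0] == self.inputs[1]:
            raise ValueError("a neuron needs two distinct inputs")
        if len(self.coefficients) != len(self.basis):
            raise ValueError("one coefficient per basis term")


def neuron_response(neuron: GmdhNeuron, u, v):
    """logistic(sum_k c_k * basis_k(u, v)); always finite, strictly inside
    (0, 1) (the linear part is clamped where float64 would round to 0 or 1)."""
    z = basis_matrix(u, v, neuron.basis) @ neuron.coefficients
    return expit(np.clip(z, -30.0, 30.0))


def _mcc_columns(pred: np.ndarray, y: np.ndarray) -> np.ndarray:
    """MCC of each column of a boolean prediction matrix against y."""
    n_pos = y.sum()
    n_neg = len(y) - n_pos
    tp = y @ pred
    fp = pred.sum(axis=0) - tp
    fn = n_pos - tp
    tn = n_neg - fp
    num = tp * tn - fp * fn
    den = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)


def fit_neuron_pso(input_pair, estimation_inputs: np.ndarray, estimation_labels,
                   basis=DEFAULT_BASIS, pso: PsoConfig | None = None,
                   rng: np.random.Generator | None = None) -> GmdhNeuron:
    """Fit one pairwise neuron by PSO maximizing estimation-set MCC at the
    fixed 0.5 response threshold (response >= 0.5  <=>  linear part >= 0)."""
    basis = validate_basis(basis)
    pso = pso or PsoConfig()
    i, j = input_pair
    y = check_labels(estimation_labels).astype(float)
    u = estimation_inputs[:, i]
    v = estimation_inputs[:, j]
    if np.ptp(u) == 0 and np.ptp(v) == 0:
        return GmdhNeuron((i, j), basis, np.zeros(len(basis)), 0.0, 0.0, degenerate=True)
    phi = basis_matrix(u, v, basis)

    def objective(coeffs: np.ndarray) -> np.ndarray:
        pred = (phi @ coeffs.T) >= 0.0
        return _mcc_columns(pred, y)

    warm = _linear_logistic_warm_start(phi, basis, y, pso.bounds)
    result = pso_maximize(objective, dim=len(basis), config=pso, rng=rng,
                          initial_positions=warm)
    # Calibrate the output scale.  The thresholded-MCC fitness is invariant to
    # any positive rescaling of the coefficient vector (the decision boundary
    # z = 0 is unchanged), so the scale is a free parameter; choosing it by
    # maximum likelihood of logistic(a*z) on the estimation labels makes the
    # neuron's graded output approximate P(y | u, v), which is what downstream
    # layers and the final ROC consume.
    coeffs = result.x
    norm = float(np.linalg.norm(coeffs))
    if norm > 0:
        coeffs = coeffs / norm
        z = phi @ coeffs
        coeffs = coeffs * _likelihood_scale(z, y)
    return GmdhNeuron((i, j), basis, coeffs, estimation_mcc=float(result.value))


def _linear_logistic_warm_start(phi: np.ndarray, basis, y: np.ndarray, bounds):
    """One swarm particle is seeded at the ridge-IRLS logistic solution over
    the linear basis terms (const, u, v): the swarm then starts from a neuron
    at least as good as a linear-logistic combiner of its two inputs, and PSO
    explores nonlinear refinements from there."""
    linear = [k for k, tag in enumerate(basis) if tag in ("const", "u", "v")]
    X = phi[:, linear]
    beta = np.zeros(len(linear))
    for _ in range(25):
        eta = np.clip(X @ beta, -30, 30)
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        XtW = X.T * w
        try:
            new = np.linalg.solve(XtW @ X + 1e-6 * np.eye(len(linear)), XtW @ z)
        except np.linalg.LinAlgError:
            return None
        if not np.isfinite(new).all():
            return None
        done = np.max(np.abs(new - beta)) < 1e-8
        beta = new
        if done:
            break
    full = np.zeros((1, len(basis)))
    full[0, linear] = beta
    return np.clip(full, bounds[0], bounds[1])


def _likelihood_scale(z: np.ndarray, y: np.ndarray, max_scale: float = 50.0) -> float:
    """argmax_a sum log p(y | logistic(a z)) for a > 0 (convex 1-D Newton)."""
    a = 1.0
    for _ in range(25):
        p = expit(np.clip(a * z, -50, 50))
        grad = float(z @ (y - p))
        hess = -float((z * z) @ (p * (1 - p)))
        if hess >= -1e-12:
            break
        step = grad / hess
        a_new = min(max(a - step, 1e-3), max_scale)
        if abs(a_new - a) < 1e-6:
            a = a_new
            break
        a = a_new
    return a


@dataclass(frozen=True)
class GmdhConfig:
    """Training configuration for the mGMDH-AFS pipeline."""

    top_k: int = 10                 # neurons kept per layer
    max_layers: int = 10            # hard cap; early stopping normally triggers sooner
    basis: tuple = DEFAULT_BASIS
    pso: PsoConfig = field(default_factory=PsoConfig)
    estimation_fraction: float = 0.6
    oversample: bool = True
    cutoff_method: str = "youden"
    cutoff_set: str = "validation"  # "validation" (honest scores) or "train" (all training rows)
    # feature selection
    relief_kernel_width: float = 1.0
    relief_max_iterations: int = 50
    relief_tolerance: float = 1e-4
    relief_max_samples: int = 600
    select_top_m: int | None = None     # overrides min_weight when given
    select_min_weight: float | None = None  # default 1/(2*n_features)
    # layer-1 pair pruning (quadratic blowup guard)
    max_enumeration_features: int = 25
    max_pairs: int = 300
    # deeper layers pair previous-layer neurons with each other and with the
    # best original features (so evidence missed by layer 1 can still enter)
    deep_feature_partners: int = 15

    def __post_init__(self):
        validate_basis(self.basis)
        if self.top_k < 1 or self.max_layers < 1:
            raise ValueError("top_k and max_layers must be >= 1")
        if not 0 < self.estimation_fraction < 1:
            raise ValueError("estimation_fraction must be in (0,1)")


def _child_rng(seed: int, *key):
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=tuple(key)))


def _child_seed(seed: int, *key) -> int:
    return int(_child_rng(seed, *key).integers(0, 2**31 - 1))


class GmdhAfs:
    """mGMDH-AFS model bound to a training feature table and labels.

    Construct with the training partition only; :meth:`fit` runs the full
    pipeline and returns a :class:`GmdhAfsResults`.
    """

    def __init__(self, table: FeatureTable, labels, config: GmdhConfig | None = None):
        self.table = table
        self.labels = check_labels(labels, table)
        if min(np.sum(self.labels == 0), np.sum(self.labels == 1)) < 2:
            raise ValueError("both classes need >= 2 training samples")
        self.config = config or GmdhConfig()

    @classmethod
    def from_dataframe(cls, df, labels, kind_map=None, config=None) -> "GmdhAfs":
        return cls(FeatureTable.from_dataframe(df, kind_map), labels, config)

    # -- pipeline pieces -------------------------------------------------

    def _encode_and_standardize(self):
        encoder = None
        table = self.table
        if any(k == "categorical" for k in table.feature_kinds):
            encoder = fit_categorical_encoder(table, self.labels)
            table = apply_encoder(encoder, table)
        means = np.zeros(table.n_features)
        sds = np.ones(table.n_features)
        for j, kind in enumerate(table.feature_kinds):
            if kind == "continuous":
                means[j] = table.values[:, j].mean()
                sd = table.values[:, j].std()
                sds[j] = sd if sd > 0 else 1.0
        X = (table.values - means) / sds
        return encoder, table, X, means, sds

    def _select_features(self, table, X, seed):
        cfg = self.config
        std_table = FeatureTable(list(table.sample_ids), list(table.feature_names),
                                 X, ["continuous"] * table.n_features)
        weights = relief_mod.irelief_weights(
            std_table, self.labels, kernel_width=cfg.relief_kernel_width,
            max_iterations=cfg.relief_max_iterations, tolerance=cfg.relief_tolerance,
            max_samples=cfg.relief_max_samples, seed=_child_seed(seed, 1))
        if cfg.select_top_m is not None:
            selected = relief_mod.select_features(weights, top_m=cfg.select_top_m)
        else:
            thr = cfg.select_min_weight
            if thr is None:
                thr = relief_mod.default_min_weight(table.n_features)
            selected = relief_mod.select_features(weights, min_weight=thr)
        usable = [j for j in selected if np.ptp(X[:, j]) > 0]
        if len(usable) < 2:
            extra = [j for j in np.argsort(-weights.weights)
                     if j not in usable and np.ptp(X[:, j]) > 0]
            usable = sorted(usable + [int(j) for j in extra[: 2 - len(usable)]])
        if len(usable) < 2:
            raise ValueError("fewer than 2 usable (non-constant) features")
        return weights, sorted(usable)

    def _layer1_pairs(self, selected, weights):
        cfg = self.config
        pairs = list(combinations(range(len(selected)), 2))
        if len(selected) > cfg.max_enumeration_features or len(pairs) > cfg.max_pairs:
            w = weights.weights[selected]
            pairs.sort(key=lambda p: (-(w[p[0]] + w[p[1]]), p))
            pairs = pairs[: cfg.max_pairs]
        return pairs

    def _deep_pairs(self, n_neurons, n_features, feature_rank):
        """Layer >= 2 candidates: all neuron-neuron pairs, then each neuron
        paired with the strongest original features (input indices
        0..n_neurons-1 are previous-layer neurons, the rest are features)."""
        cfg = self.config
        pairs = list(combinations(range(n_neurons), 2))
        partners = feature_rank[: cfg.deep_feature_partners]
        for f in partners:
            for i in range(n_neurons):
                pairs.append((i, n_neurons + int(f)))
        return pairs[: cfg.max_pairs]

    def _fit_layer(self, pairs, X_est, y_est, X_val, y_val, seed, layer_no):
        cfg = self.config
        neurons = []
        for i, j in pairs:
            rng = _child_rng(seed, 2, layer_no, i, j)
            neuron = fit_neuron_pso((i, j), X_est, y_est, basis=cfg.basis,
                                    pso=cfg.pso, rng=rng)
            val_scores = neuron_response(neuron, X_val[:, i], X_val[:, j])
            neuron.validation_mcc = float(
                metric_set(y_val, (val_scores >= 0.5).astype(int)).mcc)
            neurons.append(neuron)
        # rank by the mean of estimation and validation MCC (robust to the
        # small number of distinct minority prototypes on either side),
        # ties -> higher estimation MCC, then lower input indices
        neurons.sort(key=lambda nr: (-(nr.estimation_mcc + nr.validation_mcc) / 2,
                                     -nr.estimation_mcc, nr.inputs))
        return neurons[: cfg.top_k]

    # -- public API ------------------------------------------------------

    def fit(self, seed: int = 0) -> "GmdhAfsResults":
        cfg = self.config
        encoder, enc_table, X, means, sds = self._encode_and_standardize()
        weights, selected = self._select_features(enc_table, X, seed)
        Xsel = X[:, selected]
        y = self.labels

        sel_table = FeatureTable(list(enc_table.sample_ids),
                                 [enc_table.feature_names[j] for j in selected],
                                 Xsel, ["continuous"] * len(selected))
        if cfg.oversample:
            over_table, y_over, origins = oversample_minority(
                sel_table, y, _child_seed(seed, 3), return_origins=True)
        else:
            over_table, y_over = sel_table, y
            origins = np.arange(sel_table.n_samples)
        split = estimation_validation_split(y_over, cfg.estimation_fraction,
                                            _child_seed(seed, 4), groups=origins)
        X_est, y_est = over_table.values[split["estimation"]], y_over[split["estimation"]]
        X_val, y_val = over_table.values[split["validation"]], y_over[split["validation"]]

        # deeper layers may pair previous-layer neurons with the strongest
        # original features, so evidence missed by layer 1 can still enter
        feature_rank = np.argsort(-weights.weights[selected], kind="stable")
        layers = []
        best_val = -np.inf
        inputs_est, inputs_val = X_est, X_val
        for layer_no in range(1, cfg.max_layers + 1):
            if layer_no == 1:
                pairs = self._layer1_pairs(selected, weights)
            else:
                pairs = self._deep_pairs(len(layers[-1]), Xsel.shape[1], feature_rank)
            layer = self._fit_layer(pairs, inputs_est, y_est, inputs_val, y_val,
                                    seed, layer_no)
            layer_best = max(nr.validation_mcc for nr in layer)
            if layers and layer_best <= best_val:   # early stopping
                logger.info("early stopping before layer %d (val MCC %.4f <= %.4f)",
                            layer_no, layer_best, best_val)
                break
            layers.append(layer)
            best_val = layer_best
            out_est = np.column_stack(
                [neuron_response(nr, inputs_est[:, nr.inputs[0]], inputs_est[:, nr.inputs[1]])
                 for nr in layer])
            out_val = np.column_stack(
                [neuron_response(nr, inputs_val[:, nr.inputs[0]], inputs_val[:, nr.inputs[1]])
                 for nr in layer])
            # the network output is the top-ranked neuron of the last
            # accepted layer (same mean-MCC ranking as neuron survival)
            out_idx = 0
            val_scores = out_val[:, out_idx]
            inputs_est = np.column_stack([out_est, X_est])
            inputs_val = np.column_stack([out_val, X_val])

        results = GmdhAfsResults(
            model=self, encoder=encoder, relief_weights=weights,
            selected_indices=selected,
            selected_names=[enc_table.feature_names[j] for j in selected],
            feature_names=list(enc_table.feature_names),
            means=means, sds=sds, layers=layers,
            output_neuron=out_idx, cutoff=0.5, config=cfg, seed=seed,
            validation_mcc_path=[max(nr.validation_mcc for nr in l) for l in layers],
        )
        # Decision cutoff from the training-set ROC.  The validation subset
        # (part of the training set, but not used to fit neuron parameters)
        # gives the least biased score distribution: estimation-row scores are
        # optimistically inflated for the fitted minority prototypes, which
        # would push the Youden point too high.
        if cfg.cutoff_set == "validation":
            results.cutoff = optimal_cutoff(val_scores, y_val, method=cfg.cutoff_method)
        else:
            train_scores = results.predict_scores(self.table)
            results.cutoff = optimal_cutoff(train_scores, y, method=cfg.cutoff_method)
        return results


@dataclass
class GmdhAfsResults:
    """Fitted mGMDH-AFS network: layers of neurons, feature pipeline state and
    the ROC-derived decision cutoff."""

    model: GmdhAfs | None
    encoder: CategoricalEncoder | None
    relief_weights: relief_mod.ReliefWeights | None
    selected_indices: list
    selected_names: list
    feature_names: list
    means: np.ndarray
    sds: np.ndarray
    layers: list
    output_neuron: int
    cutoff: float
    config: GmdhConfig
    seed: int
    validation_mcc_path: list = field(default_factory=list)

    # -- prediction ------------------------------------------------------

    def _prepare(self, table: FeatureTable) -> np.ndarray:
        if self.encoder is not None:
            table = apply_encoder(self.encoder, table)
        cols = []
        for name in self.feature_names:
            if name not in table.feature_names:
                raise ValueError(f"missing feature column {name!r}")
            cols.append(table.column_index(name))
        X = (table.values[:, cols] - self.means) / self.sds
        return X[:, self.selected_indices]

    def predict_scores(self, table: FeatureTable) -> np.ndarray:
        """Feed-forward network output in [0,1] for every row of the table."""
        features = self._prepare(table)
        inputs = features
        outputs = None
        for layer in self.layers:
            outputs = np.column_stack(
                [neuron_response(nr, inputs[:, nr.inputs[0]], inputs[:, nr.inputs[1]])
                 for nr in layer])
            inputs = np.column_stack([outputs, features])
        return outputs[:, self.output_neuron]

    def predict(self, table: FeatureTable) -> np.ndarray:
        return (self.predict_scores(table) >= self.cutoff).astype(int)

    # -- reporting -------------------------------------------------------

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def summary(self) -> str:
        lines = ["mGMDH-AFS fitted network", "=" * 24]
        lines.append(f"selected features ({len(self.selected_names)}): "
                     + ", ".join(self.selected_names))
        for ln, layer in enumerate(self.layers, start=1):
            best = max(nr.validation_mcc for nr in layer)
            lines.append(f"layer {ln}: {len(layer)} neurons, best validation MCC {best:.4f}")
        lines.append(f"decision cutoff: {self.cutoff:.4f} ({self.config.cutoff_method})")
        lines.append(f"seed: {self.seed}")
        return "\n".join(lines)

    # -- serialization ---------------------------------------------------

    def to_json(self) -> str:
        cfg = self.config
        payload = {
            "feature_names": self.feature_names,
            "selected_indices": [int(i) for i in self.selected_indices],
            "selected_names": self.selected_names,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "cutoff": self.cutoff,
            "output_neuron": self.output_neuron,
            "seed": self.seed,
            "validation_mcc_path": self.validation_mcc_path,
            "encoder": self.encoder.to_json_dict() if self.encoder else None,
            "config": {
                "top_k": cfg.top_k, "max_layers": cfg.max_layers,
                "basis": list(cfg.basis),
                "pso": {"swarm_size": cfg.pso.swarm_size, "iterations": cfg.pso.iterations,
                        "inertia": cfg.pso.inertia, "cognitive": cfg.pso.cognitive,
                        "social": cfg.pso.social, "bounds": list(cfg.pso.bounds),
                        "seed": cfg.pso.seed},
                "estimation_fraction": cfg.estimation_fraction,
                "oversample": cfg.oversample, "cutoff_method": cfg.cutoff_method,
            },
            "layers": [
                [{"inputs": list(nr.inputs), "basis": list(nr.basis),
                  "coefficients": nr.coefficients.tolist(),
                  "estimation_mcc": nr.estimation_mcc,
                  "validation_mcc": nr.validation_mcc,
                  "degenerate": nr.degenerate}
                 for nr in layer]
                for layer in self.layers
            ],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GmdhAfsResults":
        obj = json.loads(text)
        c = obj["config"]
        config = GmdhConfig(
            top_k=c["top_k"], max_layers=c["max_layers"], basis=tuple(c["basis"]),
            pso=PsoConfig(swarm_size=c["pso"]["swarm_size"], iterations=c["pso"]["iterations"],
                          inertia=c["pso"]["inertia"], cognitive=c["pso"]["cognitive"],
                          social=c["pso"]["social"], bounds=tuple(c["pso"]["bounds"]),
                          seed=c["pso"]["seed"]),
            estimation_fraction=c["estimation_fraction"], oversample=c["oversample"],
            cutoff_method=c["cutoff_method"])
        layers = [
            [GmdhNeuron(tuple(n["inputs"]), tuple(n["basis"]),
                        np.asarray(n["coefficients"], dtype=float),
                        n["estimation_mcc"], n["validation_mcc"], n["degenerate"])
             for n in layer]
            for layer in obj["layers"]
        ]
        encoder = CategoricalEncoder.from_json_dict(obj["encoder"]) if obj["encoder"] else None
        return cls(
            model=None, encoder=encoder, relief_weights=None,
            selected_indices=obj["selected_indices"], selected_names=obj["selected_names"],
            feature_names=obj["feature_names"],
            means=np.asarray(obj["means"], dtype=float),
            sds=np.asarray(obj["sds"], dtype=float),
            layers=layers, output_neuron=obj["output_neuron"], cutoff=obj["cutoff"],
            config=config, seed=obj["seed"],
            validation_mcc_path=obj.get("validation_mcc_path", []),
        )


def train_gmdh(table: FeatureTable, labels, config: GmdhConfig | None = None,
               seed: int = 0) -> GmdhAfsResults:
    """Functional wrapper: build and fit an mGMDH-AFS model."""
    return GmdhAfs(table, labels, config).fit(seed=seed)


def predict_scores(results: GmdhAfsResults, table: FeatureTable) -> np.ndarray:
    return results.predict_scores(table)
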