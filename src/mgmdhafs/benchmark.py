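"""Workflow orchestration: candidate ranking and the five-classifier
benchmark report (hold-out metrics, Cochran Q + McNemar/Bonferroni table,
label-permutation report, optional feature-block ablation).

Every number in a report is traceable to (method, partition, seed); reports
are plain JSON-serializable dictionaries, byte-identical across runs with the
same global seed.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .baselines import (LogisticRegressionClassifier, PoissonGlmClassifier,
                        RbfSvmClassifier, RbfnClassifier)
from .data import FeatureTable, check_labels, stratified_holdout_split
from .gmdh import GmdhAfs, GmdhConfig, GmdhAfsResults
from .metrics import metric_set, roc_auc
from .synthetic import feature_blocks, generate_dt_benchmark
from .validation import compare_classifiers, make_trainer, permutation_test

logger = logging.getLogger(__name__)

METHOD_NAMES = ("mgmdh", "lr", "glm", "svm", "rbfn")


def derive_seed(global_seed: int, name: str) -> int:
    """Component seed = f(global seed, component name); stable across runs."""
    ss = np.random.SeedSequence([int(global_seed), zlib.crc32(name.encode())])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def default_trainers(gmdh_config: GmdhConfig | None = None) -> dict:
    """The five classifiers of the comparison under the shared trainer
    interface (each: (table, labels, seed) -> fitted results)."""
    return {
        "mgmdh": make_trainer(GmdhAfs, config=gmdh_config or GmdhConfig()),
        "lr": make_trainer(LogisticRegressionClassifier),
        "glm": make_trainer(PoissonGlmClassifier),
        "svm": make_trainer(RbfSvmClassifier),
        "rbfn": make_trainer(RbfnClassifier),
    }


def rank_candidates(results: GmdhAfsResults, table: FeatureTable,
                    known_positive_ids=None) -> dict:
    """Descending-score candidate ranking (stable tie order by sample id),
    with a ROC/AUC readout against a known-positive id set when given."""
    if table.n_samples == 0:
        raise ValueError("empty table")
    scores = results.predict_scores(table)
    order = sorted(range(table.n_samples),
                   key=lambda i: (-scores[i], str(table.sample_ids[i])))
    ranking = pd.DataFrame({
        "id": [table.sample_ids[i] for i in order],
        "score": [float(scores[i]) for i in order],
    })
    out = {"ranking": ranking}
    if known_positive_ids:
        known = set(known_positive_ids)
        labels = np.array([1 if s in known else 0 for s in table.sample_ids])
        if 0 < labels.sum() < len(labels):
            _, auc = roc_auc(scores, labels)
            out["auc_vs_known"] = float(auc)
    return out


@dataclass
class BenchmarkConfig:
    """Configuration for the five-method comparison run."""

    seed: int = 0
    train_fraction: float = 0.7
    n_permutations: int = 10
    gmdh: GmdhConfig = field(default_factory=GmdhConfig)
    methods: tuple = METHOD_NAMES
    include_permutation: bool = True
    ablation: bool = True          # feature-block reruns when topo_* columns exist
    use_sfs: bool = False          # sequential forward selection for svm/rbfn


def _evaluate_method(name, trainer, table, labels, tr, te, seed):
    fitted = trainer(table.subset_rows(tr), labels[tr], seed)
    test_table = table.subset_rows(te)
    preds = np.asarray(fitted.predict(test_table)).astype(int)
    scores = np.asarray(fitted.predict_scores(test_table), dtype=float)
    metrics = metric_set(labels[te], preds, scores=scores)
    return fitted, preds, metrics


def run_full_benchmark(config: BenchmarkConfig | None = None,
                       table: FeatureTable | None = None,
                       labels=None) -> dict:
    """Train all requested methods on one stratified 70/30 split of the
    drug-target benchmark (or user data) and report per-method indices plus
    the Cochran-Q / McNemar comparison against mGMDH-AFS."""
    cfg = config or BenchmarkConfig()
    if table is None:
        table, labels = generate_dt_benchmark(seed=derive_seed(cfg.seed, "data"))
    labels = check_labels(labels, table)
    split = stratified_holdout_split(labels, cfg.train_fraction,
                                     derive_seed(cfg.seed, "split"))
    tr, te = split["train"], split["test"]
    trainers = {k: v for k, v in default_trainers(cfg.gmdh).items()
                if k in cfg.methods}

    report = {
        "seed": cfg.seed,
        "train_fraction": cfg.train_fraction,
        "n_samples": table.n_samples,
        "n_features": table.n_features,
        "methods": {},
        "partition_sizes": {"train": int(len(tr)), "test": int(len(te))},
    }
    predictions = {}
    for name, trainer in trainers.items():
        seed = derive_seed(cfg.seed, f"train:{name}")
        logger.info("training %s (seed %d)", name, seed)
        _, preds, metrics = _evaluate_method(name, trainer, table, labels, tr, te, seed)
        predictions[name] = preds
        report["methods"][name] = {"metrics": metrics.as_dict(), "seed": seed}

    if len(predictions) >= 2 and "mgmdh" in predictions:
        comparison = compare_classifiers(labels[te], predictions, reference="mgmdh")
        report["comparison"] = {
            "cochran_q": {
                "statistic": comparison["cochran_q"].statistic,
                "df": comparison["cochran_q"].df,
                "p_value": comparison["cochran_q"].p_value,
                "undefined": comparison["cochran_q"].undefined,
            },
            "mcnemar": {
                name: {"statistic": None if np.isnan(res.statistic) else res.statistic,
                       "p_value": res.p_value, "b": res.b, "c": res.c,
                       "exact": res.exact,
                       "adjusted_p": comparison["adjusted_p"][name],
                       "favors_reference": res.b > res.c}
                for name, res in comparison["mcnemar"].items()
            },
        }

    if cfg.include_permutation and "mgmdh" in trainers:
        perm = permutation_test(trainers["mgmdh"], table, labels,
                                n_permutations=cfg.n_permutations,
                                seed=derive_seed(cfg.seed, "permutation"),
                                train_fraction=cfg.train_fraction)
        report["permutation"] = {
            "n_permutations": perm.n_permutations,
            "real": perm.real.as_dict(),
            "permuted": [m.as_dict() for m in perm.permuted],
            "p_values": perm.p_values,
        }

    blocks = feature_blocks(table)
    if cfg.ablation and blocks["topology"] and blocks["biochemical"] and "mgmdh" in trainers:
        report["ablation"] = {}
        for block_name in ("biochemical", "topology"):
            cols = [table.column_index(n) for n in blocks[block_name]]
            sub = table.select_columns(cols)
            seed = derive_seed(cfg.seed, f"ablation:{block_name}")
            _, _, metrics = _evaluate_method(
                f"mgmdh[{block_name}]", trainers["mgmdh"], sub, labels, tr, te, seed)
            report["ablation"][block_name] = {"metrics": metrics.as_dict(), "seed": seed}

    return report


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=1, sort_keys=True)


def report_summary(report: dict) -> str:
    """Human-readable Markdown digest of a benchmark report."""
    lines = ["# Benchmark report", "",
             f"seed {report['seed']}, {report['n_samples']} samples x "
             f"{report['n_features']} features, "
             f"train/test {report['partition_sizes']['train']}/{report['partition_sizes']['test']}",
             "", "| method | sens | spec | prec | acc | MCC | AUC |",
             "|---|---|---|---|---|---|---|"]
    for name, entry in report["methods"].items():
        m = entry["metrics"]
        auc = f"{m['auc']:.3f}" if m.get("auc") is not None else "-"
        lines.append(f"| {name} | {m['sensitivity']:.3f} | {m['specificity']:.3f} | "
                     f"{m['precision']:.3f} | {m['accuracy']:.3f} | {m['mcc']:.3f} | {auc} |")
    if "comparison" in report:
        q = report["comparison"]["cochran_q"]
        lines += ["", f"Cochran's Q = {q['statistic']:.3f} (df {q['df']}), p = {q['p_value']:.3g}",
                  "", "| vs | b | c | raw p | adjusted p |", "|---|---|---|---|---|"]
        for name, res in report["comparison"]["mcnemar"].items():
            lines.append(f"| mgmdh vs {name} | {res['b']} | {res['c']} | "
                         f"{res['p_value']:.3g} | {res['adjusted_p']:.3g} |")
    if "permutation" in report:
        p = report["permutation"]
        lines += ["", f"Permutation test ({p['n_permutations']} label shuffles): "
                  f"real MCC {p['real']['mcc']:.3f}, empirical p(MCC) = {p['p_values']['mcc']:.3g}"]
    if "ablation" in report:
        lines += ["", "Feature-block ablation (mGMDH-AFS):"]
        for block, entry in report["ablation"].items():
            m = entry["metrics"]
            lines.append(f"- {block} only: MCC {m['mcc']:.3f}, "
                         f"sens {m['sensitivity']:.3f}, spec {m['specificity']:.3f}")
    return "\n".join(lines)
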