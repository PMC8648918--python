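"""Feature-table data model, file I/O, class-preserving splits and minority oversampling.

The learning substrate is a dense protein x feature matrix.  Every feature
carries a kind tag (``binary`` / ``categorical`` / ``continuous``) because the
downstream pipeline treats the kinds differently: categorical columns are
re-encoded to interval values, continuous columns are z-scored before distance
computations, binary columns enter as 0/1.

The positive class is fixed as 1 = drug target (DT); every metric definition
in :mod:`mgmdhafs.metrics` depends on that convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

KINDS = ("binary", "categorical", "continuous")


class DataError(ValueError):
    """Raised on malformed tables, labels or split requests."""


@dataclass
class FeatureTable:
    """Dense numeric sample x feature matrix with per-feature kind metadata."""

    sample_ids: list
    feature_names: list
    values: np.ndarray
    feature_kinds: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("values must be a 2-D matrix")
        n, f = self.values.shape
        if len(self.sample_ids) != n:
            raise DataError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.feature_names) != f or len(self.feature_kinds) != f:
            raise DataError("feature_names/feature_kinds length must match columns")
        if len(set(self.sample_ids)) != n:
            seen, dup = set(), None
            for s in self.sample_ids:
                if s in seen:
                    dup = s
                    break
                seen.add(s)
            raise DataError(f"duplicate sample id {dup!r}")
        if len(set(self.feature_names)) != f:
            raise DataError("duplicate feature names")
        for k in self.feature_kinds:
            if k not in KINDS:
                raise DataError(f"unknown feature kind {k!r}")
        if not np.isfinite(self.values).all():
            raise DataError("feature table contains missing/non-finite values")
        for j, kind in enumerate(self.feature_kinds):
            col = self.values[:, j]
            if kind == "binary" and not np.isin(col, (0.0, 1.0)).all():
                raise DataError(f"binary feature {self.feature_names[j]!r} has values outside {{0,1}}")
            if kind == "categorical":
                if not np.array_equal(col, np.round(col)) or (col < 0).any():
                    raise DataError(
                        f"categorical feature {self.feature_names[j]!r} must hold integer codes >= 0"
                    )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def column_index(self, name: str) -> int:
        try:
            return self.feature_names.index(name)
        except ValueError:
            raise DataError(f"unknown feature {name!r}") from None

    def subset_rows(self, indices) -> "FeatureTable":
        idx = np.asarray(indices, dtype=int)
        return FeatureTable(
            [self.sample_ids[i] for i in idx],
            list(self.feature_names),
            self.values[idx],
            list(self.feature_kinds),
        )

    def select_columns(self, indices) -> "FeatureTable":
        idx = list(indices)
        return FeatureTable(
            list(self.sample_ids),
            [self.feature_names[j] for j in idx],
            self.values[:, idx],
            [self.feature_kinds[j] for j in idx],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_names)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, kind_map: dict | None = None) -> "FeatureTable":
        values = df.to_numpy(dtype=float)
        kinds = [
            _infer_kind(values[:, j], df.columns[j], kind_map) for j in range(values.shape[1])
        ]
        return cls(list(df.index), [str(c) for c in df.columns], values, kinds)


def _infer_kind(col: np.ndarray, name, kind_map: dict | None) -> str:
    if kind_map and name in kind_map:
        kind = kind_map[name]
        if kind not in KINDS:
            raise DataError(f"unknown kind {kind!r} for feature {name!r}")
        return kind
    if np.isin(col, (0.0, 1.0)).all():
        return "binary"
    return "continuous"


def load_feature_table(path, kind_map: dict | None = None) -> FeatureTable:
    """Load a CSV/TSV feature table (header row, first column = sample id).

    Kinds are inferred ({0,1} alphabet -> binary, else continuous); categorical
    columns must be declared through *kind_map*, which always wins.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt", ".sif")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise DataError(f"duplicate sample id {dup!r} in {path}")
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        if converted.isna().any() and not df[col].isna().any():
            row = df.index[converted.isna()][0]
            raise DataError(f"non-numeric value at row {row!r}, column {col!r}")
        df[col] = converted
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        raise DataError(f"missing values in column {col!r}; impute or clean the table first")
    return FeatureTable.from_dataframe(df, kind_map)


def load_labels(path, table: FeatureTable | None = None, column: str | None = None) -> np.ndarray:
    """Read a binary label vector from a two-column (id,label) CSV/TSV.

    When *table* is given, labels are reordered to the table's sample order and
    every sample must be present.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    series = df[column] if column else df.iloc[:, 0]
    if table is not None:
        missing = [s for s in table.sample_ids if s not in series.index]
        if missing:
            raise DataError(f"labels missing for sample {missing[0]!r}")
        series = series.loc[table.sample_ids]
    labels = series.to_numpy()
    return check_labels(labels)


def check_labels(labels, table: FeatureTable | None = None) -> np.ndarray:
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise DataError("labels must be binary 0/1 (1 = drug target)")
    labels = labels.astype(int)
    if table is not None and len(labels) != table.n_samples:
        raise DataError("label vector length does not match the feature table")
    return labels


@dataclass
class SplitIndices:
    """Named, disjoint, exhaustive index partitions of a sample range."""

    partitions: dict
    seed: int
    n_total: int = field(default=0)

    def __post_init__(self):
        self.partitions = {k: np.asarray(v, dtype=int) for k, v in self.partitions.items()}
        covered = np.concatenate(list(self.partitions.values())) if self.partitions else np.array([], int)
        if self.n_total == 0:
            self.n_total = len(covered)
        if len(covered) != self.n_total or len(np.unique(covered)) != self.n_total:
            raise DataError("partitions must be disjoint and exhaustive")
        for name, idx in self.partitions.items():
            if len(idx) == 0:
                raise DataError(f"empty partition {name!r}")

    def __getitem__(self, name):
        return self.partitions[name]

    def to_json(self, sample_ids=None) -> str:
        if sample_ids is None:
            payload = {k: v.tolist() for k, v in self.partitions.items()}
        else:
            payload = {k: [sample_ids[i] for i in v] for k, v in self.partitions.items()}
        return json.dumps({"seed": self.seed, "partitions": payload}, indent=1)

    @classmethod
    def from_json(cls, text: str, sample_ids=None) -> "SplitIndices":
        obj = json.loads(text)
        parts = obj["partitions"]
        if sample_ids is not None:
            lookup = {s: i for i, s in enumerate(sample_ids)}
            parts = {k: [lookup[s] for s in v] for k, v in parts.items()}
        return cls({k: np.asarray(v, int) for k, v in parts.items()}, int(obj["seed"]))


def _class_indices(labels):
    labels = check_labels(labels)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise DataError("both classes must be present")
    return labels, pos, neg


def stratified_holdout_split(labels, train_fraction: float, seed: int,
                             stratified: bool = True) -> SplitIndices:
    """Random 70/30-style split; per class, floor(train_fraction * n_c) rows go
    to training, then leftovers are topped up on the training side to preserve
    the overall train size."""
    if not 0 < train_fraction < 1:
        raise DataError("train_fraction must be in (0,1)")
    labels, pos, neg = _class_indices(labels)
    rng = np.random.default_rng(seed)
    n = len(labels)
    if not stratified:
        perm = rng.permutation(n)
        n_train = int(round(train_fraction * n))
        n_train = min(max(n_train, 1), n - 1)
        return SplitIndices({"train": np.sort(perm[:n_train]), "test": np.sort(perm[n_train:])}, seed)
    for grp in (pos, neg):
        if len(grp) < 2:
            raise DataError("cannot stratify a class with fewer than 2 members")
    target_total = int(round(train_fraction * n))
    counts, remainders = {}, {}
    for name, grp in (("pos", pos), ("neg", neg)):
        exact = train_fraction * len(grp)
        counts[name] = int(np.floor(exact))
        remainders[name] = exact - counts[name]
    # top-up largest fractional remainders first (ties: positive class first)
    order = sorted(("pos", "neg"), key=lambda k: (-remainders[k], k != "pos"))
    i = 0
    while sum(counts.values()) < target_total:
        counts[order[i % 2]] += 1
        i += 1
    train_parts, test_parts = [], []
    for name, grp in (("pos", pos), ("neg", neg)):
        k = min(max(counts[name], 1), len(grp) - 1)  # >=1 sample of each class on each side
        perm = rng.permutation(len(grp))
        train_parts.append(grp[perm[:k]])
        test_parts.append(grp[perm[k:]])
    return SplitIndices(
        {"train": np.sort(np.concatenate(train_parts)), "test": np.sort(np.concatenate(test_parts))},
        seed,
    )


def kfold_indices(labels, k: int, seed: int) -> SplitIndices:
    """k stratified folds (sizes differ by at most one per class), seeded."""
    if k < 2:
        raise DataError("k must be >= 2")
    labels, pos, neg = _class_indices(labels)
    if min(len(pos), len(neg)) < k:
        raise DataError(f"every class needs >= k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**31))
    parts = {}
    for i, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels), start=1):
        parts[f"fold_{i}"] = np.sort(test_idx)
    return SplitIndices(parts, seed)


def estimation_validation_split(labels, estimation_fraction: float, seed: int,
                                groups=None) -> SplitIndices:
    """Stratified split of a (typically oversampled) training set into the
    estimation set (neuron parameter fitting) and validation set (neuron
    ranking / early stopping).

    When *groups* is given (e.g. the origin row of each oversampled copy),
    all members of a group land on the same side, so duplicated minority rows
    cannot leak between estimation and validation — otherwise the validation
    set could not serve its stated anti-overfitting purpose.
    """
    if groups is None:
        split = stratified_holdout_split(labels, estimation_fraction, seed)
        return SplitIndices(
            {"estimation": split["train"], "validation": split["test"]}, seed
        )
    labels, pos, neg = _class_indices(labels)
    groups = np.asarray(groups)
    rng = np.random.default_rng(seed)
    est_parts, val_parts = [], []
    for cls_idx in (pos, neg):
        cls_groups = {}
        for i in cls_idx:
            cls_groups.setdefault(groups[i], []).append(i)
        keys = sorted(cls_groups)
        order = rng.permutation(len(keys))
        target = estimation_fraction * len(cls_idx)
        est, val, n_est = [], [], 0
        for k in order:
            members = cls_groups[keys[k]]
            if n_est < target:
                est.extend(members)
                n_est += len(members)
            else:
                val.extend(members)
        if not val:  # keep both sides populated per class
            val.append(est.pop())
        est_parts.append(est)
        val_parts.append(val)
    return SplitIndices(
        {"estimation": np.sort(np.concatenate(est_parts).astype(int)),
         "validation": np.sort(np.concatenate(val_parts).astype(int))}, seed
    )


def oversample_minority(table: FeatureTable, labels, seed: int,
                        return_origins: bool = False):
    """Random oversampling with replacement of the minority class to a 1:1 ratio.

    All original rows are kept and the majority class is untouched; duplicated
    rows are exact copies of existing minority rows, so binary/categorical
    feature validity is preserved.  Duplicated sample ids get a ``#dupN``
    suffix to keep ids unique.
    """
    labels, pos, neg = _class_indices(labels)
    minority, majority = (pos, neg) if len(pos) <= len(neg) else (neg, pos)
    deficit = len(majority) - len(minority)
    if deficit == 0:
        if return_origins:
            return table, labels, np.arange(table.n_samples)
        return table, labels
    rng = np.random.default_rng(seed)
    extra = rng.choice(minority, size=deficit, replace=True)
    new_ids = list(table.sample_ids) + [
        f"{table.sample_ids[i]}#dup{n}" for n, i in enumerate(extra)
    ]
    new_values = np.vstack([table.values, table.values[extra]])
    new_labels = np.concatenate([labels, labels[extra]])
    new_table = FeatureTable(new_ids, list(table.feature_names), new_values, list(table.feature_kinds))
    if return_origins:
        origins = np.concatenate([np.arange(table.n_samples), extra])
        return new_table, new_labels, origins
    return new_table, new_labels
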