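"""Feature-table I/O, stratified splitting and minority oversampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mgmdhafs.data import (DataError, FeatureTable, SplitIndices,
                           estimation_validation_split, kfold_indices,
                           load_feature_table, load_labels, oversample_minority,
                           stratified_holdout_split)
from conftest import make_labels


class TestLoadFeatureTable:
    def test_binary_alphabet_forces_kind(self, tmp_path):
        p = tmp_path / "x.csv"
        p.write_text("id,f1,f2\ns1,0,1\ns2,1,0\ns3,0,0\n")
        table = load_feature_table(p)
        assert table.values.shape == (3, 2)
        assert table.feature_kinds == ["binary", "binary"]

    def test_kind_map_override_wins(self, tmp_path):
        p = tmp_path / "x.csv"
        p.write_text("id,f1,f2\ns1,0,1\ns2,1,0\ns3,0,0\n")
        table = load_feature_table(p, kind_map={"f2": "categorical"})
        assert table.feature_kinds == ["binary", "categorical"]

    def test_duplicate_id_reported(self, tmp_path):
        p = tmp_path / "x.csv"
        p.write_text("id,f1\nP001,0\nP001,1\n")
        with pytest.raises(DataError, match="P001"):
            load_feature_table(p)

    def test_non_numeric_cell_names_row_and_column(self, tmp_path):
        p = tmp_path / "x.csv"
        p.write_text("id,f1,f2\ns1,0,1\ns2,oops,0\n")
        with pytest.raises(DataError, match="s2.*f1"):
            load_feature_table(p)

    def test_tsv_and_label_file(self, tmp_path):
        p = tmp_path / "x.tsv"
        p.write_text("id\tf1\ns1\t0.5\ns2\t1.5\n")
        table = load_feature_table(p)
        assert table.feature_kinds == ["continuous"]
        lp = tmp_path / "y.csv"
        lp.write_text("id,label\ns2,1\ns1,0\n")
        y = load_labels(lp, table)          # reordered to table order
        assert y.tolist() == [0, 1]


class TestFeatureTableInvariants:
    def test_binary_value_outside_01_rejected(self):
        with pytest.raises(DataError):
            FeatureTable(["a"], ["f"], np.array([[2.0]]), ["binary"])

    def test_categorical_codes_must_be_nonnegative_integers(self):
        with pytest.raises(DataError):
            FeatureTable(["a"], ["f"], np.array([[1.5]]), ["categorical"])

    def test_missing_values_rejected(self):
        with pytest.raises(DataError):
            FeatureTable(["a"], ["f"], np.array([[np.nan]]), ["continuous"])


class TestHoldoutSplit:
    def test_paper_style_70_30_counts(self):
        y = make_labels(10, 90)
        split = stratified_holdout_split(y, 0.7, seed=0)
        assert np.sum(y[split["train"]]) == 7 and len(split["train"]) == 70
        assert np.sum(y[split["test"]]) == 3 and len(split["test"]) == 30

    def test_minimal_balanced_split(self):
        y = make_labels(2, 2)
        split = stratified_holdout_split(y, 0.5, seed=3)
        assert np.sum(y[split["train"]]) == 1 and np.sum(y[split["test"]]) == 1

    def test_seed_determinism(self):
        y = make_labels(15, 85)
        a = stratified_holdout_split(y, 0.7, seed=7)
        b = stratified_holdout_split(y, 0.7, seed=7)
        c = stratified_holdout_split(y, 0.7, seed=8)
        assert np.array_equal(a["train"], b["train"])
        assert not np.array_equal(a["train"], c["train"])

    def test_singleton_class_rejected(self):
        with pytest.raises(DataError):
            stratified_holdout_split(make_labels(1, 9), 0.7, seed=0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(n_pos=st.integers(2, 40), n_neg=st.integers(2, 80),
           frac=st.floats(0.2, 0.8), seed=st.integers(0, 10))
    def test_partitions_are_exact_and_stratified(self, n_pos, n_neg, frac, seed):
        y = make_labels(n_pos, n_neg)
        split = stratified_holdout_split(y, frac, seed)
        merged = np.sort(np.concatenate([split["train"], split["test"]]))
        assert np.array_equal(merged, np.arange(len(y)))
        prevalence = n_pos / len(y)
        for part in ("train", "test"):
            part_prev = np.mean(y[split[part]])
            assert abs(part_prev - prevalence) < 1.0 / len(split[part]) + 1e-12


class TestKfold:
    def test_balanced_tiny_folds(self):
        y = make_labels(4, 4)
        split = kfold_indices(y, 4, seed=0)
        for name, idx in split.partitions.items():
            assert np.sum(y[idx]) == 1 and len(idx) == 2

    def test_imbalanced_fold_counts(self):
        # 260 samples at a drug-target-like ~1:12 class ratio
        y = make_labels(20, 240)
        split = kfold_indices(y, 4, seed=1)
        for idx in split.partitions.values():
            assert np.sum(y[idx]) == 5 and len(idx) == 65

    def test_class_smaller_than_k_rejected(self):
        with pytest.raises(DataError):
            kfold_indices(make_labels(4, 40), 5, seed=0)

    def test_folds_partition_everything(self):
        y = make_labels(13, 57)
        split = kfold_indices(y, 4, seed=9)
        merged = np.sort(np.concatenate(list(split.partitions.values())))
        assert np.array_equal(merged, np.arange(70))


class TestOversample:
    def test_balances_and_keeps_originals(self, rng):
        table = FeatureTable([f"s{i}" for i in range(100)], ["f"],
                             rng.normal(size=(100, 1)), ["continuous"])
        y = make_labels(10, 90)
        ot, oy = oversample_minority(table, y, seed=0)
        assert np.sum(oy == 1) == np.sum(oy == 0) == 90
        assert ot.n_samples == 180
        # originals all retained, duplicates are exact copies of minority rows
        assert np.allclose(ot.values[:100], table.values)
        minority_rows = {float(v) for v in table.values[:10, 0]}
        assert all(float(v) in minority_rows for v in ot.values[100:, 0])

    def test_balanced_input_unchanged(self, rng):
        table = FeatureTable([f"s{i}" for i in range(10)], ["f"],
                             rng.normal(size=(10, 1)), ["continuous"])
        y = make_labels(5, 5)
        ot, oy = oversample_minority(table, y, seed=0)
        assert ot is table and np.array_equal(oy, y)

    def test_seed_determinism(self, rng):
        table = FeatureTable([f"s{i}" for i in range(40)], ["f"],
                             rng.normal(size=(40, 1)), ["continuous"])
        y = make_labels(8, 32)
        a = oversample_minority(table, y, seed=5)[0]
        b = oversample_minority(table, y, seed=5)[0]
        assert np.array_equal(a.values, b.values)

    def test_grouped_estimation_validation_split_keeps_copies_together(self, rng):
        table = FeatureTable([f"s{i}" for i in range(60)], ["f"],
                             rng.normal(size=(60, 1)), ["continuous"])
        y = make_labels(10, 50)
        ot, oy, origins = oversample_minority(table, y, seed=2, return_origins=True)
        split = estimation_validation_split(oy, 0.6, seed=0, groups=origins)
        est_groups = set(origins[split["estimation"]])
        val_groups = set(origins[split["validation"]])
        assert not est_groups & val_groups


def test_split_indices_json_round_trip():
    ids = ["p1", "p2", "p3", "p4"]
    split = SplitIndices({"train": [0, 2], "test": [1, 3]}, seed=4)
    text = split.to_json(ids)
    back = SplitIndices.from_json(text, ids)
    assert back.seed == 4
    assert np.array_equal(back["train"], split["train"])
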