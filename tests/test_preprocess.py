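"""CSV dialects, min-max scaling, one-hot encoding and fold construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cardiofair.io import ParseError, read_uci_csv, write_uci_csv
from cardiofair.preprocess import (Encoder, encoded_feature_names, make_folds,
                                   transform_minmax, count_missing)
from cardiofair.schema import COLUMNS, Cohort, SchemaError
from cardiofair.simulate import CohortSpec, generate_cohort


class TestReadUciCsv:
    def test_constructed_row(self, tmp_path):
        p = tmp_path / "one.csv"
        p.write_text("57,1,2,130,236,0,2,174,0,0.0,2,1,3,0\n")
        cohort = read_uci_csv(p)
        rec = cohort.records()[0]
        assert rec.cp == 2 and rec.target == 0 and rec.age == 57

    def test_question_mark_becomes_missing_flag(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("57,1,2,130,236,0,2,174,0,0.0,2,1,?,0\n")
        cohort = read_uci_csv(p)
        assert cohort.records()[0].thal is None
        assert cohort.count_missing("thal") == 1

    def test_row_count_contract(self, tmp_path):
        rows = ["57,1,2,130,236,0,2,174,0,0.0,2,1,3,0"] * 3
        p = tmp_path / "three.csv"
        p.write_text("\n".join(rows) + "\n")
        assert read_uci_csv(p).n == 3

    def test_wrong_field_count_names_row(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("57,1,2,130,236,0,2,174,0,0.0,2,1,3,0\n1,2,3\n")
        with pytest.raises(ParseError, match="row 1"):
            read_uci_csv(p)

    def test_out_of_domain_categorical_names_field(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("57,1,9,130,236,0,2,174,0,0.0,2,1,3,0\n")
        with pytest.raises(SchemaError, match="cp"):
            read_uci_csv(p)

    def test_severity_codes_binarized(self, tmp_path):
        p = tmp_path / "sev.csv"
        p.write_text("57,1,2,130,236,0,2,174,0,0.0,2,1,3,3\n")
        assert read_uci_csv(p).records()[0].target == 1

    @pytest.mark.parametrize("dialect", ["headerless-processed", "headered"])
    def test_round_trip_is_lossless_including_missing(self, tmp_path, dialect):
        cohort = generate_cohort(CohortSpec(
            n=60, seed=2, missing_rates={"thal": 0.1, "ca": 0.1}))
        p = tmp_path / "c.csv"
        write_uci_csv(cohort, p, dialect)
        back = read_uci_csv(p, dialect)
        pd.testing.assert_frame_equal(cohort.df, back.df)


class TestMinMax:
    def test_midpoint_and_endpoints(self):
        assert transform_minmax(5.0, (0.0, 10.0)) == 0.5
        assert transform_minmax(0.0, (0.0, 10.0)) == 0.0
        assert transform_minmax(10.0, (0.0, 10.0)) == 1.0

    def test_constant_column_maps_to_zero(self):
        assert transform_minmax(7.0, (7.0, 7.0)) == 0.0

    def test_out_of_range_values_clipped(self):
        assert transform_minmax(20.0, (0.0, 10.0)) == 1.0
        assert transform_minmax(-5.0, (0.0, 10.0)) == 0.0

    @given(st.floats(-100, 100), st.floats(-100, 100))
    @settings(max_examples=50, deadline=None)
    def test_monotone_non_decreasing(self, x1, x2):
        lo, hi = -10.0, 25.0
        a, b = sorted([x1, x2])
        assert transform_minmax(a, (lo, hi)) <= transform_minmax(b, (lo, hi))

    def test_fitted_training_columns_lie_in_unit_interval(self, small_cohort):
        m = Encoder().fit_transform(small_cohort)
        for name in ("age", "trestbps", "chol", "thalach", "oldpeak"):
            col = m.column(name)
            assert col.min() >= 0.0 and col.max() <= 1.0


class TestOneHot:
    def test_column_count_oracle(self, small_matrix):
        # 5 numeric + 3 binary + blocks 4+3+3+4+3 = 25
        assert small_matrix.d == 25
        assert len(encoded_feature_names()) == 25

    def test_indicator_block(self, small_cohort):
        m = Encoder().fit_transform(small_cohort)
        cp = small_cohort.df["cp"].to_numpy()
        block = m.values[:, [m.encoding_map["cp"][c] for c in (1, 2, 3, 4)]]
        assert block.sum(axis=1).tolist() == [1.0] * small_cohort.n
        np.testing.assert_array_equal(block[:, 1], (cp == 2).astype(float))

    def test_binary_passthrough(self, small_cohort, small_matrix):
        np.testing.assert_array_equal(small_matrix.column("sex"),
                                      small_cohort.df["sex"].to_numpy())

    def test_one_hot_row_sums_are_exactly_one(self, small_matrix):
        for name, block in small_matrix.encoding_map.items():
            cols = small_matrix.values[:, list(block.values())]
            np.testing.assert_array_equal(cols.sum(axis=1), np.ones(small_matrix.n))

    def test_encode_decode_recovers_categories(self, small_cohort):
        enc = Encoder().fit(small_cohort)
        m = enc.transform(small_cohort)
        for name in ("cp", "thal", "ca", "slope", "restecg"):
            np.testing.assert_array_equal(enc.decode_categorical(m, name),
                                          small_cohort.df[name].to_numpy())

    def test_missing_values_rejected_at_transform(self):
        cohort = generate_cohort(CohortSpec(n=50, seed=3,
                                            missing_rates={"thal": 0.5}))
        with pytest.raises(SchemaError, match="impute"):
            Encoder().fit(generate_cohort(CohortSpec(n=50, seed=3, missing_rates={}))
                          ).transform(cohort)


class TestFolds:
    def test_exact_stratification_on_balanced_cohort(self):
        df = generate_cohort(CohortSpec(n=200, seed=1, missing_rates={})).df.copy()
        df["target"] = np.tile([0.0, 1.0], 100)
        cohort = Cohort(df)
        plan = make_folds(cohort, k=10, seed=0)
        for fold in range(10):
            idx = plan.test_indices(fold)
            assert len(idx) == 20
            assert df["target"].iloc[idx].sum() == 10

    def test_determinism_under_seed(self, small_cohort):
        a = make_folds(small_cohort, k=5, seed=7)
        b = make_folds(small_cohort, k=5, seed=7)
        np.testing.assert_array_equal(a.assignments, b.assignments)

    def test_partition_contract_n303_k10(self):
        cohort = generate_cohort(CohortSpec(n=303, seed=4, missing_rates={}))
        plan = make_folds(cohort, k=10, seed=1)
        sizes = [len(plan.test_indices(f)) for f in range(10)]
        assert set(sizes) <= {30, 31}
        all_test = np.concatenate([plan.test_indices(f) for f in range(10)])
        assert sorted(all_test) == list(range(303))  # disjoint and exhaustive

    def test_per_fold_class_proportions_near_global(self):
        cohort = generate_cohort(CohortSpec(n=303, seed=4, missing_rates={}))
        plan = make_folds(cohort, k=10, seed=1)
        y = cohort.df["target"].to_numpy()
        global_pos = y.sum()
        for fold in range(10):
            idx = plan.test_indices(fold)
            expected = global_pos * len(idx) / 303
            assert abs(y[idx].sum() - expected) <= 1.0

    def test_k_exceeding_n_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            make_folds(small_cohort, k=small_cohort.n + 1, seed=0)

    def test_fold_plan_json_round_trip(self, small_cohort, tmp_path):
        plan = make_folds(small_cohort, k=4, seed=3)
        plan.to_json(tmp_path / "plan.json")
        from cardiofair.preprocess import FoldPlan
        back = FoldPlan.from_json(tmp_path / "plan.json")
        np.testing.assert_array_equal(plan.assignments, back.assignments)
        assert (back.k, back.seed, back.stratified) == (4, 3, True)


def test_count_missing_complete_cohort_is_zero(small_cohort):
    for col in COLUMNS:
        assert count_missing(small_cohort, col) == 0
    with pytest.raises(SchemaError):
        count_missing(small_cohort, "nonexistent")
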