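"""Group proportions, inverse-frequency weights, the reweighted loss and the
subgroup fairness report."""

import numpy as np
import pytest

from cardiofair._autodiff import Tensor
from cardiofair.fairness import (fairness_report, group_proportions,
                                 inverse_frequency_weights, reweighted_bce,
                                 sample_weights, subgroup_metrics)


class TestGroupProportions:
    @pytest.mark.parametrize("keys,expected", [
        (["A", "A", "B", "B"], {"A": 0.5, "B": 0.5}),
        (["g"], {"g": 1.0}),
        (["A", "A", "A", "B"], {"A": 0.75, "B": 0.25}),
    ])
    def test_counting(self, keys, expected):
        assert group_proportions(keys) == expected

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            group_proportions([])


class TestInverseFrequencyWeights:
    def test_balanced_groups_get_unit_weights(self):
        table = inverse_frequency_weights({"A": 0.5, "B": 0.5})
        assert table.raw_weights == {"A": 2.0, "B": 2.0}
        assert table.weights == {"A": 1.0, "B": 1.0}

    def test_mean_weight_normalization_oracle(self):
        # raw w = {4/3, 4}; mean raw weight = .75*4/3 + .25*4 = 2
        table = inverse_frequency_weights({"A": 0.75, "B": 0.25})
        assert table.raw_weights["A"] == pytest.approx(4 / 3)
        assert table.raw_weights["B"] == pytest.approx(4.0)
        assert table.weights["A"] == pytest.approx(2 / 3)
        assert table.weights["B"] == pytest.approx(2.0)

    def test_minority_gets_strictly_largest_weight(self):
        table = inverse_frequency_weights({"A": 0.6, "B": 0.3, "C": 0.1})
        assert table.weights["C"] > table.weights["B"] > table.weights["A"]

    def test_zero_proportion_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            inverse_frequency_weights({"A": 1.0, "B": 0.0})

    def test_per_sample_weights_sum_to_n(self, rng):
        keys = rng.choice(["A", "B", "C"], p=[0.6, 0.3, 0.1], size=500)
        table = inverse_frequency_weights(group_proportions(keys))
        w = sample_weights(keys, table)
        assert w.sum() == pytest.approx(len(keys), abs=1e-9)


class TestReweightedBCE:
    def test_closed_form_ln2(self):
        loss = reweighted_bce(np.array([1.0]), np.array([0.5]), np.array([1.0]))
        assert float(loss) == pytest.approx(np.log(2.0), rel=1e-12)

    def test_perfect_fit_limit(self):
        y = np.array([1.0, 0.0, 1.0])
        loss = float(reweighted_bce(y, y.copy(), np.ones(3)))
        assert 0 <= loss < 3 * 1.1e-7  # clamp floor per sample

    def test_linearity_in_weights(self, rng):
        y = rng.integers(0, 2, 20).astype(float)
        p = rng.uniform(0.1, 0.9, 20)
        w = rng.uniform(0.5, 2.0, 20)
        assert float(reweighted_bce(y, p, 2 * w)) == pytest.approx(
            2 * float(reweighted_bce(y, p, w)), rel=1e-12)

    def test_reduces_to_plain_bce_with_unit_weights(self, rng):
        y = rng.integers(0, 2, 50).astype(float)
        p = rng.uniform(0.01, 0.99, 50)
        plain = -np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert float(reweighted_bce(y, p, np.ones(50))) == pytest.approx(plain)

    def test_balanced_groups_make_weighted_equal_unweighted(self, rng):
        keys = np.array(["A", "B"] * 25)
        table = inverse_frequency_weights(group_proportions(keys))
        w = sample_weights(keys, table)
        y = rng.integers(0, 2, 50).astype(float)
        p = rng.uniform(0.1, 0.9, 50)
        assert float(reweighted_bce(y, p, w)) == float(
            reweighted_bce(y, p, np.ones(50)))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            reweighted_bce(np.ones(3), np.full(2, 0.5), np.ones(3))

    def test_accepts_autodiff_tensor_predictions(self):
        y = np.array([1.0, 0.0])
        p = Tensor(np.array([0.8, 0.3]), requires_grad=True)
        loss = reweighted_bce(y, p, np.ones(2))
        loss.backward()
        assert p.grad is not None and np.isfinite(float(loss.data))


def _fold(**f1s):
    """Build one fold's subgroup metrics from F1 values (error rates 0)."""
    return {k: {"n": 10, "f1": v, "error_rate": 0.0} for k, v in f1s.items()}


class TestFairnessReport:
    def test_published_style_worked_example(self):
        """Single fold with subgroup F1s 98.5/97.9 and 98.3/97.8 gives
        gaps 0.6 (gender) and 0.5 (age)."""
        fold = _fold(**{"gender:male": 98.5, "gender:female": 97.9,
                        "age:lt50": 98.3, "age:ge50": 97.8})
        rep = fairness_report([fold])
        assert rep.delta_f1["gender"] == pytest.approx(0.6)
        assert rep.delta_f1["age"] == pytest.approx(0.5)

    def test_identical_subgroups_give_zero_gaps(self):
        fold = _fold(**{"gender:male": 0.9, "gender:female": 0.9,
                        "age:lt50": 0.9, "age:ge50": 0.9})
        rep = fairness_report([fold, fold])
        assert rep.delta_f1 == {"gender": 0.0, "age": 0.0}
        assert rep.delta_error == {"gender": 0.0, "age": 0.0}

    def test_mean_over_folds_aggregation(self):
        f1 = _fold(**{"gender:male": 1.0, "gender:female": 0.6,
                      "age:lt50": 1.0, "age:ge50": 1.0})
        f2 = _fold(**{"gender:male": 1.0, "gender:female": 0.2,
                      "age:lt50": 1.0, "age:ge50": 1.0})
        rep = fairness_report([f1, f2])
        assert rep.delta_f1["gender"] == pytest.approx(0.6)  # mean of 0.4, 0.8

    def test_fold_with_empty_subgroup_excluded_and_logged(self):
        good = _fold(**{"gender:male": 0.9, "gender:female": 0.8,
                        "age:lt50": 0.9, "age:ge50": 0.7})
        empty = dict(good)
        empty["gender:female"] = {"n": 0, "f1": None, "error_rate": None}
        rep = fairness_report([good, empty])
        assert rep.delta_f1["gender"] == pytest.approx(0.1)  # one fold only
        assert rep.excluded_folds["gender"] == [1]
        assert rep.delta_f1["age"] == pytest.approx(0.2)     # both folds


def test_subgroup_metrics_counts_and_rates():
    y = np.array([1, 1, 0, 0, 1, 0])
    scores = np.array([0.9, 0.2, 0.1, 0.8, 0.7, 0.3])
    # male: first 3 records, all under 50; female: last 3, all >= 50
    keys = ["male:lt50"] * 3 + ["female:ge50"] * 3
    out = subgroup_metrics(y, scores, keys)
    assert out["gender:male"]["n"] == 3
    assert out["gender:male"]["error_rate"] == pytest.approx(1 / 3)
    assert out["age:ge50"]["n"] == 3
    assert out["gender:female"]["error_rate"] == pytest.approx(1 / 3)
    assert out["age:lt50"] == out["gender:male"]
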