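import itertools
import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gainselect.selection import (EntropyGainSelector, SelectionError,
                                  compute_entropy, compute_gain,
                                  compute_threshold, gain_of_arrays,
                                  select_features, select_subset)
from gainselect.simulate import default_config, generate_cohort

from conftest import make_dataset, oracle_gain


class TestComputeEntropy:
    @pytest.mark.parametrize("counts,expected", [
        ({0: 5, 1: 5}, 1.0),
        ({0: 10, 1: 0}, 0.0),
        ({"a": 2, "b": 3, "c": 5}, 1.48548),  # frozen from -sum(p log2 p)
    ])
    def test_values(self, counts, expected):
        assert compute_entropy(counts) == pytest.approx(expected, abs=5e-6)

    def test_empty_set_errors(self):
        with pytest.raises(SelectionError):
            compute_entropy({0: 0, 1: 0})


class TestComputeGain:
    def test_perfect_predictor_equals_entropy(self):
        y = [0, 0, 1, 1, 1]
        data = make_dataset({"X": y, "PTB": y})
        assert compute_gain(data, "X") == pytest.approx(
            compute_entropy({0: 2, 1: 3}))

    def test_constant_feature_zero(self):
        data = make_dataset({"X": [7] * 6, "PTB": [0, 0, 0, 1, 1, 1]})
        assert compute_gain(data, "X") == pytest.approx(0.0, abs=1e-12)

    def test_worked_partition(self):
        # Entropy(S)=0.918296; X=a half is {1,1,0}, X=b half is pure
        data = make_dataset({"X": ["a", "a", "a", "b", "b", "b"],
                             "PTB": [1, 1, 0, 0, 0, 0]},
                            kinds={"X": "categorical"})
        assert compute_gain(data, "X") == pytest.approx(0.459148, abs=5e-7)

    def test_missing_values_error(self):
        data = make_dataset({"X": [1.0, float("nan")], "PTB": [0, 1]})
        with pytest.raises(SelectionError, match="missing"):
            compute_gain(data, "X")

    def test_continuous_feature_warns(self):
        data = make_dataset({"X": np.linspace(0, 1, 40), "PTB": [0, 1] * 20})
        with pytest.warns(UserWarning, match="continuous"):
            compute_gain(data, "X")

    def test_non_candidate_rejected(self):
        data = make_dataset({"X": [1, 2], "PTB": [0, 1]})
        with pytest.raises(SelectionError):
            compute_gain(data, "PTB")


class TestComputeThreshold:
    @pytest.mark.parametrize("gains,expected", [
        ({"A": 0.9, "B": 0.5, "C": 0.1}, 0.8 / 3),
        ({"A": 0.3, "B": 0.3}, 0.0),
        ({"A": 0.4, "B": 0.2}, 0.1),
    ])
    def test_range_formula(self, gains, expected):
        assert compute_threshold(gains) == pytest.approx(expected)

    def test_empty_errors(self):
        with pytest.raises(SelectionError):
            compute_threshold({})


class TestSelectSubset:
    def test_threshold_application(self):
        # A predicts the class perfectly, B agrees except on one row,
        # C is constant: r = (gain_A - 0)/3 cuts C but not B
        y = [0] * 6 + [1] * 6
        b = list(y)
        b[0] = 1
        data = make_dataset({"A": y, "B": b, "C": [1] * 12, "PTB": y})
        kept, report = select_subset(data, ["A", "B", "C"])
        assert kept == ["A", "B"]
        assert report.gains["A"] == pytest.approx(1.0)
        assert report.threshold == pytest.approx(
            (report.gains["A"] - report.gains["C"]) / 3)
        assert report.gains["C"] < report.threshold <= report.gains["B"]

    def test_all_equal_gains_keep_everything(self):
        data = make_dataset({"A": [0, 1, 0, 1], "B": [1, 0, 1, 0],
                             "PTB": [0, 1, 0, 1]})
        kept, report = select_subset(data, ["A", "B"])
        assert kept == ["A", "B"] and report.threshold == 0.0

    def test_single_class_subset_warns_and_keeps_all(self):
        data = make_dataset({"A": [0, 1, 0], "B": [2, 2, 2],
                             "PTB": [1, 1, 1]})
        with pytest.warns(UserWarning, match="single class"):
            kept, report = select_subset(data, ["A", "B"])
        assert kept == ["A", "B"]
        assert all(g == 0 for g in report.gains.values())

    def test_monotone_cut(self):
        rng = np.random.default_rng(4)
        data = make_dataset(
            {**{f"X{i}": rng.integers(0, 3, 60) for i in range(8)},
             "PTB": rng.integers(0, 2, 60)})
        kept, report = select_subset(data, [f"X{i}" for i in range(8)])
        removed = set(report.gains) - set(kept)
        if removed and kept:
            assert max(report.gains[a] for a in removed) < \
                min(report.gains[a] for a in kept)


class TestSelectFeatures:
    def test_perfect_feature_among_constants(self):
        y = [0, 1] * 15
        data = make_dataset({"A": y, "B": [3] * 30, "C": [5] * 30, "PTB": y})
        res = select_features(data, seed=0)
        assert res.selected_features == ["A"]
        assert all(f == ["A"] for f in res.per_subset_features)

    def test_all_tied_noise_keeps_everything(self):
        # identical constant features: every gain 0, r = 0, nothing removed
        data = make_dataset({"A": [1] * 12, "B": [1] * 12,
                             "PTB": [0, 1] * 6})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = select_features(data, seed=0)
        assert res.selected_features == ["A", "B"]

    def test_union_and_subset_invariants(self, default_cohort):
        data, _ = default_cohort
        res = select_features(data, seed=42)
        f0 = set(res.initial_features)
        union = set()
        for fk in res.per_subset_features:
            assert set(fk) <= f0
            union |= set(fk)
        assert set(res.selected_features) == union

    def test_planted_features_recovered(self, default_cohort):
        data, truth = default_cohort
        res = select_features(data, seed=42)
        assert truth <= set(res.selected_features)

    def test_identifier_and_target_excluded(self, default_cohort):
        data, _ = default_cohort
        res = select_features(data, seed=1)
        assert "PID" not in res.initial_features
        assert "PTB" not in res.initial_features
        # 36 schema columns minus the PID identifier and the PTB target
        assert all(r.n_candidates == 34 for r in res.gain_reports)

    def test_too_few_rows(self):
        data = make_dataset({"A": [0, 1], "PTB": [0, 1]})
        with pytest.raises(SelectionError):
            select_features(data, seed=0)

    def test_deterministic_given_seed(self, default_cohort):
        data, _ = default_cohort
        a = select_features(data, seed=7)
        b = select_features(data, seed=7)
        assert a.selected_features == b.selected_features
        assert [r.gains for r in a.gain_reports] == \
            [r.gains for r in b.gain_reports]


class TestEntropyGainSelector:
    def test_sklearn_transform_reduces_columns(self, default_cohort):
        data, _ = default_cohort
        X = data.frame[data.candidate_codes]
        sel = EntropyGainSelector(random_state=0)
        Xt = sel.fit(X, data.y.to_numpy()).transform(X)
        assert Xt.shape[1] == len(sel.selected_features_)
        assert sel.support_.sum() == Xt.shape[1]

    def test_get_set_params_round_trip(self):
        sel = EntropyGainSelector(n_subsets=3, random_state=5)
        params = sel.get_params()
        assert params == {"n_subsets": 3, "random_state": 5}
        sel.set_params(random_state=9)
        assert sel.random_state == 9


# ---------------------------------------------------------------------------
# Oracle equivalence and distributional properties
# ---------------------------------------------------------------------------

def test_gain_matches_oracle_exhaustively_small_n():
    """Exhaustive (class, feature) column pairs for n <= 4 agree to 1e-12."""
    for n in (2, 3, 4):
        for y in itertools.product((0, 1), repeat=n):
            for x in itertools.product((0, 1, 2), repeat=n):
                got = gain_of_arrays(np.array(x), np.array(y))
                assert got == pytest.approx(oracle_gain(x, y), abs=1e-12)


@settings(max_examples=300, deadline=None, derandomize=True)
@given(st.integers(min_value=2, max_value=30).flatmap(
    lambda n: st.tuples(
        st.lists(st.integers(0, 4), min_size=n, max_size=n),
        st.lists(st.integers(0, 2), min_size=n, max_size=n))))
def test_gain_bounds_property(xy):
    """0 <= Gain <= Entropy(S) <= log2(c) on arbitrary discrete tables."""
    x, y = xy
    g = gain_of_arrays(np.array(x), np.array(y))
    ent = compute_entropy(np.bincount(np.array(y), minlength=1))
    c = len(set(y))
    assert -1e-12 <= g <= ent + 1e-12
    assert ent <= math.log2(max(c, 2)) + 1e-12
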