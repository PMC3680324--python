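"""Differential-expression kernel: Mann-Whitney tests, corrections, calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from clustermir import (
    ExpressionMatrix, RunConfig, adjust_p, call_features, mann_whitney,
)
from oracles import bh_stepup, mw_permutation_p


class TestMannWhitney:
    @pytest.mark.parametrize("tail,expected", [
        ("less", 1 / 20),       # most extreme of C(6,3)=20 orderings
        ("two-sided", 2 / 20),
        ("greater", 1.0),
    ])
    def test_extreme_ordering_exact_p(self, tail, expected):
        res = mann_whitney([1, 2, 3], [4, 5, 6], tail)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(expected, abs=1e-12)

    def test_matches_permutation_oracle(self, rng):
        """Exact p equals brute-force enumeration over all group labelings
        for tie-free samples with group sizes <= 6."""
        for _ in range(60):
            n1, n2 = rng.integers(2, 7, size=2)
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            for tail in ("less", "greater", "two-sided"):
                got = mann_whitney(x, y, tail)
                assert got.method == "exact"
                assert got.p_value == pytest.approx(
                    mw_permutation_p(x, y, tail), abs=1e-12
                ), (tail, x, y)

    def test_all_identical_values_give_p_one(self):
        res = mann_whitney([3.0, 3.0], [3.0, 3.0, 3.0], "two-sided")
        assert res.p_value == 1.0
        assert res.u_stat == 3.0  # n1*n2/2

    def test_ties_fall_back_to_asymptotic(self):
        res = mann_whitney([1, 2, 2], [2, 3, 4], "two-sided")
        assert res.method == "asymptotic"
        assert 0 <= res.p_value <= 1

    def test_empty_group_raises(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney([], [1.0, 2.0])

    def test_unknown_tail_raises(self):
        with pytest.raises(ValueError, match="tail"):
            mann_whitney([1.0], [2.0], "sideways")

    def test_exact_and_asymptotic_agree_at_8v8(self, rng):
        """On tie-free 8 vs 8 samples the normal approximation stays within
        0.01 of the exact enumeration p per tail (two-sided doubles the
        one-tailed discrepancy, so its bound doubles too)."""
        from scipy.stats import mannwhitneyu

        for _ in range(30):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            for tail, bound in (("less", 0.01), ("greater", 0.01),
                                ("two-sided", 0.02)):
                exact = mann_whitney(x, y, tail)
                assert exact.method == "exact"
                approx = mannwhitneyu(x, y, alternative=tail,
                                      method="asymptotic").pvalue
                assert abs(exact.p_value - approx) < bound


class TestAdjustP:
    def test_bonferroni_multiplies_by_n_tested(self):
        out = adjust_p([1e-5], "bonferroni", n_tests=534)
        assert out[0] == pytest.approx(5.34e-3)

    def test_bonferroni_caps_at_one(self):
        out = adjust_p([0.01], "bonferroni", n_tests=534)
        assert out[0] == 1.0

    def test_bh_matches_stepup_oracle(self, rng):
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(
                adjust_p(p, "bh_fdr"), bh_stepup(p), atol=1e-12
            )

    def test_bh_known_list(self):
        p = [0.001, 0.01, 0.03, 0.8]
        np.testing.assert_allclose(adjust_p(p, "bh_fdr"), bh_stepup(p))

    def test_none_passthrough(self):
        p = [0.2, 0.9]
        np.testing.assert_array_equal(adjust_p(p, "none"), p)

    @pytest.mark.parametrize("bad", [[-0.1], [1.5], [np.nan]])
    def test_out_of_range_p_raises(self, bad):
        with pytest.raises(ValueError):
            adjust_p(bad, "bonferroni")

    def test_adjusted_never_below_raw(self, rng):
        p = rng.uniform(size=25)
        for method in ("bonferroni", "bh_fdr"):
            assert (adjust_p(p, method) >= p - 1e-15).all()


def _matrix_from_arrays(case, ctrl):
    n_f = case.shape[0]
    values = np.concatenate([case, ctrl], axis=1)
    samples = [f"case{i}" for i in range(case.shape[1])] + \
              [f"ctrl{i}" for i in range(ctrl.shape[1])]
    df = pd.DataFrame(values, index=[f"f{i}" for i in range(n_f)], columns=samples)
    group = pd.Series(["case"] * case.shape[1] + ["control"] * ctrl.shape[1],
                      index=samples)
    return ExpressionMatrix(df, group)


class TestCallFeatures:
    def test_label_swap_antisymmetry(self, rng):
        """Swapping case/control labels maps every down call to an up call."""
        m = _matrix_from_arrays(rng.normal(-1, 1, (30, 6)), rng.normal(0, 1, (30, 6)))
        cfg = RunConfig(correction_method="none", alpha=0.2)
        a = call_features(m, cfg)
        b = call_features(m.swap_labels(), cfg)
        assert a.down_ids == b.up_ids
        assert a.up_ids == b.down_ids

    def test_label_swap_antisymmetry_vectorised_path(self, rng):
        m = _matrix_from_arrays(rng.normal(-1, 1, (20, 12)), rng.normal(0, 1, (20, 12)))
        cfg = RunConfig(correction_method="none", alpha=0.2)
        a = call_features(m, cfg)
        b = call_features(m.swap_labels(), cfg)
        assert a.down_ids == b.up_ids and a.up_ids == b.down_ids

    def test_monotone_control_shift_strengthens_down_evidence(self, rng):
        """Raising every control value can only lower (or keep) the one-tailed
        case<control p."""
        x = rng.normal(size=7)
        y = rng.normal(size=7)
        p0 = mann_whitney(x, y, "less").p_value
        for shift in (0.5, 1.0, 3.0):
            assert mann_whitney(x, y + shift, "less").p_value <= p0 + 1e-12

    def test_down_call_requires_corrected_one_tailed_alpha(self, rng):
        case = np.full((1, 10), 0.0) + rng.normal(0, 0.1, (1, 10)) - 5
        ctrl = rng.normal(0, 0.1, (1, 10))
        m = _matrix_from_arrays(case, ctrl)
        res = call_features(m, RunConfig())
        row = res.table.iloc[0]
        assert row["call"] == "down"
        assert row["p_adj_less"] < 0.05
        assert row["median_diff"] < 0

    def test_feature_missing_in_one_group_is_skipped(self):
        values = pd.DataFrame(
            [[np.nan, np.nan, 1.0, 2.0], [0.5, 0.7, 1.0, 2.0]],
            index=["gone", "kept"],
            columns=["case0", "case1", "ctrl0", "ctrl1"],
        )
        group = pd.Series(["case", "case", "control", "control"],
                          index=values.columns)
        res = call_features(ExpressionMatrix(values, group), RunConfig())
        assert res.skipped == ["gone"]
        assert list(res.table["feature_id"]) == ["kept"]
        assert res.n_tested == 1

    def test_correction_uses_number_actually_tested(self):
        values = pd.DataFrame(
            np.vstack([
                np.array([[np.nan, np.nan, 1.0, 2.0]]),
                np.arange(8).reshape(2, 4).astype(float),
            ]),
            index=["gone", "a", "b"],
            columns=["case0", "case1", "ctrl0", "ctrl1"],
        )
        group = pd.Series(["case", "case", "control", "control"],
                          index=values.columns)
        res = call_features(ExpressionMatrix(values, group), RunConfig())
        row = res.table.set_index("feature_id").loc["a"]
        assert row["p_adj"] == pytest.approx(min(1.0, row["p_two"] * 2))

    def test_p_adj_at_least_p_two(self, rng):
        m = _matrix_from_arrays(rng.normal(size=(25, 10)), rng.normal(size=(25, 10)))
        res = call_features(m, RunConfig())
        assert (res.table["p_adj"] >= res.table["p_two"] - 1e-15).all()

    def test_require_two_tailed_gate(self, rng):
        m = _matrix_from_arrays(rng.normal(-0.5, 1, (40, 8)),
                                rng.normal(0, 1, (40, 8)))
        loose = call_features(m, RunConfig(correction_method="none", alpha=0.3))
        strict = call_features(
            m, RunConfig(correction_method="none", alpha=0.3,
                         require_two_tailed=True)
        )
        assert set(strict.down_ids) <= set(loose.down_ids)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.lists(st.floats(-50, 50), min_size=2, max_size=6, unique=True),
       st.lists(st.floats(-50, 50), min_size=2, max_size=6, unique=True))
def test_mann_whitney_tails_are_coherent(x, y):
    """One-tailed p-values from opposite tails cover the distribution:
    p_less + p_greater >= 1 (they share the observed point mass)."""
    if set(x) & set(y):
        return
    less = mann_whitney(x, y, "less").p_value
    greater = mann_whitney(x, y, "greater").p_value
    assert less + greater >= 1.0 - 1e-12
    two = mann_whitney(x, y, "two-sided").p_value
    assert two >= min(less, greater) - 1e-12
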