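"""Unit and property tests for the JZS Bayes-factor engine."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from twotrials.bayes_core import (
    BFSpec,
    DEFAULT_PRIOR_SCALE,
    jzs_bf10,
    jzs_bf_directional,
    pooled_t_test,
    savage_dickey_oracle,
)

arm = st.lists(
    st.floats(-50, 50, allow_nan=False, allow_infinity=False, width=32),
    min_size=3,
    max_size=12,
).filter(lambda xs: np.asarray(xs).std() > 1e-3)


class TestPooledTTest:
    def test_identical_samples_give_null_result(self):
        res = pooled_t_test([1, 2, 3], [1, 2, 3])
        assert res.t == pytest.approx(0.0)
        assert res.p_two_tailed == pytest.approx(1.0)
        assert res.df == 4

    def test_hand_computed_example(self):
        # means 3 and 2, pooled variance 2, se = sqrt(2) -> t = 1/sqrt(2)
        res = pooled_t_test([2, 4], [1, 3])
        assert res.t == pytest.approx(1 / math.sqrt(2))
        assert res.df == 2
        assert res.mean_diff == pytest.approx(1.0)

    @given(x=arm, y=arm)
    def test_antisymmetry_and_sign_consistency(self, x, y):
        fwd = pooled_t_test(x, y)
        rev = pooled_t_test(y, x)
        assert fwd.t == pytest.approx(-rev.t, abs=1e-10)
        assert fwd.p_two_tailed == pytest.approx(rev.p_two_tailed, abs=1e-10)
        if fwd.mean_diff != 0:
            assert np.sign(fwd.t) == np.sign(fwd.mean_diff)

    @pytest.mark.parametrize(
        "x, y",
        [([1.0], [1.0, 2.0]), ([1.0, 2.0], [3.0]), ([2, 2, 2], [2, 2, 2])],
    )
    def test_invalid_inputs_raise(self, x, y):
        with pytest.raises(ValueError):
            pooled_t_test(x, y)


class TestBFSpec:
    @pytest.mark.parametrize("kwargs", [
        {"prior_scale": 0.0},
        {"prior_scale": -1.0},
        {"prior_scale": float("nan")},
        {"direction": "both"},
    ])
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(ValueError):
            BFSpec(**kwargs)

    def test_default_prior_scale_is_root_half(self):
        assert BFSpec().prior_scale == pytest.approx(math.sqrt(2) / 2)


class TestTwoSidedBF:
    def test_null_favoring_at_t_zero(self):
        assert jzs_bf10(0.0, 20, 20) < 1.0

    def test_strictly_increasing_in_abs_t(self):
        values = [jzs_bf10(t, 20, 20) for t in (0.0, 1.0, 2.0, 3.0, 4.0)]
        assert all(a < b for a, b in zip(values, values[1:]))

    @pytest.mark.parametrize("t, n", [(1.3, 25), (2.7, 60), (4.0, 400)])
    def test_even_in_t(self, t, n):
        assert jzs_bf10(t, n, n) == pytest.approx(jzs_bf10(-t, n, n), rel=1e-9)

    @pytest.mark.parametrize(
        "t, n1, n2",
        [(0.0, 20, 20), (1.0, 20, 20), (2.5, 50, 50), (3.0, 100, 100),
         (5.0, 200, 200), (2.0, 1000, 1000), (1.5, 30, 45), (6.0, 1000, 1000)],
    )
    def test_matches_independent_g_integral_implementation(self, t, n1, n2):
        """Cross-check against pingouin's Rouder-style g-quadrature."""
        pingouin = pytest.importorskip("pingouin")
        ref = float(
            pingouin.bayesfactor_ttest(t, n1, n2, paired=False, r=DEFAULT_PRIOR_SCALE)
        )
        assert jzs_bf10(t, n1, n2) == pytest.approx(ref, rel=1e-6)

    def test_stable_at_extreme_t_and_n(self):
        # moderate n: the value itself is representable
        big = jzs_bf10(50.0, 20, 20)
        assert np.isfinite(big) and big > 1e30
        # huge evidence: the log-scale result stays finite and usable
        log_bf = jzs_bf10(50.0, 1000, 1000, log=True)
        assert np.isfinite(log_bf) and log_bf > 100
        small = jzs_bf10(0.5, 1000, 1000)
        assert 0 < small < 1

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            jzs_bf10(float("nan"), 20, 20)
        with pytest.raises(ValueError):
            jzs_bf10(1.0, 1, 20)
        with pytest.raises(ValueError):
            jzs_bf10(1.0, 20, 20, BFSpec(direction="greater"))


class TestDirectionalBF:
    def test_equals_two_sided_at_t_zero(self):
        two = jzs_bf10(0.0, 35, 35)
        for direction in ("greater", "less"):
            one = jzs_bf_directional(0.0, 35, 35, BFSpec(direction=direction))
            assert one == pytest.approx(two, rel=1e-9)

    @pytest.mark.parametrize(
        "t, n", [(0.5, 20), (1.7, 30), (3.0, 100), (-2.2, 50), (5.0, 500)]
    )
    def test_half_prior_mixture_identity(self, t, n):
        greater = jzs_bf_directional(t, n, n, BFSpec(direction="greater"))
        less = jzs_bf_directional(t, n, n, BFSpec(direction="less"))
        assert greater + less == pytest.approx(2 * jzs_bf10(t, n, n), rel=1e-6)

    @pytest.mark.parametrize("t, n", [(1.5, 40), (2.5, 80), (-1.8, 60)])
    def test_sign_concordant_direction_beats_two_sided(self, t, n):
        direction = "greater" if t > 0 else "less"
        one = jzs_bf_directional(t, n, n, BFSpec(direction=direction))
        assert one > jzs_bf10(t, n, n)

    def test_mirror_symmetry(self):
        greater = jzs_bf_directional(2.1, 45, 45, BFSpec(direction="greater"))
        less = jzs_bf_directional(-2.1, 45, 45, BFSpec(direction="less"))
        assert greater == pytest.approx(less, rel=1e-9)

    def test_two_sided_spec_rejected(self):
        with pytest.raises(ValueError):
            jzs_bf_directional(1.0, 20, 20, BFSpec(direction="two_sided"))


class TestSavageDickeyOracle:
    def test_self_consistent_at_symmetric_point(self):
        est, se = savage_dickey_oracle(0.0, 20, 20, draws=20_000, seed=1)
        assert abs(est - jzs_bf10(0.0, 20, 20)) < 3 * se

    def test_brackets_quadrature_value(self):
        est, se = savage_dickey_oracle(2.5, 50, 50, draws=40_000, seed=2)
        assert abs(est - jzs_bf10(2.5, 50, 50)) < 3 * se

    def test_directional_oracle_agrees(self):
        spec = BFSpec(direction="greater")
        est, se = savage_dickey_oracle(3.0, 100, 100, spec, draws=40_000, seed=3)
        assert abs(est - jzs_bf_directional(3.0, 100, 100, spec)) < 3 * se

    def test_reproducible_across_seeds_within_mc_error(self):
        a, se_a = savage_dickey_oracle(1.5, 40, 40, draws=20_000, seed=10)
        b, se_b = savage_dickey_oracle(1.5, 40, 40, draws=20_000, seed=11)
        assert abs(a - b) < 6 * max(se_a, se_b)

    def test_same_seed_is_deterministic(self):
        assert savage_dickey_oracle(1.5, 40, 40, draws=5_000, seed=4) == \
            savage_dickey_oracle(1.5, 40, 40, draws=5_000, seed=4)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            savage_dickey_oracle(1.0, 20, 20, draws=10, seed=0)
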