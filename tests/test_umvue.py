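"""Closed-form properties of the conditionally unbiased estimators."""

import math

import numpy as np
import pytest

from seamest import DesignConfig, TrialData, conditioning_stats, pooled_means
from seamest.umvue import (
    cohen_sackrowitz_selected,
    mills_ratio,
    umvue_control,
    umvue_k1,
    umvue_selected,
    unbiased_estimate,
)
from seamest.design import naive_estimate
from conftest import make_trial


class TestMillsRatio:
    def test_matches_direct_evaluation_in_bulk(self):
        from scipy.stats import norm

        w = np.linspace(-8, 8, 161)
        direct = norm.pdf(w) / norm.cdf(w)
        assert np.allclose(mills_ratio(w), direct, rtol=1e-12)

    def test_deep_left_tail_finite_and_asymptotic(self):
        # phi/Phi ~ -w for w << 0; naive evaluation would be 0/0 long before -40
        for w in (-10.0, -20.0, -40.0, -100.0):
            r = mills_ratio(w)
            assert math.isfinite(r)
            assert r == pytest.approx(-w + 1.0 / (-w), rel=1e-2)

    def test_right_tail_vanishes(self):
        assert mills_ratio(9.0) < 1e-17
        assert mills_ratio(math.inf) == 0.0


class TestConditioningStats:
    def test_worked_example(self, example_trial):
        st = conditioning_stats(example_trial)
        assert st.B == pytest.approx(-0.082)
        assert st.B1 == pytest.approx(1.766)
        assert st.x_second == pytest.approx(1.567)
        assert st.m == pytest.approx(max(-0.082, 1.567))

    def test_no_gate_truncation_deactivates(self):
        trial = make_trial(k=2, b=-np.inf, x=[0.0, 0.2, 0.5], y0=0.0, yS=0.4)
        st = conditioning_stats(trial)
        assert st.B == -math.inf
        assert st.m == pytest.approx(0.2)  # just the runner-up
        assert umvue_control(trial) == st.z0_mle  # exact reduction

    def test_k1_truncation_is_the_gate(self):
        trial = make_trial(k=1, b=0.1, x=[0.0, 0.4], y0=0.0, yS=0.3)
        st = conditioning_stats(trial)
        assert st.x_second == -math.inf
        assert st.m == pytest.approx(0.1 + 0.0)


class TestSelectedArmUMVUE:
    def test_shrinks_below_pooled_mean(self, rng):
        # n1 = n2 = 2 keeps the Mills argument moderate so the strictly
        # positive correction is resolvable in floating point
        for _ in range(50):
            x = list(rng.normal(size=4))
            trial = make_trial(k=3, n1=2, n2=2, b=-5.0, x=x,
                               y0=rng.normal(), yS=rng.normal())
            _, zS = pooled_means(trial)
            assert umvue_selected(trial) <= zS
        trial = make_trial(k=3, b=0.0, x=[0.0, 0.1, 0.6, 0.3], y0=0.1, yS=0.5)
        _, zS = pooled_means(trial)
        assert umvue_selected(trial) < zS

    def test_correction_vanishes_far_above_truncation(self):
        trial = make_trial(k=2, b=0.0, x=[0.0, 0.1, 50.0], y0=0.0, yS=50.0)
        _, zS = pooled_means(trial)
        assert umvue_selected(trial) == pytest.approx(zS, abs=1e-12)

    def test_monotone_in_pooled_mean_at_fixed_truncation(self):
        # raise yS (hence zS) holding the stage-1 configuration fixed
        vals = []
        for yS in np.linspace(-1.0, 3.0, 41):
            trial = make_trial(k=2, b=0.0, x=[0.0, 0.1, 0.8], y0=0.0, yS=yS)
            vals.append(umvue_selected(trial))
        assert np.all(np.diff(vals) > 0)

    def test_worked_example_value_regression(self, example_trial):
        # frozen value of the Rao-Blackwell closed form, certified by the
        # brute-force conditional-expectation oracle in the MC test module
        assert umvue_selected(example_trial) == pytest.approx(1.2328, abs=5e-4)
        assert umvue_control(example_trial) == pytest.approx(-0.0161, abs=5e-4)


class TestReductions:
    def test_no_gate_control_equals_pooled_exactly(self, rng):
        for _ in range(30):
            x = list(rng.normal(size=3))
            trial = make_trial(k=2, b=-np.inf, x=x, y0=rng.normal(), yS=rng.normal())
            z0, _ = pooled_means(trial)
            assert umvue_control(trial) == z0

    def test_unit_design_reduces_to_cohen_sackrowitz(self, rng):
        # sigma = 1, n1 = n2 = 1, no gate: the general formula must agree with
        # the independently coded classical drop-the-losers estimator
        for _ in range(50):
            x = list(rng.normal(size=4))
            trial = make_trial(k=3, n1=1, n2=1, sigma=1.0, b=-np.inf,
                               x=x, y0=rng.normal(), yS=rng.normal())
            st = conditioning_stats(trial)
            expect = cohen_sackrowitz_selected(st.zS_mle, st.x_second)
            assert umvue_selected(trial) == pytest.approx(expect, abs=1e-12)

    def test_k1_no_gate_equals_naive(self, rng):
        for _ in range(20):
            trial = make_trial(k=1, b=-np.inf, x=[rng.normal(), rng.normal()],
                               y0=rng.normal(), yS=rng.normal())
            assert unbiased_estimate(trial) == pytest.approx(
                naive_estimate(trial), abs=1e-12
            )


class TestK1Interface:
    def test_boundary_minus_inf_returns_input(self):
        design = DesignConfig(k=1, n1=30, n2=20, sigma=1.5)
        assert umvue_k1(0.7, design) == 0.7

    def test_matches_selected_arm_formula_via_trial(self):
        design = DesignConfig(k=1, n1=40, n2=60, sigma=2.0, b=0.05)
        trial = TrialData(design=design, x=[0.0, 0.3], y0=0.05, yS=0.25)
        st = conditioning_stats(trial)
        # same truncation: B = x0 + b on the mean scale
        assert umvue_k1(st.zS_mle, design, boundary=st.B) == pytest.approx(
            umvue_selected(trial), abs=1e-12
        )

    def test_k_mismatch_rejected(self):
        design = DesignConfig(k=2, n1=10, n2=10, sigma=1.0)
        with pytest.raises(ValueError, match="k=1"):
            umvue_k1(0.0, design)


def test_unbiased_is_difference_of_components(example_trial):
    assert unbiased_estimate(example_trial) == pytest.approx(
        umvue_selected(example_trial) - umvue_control(example_trial), abs=1e-15
    )
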