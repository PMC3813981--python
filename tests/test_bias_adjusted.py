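"""Selection density, conditional bias functions and the fixed-point solve."""

import math

import numpy as np
import pytest
from scipy import integrate

from seamest import DesignConfig
from seamest.bias_adjusted import (
    BiasModel,
    BiasSolverError,
    SolverConfig,
    bias_adjusted_estimate,
    bias_dropped,
    bias_selected,
    bias_vector,
    bias_vector_batch,
    prob_continue_select,
    selection_density,
    solve_bias_adjusted_batch,
)
from conftest import make_trial


def model(theta, k=None, n1=50, sigma=1.0, b=-math.inf, n2=50):
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    design = DesignConfig(k=len(theta), n1=n1, n2=n2, sigma=sigma, b=float(b))
    return BiasModel(theta=theta, design=design)


class TestSelectionDensity:
    def test_symmetry_under_exchangeable_theta(self):
        m = model([0.05, 0.05])
        for d in (-0.5, 0.0, 0.3):
            assert selection_density(d, 1, m) == pytest.approx(
                selection_density(d, 2, m), rel=1e-9
            )

    def test_total_probability_is_one(self):
        m = model([0.0, 0.1, 0.2], n1=25)
        total = sum(
            integrate.quad(lambda d: selection_density(d, i, m), -3.0, 3.0,
                           epsabs=1e-11, limit=200)[0]
            for i in (1, 2, 3)
        )
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_density_integral_matches_selection_probability(self):
        # integral over [b, inf) equals the gate-aware selection probability
        m = model([0.1, 0.3], b=0.05)
        for i in (1, 2):
            num = integrate.quad(lambda d: selection_density(d, i, m), 0.05, 4.0,
                                 epsabs=1e-11, limit=200)[0]
            assert num == pytest.approx(prob_continue_select(i, m), abs=1e-8)


class TestContinuationProbability:
    def test_no_gate_exchangeable_gives_one_over_k(self):
        for k in (2, 3, 4):
            m = model([0.05] * k)
            for i in range(1, k + 1):
                assert prob_continue_select(i, m) == pytest.approx(1.0 / k, abs=1e-9)

    def test_k1_boundary_at_true_difference_gives_half(self):
        m = model([0.3], b=0.3)
        assert prob_continue_select(1, m) == pytest.approx(0.5, abs=1e-9)

    def test_probabilities_sum_to_continuation(self):
        m = model([0.0, 0.05, 0.1], b=0.05, n1=40)
        total = sum(prob_continue_select(i, m) for i in (1, 2, 3))
        assert 0.0 < total < 1.0


class TestBiasFunctions:
    def test_no_selection_no_gate_is_unbiased(self):
        m = model([0.4])
        assert bias_selected(1, m) == pytest.approx(0.0, abs=1e-12)
        assert bias_vector(m, selected=1) == pytest.approx([0.0], abs=1e-12)

    def test_exchangeable_symmetry(self):
        m = model([0.05, 0.05], b=0.05)
        assert bias_selected(1, m) == pytest.approx(bias_selected(2, m), rel=1e-9)
        assert bias_dropped(2, m, selected=1) == pytest.approx(
            bias_dropped(1, m, selected=2), rel=1e-9
        )

    def test_selected_bias_positive_dropped_negative(self):
        m = model([0.05, 0.05])
        assert bias_selected(1, m) > 0
        assert bias_dropped(2, m, selected=1) < 0

    def test_selected_bias_increases_with_boundary_and_time(self):
        # gate pressure and later selection both inflate the naive estimate
        vals_b = [bias_selected(1, model([0.05, 0.05], b=b)) for b in (0.0, 0.05, 0.1)]
        assert vals_b[0] < vals_b[1] < vals_b[2]
        vals_t = [
            DesignConfig(k=2, n1=n1, n2=100 - n1, sigma=1.0, b=0.05)
            for n1 in (20, 50, 80)
        ]
        biases = [
            bias_selected(1, BiasModel(theta=np.array([0.05, 0.05]), design=d))
            for d in vals_t
        ]
        assert biases[0] < biases[1] < biases[2]

    def test_k1_dropped_rejected(self):
        with pytest.raises(ValueError, match="k >= 2"):
            bias_dropped(1, model([0.1]), selected=1)

    def test_batch_matches_scalar(self):
        m = model([0.0, 0.05, 0.1], b=0.05, n1=30, n2=70)
        bv = bias_vector(m, selected=2)
        bvb = bias_vector_batch(m.theta[None, :], np.array([2]), m.design)[0]
        assert bvb == pytest.approx(bv, abs=1e-10)
        # several rows with different selected arms at once
        thetas = np.array([[0.0, 0.05, 0.1], [0.2, 0.1, 0.0], [0.05, 0.05, 0.05]])
        sel = np.array([2, 1, 3])
        got = bias_vector_batch(thetas, sel, m.design)
        for r in range(3):
            ref = bias_vector(BiasModel(theta=thetas[r], design=m.design), int(sel[r]))
            assert got[r] == pytest.approx(ref, abs=1e-10)


class TestFixedPointSolve:
    def test_worked_example_value_and_iteration_count(self, example_trial):
        est, iters = bias_adjusted_estimate(example_trial)
        assert est == pytest.approx(1.135, abs=5e-4)
        assert abs(iters - 15) <= 2  # quadrature-tolerance variation allowed

    def test_zero_bias_returns_naive_in_one_iteration(self):
        trial = make_trial(k=1, b=-np.inf, x=[0.0, 0.3], y0=0.05, yS=0.35)
        from seamest.design import naive_estimate

        est, iters = bias_adjusted_estimate(trial)
        assert est == pytest.approx(naive_estimate(trial), abs=1e-12)
        assert iters == 1

    def test_adjusted_below_naive_on_continued_trials(self, example_trial):
        from seamest.design import naive_estimate

        est, _ = bias_adjusted_estimate(example_trial)
        assert est < naive_estimate(example_trial)

    def test_nonconvergence_raises_with_trajectory(self, example_trial):
        with pytest.raises(BiasSolverError) as exc:
            bias_adjusted_estimate(example_trial, SolverConfig(tol=1e-9, max_iter=3))
        assert exc.value.trajectory.shape[-1] == 3

    def test_batch_solver_matches_single(self, example_trial):
        from seamest.design import naive_vector

        th = naive_vector(example_trial)[None, :]
        sol, iters = solve_bias_adjusted_batch(
            np.vstack([th, th]), np.array([2, 2]), example_trial.design
        )
        est, it1 = bias_adjusted_estimate(example_trial)
        assert sol[0, 1] == pytest.approx(est, abs=1e-12)
        assert iters[0] == iters[1] == it1
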