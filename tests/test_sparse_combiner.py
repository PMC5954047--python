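"""Combiner objective, bias rules, gradient, line search and solver."""

import numpy as np
import pytest

import colbci
from colbci import COLConfig, CombinerProblem, ValidationError
from colbci.sparse_combiner import LineSearchStalled, reduced_objective
from conftest import random_combiner_instance

TIGHT = COLConfig(rel_tol=1e-12, max_iter=50000)


def _problem(rng, alpha=0.05, bias_mode="corrected", n=60, c=12):
    P, y = random_combiner_instance(rng, n, c)
    return CombinerProblem(P=P, y=y, alpha=alpha, bias_mode=bias_mode)


class TestObjective:
    def test_zero_weights_zero_bias(self):
        P = np.zeros((10, 3))
        y = np.r_[np.ones(4), np.zeros(6)]
        prob = CombinerProblem(P=P, y=y, alpha=0.1)
        assert colbci.objective(prob, np.zeros(3), 0.0) == pytest.approx(2.0)  # k/2

    def test_perfect_fit_is_zero(self):
        y = np.array([1.0, 0.0, 1.0])
        prob = CombinerProblem(P=np.eye(3), y=y, alpha=0.0)
        assert colbci.objective(prob, y, 0.0) == pytest.approx(0.0)

    def test_matches_direct_formula(self, rng):
        prob = _problem(rng)
        w = rng.random(prob.n_channels)
        b = rng.normal()
        r = prob.P @ w + b - prob.y
        expected = 0.5 * np.sum(r**2) + prob.alpha * np.sum(np.abs(w))
        assert colbci.objective(prob, w, b) == pytest.approx(expected, rel=1e-14)


class TestUpdateBias:
    def test_zero_residual_gives_zero_bias(self, rng):
        P = rng.random((20, 4))
        w = rng.random(4)
        y = P @ w
        for mode in ("paper", "corrected"):
            prob = CombinerProblem(P=P, y=y, alpha=0.0, bias_mode=mode)
            assert colbci.update_bias(prob, w) == pytest.approx(0.0, abs=1e-12)

    def test_corrected_mode_minimizes_bias_objective(self, rng):
        prob = _problem(rng, bias_mode="corrected")
        w = rng.random(prob.n_channels)
        b_star = colbci.update_bias(prob, w)
        grid = b_star + np.linspace(-1.0, 1.0, 2001)
        values = [colbci.objective(prob, w, b) for b in grid]
        assert colbci.objective(prob, w, b_star) <= min(values) + 1e-12

    def test_paper_mode_returns_positive_mean_residual(self, rng):
        prob = _problem(rng, bias_mode="paper")
        w = rng.random(prob.n_channels)
        r_mean = np.mean(prob.P @ w - prob.y)
        assert colbci.update_bias(prob, w) == pytest.approx(r_mean)

    def test_reduced_objective_substitutes_bias_rule(self, rng):
        for mode in ("paper", "corrected"):
            prob = _problem(rng, bias_mode=mode)
            w = rng.random(prob.n_channels)
            b = colbci.update_bias(prob, w)
            assert reduced_objective(prob, w) == pytest.approx(
                colbci.objective(prob, w, b), rel=1e-12
            )


class TestGradient:
    @pytest.mark.parametrize("mode", ["paper", "corrected"])
    def test_matches_central_finite_differences(self, mode, rng):
        eps = 1e-6
        worst = 0.0
        for _ in range(25):
            prob = _problem(rng, alpha=0.03, bias_mode=mode, n=30, c=6)
            w = rng.random(6) + 0.5  # keep away from the kink at 0
            grad = colbci.gradient_w(prob, w)
            for j in range(6):
                e = np.zeros(6)
                e[j] = eps
                num = (reduced_objective(prob, w + e) - reduced_objective(prob, w - e)) / (2 * eps)
                worst = max(worst, abs(num - grad[j]) / max(1.0, abs(num)))
        assert worst <= 1e-5

    def test_homogeneous_case_is_pure_quadratic_term(self, rng):
        P = rng.random((20, 5))
        prob = CombinerProblem(P=P, y=np.zeros(20), alpha=0.0, bias_mode="paper")
        w = rng.random(5)
        n = 20
        ones_p = P.sum(axis=0, keepdims=True)
        expected = (3.0 * ones_p.T @ ones_p / n + P.T @ P) @ w
        np.testing.assert_allclose(colbci.gradient_w(prob, w), expected, rtol=1e-10)

    def test_sign_convention_at_zero(self, rng):
        prob = _problem(rng, alpha=0.7)
        grad = colbci.gradient_w(prob, np.zeros(prob.n_channels))
        # subgradient term vanishes at w = 0: only the linear data term remains
        r = -prob.y
        expected = prob.P.T @ (r - r.mean())
        np.testing.assert_allclose(grad, expected, rtol=1e-10)

    def test_frozen_channels_masked_to_zero(self, rng):
        prob = _problem(rng)
        w = rng.random(prob.n_channels)
        active = np.ones(prob.n_channels, dtype=bool)
        active[[1, 5]] = False
        grad = colbci.gradient_w(prob, w, active)
        assert grad[1] == 0.0 and grad[5] == 0.0


class TestStepLength:
    def test_exact_parabola_vertex_recovered(self):
        # quadratic along the ray with interior minimizer at eta = 0.1
        h = lambda eta: 2.0 * (eta - 0.1) ** 2 + 0.1
        res = colbci.step_length(np.array([1e6]), np.array([1.0]), h(0.0), h)
        assert res.eta == pytest.approx(0.1, abs=1e-8)
        assert res.objective_after <= h(0.0)

    def test_increasing_objective_stalls(self):
        h = lambda eta: 1.0 + eta
        with pytest.raises(LineSearchStalled):
            colbci.step_length(np.array([1.0]), np.array([1.0]), 1.0, h, max_halvings=60)

    def test_nonnegativity_cap_limits_step(self):
        w = np.array([0.001, 5.0])
        grad = np.array([1.0, 1.0])
        h = lambda eta: 1.0 - eta  # always decreasing: cap must bind
        res = colbci.step_length(w, grad, 1.0, h)
        assert res.eta <= 0.001 + 1e-15
        assert (w - res.eta * grad >= -1e-15).all()

    def test_zero_gradient_rejected(self):
        with pytest.raises(ValidationError):
            colbci.step_length(np.array([1.0]), np.array([0.0]), 1.0, lambda e: 1.0)


class TestFitWeights:
    def test_descent_feasibility_and_permanent_freezing(self, rng):
        for mode in ("paper", "corrected"):
            for _ in range(10):
                prob = _problem(rng, alpha=0.05, bias_mode=mode, n=40, c=8)
                seen = []
                w, b, trace = colbci.fit_weights(prob, callback=lambda w, h, e: seen.append(w.copy()))
                assert (w >= 0).all()
                assert all((wi >= 0).all() for wi in seen)
                diffs = np.diff(trace.objective)
                assert (diffs <= 1e-12).all()
                assert (np.diff(trace.active) <= 0).all()
                # once zero, always zero
                for earlier, later in zip(seen, seen[1:]):
                    assert not np.any((earlier == 0) & (later > 0))

    def test_converges_to_exact_optimum_on_its_face(self, rng):
        """The solver's endpoint is the exact minimizer of the problem
        restricted to the channels it kept active (permanent freezing can
        pick a suboptimal face, but on that face it solves the problem)."""
        for _ in range(10):
            prob = _problem(rng, alpha=0.05, bias_mode="corrected")
            w, b, _ = colbci.fit_weights(prob, TIGHT)
            support = w > 0
            grad = colbci.gradient_w(prob, w)
            assert np.abs(grad[support]).max() <= 1e-4  # stationary on the face
            w_face, b_face = colbci.coordinate_descent_reference(
                prob.P[:, support], prob.y, prob.alpha
            )
            assert np.abs(w[support] - w_face).max() <= 1e-4
            assert abs(b - b_face) <= 1e-4

    def test_weight_agreement_when_supports_agree(self, rng):
        """When greedy freezing lands on the globally optimal face, the
        weights agree with the independent nonnegative-lasso solution."""
        agreed = 0
        for _ in range(10):
            prob = _problem(rng, alpha=0.05, bias_mode="corrected")
            w, b, _ = colbci.fit_weights(prob, TIGHT)
            w_ref, _ = colbci.coordinate_descent_reference(prob.P, prob.y, prob.alpha)
            if np.array_equal(w > 0, w_ref > 1e-10):
                agreed += 1
                assert np.abs(w - w_ref).max() <= 1e-4
        assert agreed >= 5  # the face usually is the optimal one

    def test_alpha_above_threshold_zeroes_weights(self, rng):
        for _ in range(3):
            P, y = random_combiner_instance(rng, 40, 8)
            centered = y - y.mean()
            threshold = max(0.0, (P.T @ centered).max())
            prob = CombinerProblem(P=P, y=y, alpha=1.2 * threshold, bias_mode="corrected")
            w, b, trace = colbci.fit_weights(prob, TIGHT)
            assert (w == 0).all()

    def test_sparsity_increases_with_alpha_on_average(self, rng):
        sizes = {0.001: 0, 0.1: 0}
        for _ in range(50):
            P, y = random_combiner_instance(rng, 40, 10)
            for alpha in sizes:
                w, _, _ = colbci.fit_weights(
                    CombinerProblem(P=P, y=y, alpha=alpha, bias_mode="corrected"), TIGHT
                )
                sizes[alpha] += int((w > 0).sum())
        assert sizes[0.1] <= sizes[0.001]


class TestNormalizePrediction:
    def test_center_maps_to_half(self):
        assert colbci.normalize_prediction(0.5, 4.0) == pytest.approx(0.5)

    def test_unit_slope_at_center_for_beta_4(self):
        eps = 1e-6
        slope = (
            colbci.normalize_prediction(0.5 + eps, 4.0)
            - colbci.normalize_prediction(0.5 - eps, 4.0)
        ) / (2 * eps)
        assert slope == pytest.approx(1.0, abs=1e-9)
        assert slope == pytest.approx(4.0 / 4.0)

    def test_symmetry(self, rng):
        p = rng.random(50)
        total = colbci.normalize_prediction(p, 4.0) + colbci.normalize_prediction(1 - p, 4.0)
        np.testing.assert_allclose(total, 1.0, atol=1e-12)

    def test_invalid_beta_rejected(self):
        with pytest.raises(ValidationError):
            colbci.normalize_prediction(0.5, 0.0)
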