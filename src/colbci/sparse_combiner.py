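"""l1-regularized nonnegative channel combiner.

Solves

    min_{w >= 0, b}  1/2 * ||P w + 1 b - y||^2  +  alpha * ||w||_1

by alternating a closed-form bias update with one line-searched gradient
step on w per outer iteration. Channels whose weight reaches zero are
frozen: they are removed from the gradient, the step-length ratios and
all further updates, which is what performs channel selection.

Two bias conventions are implemented. ``corrected`` mode (default) uses
the least-squares minimizer b <- -mean(P w - y), whose substituted
objective is the trial-centered problem
1/2 * ||(I - J/N)(P w - y)||^2 + alpha * ||w||_1 (J the all-ones
matrix); its solution can be cross-checked against an independent
nonnegative-lasso solver. ``paper`` mode applies the sign-flipped
update b <- +mean(P w - y) verbatim as printed in the method's source,
together with the gradient that is algebraically consistent with
substituting that b (its quadratic form carries a 3 J / N term because
(I + J/N)'(I + J/N) = I + 3 J/N). The flipped sign makes every
substituted design column share a large all-ones component, which
drives the optimum to one- or two-channel supports; the variant is kept
for faithfulness studies.

The step length follows a fixed recipe: a linear estimate H/||g||^2,
a cap from the nonnegativity ratios w_c / g_c, halving until the
objective decreases, then a parabolic fit through the objective at
{0, eta_m/2, eta_m} with a final best-evaluated-point guard.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.special import expit

from .dataio import COLConfig, SolverTrace, ValidationError

#: weights with magnitude below this snap to exactly zero and freeze
ZERO_SNAP = 1e-12


class LineSearchStalled(RuntimeError):
    """Halving could not find a decrease; treated as convergence upstream."""


@dataclass(frozen=True)
class CombinerProblem:
    """Decision matrix P (N x C), labels y in {0,1}^N, l1 weight alpha."""

    P: np.ndarray
    y: np.ndarray
    alpha: float
    bias_mode: str = "corrected"

    def __post_init__(self) -> None:
        object.__setattr__(self, "P", np.asarray(self.P, dtype=np.float64))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=np.float64))
        if self.P.ndim != 2 or self.y.shape != (self.P.shape[0],):
            raise ValidationError(
                f"P {self.P.shape} and y {self.y.shape} are inconsistent"
            )
        if self.alpha < 0:
            raise ValidationError("alpha must be nonnegative")
        if self.bias_mode not in ("paper", "corrected"):
            raise ValidationError(f"unknown bias_mode {self.bias_mode!r}")

    @property
    def n_trials(self) -> int:
        return self.P.shape[0]

    @property
    def n_channels(self) -> int:
        return self.P.shape[1]


def objective(problem: CombinerProblem, w: np.ndarray, b: float) -> float:
    """1/2 * ||P w + 1 b - y||^2 + alpha * ||w||_1."""
    w = np.asarray(w, dtype=np.float64)
    if w.shape != (problem.n_channels,):
        raise ValidationError(f"w must have length {problem.n_channels}")
    r = problem.P @ w + b - problem.y
    return float(0.5 * r @ r + problem.alpha * np.abs(w).sum())


def update_bias(problem: CombinerProblem, w: np.ndarray) -> float:
    """Closed-form bias for fixed w: +mean residual (paper) or -mean (corrected)."""
    r_mean = float(np.mean(problem.P @ w - problem.y))
    return r_mean if problem.bias_mode == "paper" else -r_mean


def reduced_objective(problem: CombinerProblem, w: np.ndarray) -> float:
    """H(w): the objective with the bias eliminated by the mode's bias rule."""
    r = problem.P @ w - problem.y
    r_mean = r.mean()
    rb = r + r_mean if problem.bias_mode == "paper" else r - r_mean
    return float(0.5 * rb @ rb + problem.alpha * np.abs(np.asarray(w)).sum())


def gradient_w(
    problem: CombinerProblem, w: np.ndarray, active: np.ndarray | None = None
) -> np.ndarray:
    """Gradient of H(w); entries of frozen (inactive) channels are 0.

    Paper mode evaluates (P'P + 3 (1P)'(1P)/N) w - (P' + 3 P'1'1/N) y
    plus alpha * sign(w), i.e. P'(I + 3J/N)(P w - y); corrected mode
    evaluates P'(I - J/N)(P w - y). sign(0) is taken as 0.
    """
    w = np.asarray(w, dtype=np.float64)
    r = problem.P @ w - problem.y
    r_mean = r.mean()
    shifted = r + 3.0 * r_mean if problem.bias_mode == "paper" else r - r_mean
    grad = problem.P.T @ shifted + problem.alpha * np.sign(w)
    if active is not None:
        grad = np.where(active, grad, 0.0)
    return grad


@dataclass
class StepSearchResult:
    """Accepted step with the line-search intermediates."""

    eta: float
    eta_l: float
    eta_m: float
    a_eta: float
    b_eta: float
    objective_after: float
    halvings: int = 0


def step_length(
    w: np.ndarray,
    grad: np.ndarray,
    h0: float,
    h_eval: Callable[[float], float],
    max_halvings: int = 200,
) -> StepSearchResult:
    """Line search along -grad: linear estimate, nonnegativity cap, halving,
    parabolic interpolation, best-evaluated-point guard.

    ``h_eval(eta)`` must return the objective at the (feasible) point
    reached with step ``eta``; ``h0 = h_eval(0)``. Guarantees
    ``objective_after <= h0`` and a strictly positive step.
    """
    grad = np.asarray(grad, dtype=np.float64)
    g2 = float(grad @ grad)
    if g2 <= 0:
        raise ValidationError("step_length requires a nonzero gradient")
    eta_l = h0 / g2
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.asarray(w, dtype=np.float64) / grad
    positive = ratios[np.isfinite(ratios) & (ratios > 0)]
    eta_m = min(eta_l, positive.min()) if positive.size else eta_l

    halvings = 0
    h_m = h_eval(eta_m)
    while h_m >= h0:
        eta_m /= 2.0
        halvings += 1
        if halvings > max_halvings or eta_m <= 0:
            raise LineSearchStalled("no decrease along the negative gradient")
        h_m = h_eval(eta_m)

    eta_best, h_best = eta_m, h_m
    h_half = h_eval(eta_m / 2.0)
    if h_half < h_best:
        eta_best, h_best = eta_m / 2.0, h_half

    # parabola h(eta) ~ a*eta^2 + b*eta + h0 through (eta_m/2, h_half), (eta_m, h_m)
    d1, d2 = h_half - h0, h_m - h0
    b_eta = (4.0 * d1 - d2) / eta_m
    a_eta = (2.0 * d2 - 4.0 * d1) / eta_m**2
    if a_eta <= 0:
        eta = eta_m
        h_eta = h_m
    else:
        eta = min(-b_eta / (2.0 * a_eta), eta_m)
        if eta == eta_m:
            h_eta = h_m
        elif eta == eta_m / 2.0:
            h_eta = h_half
        else:
            h_eta = h_eval(eta)
    if h_eta > h_best:
        eta, h_eta = eta_best, h_best
    return StepSearchResult(
        eta=float(eta),
        eta_l=float(eta_l),
        eta_m=float(eta_m),
        a_eta=float(a_eta),
        b_eta=float(b_eta),
        objective_after=float(h_eta),
        halvings=halvings,
    )


def fit_weights(
    problem: CombinerProblem,
    config: COLConfig | None = None,
    callback: Callable[[np.ndarray, float, float], None] | None = None,
) -> tuple[np.ndarray, float, SolverTrace]:
    """Alternating solver: one bias update and one gradient step per iteration.

    Starts from the uniform positive point w = 1/C, b = 0. Terminates
    when the relative objective decrease falls below ``config.rel_tol``
    (the H(w - eta g) > (1 - rel_tol) H(w) rule), when every channel has
    frozen at zero, or after ``config.max_iter`` iterations. Returns
    nonnegative weights, the final bias and the iteration trace;
    ``callback(w, h, eta)`` observes every accepted iterate.
    """
    if config is None:
        config = COLConfig()
    c = problem.n_channels
    w = np.full(c, 1.0 / c)
    active = np.ones(c, dtype=bool)
    trace = SolverTrace()
    h = reduced_objective(problem, w)

    for _ in range(config.max_iter):
        grad = gradient_w(problem, w, active)
        if not active.any() or float(grad @ grad) == 0.0:
            trace.termination = "all_frozen"
            break

        def h_eval(eta: float, w=w, grad=grad) -> float:
            # nonnegativity cap makes clipping a no-op in exact arithmetic;
            # clipping here only absorbs last-ulp overshoot
            return reduced_objective(problem, np.maximum(w - eta * grad, 0.0))

        try:
            res = step_length(w, grad, h, h_eval)
        except LineSearchStalled:
            trace.termination = "stalled"
            break
        w_new = np.maximum(w - res.eta * grad, 0.0)
        w_new[np.abs(w_new) < ZERO_SNAP] = 0.0
        active &= w_new > 0.0
        h_new = reduced_objective(problem, w_new)
        if h_new > h:  # zero-snap can only move the objective at rounding level
            h_new = h
        trace.objective.append(h_new)
        trace.step.append(res.eta)
        trace.active.append(int(active.sum()))
        if callback is not None:
            callback(w_new, h_new, res.eta)
        converged = h_new > (1.0 - config.rel_tol) * h
        w, h = w_new, h_new
        if converged:
            trace.termination = "rel_tol"
            break
    if not trace.termination:
        trace.termination = "max_iter"
    b = update_bias(problem, w)
    return w, float(b), trace


def normalize_prediction(p: np.ndarray | float, beta: float = 4.0) -> np.ndarray | float:
    """Output-normalizing logistic S(beta * (p - 0.5)); beta = 4 gives unit slope at 0.5."""
    if beta <= 0:
        raise ValidationError("beta must be positive")
    out = expit(beta * (np.asarray(p, dtype=np.float64) - 0.5))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Independent reference solver (cross-checking only)
# ---------------------------------------------------------------------------


def coordinate_descent_reference(
    P: np.ndarray,
    y: np.ndarray,
    alpha: float,
    tol: float = 1e-10,
    max_iter: int = 100000,
) -> tuple[np.ndarray, float]:
    """Projected coordinate descent for the nonnegative lasso with intercept.

    Independent reference for the corrected-mode problem
    min_{w>=0,b} 1/2 ||P w + b - y||^2 + alpha ||w||_1, used only to
    cross-check :func:`fit_weights`; it shares no code with the
    gradient-descent path. Runs full sweeps until the largest coordinate
    change falls below ``tol``.
    """
    P = np.asarray(P, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, c = P.shape
    w = np.zeros(c)
    col_sq = np.einsum("ij,ij->j", P, P)
    b = float(y.mean())
    resid = y - b - P @ w
    for _ in range(max_iter):
        delta = 0.0
        for j in range(c):
            if col_sq[j] == 0:
                continue
            rho = P[:, j] @ resid + col_sq[j] * w[j]
            w_j = max(0.0, (rho - alpha) / col_sq[j])
            if w_j != w[j]:
                resid += P[:, j] * (w[j] - w_j)
                delta = max(delta, abs(w_j - w[j]))
                w[j] = w_j
        b_new = float(np.mean(y - P @ w))
        if b_new != b:
            resid += b - b_new
            delta = max(delta, abs(b_new - b))
            b = b_new
        if delta < tol:
            break
    return w, b
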