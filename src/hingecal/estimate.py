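"""Joint-axis estimation.

Solves the weighted nonlinear least-squares problem

    min_x V(x) = sum_k e_w(k, x)^2 + e_a(k, x)^2

over the spherical parameters ``x = (theta1, phi1, theta2, phi2)`` with a
damped Gauss-Newton iteration and Armijo backtracking line search.  Because
``(+j1, +j2)`` and ``(-j1, -j2)`` describe the same physical axis while
``(+j1, -j2)`` reverses one sensor's rotation sense, the solver is run twice:
once from the supplied start and once reinitialized at the opposite sign
pairing of the first solution; the candidate with the smaller cost wins.
When the two candidate costs are numerically indistinguishable the returned
estimate is flagged ``pairing_ambiguous``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .kinematics import (AxisParams, ResidualWeights, angular_deviation,
                         axis_to_spherical, cost, residual_jacobian)

__all__ = [
    "EstimatorConfig",
    "EstimateResult",
    "gauss_newton",
    "estimate_joint_axis",
    "grid_initializations",
    "random_initialization",
    "signed_axis_errors",
    "rmsae",
    "maxae",
]


@dataclass(frozen=True)
class EstimatorConfig:
    """Solver settings.

    ``w0`` is the gyro/accel residual weight ratio (default 50).  ``v_tol``
    is the absolute cost-change stopping tolerance; ``beta`` and ``c`` are
    the backtracking shrink factor and Armijo sufficient-decrease constant.
    """

    w0: float = 50.0
    v_tol: float = 1e-10
    max_iters: int = 200
    beta: float = 0.5
    c: float = 1e-4
    min_alpha: float = 1e-8

    def __post_init__(self):
        if not (self.w0 > 0 and self.v_tol > 0 and self.max_iters > 0
                and 0 < self.beta < 1 and 0 < self.c < 1 and self.min_alpha > 0):
            raise ValueError("invalid estimator configuration")

    def weights(self) -> ResidualWeights:
        return ResidualWeights.from_w0(self.w0)


@dataclass(frozen=True)
class EstimateResult:
    """Converged estimate with both sign-pairing candidates' costs."""

    x_hat: AxisParams
    j1_hat: np.ndarray
    j2_hat: np.ndarray
    final_cost: float
    iterations: int
    converged: bool
    candidate_costs: tuple
    pairing_ambiguous: bool = False


def gauss_newton(x0, data, cfg: EstimatorConfig) -> tuple[AxisParams, float, int, bool]:
    """Damped Gauss-Newton with Armijo backtracking from ``x0``.

    Iterates ``x <- x - alpha * (J^T J + lam I)^-1 J^T e`` until the cost
    change drops below ``v_tol``, the line search fails to find a decrease,
    or ``max_iters`` is reached.  The tiny Tikhonov damping
    ``lam = 1e-12 tr(J^T J)/4`` keeps the normal solve defined on
    non-informative data where ``J^T J`` is singular.  The cost sequence is
    non-increasing by construction.
    """
    if isinstance(x0, AxisParams):
        x = x0.as_array()
    else:
        x = np.asarray(x0, dtype=float).reshape(4).copy()
    w = cfg.weights()
    V = cost(x, data, w)
    if not np.isfinite(V):
        raise ValueError("non-finite cost at the initial estimate; corrupt input?")
    converged = False
    it = 0
    for it in range(1, cfg.max_iters + 1):
        J, e = residual_jacobian(x, data, w)
        if not np.all(np.isfinite(e)):
            raise ValueError("non-finite residuals encountered; corrupt input?")
        g = J.T @ e                       # half the cost gradient
        H = J.T @ J
        lam = 1e-12 * np.trace(H) / 4.0
        try:
            dx = np.linalg.solve(H + lam * np.eye(4), g)
        except np.linalg.LinAlgError:
            dx = np.linalg.pinv(H + lam * np.eye(4)) @ g
        descent = 2.0 * float(g @ dx)     # -grad(V) . step direction
        if not np.isfinite(descent) or descent <= 0:
            converged = True
            break
        alpha = 1.0
        accepted = False
        while alpha >= cfg.min_alpha:
            V_new = cost(x - alpha * dx, data, w)
            if V_new <= V - cfg.c * alpha * descent:
                accepted = True
                break
            alpha *= cfg.beta
        if not accepted:
            converged = True              # no decrease possible: at a minimum
            break
        x = x - alpha * dx
        dV = V - V_new
        V = V_new
        if dV < cfg.v_tol:
            converged = True
            break
    return AxisParams.from_array(x), float(V), it, converged


def estimate_joint_axis(data, x0, cfg: EstimatorConfig | None = None) -> EstimateResult:
    """Full estimation with sign-pairing disambiguation.

    Runs Gauss-Newton from ``x0``, reinitializes at the flipped second axis
    of the first solution, runs again, and returns the candidate with the
    smaller cost.
    """
    if cfg is None:
        cfg = EstimatorConfig()
    x1, v1, it1, conv1 = gauss_newton(x0, data, cfg)
    x2, v2, it2, conv2 = gauss_newton(x1.flipped(), data, cfg)
    ambiguous = abs(v1 - v2) < 1e-12 * max(1.0, max(v1, v2))
    if ambiguous or v1 <= v2:
        best, v_best, conv = x1, v1, conv1
    else:
        best, v_best, conv = x2, v2, conv2
    best = best.normalized()
    return EstimateResult(x_hat=best, j1_hat=best.axis1(), j2_hat=best.axis2(),
                          final_cost=v_best, iterations=it1 + it2,
                          converged=conv, candidate_costs=(v1, v2),
                          pairing_ambiguous=ambiguous)


def grid_initializations() -> list[AxisParams]:
    """The 36 deterministic starts: all pairs of the six axis-aligned unit
    vectors for ``(j1, j2)``, covering every sign pairing equally often."""
    axes = [np.array(v, dtype=float) for v in
            [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]]
    return [AxisParams(*axis_to_spherical(a1), *axis_to_spherical(a2))
            for a1 in axes for a2 in axes]


def random_initialization(rng: np.random.Generator) -> AxisParams:
    """Area-uniform random start: each axis uniform on the unit sphere
    (``sin(theta) ~ U(-1, 1)``, ``phi ~ U(-pi, pi)``), independently."""
    u = rng.uniform(-1.0, 1.0, size=2)
    phi = rng.uniform(-math.pi, math.pi, size=2)
    th = np.arcsin(u)
    return AxisParams(th[0], phi[0], th[1], phi[1])


def signed_axis_errors(true_j1, true_j2, result: EstimateResult) -> tuple[float, float]:
    """Angular errors of one estimate under the sign-pairing convention.

    The global sign of the estimate is chosen so that ``AD(j1_hat, j1)`` is
    at most 90 deg; the same sign is then applied to ``j2_hat``, so its error
    may reach 180 deg — which flags a wrong sign pairing.
    """
    j1h, j2h = result.j1_hat, result.j2_hat
    ad1 = angular_deviation(j1h, true_j1)
    if ad1 > 90.0:
        j1h, j2h = -j1h, -j2h
        ad1 = angular_deviation(j1h, true_j1)
    ad2 = angular_deviation(j2h, true_j2)
    return ad1, ad2


def rmsae(true_j1, true_j2, results: Sequence[EstimateResult]) -> float:
    """Root-mean-square angular error over both axes and all estimates, in
    degrees: ``sqrt(1/(2M) sum_k AD1_k^2 + AD2_k^2)``."""
    if not results:
        raise ValueError("rmsae requires at least one estimate")
    sq = [ad ** 2 for r in results for ad in signed_axis_errors(true_j1, true_j2, r)]
    return math.sqrt(sum(sq) / len(sq))


def maxae(true_j1, true_j2, results: Sequence[EstimateResult]) -> float:
    """Maximum angular error over both axes and all estimates, in degrees."""
    if not results:
        raise ValueError("maxae requires at least one estimate")
    return max(ad for r in results
               for ad in signed_axis_errors(true_j1, true_j2, r))
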