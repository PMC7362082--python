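"""Trust-region dogleg root solver for the quasi-static force balance.

Solves f(x) = 0 by minimising the merit function 0.5*||f||^2 over a trust
region, combining the Newton step with the steepest-descent (Cauchy) step
along the classical dogleg path.  The network Jacobian is supplied
analytically by the caller, dense for small systems and sparse
(``scipy.sparse``) for the full protofibril chain, where the factorisation
is banded and cheap.

The network energy is strictly convex, so the Jacobian (the negative
stiffness matrix) is nonsingular and the Newton direction always exists;
the trust region only guards against overshooting in the strongly
nonlinear saturation regime of the erf bonds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = ["RootResult", "dogleg_root"]


@dataclass
class RootResult:
    x: np.ndarray
    residual_norm: float
    converged: bool
    n_iter: int


def _solve_linear(J, rhs):
    if sp.issparse(J):
        return spla.spsolve(J.tocsc(), rhs)
    return np.linalg.solve(J, rhs)


def dogleg_root(
    fun: Callable[[np.ndarray], np.ndarray],
    jac: Callable[[np.ndarray], np.ndarray],
    x0: np.ndarray,
    tol: float,
    max_iter: int = 200,
    max_radius: float = 1.0e6,
) -> RootResult:
    """Find a root of ``fun`` starting from ``x0``.

    Convergence: ||f(x)||_2 <= max(tol, floor), where the floor is the
    machine-precision quantization limit ~ eps * ||J|| * ||x|| -- residual
    components below it are unreachable because the corresponding
    displacement updates are smaller than the spacing of floating-point
    numbers near x (relevant only for near-rigid spring stiffnesses).
    Non-convergence is reported through ``converged=False``, never raised;
    the continuation loop interprets a stalled solve as mechanical failure
    of the fiber.
    """
    x = np.array(x0, dtype=float, copy=True)
    if x.size == 0:
        return RootResult(x, 0.0, True, 0)
    r = np.asarray(fun(x), dtype=float)
    rnorm = float(np.linalg.norm(r))
    radius = None
    eff_tol = tol
    eps = float(np.finfo(float).eps)

    for it in range(max_iter):
        if rnorm <= eff_tol:
            return RootResult(x, rnorm, True, it)

        J = jac(x)
        Jnorm = (
            float(abs(J).sum(axis=1).max()) if sp.issparse(J)
            else float(np.abs(J).sum(axis=1).max())
        )
        xnorm = float(np.max(np.abs(x))) if x.size else 0.0
        eff_tol = max(tol, 32.0 * eps * Jnorm * (1.0 + xnorm))
        if rnorm <= eff_tol:
            return RootResult(x, rnorm, True, it)
        try:
            p_newton = _solve_linear(J, -r)
        except Exception:
            p_newton = None
        if p_newton is not None and not np.all(np.isfinite(p_newton)):
            p_newton = None

        g = J.T @ r  # gradient of the merit function
        Jg = J @ g
        gg = float(g @ g)
        JgJg = float(Jg @ Jg)

        if radius is None:
            guess = np.linalg.norm(p_newton) if p_newton is not None else 1.0
            radius = max(1.0, 2.0 * float(guess))

        accepted = False
        for _ in range(40):  # shrink the trust region until a step is accepted
            step = _dogleg_step(p_newton, g, gg, JgJg, radius)
            if step is None:
                break
            r_trial = np.asarray(fun(x + step), dtype=float)
            trial_norm = float(np.linalg.norm(r_trial))
            pred = 0.5 * rnorm**2 - 0.5 * float(np.linalg.norm(r + J @ step)) ** 2
            actual = 0.5 * rnorm**2 - 0.5 * trial_norm**2
            rho = actual / pred if pred > 0 else (1.0 if actual > 0 else -1.0)

            step_len = float(np.linalg.norm(step))
            if rho < 0.25:
                radius = 0.25 * step_len
            elif rho > 0.75 and step_len >= 0.9 * radius:
                radius = min(2.0 * radius, max_radius)

            if rho > 1.0e-4 and np.all(np.isfinite(r_trial)):
                x = x + step
                r = r_trial
                rnorm = trial_norm
                accepted = True
                break
            if radius < 1e-14 * (1.0 + float(np.linalg.norm(x))):
                break
        if not accepted:
            return RootResult(x, rnorm, rnorm <= eff_tol, it + 1)

    return RootResult(x, rnorm, rnorm <= eff_tol, max_iter)


def _dogleg_step(p_newton, g, gg, JgJg, radius):
    """Classical dogleg path: Newton inside the region, else blend with Cauchy."""
    if p_newton is not None:
        pn_len = float(np.linalg.norm(p_newton))
        if pn_len <= radius:
            return p_newton
    if gg <= 0.0 or JgJg <= 0.0:
        return None
    p_cauchy = -(gg / JgJg) * g
    pc_len = float(np.linalg.norm(p_cauchy))
    if p_newton is None or pc_len >= radius:
        return -(radius / float(np.linalg.norm(g))) * g
    # intersection of the segment Cauchy -> Newton with the region boundary
    d = p_newton - p_cauchy
    a = float(d @ d)
    b = 2.0 * float(p_cauchy @ d)
    c = pc_len**2 - radius**2
    disc = max(b * b - 4 * a * c, 0.0)
    t = (-b + np.sqrt(disc)) / (2 * a) if a > 0 else 0.0
    t = min(max(t, 0.0), 1.0)
    return p_cauchy + t * d
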