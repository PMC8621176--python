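"""Alternating split-Bregman solver for the two-player game and the
single-player baseline.

Each outer iteration performs one Gauss-Seidel sweep over the two players:

1. ``update_g``        — spectral solve of the image player's linear system
2. ``shrink_isotropic``— closed-form prox of the isotropic L1 on ``grad g``
3. Bregman update of the first split variable
4. ``update_G``        — per-component spectral solve for the gradient player
5. ``shrink_anisotropic`` — component-wise prox of the L1 on the Jacobian
6. Bregman update of the second split variable

Every linear sub-step is the exact minimiser of its quadratic sub-problem
(the gradient operator's boundary convention follows the transform mode, so
the transform diagonalises the exact normal equations).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .grid_ops import VectorField, gradient, gradient_adjoint, solve_screened
from .model_core import (
    JacobianField,
    SolverParams,
    energy_E1,
    energy_E2,
    energy_ccz,
    jacobian,
)

__all__ = [
    "DivergenceError",
    "GameState",
    "SolveReport",
    "bregman_update",
    "run_ccz",
    "run_game",
    "shrink_anisotropic",
    "shrink_isotropic",
    "update_G",
    "update_g",
]


class DivergenceError(ArithmeticError):
    """Raised when an iterate becomes non-finite; names the offending step."""


@dataclass
class GameState:
    """All solver variables at one outer iteration."""

    g: np.ndarray
    G: VectorField
    v: VectorField
    b1: VectorField
    w: JacobianField
    b2: JacobianField
    iteration: int = 0

    @classmethod
    def initial(cls, f: np.ndarray) -> "GameState":
        """Conventional split-Bregman start: g = f, everything else zero."""
        z = lambda: np.zeros_like(f)  # noqa: E731
        zv = lambda: VectorField(z(), z())  # noqa: E731
        zj = lambda: JacobianField(zv(), zv())  # noqa: E731
        return cls(g=f.astype(float).copy(), G=zv(), v=zv(), b1=zv(), w=zj(), b2=zj())


@dataclass
class SolveReport:
    iterations_run: int = 0
    relative_changes: list[float] = field(default_factory=list)
    E1_trace: list[float] = field(default_factory=list)
    E2_trace: list[float] = field(default_factory=list)
    converged: bool = False

    def to_dict(self) -> dict:
        return {
            "iterations_run": self.iterations_run,
            "relative_changes": self.relative_changes,
            "E1_trace": self.E1_trace,
            "E2_trace": self.E2_trace,
            "converged": self.converged,
        }


def update_g(state: GameState, f: np.ndarray, p: SolverParams) -> np.ndarray:
    """Exact minimiser of the image player's quadratic sub-problem.

    Solves ``(lambda1*I + (mu1+xi1+rho1) grad_T grad) g
    = lambda1 f + xi1 grad_T G + rho1 grad_T (v - b1)``.
    """
    mode = p.transform_mode
    rhs = p.lambda1 * f
    rhs = rhs + p.xi1 * gradient_adjoint(state.G, mode)
    vhat = VectorField(state.v.x - state.b1.x, state.v.y - state.b1.y)
    rhs = rhs + p.rho1 * gradient_adjoint(vhat, mode)
    return solve_screened(rhs, p.lambda1, p.mu1 + p.xi1 + p.rho1, mode)


def shrink_isotropic(s: VectorField, kappa: float) -> VectorField:
    """Generalised (isotropic) shrinkage: prox of ``kappa * ||.||_2`` per pixel.

    Shrinks the per-pixel magnitude by ``kappa``, preserving direction;
    exactly (0, 0) where the magnitude is 0.
    """
    if kappa <= 0:
        raise ValueError(f"kappa must be > 0, got {kappa}")
    m = np.hypot(s.x, s.y)
    # max(m - kappa, 0) is 0 wherever m is, so the guard value never leaks
    scale = np.maximum(m - kappa, 0.0) / np.where(m > 0, m, 1.0)
    return VectorField(scale * s.x, scale * s.y)


def update_G(state: GameState, f: np.ndarray, p: SolverParams) -> VectorField:
    """Exact minimiser of the gradient player's quadratic sub-problem.

    Each component solves ``((lambda2+xi2)*I + (mu2+rho2) grad_T grad) Gc
    = lambda2 (grad f)_c + xi2 (grad g)_c + rho2 grad_T (w - b2)_c``.
    """
    if p.lambda2 + p.xi2 <= 0:
        raise ValueError("lambda2 + xi2 must be > 0")
    mode = p.transform_mode
    df = gradient(f, mode)
    dg = gradient(state.g, mode)
    out = []
    for c, (wc, bc) in enumerate(
        ((state.w.dGx, state.b2.dGx), (state.w.dGy, state.b2.dGy))
    ):
        what = VectorField(wc.x - bc.x, wc.y - bc.y)
        rhs = p.lambda2 * (df.x if c == 0 else df.y)
        rhs = rhs + p.xi2 * (dg.x if c == 0 else dg.y)
        rhs = rhs + p.rho2 * gradient_adjoint(what, mode)
        out.append(solve_screened(rhs, p.lambda2 + p.xi2, p.mu2 + p.rho2, mode))
    return VectorField(out[0], out[1])


def shrink_anisotropic(r: JacobianField, kappa: float) -> JacobianField:
    """Component-wise soft-thresholding on all four Jacobian channels."""
    if kappa <= 0:
        raise ValueError(f"kappa must be > 0, got {kappa}")

    def soft(c: np.ndarray) -> np.ndarray:
        return np.sign(c) * np.maximum(np.abs(c) - kappa, 0.0)

    return JacobianField(
        VectorField(soft(r.dGx.x), soft(r.dGx.y)),
        VectorField(soft(r.dGy.x), soft(r.dGy.y)),
    )


def _tree_op(op: Callable[[np.ndarray, ...], np.ndarray], *fields):
    """Apply a numpy operation leaf-wise across matching nested field tuples."""
    head = fields[0]
    if isinstance(head, np.ndarray):
        shapes = {f.shape for f in fields}
        if len(shapes) != 1:
            raise ValueError(f"shape mismatch across operands: {shapes}")
        return op(*fields)
    return type(head)(*(_tree_op(op, *parts) for parts in zip(*fields)))


def bregman_update(b, target, auxiliary):
    """Bregman (dual) update ``b + target - auxiliary``, component-wise.

    Works for vector fields and Jacobian fields alike; ``target`` is the
    constrained derivative (``grad g`` or ``grad G``), ``auxiliary`` the
    split variable (``v`` or ``w``).
    """
    return _tree_op(lambda b_, t_, a_: b_ + t_ - a_, b, target, auxiliary)


def _assert_finite(arr: np.ndarray, step: str, iteration: int) -> None:
    if not np.all(np.isfinite(arr)):
        raise DivergenceError(
            f"non-finite values produced by step {step!r} at outer iteration {iteration}"
        )


def run_game(
    f: np.ndarray, p: SolverParams, track_energies: bool = True
) -> tuple[GameState, SolveReport]:
    """Run the alternating split-Bregman scheme for the two-player game.

    Stops when the relative changes of BOTH players' variables (``g`` and
    ``G``) drop to ``p.tol``, or ``p.max_outer`` iterations elapse; the
    recorded per-iteration relative change is the larger of the two.
    Requiring both players guarantees the converged state is a numerical
    fixed point of each player's own update.  Fully deterministic.
    """
    f = np.asarray(f, dtype=float)
    if f.ndim != 2:
        raise ValueError(f"input image must be 2-D, got shape {f.shape}")
    if not np.all(np.isfinite(f)):
        raise ValueError("input image contains non-finite values")
    mode = p.transform_mode
    state = GameState.initial(f)
    report = SolveReport()
    for k in range(p.max_outer):
        g_prev = state.g
        G_prev = state.G
        state.g = update_g(state, f, p)
        _assert_finite(state.g, "update_g", k)
        dg = gradient(state.g, mode)
        s = VectorField(dg.x + state.b1.x, dg.y + state.b1.y)
        state.v = shrink_isotropic(s, 1.0 / p.rho1)
        state.b1 = bregman_update(state.b1, dg, state.v)
        _assert_finite(state.b1.x, "bregman_update(b1)", k)
        state.G = update_G(state, f, p)
        _assert_finite(state.G.x, "update_G", k)
        _assert_finite(state.G.y, "update_G", k)
        dG = jacobian(state.G, mode)
        r = _tree_op(lambda a, b: a + b, dG, state.b2)
        state.w = shrink_anisotropic(r, 1.0 / p.rho2)
        state.b2 = bregman_update(state.b2, dG, state.w)
        _assert_finite(state.b2.dGx.x, "bregman_update(b2)", k)
        state.iteration = k + 1

        tiny = np.finfo(float).tiny
        rel_g = float(np.linalg.norm(state.g - g_prev) / max(np.linalg.norm(g_prev), tiny))
        dG_norm = np.sqrt(
            np.linalg.norm(state.G.x - G_prev.x) ** 2
            + np.linalg.norm(state.G.y - G_prev.y) ** 2
        )
        G_norm = np.sqrt(np.linalg.norm(G_prev.x) ** 2 + np.linalg.norm(G_prev.y) ** 2)
        # first iteration starts from G = 0; fall back to the new G's norm
        if G_norm == 0.0:
            G_norm = np.sqrt(np.linalg.norm(state.G.x) ** 2 + np.linalg.norm(state.G.y) ** 2)
        rel_G = float(dG_norm / max(G_norm, tiny))
        rel = max(rel_g, rel_G)
        report.relative_changes.append(rel)
        if track_energies:
            report.E1_trace.append(energy_E1(f, state.g, state.G, p))
            report.E2_trace.append(energy_E2(f, state.G, state.g, p))
        report.iterations_run = k + 1
        if rel <= p.tol:
            report.converged = True
            break
    return state, report


def run_ccz(
    f: np.ndarray, p: SolverParams, track_energies: bool = True
) -> tuple[np.ndarray, SolveReport]:
    """Split-Bregman solver for the single-player baseline energy.

    Reuses the ``g`` machinery with the coupling switched off (no ``G``/``w``
    player): solve ``(lambda1*I + (mu1+rho1) grad_T grad) g
    = lambda1 f + rho1 grad_T (v - b1)``, shrink, Bregman-update.
    """
    f = np.asarray(f, dtype=float)
    if f.ndim != 2:
        raise ValueError(f"input image must be 2-D, got shape {f.shape}")
    if not np.all(np.isfinite(f)):
        raise ValueError("input image contains non-finite values")
    mode = p.transform_mode
    g = f.astype(float).copy()
    v = VectorField(np.zeros_like(g), np.zeros_like(g))
    b1 = VectorField(np.zeros_like(g), np.zeros_like(g))
    report = SolveReport()
    for k in range(p.max_outer):
        g_prev = g
        vhat = VectorField(v.x - b1.x, v.y - b1.y)
        rhs = p.lambda1 * f + p.rho1 * gradient_adjoint(vhat, mode)
        g = solve_screened(rhs, p.lambda1, p.mu1 + p.rho1, mode)
        _assert_finite(g, "update_g", k)
        dg = gradient(g, mode)
        v = shrink_isotropic(VectorField(dg.x + b1.x, dg.y + b1.y), 1.0 / p.rho1)
        b1 = bregman_update(b1, dg, v)
        _assert_finite(b1.x, "bregman_update(b1)", k)

        denom = np.linalg.norm(g_prev)
        rel = float(np.linalg.norm(g - g_prev) / max(denom, np.finfo(float).tiny))
        report.relative_changes.append(rel)
        if track_energies:
            report.E1_trace.append(energy_ccz(f, g, p))
        report.iterations_run = k + 1
        if rel <= p.tol:
            report.converged = True
            break
    return g, report
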