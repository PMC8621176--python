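"""Solver parameters and evaluable energies for the two players and the
single-player baseline.

The first player smooths the image (variable ``g``); the second player
smooths an approximate image gradient (variable ``G``); a quadratic coupling
term ties ``G`` to ``grad g``.  The baseline (``energy_ccz``) is the
classical smooth-then-threshold energy with first-order regularisation only.

All energies are evaluated on the native intensity scale (by convention
0-255); rescaling the image requires rescaling the fidelity weights.
"""

from __future__ import annotations

import ast
from dataclasses import dataclass, fields as _dc_fields
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .grid_ops import MODES, VectorField, gradient

__all__ = [
    "JacobianField",
    "SolverParams",
    "energy_E1",
    "energy_E2",
    "energy_ccz",
    "jacobian",
]

JACOBIAN_NORMS = ("anisotropic", "divergence")


@dataclass
class SolverParams:
    """Model weights and algorithm constants.

    ``lambda1, mu1, xi1, rho1`` weight the image player's fidelity,
    quadratic smoothness, coupling and split penalty; ``lambda2, mu2, xi2,
    rho2`` the same for the gradient player.  The L1 terms carry unit
    weight, so their shrinkage thresholds are ``1/rho1`` and ``1/rho2``.

    Defaults are a neutral starting point; no canonical values exist.  As a
    tuning guide, ``lambda1`` scales inversely with the noise level (more
    noise -> smaller ``lambda1`` -> stronger smoothing).
    """

    lambda1: float = 1.0
    mu1: float = 1.0
    xi1: float = 1.0
    rho1: float = 1.0
    lambda2: float = 1.0
    mu2: float = 1.0
    xi2: float = 1.0
    rho2: float = 1.0
    max_outer: int = 500
    tol: float = 1e-4
    transform_mode: str = "periodic"
    jacobian_norm: str = "anisotropic"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("lambda1", "mu1", "xi1", "rho1", "lambda2", "mu2", "xi2", "rho2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be > 0, got {getattr(self, name)}")
        if self.tol <= 0:
            raise ValueError(f"tol must be > 0, got {self.tol}")
        if self.max_outer < 1:
            raise ValueError(f"max_outer must be >= 1, got {self.max_outer}")
        if self.transform_mode not in MODES:
            raise ValueError(f"transform_mode must be one of {MODES}")
        if self.jacobian_norm not in JACOBIAN_NORMS:
            raise ValueError(f"jacobian_norm must be one of {JACOBIAN_NORMS}")

    def to_config(self, path: str | Path) -> None:
        """Write a flat ``key = value`` config file, one scalar per line."""
        lines = [f"{f.name} = {getattr(self, f.name)}" for f in _dc_fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_config(cls, path: str | Path) -> "SolverParams":
        """Read a flat key-value config written by :meth:`to_config`."""
        known = {f.name: f.type for f in _dc_fields(cls)}
        kwargs: dict[str, object] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
            key, raw = (part.strip() for part in line.split("=", 1))
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
            if key in ("transform_mode", "jacobian_norm"):
                kwargs[key] = raw
            else:
                kwargs[key] = ast.literal_eval(raw)
        return cls(**kwargs)


class JacobianField(NamedTuple):
    """Gradients of both components of a vector field: four scalar channels."""

    dGx: VectorField
    dGy: VectorField

    def channels(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        return (self.dGx.x, self.dGx.y, self.dGy.x, self.dGy.y)


def jacobian(G: VectorField, mode: str = "symmetric") -> JacobianField:
    """Backward-difference Jacobian of a vector field (four channels)."""
    return JacobianField(gradient(G.x, mode), gradient(G.y, mode))


def _sq(arr: np.ndarray) -> float:
    return float(np.sum(arr * arr))


def energy_E1(f: np.ndarray, g: np.ndarray, G: VectorField, p: SolverParams) -> float:
    """Image player's energy.

    ``lambda1/2 ||f-g||^2 + mu1/2 ||grad g||^2 + ||grad g||_1
    + xi1/2 ||G - grad g||^2`` with the isotropic (per-pixel magnitude) L1.
    """
    f = np.asarray(f, dtype=float)
    g = np.asarray(g, dtype=float)
    if f.shape != g.shape or G.x.shape != f.shape:
        raise ValueError(
            f"shape mismatch: f {f.shape}, g {g.shape}, G {G.x.shape}"
        )
    dg = gradient(g, p.transform_mode)
    e = 0.5 * p.lambda1 * _sq(f - g)
    e += 0.5 * p.mu1 * (_sq(dg.x) + _sq(dg.y))
    e += float(np.sum(dg.magnitude()))
    e += 0.5 * p.xi1 * (_sq(G.x - dg.x) + _sq(G.y - dg.y))
    return e


def energy_E2(f: np.ndarray, G: VectorField, g: np.ndarray, p: SolverParams) -> float:
    """Gradient player's energy.

    ``lambda2/2 ||grad f - G||^2 + mu2/2 ||grad G||^2 + ||grad G||_1
    + xi2/2 ||G - grad g||^2``.  The L1 term follows ``p.jacobian_norm``:
    ``anisotropic`` sums |.| over all four Jacobian channels (consistent
    with the component-wise shrinkage used by the solver), ``divergence``
    sums |dGx/dx + dGy/dy|.
    """
    f = np.asarray(f, dtype=float)
    g = np.asarray(g, dtype=float)
    if f.shape != g.shape or G.x.shape != f.shape or G.y.shape != f.shape:
        raise ValueError(
            f"shape mismatch: f {f.shape}, g {g.shape}, G {G.x.shape}/{G.y.shape}"
        )
    mode = p.transform_mode
    df = gradient(f, mode)
    dg = gradient(g, mode)
    J = jacobian(G, mode)
    e = 0.5 * p.lambda2 * (_sq(df.x - G.x) + _sq(df.y - G.y))
    e += 0.5 * p.mu2 * sum(_sq(c) for c in J.channels())
    if p.jacobian_norm == "anisotropic":
        e += float(sum(np.sum(np.abs(c)) for c in J.channels()))
    else:
        e += float(np.sum(np.abs(J.dGx.x + J.dGy.y)))
    e += 0.5 * p.xi2 * (_sq(G.x - dg.x) + _sq(G.y - dg.y))
    return e


def energy_ccz(f: np.ndarray, g: np.ndarray, p: SolverParams) -> float:
    """Single-player baseline energy: ``lambda/2 ||f-g||^2 + mu/2 ||grad g||^2
    + ||grad g||_1`` (reusing ``lambda1``/``mu1`` as the weights)."""
    f = np.asarray(f, dtype=float)
    g = np.asarray(g, dtype=float)
    if f.shape != g.shape:
        raise ValueError(f"shape mismatch: f {f.shape}, g {g.shape}")
    dg = gradient(g, p.transform_mode)
    e = 0.5 * p.lambda1 * _sq(f - g)
    e += 0.5 * p.mu1 * (_sq(dg.x) + _sq(dg.y))
    e += float(np.sum(dg.magnitude()))
    return e
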