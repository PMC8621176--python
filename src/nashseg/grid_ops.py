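"""Discrete differential operators and spectral solvers on regular 2-D grids.

Two boundary/transform conventions are supported throughout:

``"periodic"``
    Backward differences with wrap-around.  ``grad_T @ grad`` is the
    circulant 5-point Laplacian, diagonalised by the 2-D DFT.
``"symmetric"``
    Backward differences with a zero (replicate) first row/column, the
    zero-Neumann convention.  ``grad_T @ grad`` is the Neumann 5-point
    Laplacian, diagonalised by the DCT-II.

In either convention ``gradient_adjoint`` is the exact matrix transpose of
``gradient``, and ``solve_screened`` inverts ``a*I + b*grad_T@grad`` to
spectral accuracy for the matching Laplacian.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy import fft as _fft

__all__ = [
    "MODES",
    "VectorField",
    "gradient",
    "gradient_adjoint",
    "laplacian_symbol",
    "solve_screened",
]

MODES = ("periodic", "symmetric")


class VectorField(NamedTuple):
    """A pair of same-shaped 2-D arrays: (x-component, y-component).

    The x-component varies along columns (axis 1), the y-component along
    rows (axis 0).
    """

    x: np.ndarray
    y: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.x.shape

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.x, self.y)


def _as_field(u: np.ndarray, name: str = "field") -> np.ndarray:
    u = np.asarray(u, dtype=float)
    if u.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {u.shape}")
    return u


def _check_mode(mode: str) -> None:
    if mode not in MODES:
        raise ValueError(f"unknown transform mode {mode!r}; expected one of {MODES}")


def gradient(u: np.ndarray, mode: str = "symmetric") -> VectorField:
    """Backward-difference gradient of a scalar field.

    In ``symmetric`` mode the difference is 0 on the first row/column
    (replicate padding, zero-Neumann); in ``periodic`` mode it wraps.
    """
    u = _as_field(u)
    _check_mode(mode)
    if mode == "periodic":
        gx = u - np.roll(u, 1, axis=1)
        gy = u - np.roll(u, 1, axis=0)
    else:
        gx = np.zeros_like(u)
        gy = np.zeros_like(u)
        gx[:, 1:] = u[:, 1:] - u[:, :-1]
        gy[1:, :] = u[1:, :] - u[:-1, :]
    return VectorField(gx, gy)


def gradient_adjoint(p: VectorField, mode: str = "symmetric") -> np.ndarray:
    """Exact adjoint of :func:`gradient` under the Euclidean inner product.

    Equals the transpose of the sparse difference matrix of the matching
    mode; a forward-difference negative divergence.
    """
    px = _as_field(p.x, "p.x")
    py = _as_field(p.y, "p.y")
    if px.shape != py.shape:
        raise ValueError(f"component shape mismatch: {px.shape} vs {py.shape}")
    _check_mode(mode)
    if mode == "periodic":
        out = px - np.roll(px, -1, axis=1)
        out += py - np.roll(py, -1, axis=0)
    else:
        out = np.zeros_like(px)
        out[:, 1:] += px[:, 1:]
        out[:, :-1] -= px[:, 1:]
        out[1:, :] += py[1:, :]
        out[:-1, :] -= py[1:, :]
    return out


def laplacian_symbol(shape: tuple[int, int], mode: str = "periodic") -> np.ndarray:
    """Per-frequency eigenvalues of ``grad_T @ grad`` under the given transform.

    Periodic mode: ``2(2 - cos(2 pi k/H) - cos(2 pi l/W))`` (DFT symbol of
    the circulant 5-point Laplacian).  Symmetric mode: the DCT-II symbol
    ``(2 - 2 cos(pi k/H)) + (2 - 2 cos(pi l/W))`` of the Neumann Laplacian.
    The zero-frequency entry is exactly 0 and all entries are >= 0.
    """
    _check_mode(mode)
    H, W = int(shape[0]), int(shape[1])
    if H < 2 or W < 2:
        raise ValueError(f"grid must be at least 2x2, got {(H, W)}")
    if mode == "periodic":
        wy = 2.0 - 2.0 * np.cos(2.0 * np.pi * np.arange(H) / H)
        wx = 2.0 - 2.0 * np.cos(2.0 * np.pi * np.arange(W) / W)
    else:
        wy = 2.0 - 2.0 * np.cos(np.pi * np.arange(H) / H)
        wx = 2.0 - 2.0 * np.cos(np.pi * np.arange(W) / W)
    sym = wy[:, None] + wx[None, :]
    sym[0, 0] = 0.0
    return sym


def solve_screened(
    rhs: np.ndarray, a: float, b: float, mode: str = "periodic"
) -> np.ndarray:
    """Solve ``(a*I + b*grad_T@grad) x = rhs`` by a fast transform.

    ``a`` must be strictly positive (the Laplacian symbol is >= 0, so the
    system is then positive definite).  ``b`` may be zero, in which case the
    solve degenerates to ``rhs / a``.
    """
    rhs = _as_field(rhs, "rhs")
    if a <= 0:
        raise ValueError(f"screening coefficient a must be > 0, got {a}")
    if b < 0:
        raise ValueError(f"Laplacian coefficient b must be >= 0, got {b}")
    _check_mode(mode)
    if b == 0:
        return rhs / a
    denom = a + b * laplacian_symbol(rhs.shape, mode)
    if mode == "periodic":
        return np.real(_fft.ifft2(_fft.fft2(rhs) / denom))
    coef = _fft.dctn(rhs, type=2, norm="ortho")
    return _fft.idctn(coef / denom, type=2, norm="ortho")
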