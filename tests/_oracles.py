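"""Independent sparse-matrix oracles for the difference operators.

Assembled from scratch with scipy.sparse so tests can compare the package's
fast array implementations against explicit linear algebra.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp


def backward_diff_1d(n: int, periodic: bool) -> sp.csr_matrix:
    """1-D backward-difference matrix; zero first row unless periodic."""
    D = sp.lil_matrix((n, n))
    for j in range(1, n):
        D[j, j] = 1.0
        D[j, j - 1] = -1.0
    if periodic:
        D[0, 0] = 1.0
        D[0, n - 1] = -1.0
    return D.tocsr()


def diff_matrices(H: int, W: int, mode: str) -> tuple[sp.csr_matrix, sp.csr_matrix]:
    """(Dx, Dy) acting on row-major flattened H x W fields."""
    periodic = mode == "periodic"
    Dx = sp.kron(sp.identity(H), backward_diff_1d(W, periodic), format="csr")
    Dy = sp.kron(backward_diff_1d(H, periodic), sp.identity(W), format="csr")
    return Dx, Dy


def laplacian_matrix(H: int, W: int, mode: str) -> np.ndarray:
    Dx, Dy = diff_matrices(H, W, mode)
    return (Dx.T @ Dx + Dy.T @ Dy).toarray()
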