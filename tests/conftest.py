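"""Shared helpers: dense-matrix oracles and small random problem instances."""

import numpy as np
import pytest

from zsrecon.fourier_ops import forward_op, adjoint_op


def random_instance(rng, ny=8, nx=8, n_coils=2, pf=False):
    """Random complex image, RSS-normalized coil maps, and a random mask."""
    x = rng.normal(size=(ny, nx)) + 1j * rng.normal(size=(ny, nx))
    S = rng.normal(size=(n_coils, ny, nx)) + 1j * rng.normal(size=(n_coils, ny, nx))
    S /= np.sqrt((np.abs(S) ** 2).sum(axis=0))[None]
    mask = (rng.random((ny, nx)) < 0.5).astype(np.float64)
    if pf:  # emulate partial Fourier: drop the highest positive-frequency rows
        mask[-max(1, ny // 4):, :] = 0.0
    if not mask.any():
        mask[ny // 2, nx // 2] = 1.0
    return x, S, mask


def dense_forward_matrix(S, mask):
    """Dense matrix of A = P F S, shape (C*ny*nx, ny*nx), built column by column."""
    C, ny, nx = S.shape
    n = ny * nx
    A = np.zeros((C * n, n), dtype=np.complex128)
    for i in range(n):
        e = np.zeros(n, dtype=np.complex128)
        e[i] = 1.0
        A[:, i] = np.asarray(forward_op(e.reshape(ny, nx), S, mask)).ravel()
    return A


def dense_normal_solve(rhs, S, mask, lam):
    """Independent dense solve of (A^H A + lam I) x = rhs (min-norm for lam=0)."""
    ny, nx = rhs.shape
    A = dense_forward_matrix(S, mask)
    M = A.conj().T @ A + lam * np.eye(ny * nx)
    b = rhs.ravel()
    if lam == 0:
        sol = np.linalg.pinv(M, rcond=1e-12) @ b
    else:
        sol = np.linalg.solve(M, b)
    return sol.reshape(ny, nx)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
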