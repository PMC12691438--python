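"""Centered unitary Fourier transforms, SENSE forward/adjoint operators,
and conjugate-gradient solvers.

The encoding model for parallel MRI is ``y_c = P_Omega F S_c x + eps_c``:
each receiver coil sees the object ``x`` modulated by its complex
sensitivity profile ``S_c``; the scanner measures the Fourier transform of
that coil image on the acquired index set Omega.  ``A = P F S`` denotes the
full multicoil forward operator.

All functions accept plain numpy arrays or autodiff Tensors; gradients flow
through every operation (including the fixed-iteration CG solve) when
Tensors are supplied, which is what lets the unrolled model train its
regularization weights through the data-consistency step.

Conventions: the DC (zero-frequency) sample sits at index ``floor(N/2)`` on
each axis; transforms are unitary (1/sqrt(N) both ways), so Parseval holds
exactly and ``A^H A`` has spectrum in [0, 1] for RSS-normalized maps.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, asarray

__all__ = ["centered_fft", "forward_op", "adjoint_op", "cg_normal_solve", "cg_sense"]


def centered_fft(img, direction: str = "forward"):
    """Centered orthonormal 2-D DFT of ``img`` (last two axes).

    Parameters
    ----------
    img : (..., ny, nx) complex array or Tensor
    direction : "forward" or "inverse"

    The inverse is the exact adjoint and exact inverse of the forward
    transform (unitary normalization, shift-transform-shift centering).
    """
    data = asarray(img)
    if data.ndim < 2:
        raise ValueError(f"expected at least a 2-D grid, got shape {data.shape}")
    if direction == "forward":
        return ad.fft2c(img)
    if direction == "inverse":
        return ad.ifft2c(img)
    raise ValueError(f"direction must be 'forward' or 'inverse', got {direction!r}")


def _check_shapes(x, S, mask):
    xs, Ss, ms = asarray(x).shape, asarray(S).shape, asarray(mask).shape
    if xs != Ss[1:]:
        raise ValueError(f"image shape {xs} does not match sensitivities {Ss}")
    if ms != xs:
        raise ValueError(f"mask shape {ms} does not match image shape {xs}")


def forward_op(x, S, mask):
    """Multicoil SENSE forward operator ``A x = P (F (S_c * x))_c``.

    Returns per-coil k-space, zero at unsampled locations.
    """
    _check_shapes(x, S, mask)
    coil_imgs = ad.mul(S, x)          # (C, ny, nx) via broadcasting
    ksp = ad.fft2c(coil_imgs)
    return ad.mul(ksp, asarray(mask))


def adjoint_op(y, S, mask):
    """Adjoint ``A^H y = sum_c conj(S_c) * F^H (P y_c)``; coil-combined image."""
    yd, Sd, md = asarray(y), asarray(S), asarray(mask)
    if yd.shape != Sd.shape:
        raise ValueError(f"k-space shape {yd.shape} does not match sensitivities {Sd.shape}")
    if md.shape != yd.shape[1:]:
        raise ValueError(f"mask shape {md.shape} does not match grid {yd.shape[1:]}")
    imgs = ad.ifft2c(ad.mul(y, md))
    weighted = ad.mul(imgs, ad.conj(S) if isinstance(S, Tensor) else np.conj(Sd))
    # sum over coils
    if isinstance(weighted, Tensor):
        out = ad.unstack(weighted, 0)
        for c in range(1, yd.shape[0]):
            out = ad.add(out, ad.unstack(weighted, c))
        return out
    return weighted.sum(axis=0)


def _normal_op(x, S, mask, lam):
    """(A^H A + lam I) x."""
    Ax = forward_op(x, S, mask)
    out = adjoint_op(Ax, S, mask)
    if isinstance(lam, Tensor) or (np.ndim(asarray(lam)) == 0 and float(asarray(lam)) != 0.0):
        out = ad.add(out, ad.mul(lam, x))
    return out


def cg_normal_solve(rhs, S, mask, lambda_total=0.0, n_iter: int = 10, tol: float | None = None):
    """Solve ``(A^H A + lambda I) x = rhs`` by complex conjugate gradients.

    Runs exactly ``n_iter`` iterations from ``x = 0`` (no early exit unless
    ``tol`` is given or the residual vanishes).  When ``rhs`` or
    ``lambda_total`` carry gradients the whole iteration is recorded on the
    tape and differentiated through.

    Raises on non-finite inputs and on divergence (residual growing by more
    than 1e6 over its initial value).
    """
    rhs_d = asarray(rhs)
    if not np.all(np.isfinite(rhs_d)):
        raise ValueError("cg_normal_solve: non-finite values in rhs")
    lam_d = float(np.real(asarray(lambda_total))) if not isinstance(lambda_total, Tensor) \
        else float(asarray(lambda_total))
    if lam_d < 0:
        raise ValueError("lambda_total must be nonnegative")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")

    x = np.zeros_like(rhs_d) if not isinstance(rhs, Tensor) else Tensor(np.zeros_like(rhs_d))
    r = rhs
    p = r
    rho = ad.vdot_real(r, r)
    rho0 = float(asarray(rho))
    if rho0 == 0.0:
        return x

    for _ in range(n_iter):
        Ap = _normal_op(p, S, mask, lambda_total)
        pAp = ad.vdot_real(p, Ap)
        if float(asarray(pAp)) <= 0:
            break  # numerically singular direction; x is the best estimate so far
        alpha = ad.div(rho, pAp)
        x = ad.add(x, ad.mul(alpha, p))
        r = ad.sub(r, ad.mul(alpha, Ap))
        rho_new = ad.vdot_real(r, r)
        res = float(asarray(rho_new))
        if not np.isfinite(res) or res > 1e12 * rho0:
            raise RuntimeError(
                f"cg_normal_solve diverged: |r|^2 grew from {rho0:.3e} to {res:.3e}"
            )
        if res == 0.0 or (tol is not None and np.sqrt(res / rho0) < tol):
            break
        beta = ad.div(rho_new, rho)
        p = ad.add(r, ad.mul(beta, p))
        rho = rho_new
    return x


def cg_sense(y, S, mask, n_iter: int = 15, tol: float | None = None):
    """Unregularized least-squares SENSE: argmin_x ||P F S x - y||_2.

    Solved via CG on the normal equations with the zero-filled adjoint as
    right-hand side.  Rejects an all-zero mask (the system is singular).
    """
    md = asarray(mask)
    if not md.any():
        raise ValueError("cg_sense: empty sampling mask, system is singular")
    rhs = adjoint_op(y, S, mask)
    return cg_normal_solve(rhs, S, mask, 0.0, n_iter, tol=tol)
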