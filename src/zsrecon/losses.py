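"""K-space training losses: conventional normalized l1/l2, log-scaled, combined.

Self-supervised k-space losses are dominated by the low-frequency samples,
which hold almost all the signal energy; residuals at high spatial
frequencies then contribute almost nothing to the gradient.  The log-scaled
loss compresses the dynamic range of the residual magnitudes,

    L_p = || log(1 + |y_hat - y|) ||_p^p / || log(1 + |y|) ||_p^p ,

so that many small (high-frequency) errors weigh more relative to a single
large (low-frequency) error.  Conventional losses are the normalized l2
(NRMSE) and l1 (NMAE) ratios.  All losses are restricted to an index subset
(the Theta/Psi sets of self-supervised training) and are 0 iff the
reconstruction matches the measurements there.

Note the deliberate asymmetry: conventional terms use p-norm *ratios*
(scale-invariant), log-scaled terms use p-th-power norm ratios and are
*not* scale-invariant — inputs are normalized upstream (max |A^H y| = 1).
The natural logarithm is used throughout (the base cancels in the p=1
ratio but not p=2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, asarray

__all__ = ["LossSpec", "normalized_loss", "log_scaled_loss", "composite_loss"]


@dataclass
class LossSpec:
    """Which loss terms to combine, and their weights.

    kind "conventional" = NMAE + NRMSE; "log_scaled" = log-l1 + log-l2;
    "combined" = all four.  Default unit weights.
    """

    kind: str = "combined"
    p_set: tuple = (1, 2)
    weights: dict = field(default_factory=dict)

    _KINDS = ("conventional", "log_scaled", "combined")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}")
        if not self.p_set or any(p not in (1, 2) for p in self.p_set):
            raise ValueError("p_set must be a non-empty subset of {1, 2}")
        for v in self.weights.values():
            if v <= 0:
                raise ValueError("loss weights must be positive")

    def terms(self):
        """Yield (family, p, weight) for the active terms."""
        families = {"conventional": ("conventional",),
                    "log_scaled": ("log_scaled",),
                    "combined": ("conventional", "log_scaled")}[self.kind]
        for fam in families:
            for p in self.p_set:
                yield fam, p, float(self.weights.get(f"{fam}_l{p}", 1.0))


def _subset_mask(subset, shape):
    """Accept a flat index array or a broadcastable binary mask."""
    sub = np.asarray(subset)
    if sub.ndim == 1:                      # flat index array into the (ny, nx) grid
        if sub.size == 0:
            raise ValueError("empty loss subset")
        m = np.zeros(int(np.prod(shape[-2:])), dtype=np.float64)
        m[sub.astype(np.int64)] = 1.0
        return m.reshape(shape[-2:])
    m = sub.astype(np.float64)
    if m.shape != tuple(shape[-2:]):
        raise ValueError(f"subset mask shape {m.shape} does not match grid {shape[-2:]}")
    if not m.any():
        raise ValueError("empty loss subset")
    return m


def normalized_loss(y_hat, y, subset, p: int = 2):
    """Normalized l_p ratio ||P(y_hat - y)||_p / ||P y||_p on complex magnitudes.

    p=2 is the NRMSE and p=1 the NMAE convention, reported as a fraction.
    """
    if p not in (1, 2):
        raise ValueError("p must be 1 or 2")
    yd = asarray(y)
    m = _subset_mask(subset, yd.shape)
    denom_v = np.abs(m * yd)
    denom = float(denom_v.sum()) if p == 1 else float(np.sqrt((denom_v ** 2).sum()))
    if denom == 0:
        raise ValueError("reference k-space is zero on the loss subset")
    r = ad.absolute(ad.mul(ad.sub(y_hat, y), m))
    if p == 1:
        num = ad.sum_all(r)
    else:
        num = ad.sqrt(ad.vdot_real(r, r))
    return ad.div(num, denom)


def log_scaled_loss(y_hat, y, subset, p: int = 2):
    """Log-compressed ratio ||log(1+|y_hat-y|)||_p^p / ||log(1+|y|)||_p^p."""
    if p not in (1, 2):
        raise ValueError("p must be 1 or 2")
    yd = asarray(y)
    m = _subset_mask(subset, yd.shape)
    ref = np.log1p(np.abs(m * yd))
    denom = float((ref ** p).sum())
    if denom == 0:
        raise ValueError("reference k-space is zero on the loss subset")
    r = ad.log1p(ad.absolute(ad.mul(ad.sub(y_hat, y), m)))
    if p == 2:
        r = ad.square(r)
    return ad.div(ad.sum_all(r), denom)


def composite_loss(y_hat, y, subset, spec: LossSpec | None = None):
    """Weighted sum of the loss terms selected by ``spec`` (default: combined)."""
    spec = spec or LossSpec()
    total = None
    for fam, p, w in spec.terms():
        fn = normalized_loss if fam == "conventional" else log_scaled_loss
        term = ad.mul(w, fn(y_hat, y, subset, p))
        total = term if total is None else ad.add(total, term)
    return total
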