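"""Virtual-coil conjugate-symmetry augmentation.

The spectrum of the complex conjugate of an image is the conjugated,
index-reflected spectrum of the image itself.  Stacking ``x`` with
``conj(x)`` therefore hands a denoising network an explicit copy of the
conjugate-symmetric half of k-space — the information partial-Fourier
acquisition relies on.  The reduction ``V^H`` averages the two branches so
that ``vc_reduce(vc_augment(x)) == x`` exactly.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import asarray

__all__ = ["vc_augment", "vc_reduce"]


def vc_augment(x):
    """Stack ``[x, conj(x)]`` along a new leading axis -> (2, ny, nx)."""
    return ad.stack([x, ad.conj(x)])


def vc_reduce(s):
    """Average the two conjugate branches: ``(s[0] + conj(s[1])) / 2``.

    Exact left inverse of :func:`vc_augment`.
    """
    sd = asarray(s)
    if sd.shape[0] != 2:
        raise ValueError(f"expected a 2-channel stack, got shape {sd.shape}")
    a = ad.unstack(s, 0) if not isinstance(s, np.ndarray) else s[0]
    b = ad.unstack(s, 1) if not isinstance(s, np.ndarray) else s[1]
    return ad.mul(0.5, ad.add(a, ad.conj(b)))
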