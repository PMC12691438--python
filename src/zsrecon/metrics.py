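"""Image-quality metrics: NRMSE, PSNR, SSIM, HFEN, GMSD.

All metrics operate on magnitude images scaled by the reference maximum
(so the pair lives on [0, ~1] with peak 1 for the reference):

* NRMSE  — 100 * || |x_hat| - |x| ||_2 / || |x| ||_2, in percent.
* PSNR   — 20 log10(peak / RMSE) in dB on the scaled pair (peak = 1);
  identical images are reported as the cap ``PSNR_CAP``.
* SSIM   — Wang et al. configuration: Gaussian window sigma 1.5
  (truncate 3.5), K1=0.01, K2=0.03, population covariance, border crop.
* HFEN   — relative l2 error between Laplacian-of-Gaussian filtered
  images (15x15 kernel, sigma 1.5); sensitive to edges and fine texture.
* GMSD   — standard deviation of the gradient-magnitude similarity map
  (3x3 Prewitt gradients, stability constant c = 170/255^2 on [0,1]).

FSIM and LPIPS are available only as optional plug-ins registered at run
time (they require external implementations / pretrained weights).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve, gaussian_filter

__all__ = ["PSNR_CAP", "MetricsReport", "compute_metric", "metrics_report",
           "register_plugin_metric", "nrmse", "psnr", "ssim", "hfen", "gmsd"]

PSNR_CAP = 100.0          # dB sentinel for identical images
_GMSD_C = 170.0 / 255.0 ** 2

_PLUGINS: dict = {}       # name -> callable(recon_mag, ref_mag) -> float


def register_plugin_metric(name: str, fn):
    """Register an external metric (e.g. FSIM, LPIPS) under ``name``."""
    _PLUGINS[name.lower()] = fn


def _scaled_magnitudes(recon, reference):
    x = np.abs(np.asarray(recon))
    ref = np.abs(np.asarray(reference))
    if x.shape != ref.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {ref.shape}")
    peak = ref.max()
    if peak == 0:
        raise ValueError("reference image is zero")
    return x / peak, ref / peak


def nrmse(recon, reference) -> float:
    """Normalized RMSE in percent."""
    x, ref = _scaled_magnitudes(recon, reference)
    return 100.0 * float(np.linalg.norm(x - ref) / np.linalg.norm(ref))


def psnr(recon, reference) -> float:
    """Peak SNR in dB (peak = reference maximum); capped at PSNR_CAP."""
    x, ref = _scaled_magnitudes(recon, reference)
    mse = float(np.mean((x - ref) ** 2))
    if mse == 0:
        return PSNR_CAP
    return min(PSNR_CAP, 20.0 * np.log10(1.0 / np.sqrt(mse)))


def ssim(recon, reference, K1: float = 0.01, K2: float = 0.03,
         sigma: float = 1.5) -> float:
    """Mean SSIM, Wang-et-al. configuration on the [0,1]-scaled pair."""
    x, ref = _scaled_magnitudes(recon, reference)
    truncate = 3.5
    r = int(truncate * sigma + 0.5)
    win = 2 * r + 1
    if min(x.shape) < win:
        raise ValueError(f"image smaller than the {win}x{win} SSIM window")
    fl = dict(sigma=sigma, truncate=truncate, mode="reflect")
    ux = gaussian_filter(x, **fl)
    uy = gaussian_filter(ref, **fl)
    uxx = gaussian_filter(x * x, **fl)
    uyy = gaussian_filter(ref * ref, **fl)
    uxy = gaussian_filter(x * ref, **fl)
    vx = uxx - ux * ux
    vy = uyy - uy * uy
    vxy = uxy - ux * uy
    C1, C2 = (K1 * 1.0) ** 2, (K2 * 1.0) ** 2
    S = ((2 * ux * uy + C1) * (2 * vxy + C2)) / ((ux ** 2 + uy ** 2 + C1) * (vx + vy + C2))
    pad = (win - 1) // 2
    return float(S[pad:-pad, pad:-pad].mean())


def log_kernel(size: int = 15, sigma: float = 1.5) -> np.ndarray:
    """Rotationally symmetric Laplacian-of-Gaussian kernel, zero-sum."""
    r = (size - 1) / 2
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    s2 = sigma ** 2
    g = np.exp(-(xx ** 2 + yy ** 2) / (2 * s2))
    g /= g.sum()
    h = g * (xx ** 2 + yy ** 2 - 2 * s2) / (s2 ** 2)
    return h - h.mean()


def hfen(recon, reference, size: int = 15, sigma: float = 1.5) -> float:
    """High-frequency error norm: relative l2 error of LoG-filtered images."""
    x, ref = _scaled_magnitudes(recon, reference)
    k = log_kernel(size, sigma)
    fx = convolve(x, k, mode="constant")
    fr = convolve(ref, k, mode="constant")
    denom = np.linalg.norm(fr)
    if denom == 0:
        raise ValueError("LoG of reference is zero")
    return float(np.linalg.norm(fx - fr) / denom)


_PREWITT_X = np.array([[1.0, 0.0, -1.0]] * 3) / 3.0
_PREWITT_Y = _PREWITT_X.T


def _grad_mag(img: np.ndarray) -> np.ndarray:
    gx = convolve(img, _PREWITT_X, mode="constant")
    gy = convolve(img, _PREWITT_Y, mode="constant")
    return np.sqrt(gx ** 2 + gy ** 2)


def gmsd(recon, reference, c: float = _GMSD_C) -> float:
    """Std of the gradient-magnitude similarity map (population std)."""
    x, ref = _scaled_magnitudes(recon, reference)
    g1 = _grad_mag(x)
    g2 = _grad_mag(ref)
    gms = (2.0 * g1 * g2 + c) / (g1 ** 2 + g2 ** 2 + c)
    return float(gms.std())


_METRICS = {"nrmse": nrmse, "psnr": psnr, "ssim": ssim, "hfen": hfen, "gmsd": gmsd}


def compute_metric(recon, reference, name: str) -> float:
    """Evaluate one named metric on (recon, reference) complex images."""
    key = name.lower()
    if key in _METRICS:
        return _METRICS[key](recon, reference)
    if key in _PLUGINS:
        x, ref = _scaled_magnitudes(recon, reference)
        return float(_PLUGINS[key](x, ref))
    raise ValueError(
        f"unknown metric {name!r}; built-ins: {sorted(_METRICS)}; "
        f"registered plug-ins: {sorted(_PLUGINS)}"
    )


@dataclass
class MetricsReport:
    """Per-slice metric values, their mean, and volume-pooled values."""

    per_slice: dict = field(default_factory=dict)   # name -> list of floats
    mean: dict = field(default_factory=dict)        # name -> float
    pooled: dict = field(default_factory=dict)      # name -> float over stacked slices

    def as_rows(self):
        names = sorted(self.mean)
        yield ["slice"] + names
        n = len(next(iter(self.per_slice.values()))) if self.per_slice else 0
        for i in range(n):
            yield [i] + [self.per_slice[m][i] for m in names]
        yield ["mean"] + [self.mean[m] for m in names]
        yield ["pooled"] + [self.pooled[m] for m in names]


def metrics_report(recons, references, names=("nrmse", "psnr", "ssim", "hfen", "gmsd")
                   ) -> MetricsReport:
    """Evaluate metrics per slice and pooled over the whole stack."""
    recons = np.asarray(recons)
    references = np.asarray(references)
    if recons.ndim == 2:
        recons = recons[None]
        references = references[None]
    rep = MetricsReport()
    for m in names:
        vals = [compute_metric(r, g, m) for r, g in zip(recons, references)]
        rep.per_slice[m] = vals
        rep.mean[m] = float(np.mean(vals))
    big_r = np.concatenate([np.abs(r) for r in recons], axis=0)
    big_g = np.concatenate([np.abs(g) for g in references], axis=0)
    for m in names:
        rep.pooled[m] = compute_metric(big_r, big_g, m)
    return rep
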