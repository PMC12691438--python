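"""Synthetic multicoil brain-like acquisitions and fixture I/O.

Emulates the structure of a multicoil 2-D brain acquisition so the whole
pipeline is testable without downloading data: a complex-valued phantom
with smooth low-order polynomial phase (complex phase is what makes
partial Fourier and the virtual coil meaningful), smooth complex coil
sensitivity profiles on a ring with unit root-sum-of-squares, and additive
circular complex Gaussian k-space noise.

Two grid presets mirror the two scales the package targets: ``desk``
(64 x 64, 8 coils, 2 slices — CPU-trainable) and ``full`` (320 x 320,
20 coils, 16 slices — the geometry of a 20-channel head-coil acquisition).

Fixtures round-trip through a single HDF5 file whose main dataset is named
``kspace`` with (slices, coils, ny, nx) layout, mirroring the fastMRI
convention so the optional fastMRI reader shares the downstream path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import h5py
import numpy as np

from .fourier_ops import forward_op, centered_fft
from .sampling import SamplingMask, full_mask

__all__ = [
    "PhantomSpec", "CoilSpec", "NoiseSpec", "PRESETS",
    "generate_phantom", "simulate_coils", "simulate_acquisition",
    "simulate_dataset", "save_fixture", "load_fixture",
    "read_fastmri", "estimate_sensitivities",
]

PRESETS = {
    "desk": dict(grid=(64, 64), n_coils=8, n_slices=2),
    "full": dict(grid=(320, 320), n_coils=20, n_slices=16),
}


@dataclass
class PhantomSpec:
    kind: str = "shepp_logan"            # or "random_ellipses"
    grid: tuple = (64, 64)
    phase_amplitude: float = 0.5         # radians, peak of the smooth phase map
    seed: int = 0

    def __post_init__(self):
        if min(self.grid) < 16:
            raise ValueError("phantom grid must be at least 16x16")
        if self.kind not in ("shepp_logan", "random_ellipses"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")


@dataclass
class CoilSpec:
    n_coils: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.n_coils < 1:
            raise ValueError("n_coils must be >= 1")


@dataclass
class NoiseSpec:
    sigma: float = 0.005                 # total complex std per k-space sample
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


# (amplitude, a, b, x0, y0, angle_deg) — modified Shepp-Logan intensities
_SHEPP_LOGAN = [
    (1.00, 0.6900, 0.9200, 0.00, 0.0000, 0.0),
    (-0.80, 0.6624, 0.8740, 0.00, -0.0184, 0.0),
    (-0.20, 0.1100, 0.3100, 0.22, 0.0000, -18.0),
    (-0.20, 0.1600, 0.4100, -0.22, 0.0000, 18.0),
    (0.10, 0.2100, 0.2500, 0.00, 0.3500, 0.0),
    (0.10, 0.0460, 0.0460, 0.00, 0.1000, 0.0),
    (0.10, 0.0460, 0.0460, 0.00, -0.1000, 0.0),
    (0.10, 0.0460, 0.0230, -0.08, -0.6050, 0.0),
    (0.10, 0.0230, 0.0230, 0.00, -0.6060, 0.0),
    (0.10, 0.0230, 0.0460, 0.06, -0.6050, 0.0),
]


def _ellipse_sum(grid, ellipses):
    ny, nx = grid
    y = np.linspace(-1, 1, ny)[:, None]
    x = np.linspace(-1, 1, nx)[None, :]
    img = np.zeros((ny, nx))
    for amp, a, b, x0, y0, ang in ellipses:
        t = np.deg2rad(ang)
        xr = (x - x0) * np.cos(t) + (y - y0) * np.sin(t)
        yr = -(x - x0) * np.sin(t) + (y - y0) * np.cos(t)
        img += amp * ((xr / a) ** 2 + (yr / b) ** 2 <= 1.0)
    return img


def _smooth_phase(grid, amplitude: float, rng: np.random.Generator):
    """Low-order (quadratic) 2-D polynomial phase with the given peak amplitude."""
    ny, nx = grid
    y = np.linspace(-1, 1, ny)[:, None]
    x = np.linspace(-1, 1, nx)[None, :]
    c = rng.uniform(-1, 1, 6)
    poly = c[0] + c[1] * x + c[2] * y + c[3] * x * y + c[4] * x ** 2 + c[5] * y ** 2
    peak = np.abs(poly).max()
    if peak == 0:
        return np.zeros(grid)
    return amplitude * poly / peak


def generate_phantom(spec: PhantomSpec) -> np.ndarray:
    """Complex phantom with magnitude in [0, 1] and smooth phase; seeded."""
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "shepp_logan":
        mag = _ellipse_sum(spec.grid, _SHEPP_LOGAN)
    else:
        ellipses = []
        for _ in range(rng.integers(5, 10)):
            ellipses.append((
                rng.uniform(0.1, 0.5),
                rng.uniform(0.08, 0.5), rng.uniform(0.08, 0.5),
                rng.uniform(-0.5, 0.5), rng.uniform(-0.5, 0.5),
                rng.uniform(0, 180),
            ))
        mag = _ellipse_sum(spec.grid, ellipses)
    mag = np.clip(mag, 0.0, None)
    if mag.max() > 0:
        mag = mag / mag.max()
    phase = _smooth_phase(spec.grid, spec.phase_amplitude, rng)
    return mag * np.exp(1j * phase)


def simulate_coils(spec: CoilSpec, support: np.ndarray) -> np.ndarray:
    """Smooth complex coil profiles on a ring, RSS-normalized.

    Gaussian magnitude bells centered on a ring around the field of view,
    each with a gentle linear phase ramp; the root-sum-of-squares over
    coils is 1 everywhere on the grid (hence inside the object support).
    """
    support = np.asarray(support).astype(bool)
    if not support.any():
        raise ValueError("empty object support")
    ny, nx = support.shape
    y = np.linspace(-1, 1, ny)[:, None]
    x = np.linspace(-1, 1, nx)[None, :]
    rng = np.random.default_rng(spec.seed)
    maps = np.empty((spec.n_coils, ny, nx), dtype=np.complex128)
    width = 1.0 + 0.1 * rng.uniform(-1, 1, spec.n_coils)
    for c in range(spec.n_coils):
        ang = 2 * np.pi * c / spec.n_coils + rng.uniform(-0.1, 0.1)
        cx, cy = 1.3 * np.cos(ang), 1.3 * np.sin(ang)
        mag = np.exp(-(((x - cx) ** 2 + (y - cy) ** 2) / (2 * width[c] ** 2)))
        ph = rng.uniform(-1.5, 1.5) * x + rng.uniform(-1.5, 1.5) * y + rng.uniform(0, 2 * np.pi)
        maps[c] = mag * np.exp(1j * ph)
    rss = np.sqrt((np.abs(maps) ** 2).sum(axis=0))
    maps /= rss[None]
    return maps


def simulate_acquisition(x, S, mask, noise: NoiseSpec | None = None) -> np.ndarray:
    """Measured multicoil k-space: mask * (F S x + eps), eps circular Gaussian."""
    noise = noise or NoiseSpec(sigma=0.0)
    m = mask.as_float() if isinstance(mask, SamplingMask) else np.asarray(mask, dtype=np.float64)
    y = np.asarray(forward_op(x, S, m))
    if noise.sigma > 0:
        rng = np.random.default_rng(noise.seed)
        s = noise.sigma / np.sqrt(2.0)
        eps = rng.normal(0, s, y.shape) + 1j * rng.normal(0, s, y.shape)
        y = y + m * eps
    return y


def simulate_dataset(preset: str = "desk", kind: str = "shepp_logan",
                     mask: SamplingMask | None = None, sigma: float = 0.005,
                     phase_amplitude: float = 0.5, seed: int = 0,
                     n_slices: int | None = None):
    """Multi-slice acquisition: returns (kspace, sensitivities, ground_truth, mask).

    Slices share the coil array (one subject, one scan) but differ in
    phantom content/phase (seed offset per slice).  Shapes:
    kspace (S, C, ny, nx), sensitivities (C, ny, nx), ground_truth (S, ny, nx).
    """
    p = PRESETS[preset]
    grid, n_coils = p["grid"], p["n_coils"]
    n_slices = n_slices or p["n_slices"]
    mask = mask or full_mask(*grid)

    gts = []
    for s in range(n_slices):
        spec = PhantomSpec(kind=kind, grid=grid, phase_amplitude=phase_amplitude,
                           seed=seed + 101 * s)
        gts.append(generate_phantom(spec))
    gt = np.stack(gts)
    support = np.abs(gt).max(axis=0) > 0
    S = simulate_coils(CoilSpec(n_coils=n_coils, seed=seed + 7), support)
    ksp = np.stack([
        simulate_acquisition(gt[s], S, mask, NoiseSpec(sigma=sigma, seed=seed + 1000 + s))
        for s in range(n_slices)
    ])
    return ksp, S, gt, mask


# ----------------------------------------------------------------------
# fixture I/O
# ----------------------------------------------------------------------

def save_fixture(path, kspace, sensitivities, ground_truth, mask: SamplingMask,
                 specs: dict | None = None):
    """Write an HDF5 fixture: kspace / sensitivities / ground_truth / mask."""
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=np.asarray(kspace, dtype=np.complex128))
        f.create_dataset("sensitivities", data=np.asarray(sensitivities, dtype=np.complex128))
        f.create_dataset("ground_truth", data=np.asarray(ground_truth, dtype=np.complex128))
        f.create_dataset("mask", data=mask.grid)
        f.attrs["mask_spec"] = mask.spec_json()
        f.attrs["specs"] = json.dumps(specs or {}, default=str)


def load_fixture(path):
    """Read a fixture written by :func:`save_fixture`.

    Returns (kspace, sensitivities, ground_truth, mask, specs).
    """
    with h5py.File(path, "r") as f:
        ksp = f["kspace"][()]
        S = f["sensitivities"][()]
        gt = f["ground_truth"][()]
        mask = SamplingMask(f["mask"][()], json.loads(f.attrs["mask_spec"]))
        specs = json.loads(f.attrs.get("specs", "{}"))
    return ksp, S, gt, mask, specs


# ----------------------------------------------------------------------
# optional fastMRI reader
# ----------------------------------------------------------------------

def read_fastmri(path) -> np.ndarray:
    """Read the "kspace" dataset of a fastMRI multicoil HDF5 file.

    Returns complex k-space with (slices, coils, ny, nx) layout.  fastMRI
    stores uncentered-convention data; this reader only loads the array —
    downstream code assumes DC at the grid center, so apply fftshift if the
    source file uses a corner-DC convention.
    """
    with h5py.File(path, "r") as f:
        if "kspace" not in f:
            raise KeyError(f"{path} has no 'kspace' dataset")
        return np.asarray(f["kspace"][()])


def estimate_sensitivities(kspace_slice: np.ndarray, acs_width: int = 24) -> np.ndarray:
    """Sensitivity maps from the central ACS block of one slice.

    Low-resolution coil images from the Hann-apodized central
    acs_width x acs_width block, normalized by their root-sum-of-squares.
    """
    C, ny, nx = kspace_slice.shape
    w = np.zeros((ny, nx))
    ry = slice(ny // 2 - acs_width // 2, ny // 2 - acs_width // 2 + acs_width)
    rx = slice(nx // 2 - acs_width // 2, nx // 2 - acs_width // 2 + acs_width)
    han = np.hanning(acs_width)
    w[ry, rx] = han[:, None] * han[None, :]
    low = np.asarray(centered_fft(kspace_slice * w[None], "inverse"))
    rss = np.sqrt((np.abs(low) ** 2).sum(axis=0))
    rss = np.where(rss == 0, 1.0, rss)
    return low / rss[None]
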