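"""Acquisition masks and self-supervised k-space partitioning.

Two retrospective undersampling families are provided:

* 1-D lattice undersampling of the phase-encode (row) axis at acceleration
  R, optionally with partial-Fourier (PF) truncation of the highest
  positive-frequency rows and a fully sampled central ACS block, as used
  for 2-D multi-slice acquisitions.
* 2-D CAIPI lattice undersampling (Ry x Rz with an inter-column row shift
  that spreads aliasing across the coil geometry), plus PF and a square
  central ACS block, as used for 3-D acquisitions.

For scan-specific self-supervision the acquired set Omega is partitioned
into three disjoint subsets: Lambda (network input), Theta (training loss)
and Psi (validation loss).  Psi is drawn once; many (Lambda, Theta) splits
of the remainder provide the training pairs.

Index convention: row-major 0-based (row, col); the DC sample sits at
(floor(ny/2), floor(nx/2)), matching the centered FFT.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

__all__ = [
    "SamplingMask", "PartitionSet",
    "make_1d_mask", "make_caipi_mask", "full_mask", "partition_kspace",
]


@dataclass
class SamplingMask:
    """Binary acquisition mask with the spec that generated it."""

    grid: np.ndarray                      # (ny, nx) uint8
    spec: dict = field(default_factory=dict)

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise ValueError("mask grid must be 2-D")
        vals = np.unique(self.grid)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError("mask entries must be 0/1")
        self.grid = self.grid.astype(np.uint8)

    @property
    def n_sampled(self) -> int:
        return int(self.grid.sum())

    @property
    def indices(self) -> np.ndarray:
        """Flat indices of sampled locations (row-major)."""
        return np.flatnonzero(self.grid.ravel())

    def as_float(self) -> np.ndarray:
        return self.grid.astype(np.float64)

    def spec_json(self) -> str:
        return json.dumps(self.spec, default=str)


@dataclass
class PartitionSet:
    """Disjoint split of the acquired set Omega into Lambda/Theta/Psi.

    ``psi`` is shared across all pairs; each pair is a (lambda, theta)
    tuple of flat index arrays.  lambda | theta | psi == Omega for every
    pair, pairwise disjoint.
    """

    psi: np.ndarray
    pairs: list          # [(lambda_idx, theta_idx), ...]
    ratios: tuple
    seed: int
    shape: tuple

    def masks(self, k: int):
        """Binary (ny, nx) indicator masks (lambda, theta, psi) for pair k."""
        lam, theta = self.pairs[k]
        out = []
        for idx in (lam, theta, self.psi):
            m = np.zeros(int(np.prod(self.shape)), dtype=np.float64)
            m[idx] = 1.0
            out.append(m.reshape(self.shape))
        return tuple(out)


def _pf_removed_rows(ny: int, pf_fraction) -> int:
    """Number of highest positive-frequency rows removed by partial Fourier."""
    frac = Fraction(pf_fraction).limit_denominator(64) if not isinstance(pf_fraction, Fraction) \
        else pf_fraction
    if not (Fraction(1, 2) < frac <= 1):
        raise ValueError(f"pf_fraction must be in (1/2, 1], got {pf_fraction}")
    return int(np.ceil((1 - float(frac)) * ny))


def _acs_rows(ny: int, width: int) -> slice:
    c = ny // 2
    lo = c - width // 2
    return slice(lo, lo + width)


def make_1d_mask(ny: int, nx: int, R: int, pf_fraction=1, acs_width: int = 0) -> SamplingMask:
    """1-D uniform lattice undersampling of the row (phase-encode) axis.

    Rows congruent to the DC row modulo R are sampled within the
    partial-Fourier-retained region; the highest positive-frequency rows are
    removed by PF; ``acs_width`` central rows are always sampled.  The
    column (frequency-encode) axis is fully sampled.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    if acs_width < 0:
        raise ValueError("acs_width must be >= 0")
    n_removed = _pf_removed_rows(ny, pf_fraction)
    retained = ny - n_removed

    grid = np.zeros((ny, nx), dtype=np.uint8)
    offset = (ny // 2) % R  # keep the DC row on the lattice
    rows = np.arange(retained)
    grid[rows[rows % R == offset], :] = 1

    if acs_width > 0:
        acs = _acs_rows(ny, acs_width)
        if acs.start < 0 or acs.stop > retained:
            raise ValueError(
                f"ACS block rows [{acs.start}, {acs.stop}) extend outside the "
                f"partial-Fourier-retained region [0, {retained})"
            )
        grid[acs, :] = 1

    spec = dict(pattern="1d", R=R, pf_fraction=str(pf_fraction), acs_width=acs_width,
                ny=ny, nx=nx)
    return SamplingMask(grid, spec)


def make_caipi_mask(ny: int, nx: int, Ry: int, Rz: int, shift: int = 1,
                    pf_fraction=1, acs_width: int = 0) -> SamplingMask:
    """2-D CAIPI lattice: every Rz-th column, with the row lattice shifted
    by ``shift`` rows per sampled column, interleaving the aliasing pattern.

    Point (i, j) is sampled iff ``j % Rz == 0`` and
    ``(i - shift * (j // Rz)) % Ry == 0``.  Partial Fourier removes the
    highest positive-frequency rows; a central acs_width x acs_width block
    is always sampled.
    """
    if Ry < 1 or Rz < 1:
        raise ValueError("Ry, Rz must be >= 1")
    if not (0 <= shift < max(Ry, 1)):
        raise ValueError(f"shift must satisfy 0 <= shift < Ry, got {shift}")
    n_removed = _pf_removed_rows(ny, pf_fraction)
    retained = ny - n_removed

    i = np.arange(ny)[:, None]
    j = np.arange(nx)[None, :]
    lattice = (j % Rz == 0) & ((i - shift * (j // Rz)) % Ry == 0)
    grid = np.zeros((ny, nx), dtype=np.uint8)
    grid[lattice] = 1
    grid[retained:, :] = 0

    if acs_width > 0:
        rs = _acs_rows(ny, acs_width)
        cs = _acs_rows(nx, acs_width)
        if rs.start < 0 or rs.stop > retained:
            raise ValueError("ACS block extends outside the partial-Fourier-retained region")
        grid[rs, cs] = 1

    spec = dict(pattern="caipi", Ry=Ry, Rz=Rz, shift=shift,
                pf_fraction=str(pf_fraction), acs_width=acs_width, ny=ny, nx=nx)
    return SamplingMask(grid, spec)


def full_mask(ny: int, nx: int) -> SamplingMask:
    return SamplingMask(np.ones((ny, nx), dtype=np.uint8), dict(pattern="full", ny=ny, nx=nx))


def _acs_flat_indices(mask: SamplingMask) -> np.ndarray:
    """Flat indices of the ACS block recorded in the mask spec (may be empty)."""
    spec = mask.spec
    w = int(spec.get("acs_width", 0) or 0)
    if w <= 0:
        return np.array([], dtype=np.int64)
    ny, nx = mask.grid.shape
    rs = _acs_rows(ny, w)
    block = np.zeros_like(mask.grid)
    if spec.get("pattern") == "caipi":
        cs = _acs_rows(nx, w)
        block[rs, cs] = 1
    else:
        block[rs, :] = 1
    return np.flatnonzero((block & mask.grid).ravel())


def partition_kspace(mask: SamplingMask, ratios=(0.48, 0.32, 0.20), n_pairs: int = 50,
                     seed: int = 0, protect_acs: bool = True) -> PartitionSet:
    """Partition the acquired set Omega into Psi and n_pairs (Lambda, Theta) splits.

    ``|Psi| = floor(r_psi |Omega|)`` drawn once uniformly (never from the ACS
    block when ``protect_acs``); for each pair the remaining points split
    uniformly with ``|Theta| = floor(r_theta |Omega|)`` and Lambda taking the
    remainder (the ACS block always lands in Lambda when ``protect_acs``).
    Fully reproducible from ``seed``.
    """
    r_lam, r_theta, r_psi = ratios
    if min(ratios) <= 0 or abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must be positive and sum to 1")
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")

    omega = mask.indices
    n = omega.size
    n_psi = int(np.floor(r_psi * n))
    n_theta = int(np.floor(r_theta * n))
    acs = _acs_flat_indices(mask) if protect_acs else np.array([], dtype=np.int64)
    free = np.setdiff1d(omega, acs)  # sorted
    if n_psi + n_theta > free.size:
        raise ValueError(
            f"ratios infeasible: need {n_psi + n_theta} free points for Psi+Theta "
            f"but only {free.size} outside the protected ACS block"
        )
    if n_psi == 0 or n_theta == 0:
        raise ValueError("ratios give an empty Theta or Psi subset for this mask")

    rng = np.random.default_rng(seed)
    psi = rng.choice(free, size=n_psi, replace=False)
    rest = np.setdiff1d(free, psi)

    pairs = []
    for _ in range(n_pairs):
        theta = rng.choice(rest, size=n_theta, replace=False)
        lam = np.setdiff1d(np.setdiff1d(omega, psi), theta)  # includes ACS
        pairs.append((np.sort(lam), np.sort(theta)))

    return PartitionSet(psi=np.sort(psi), pairs=pairs, ratios=tuple(ratios),
                        seed=seed, shape=mask.grid.shape)
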