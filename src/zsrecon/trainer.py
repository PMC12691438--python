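"""Scan-specific self-supervised training loop and inference.

No fully sampled reference is ever used: the acquired k-space Omega of the
scan being reconstructed is partitioned into Lambda (network input), Theta
(training loss) and Psi (validation).  Each optimization step draws one
(slice, (Lambda, Theta)) pair, reconstructs from P_Lambda y, and penalizes
the k-space mismatch on Theta; after each epoch the loss on the held-out
Psi (with P_{Lambda u Theta} y as input) drives checkpoint selection and
early stopping.  At inference the entire measurement set Omega is the
network input, and the best-validation weights are used.

One network is trained for, and applied to, all slices of the scan.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, asarray, no_grad
from .fourier_ops import adjoint_op
from .losses import LossSpec, composite_loss
from .networks import UnrolledModel, unrolled_forward
from .sampling import SamplingMask, PartitionSet

__all__ = ["TrainConfig", "TrainHistory", "Adam", "train_scan_specific",
           "reconstruct_inference"]


@dataclass
class TrainConfig:
    lr: float = 1e-3
    max_epochs: int = 30
    patience: int = 10
    seed: int = 0
    loss: LossSpec = field(default_factory=LossSpec)

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")


@dataclass
class TrainHistory:
    train_loss: list = field(default_factory=list)     # per-epoch mean step loss
    val_loss: list = field(default_factory=list)
    lambda1: list = field(default_factory=list)
    lambda2: list = field(default_factory=list)
    best_epoch: int = -1
    best_val: float = np.inf

    def to_csv(self, path):
        with open(path, "w", newline="") as f:
            w = csv.writer(f)
            w.writerow(["epoch", "train_loss", "val_loss", "lambda1", "lambda2"])
            for i, (t, v, l1, l2) in enumerate(
                    zip(self.train_loss, self.val_loss, self.lambda1, self.lambda2)):
                w.writerow([i, t, v, l1, l2])


class Adam:
    """Adaptive-moment first-order optimizer over a list of real parameters."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = np.asarray(p.grad)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def _normalized_input(y, S, input_mask):
    """Project y onto the input mask and scale so max |A^H y_in| = 1."""
    y_in = np.asarray(y) * input_mask
    scale = float(np.abs(np.asarray(adjoint_op(y_in, S, input_mask))).max())
    if scale == 0:
        raise ValueError("input k-space subset carries no signal")
    return y_in / scale, scale


def _recon_kspace(x, S):
    """Fully sampled multicoil k-space of a reconstruction: F S x."""
    return ad.fft2c(ad.mul(S, x))


def train_scan_specific(kspace, S, mask: SamplingMask,
                        partitions: list[PartitionSet], model: UnrolledModel,
                        cfg: TrainConfig | None = None):
    """Train one model on the undersampled measurements of one scan.

    Parameters
    ----------
    kspace : (n_slices, C, ny, nx) measured multicoil k-space (zero off-mask)
    S : (C, ny, nx) coil sensitivities
    mask : acquisition mask Omega
    partitions : one PartitionSet per slice
    model : UnrolledModel (modified in place; best-validation weights restored)

    Returns (model, TrainHistory).
    """
    cfg = cfg or TrainConfig()
    kspace = np.asarray(kspace)
    n_slices = kspace.shape[0]
    if len(partitions) != n_slices:
        raise ValueError("one PartitionSet per slice required")
    for part in partitions:
        if part.psi.size == 0 or any(th.size == 0 for _, th in part.pairs):
            raise ValueError("empty Theta or Psi subset")

    omega = mask.as_float()
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr)
    hist = TrainHistory()
    best_state = None
    stall = 0

    steps = [(s, k) for s in range(n_slices) for k in range(len(partitions[s].pairs))]

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(steps))
        losses = []
        for j in order:
            s, k = steps[j]
            lam_m, theta_m, _ = partitions[s].masks(k)
            y_in, scale = _normalized_input(kspace[s], S, lam_m)
            recon = unrolled_forward(y_in, S, lam_m, model)
            y_hat = _recon_kspace(recon, S)
            loss = composite_loss(y_hat, kspace[s] / scale, theta_m, cfg.loss)
            lval = float(asarray(loss))
            if not np.isfinite(lval):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, slice {s}, pair {k}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(lval)

        val = _validation_loss(kspace, S, partitions, model, cfg.loss)
        hist.train_loss.append(float(np.mean(losses)))
        hist.val_loss.append(val)
        hist.lambda1.append(model.lambda1)
        hist.lambda2.append(model.lambda2)

        if val < hist.best_val:
            hist.best_val = val
            hist.best_epoch = epoch
            best_state = {k_: np.array(v, copy=True) for k_, v in model.state_dict().items()}
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break

    if best_state is not None:
        model.load_state_dict(best_state)
    return model, hist


def _validation_loss(kspace, S, partitions, model, loss_spec: LossSpec) -> float:
    """Mean over slices of the held-out loss on Psi with Lambda u Theta input."""
    vals = []
    with no_grad():
        for s in range(kspace.shape[0]):
            part = partitions[s]
            lam_m, theta_m, psi_m = part.masks(0)
            in_m = lam_m + theta_m        # Omega \ Psi (disjoint indicators)
            y_in, scale = _normalized_input(kspace[s], S, in_m)
            recon = unrolled_forward(y_in, S, in_m, model)
            y_hat = _recon_kspace(recon, S)
            loss = composite_loss(y_hat, kspace[s] / scale, psi_m, loss_spec)
            vals.append(float(asarray(loss)))
    return float(np.mean(vals))


def reconstruct_inference(y, S, mask: SamplingMask, model: UnrolledModel) -> np.ndarray:
    """Reconstruct one slice using the entire measurement set Omega.

    Input normalization (max |A^H y| = 1) is applied and inverted, so the
    output is on the scale of the measurements.
    """
    omega = mask.as_float() if isinstance(mask, SamplingMask) else np.asarray(mask, dtype=np.float64)
    y_in, scale = _normalized_input(y, S, omega)
    with no_grad():
        recon = unrolled_forward(y_in, S, omega, model)
    return np.asarray(asarray(recon)) * scale
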