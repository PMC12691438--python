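"""Residual denoiser CNNs and the unrolled reconstruction models.

Two unrolled variants are provided:

* ``zero_mirid`` — dual-domain: a residual CNN in the image domain and a
  second residual CNN in the k-space domain, each wrapped in virtual-coil
  augmentation/reduction, with trainable regularization weights lambda1
  (image prior) and lambda2 (k-space prior).
* ``zs_ssl`` — single-domain: image-space residual CNN only, no virtual
  coil, lambda2 fixed to zero.

One unroll alternates a conjugate-gradient data-consistency solve

    x_{n+1} = (A^H A + (lambda1 + lambda2) I)^{-1} (A^H y + lambda1 eta_n + lambda2 zeta_n)

with denoiser refreshes eta_{n+1} = V^H N_i(V x_{n+1}) and
zeta_{n+1} = V^H F^H N_k(F V x_{n+1}).  Denoiser weights are shared across
all unrolls, so the trainable parameter count is independent of the unroll
depth.  Complex maps enter the CNNs as separate real/imaginary channels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, asarray
from .fourier_ops import adjoint_op, cg_normal_solve
from .virtual_coil import vc_augment, vc_reduce
from .sampling import SamplingMask

__all__ = [
    "DenoiserConfig", "Denoiser", "UnrolledModel",
    "apply_denoiser", "unrolled_forward", "save_checkpoint", "load_checkpoint",
]


@dataclass
class DenoiserConfig:
    n_layers: int = 15
    kernel: int = 3
    channels: int = 46
    activation_slope: float = 0.1
    in_channels: int = 4        # real/imag x virtual-coil stack; 2 without VC

    def __post_init__(self):
        if self.n_layers < 2:
            raise ValueError("n_layers must be >= 2")
        if self.channels < 1:
            raise ValueError("channels must be >= 1")
        if self.activation_slope < 0:
            raise ValueError("activation_slope must be >= 0")


class Denoiser:
    """Plain conv stack with leaky-ReLU activations and a global residual skip.

    The final layer is zero-initialized so an untrained denoiser is exactly
    the identity, making the initial unrolled iterate well-behaved.
    """

    def __init__(self, config: DenoiserConfig, rng: np.random.Generator | None = None):
        self.config = config
        rng = rng or np.random.default_rng(0)
        c, k, n = config.channels, config.kernel, config.n_layers
        widths = [config.in_channels] + [c] * (n - 1) + [config.in_channels]
        self.weights: list[Tensor] = []
        self.biases: list[Tensor] = []
        for i in range(n):
            cin, cout = widths[i], widths[i + 1]
            if i == n - 1:
                w = np.zeros((cout, cin, k, k))
            else:
                w = rng.normal(0.0, np.sqrt(2.0 / (cin * k * k)), (cout, cin, k, k))
            self.weights.append(Tensor(w, requires_grad=True))
            self.biases.append(Tensor(np.zeros(cout), requires_grad=True))

    def parameters(self) -> list[Tensor]:
        return self.weights + self.biases

    @property
    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def __call__(self, channels):
        """Apply the residual CNN to a real (C_in, H, W) channel stack."""
        h = channels
        last = len(self.weights) - 1
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = ad.conv2d(h, w, b)
            if i < last:
                h = ad.leaky_relu(h, self.config.activation_slope)
        return ad.add(channels, h)


def apply_denoiser(x, denoiser: Denoiser, domain: str = "image", use_vc: bool = True):
    """Run a denoiser on a complex image, in the image or k-space domain.

    image domain:   V^H CNN(V x)
    k-space domain: V^H F^H CNN(F V x)

    Without virtual-coil augmentation the single complex map is passed as a
    1-channel stack (2 real channels).
    """
    s = vc_augment(x) if use_vc else ad.stack([x])
    expected = 4 if use_vc else 2
    if denoiser.config.in_channels != expected:
        raise ValueError(
            f"denoiser expects {denoiser.config.in_channels} input channels "
            f"but the {'VC' if use_vc else 'plain'} stack provides {expected}"
        )
    if domain == "kspace":
        s = ad.fft2c(s)
    elif domain != "image":
        raise ValueError(f"domain must be 'image' or 'kspace', got {domain!r}")
    out = ad.channels_to_complex(denoiser(ad.complex_to_channels(s)))
    if domain == "kspace":
        out = ad.ifft2c(out)
    return vc_reduce(out) if use_vc else ad.unstack(out, 0)


class UnrolledModel:
    """Weights and configuration of an unrolled reconstruction network.

    lambda1/lambda2 are parametrized as exp(rho) to stay positive; both start
    at ``lambda_init``.  With zero-initialized final denoiser layers the
    untrained model solves (A^H A + 2*lambda_init I) x = A^H y + 2*lambda_init A^H y,
    i.e. a Tikhonov-damped SENSE problem anchored at the zero-filled image, so
    a small ``lambda_init`` makes the initial iterate nearly data-consistent
    and lets training grow the prior weights as the denoisers become useful.
    ``zs_ssl`` has no k-space denoiser and lambda2 == 0.
    """

    def __init__(self, variant: str = "zero_mirid", n_unrolls: int = 10, n_cg: int = 10,
                 denoiser_config: DenoiserConfig | None = None, seed: int = 0,
                 lambda_init: float = 0.05):
        if variant not in ("zero_mirid", "zs_ssl"):
            raise ValueError(f"unknown variant {variant!r}")
        self.variant = variant
        self.n_unrolls = int(n_unrolls)
        self.n_cg = int(n_cg)
        self.use_vc = variant == "zero_mirid"
        if denoiser_config is None:
            denoiser_config = DenoiserConfig(
                channels=46 if variant == "zero_mirid" else 64,
                in_channels=4 if self.use_vc else 2,
            )
        self.denoiser_config = denoiser_config
        rng = np.random.default_rng(seed)
        self.image_denoiser = Denoiser(denoiser_config, rng)
        self.kspace_denoiser = Denoiser(denoiser_config, rng) if self.use_vc else None
        if lambda_init <= 0:
            raise ValueError("lambda_init must be positive")
        self.lambda_init = float(lambda_init)
        rho0 = np.float64(np.log(lambda_init))
        self.rho1 = Tensor(rho0, requires_grad=True)
        self.rho2 = Tensor(rho0.copy(), requires_grad=True) if self.use_vc else None

    # -- parameters ------------------------------------------------------
    def parameters(self) -> list[Tensor]:
        params = self.image_denoiser.parameters() + [self.rho1]
        if self.kspace_denoiser is not None:
            params += self.kspace_denoiser.parameters() + [self.rho2]
        return params

    @property
    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    @property
    def lambda1(self) -> float:
        return float(np.exp(self.rho1.data))

    @property
    def lambda2(self) -> float:
        return float(np.exp(self.rho2.data)) if self.rho2 is not None else 0.0

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        d = {"rho1": self.rho1.data}
        for i, (w, b) in enumerate(zip(self.image_denoiser.weights, self.image_denoiser.biases)):
            d[f"img_w{i}"], d[f"img_b{i}"] = w.data, b.data
        if self.kspace_denoiser is not None:
            d["rho2"] = self.rho2.data
            for i, (w, b) in enumerate(zip(self.kspace_denoiser.weights, self.kspace_denoiser.biases)):
                d[f"ksp_w{i}"], d[f"ksp_b{i}"] = w.data, b.data
        return d

    def load_state_dict(self, d: dict):
        self.rho1.data = np.asarray(d["rho1"])
        for i, (w, b) in enumerate(zip(self.image_denoiser.weights, self.image_denoiser.biases)):
            w.data, b.data = np.asarray(d[f"img_w{i}"]), np.asarray(d[f"img_b{i}"])
        if self.kspace_denoiser is not None:
            self.rho2.data = np.asarray(d["rho2"])
            for i, (w, b) in enumerate(zip(self.kspace_denoiser.weights, self.kspace_denoiser.biases)):
                w.data, b.data = np.asarray(d[f"ksp_w{i}"]), np.asarray(d[f"ksp_b{i}"])


def unrolled_forward(y_in, S, mask_in, model: UnrolledModel):
    """Run the unrolled reconstruction.

    ``mask_in`` must mark exactly the k-space locations present in ``y_in``
    (it is both the data-consistency mask and the input projector).
    Returns the coil-combined complex image after ``model.n_unrolls``
    alternations; with ``n_unrolls == 0`` this is the network input A^H y.
    """
    mask = mask_in.as_float() if isinstance(mask_in, SamplingMask) else np.asarray(mask_in, dtype=np.float64)
    x = adjoint_op(y_in, S, mask)
    if model.n_unrolls == 0:
        return x
    ahy = x
    lam1 = ad.exp(model.rho1)
    if model.use_vc:
        lam2 = ad.exp(model.rho2)
        lam_total = ad.add(lam1, lam2)
    else:
        lam2 = None
        lam_total = lam1
    eta = x
    zeta = x if model.use_vc else None
    for n in range(model.n_unrolls):
        rhs = ad.add(ahy, ad.mul(lam1, eta))
        if model.use_vc:
            rhs = ad.add(rhs, ad.mul(lam2, zeta))
        x = cg_normal_solve(rhs, S, mask, lam_total, model.n_cg)
        if not np.all(np.isfinite(asarray(x))):
            raise RuntimeError(f"non-finite reconstruction at unroll {n}")
        eta = apply_denoiser(x, model.image_denoiser, "image", model.use_vc)
        if model.use_vc:
            zeta = apply_denoiser(x, model.kspace_denoiser, "kspace", model.use_vc)
    return x


def save_checkpoint(model: UnrolledModel, path):
    """Serialize weights + config to a single .npz checkpoint."""
    cfg = dict(variant=model.variant, n_unrolls=model.n_unrolls, n_cg=model.n_cg,
               lambda_init=model.lambda_init,
               denoiser_config=asdict(model.denoiser_config))
    np.savez(path, __config__=np.bytes_(json.dumps(cfg).encode()), **model.state_dict())


def load_checkpoint(path) -> UnrolledModel:
    with np.load(path) as f:
        cfg = json.loads(bytes(f["__config__"]).decode())
        state = {k: f[k] for k in f.files if k != "__config__"}
    model = UnrolledModel(variant=cfg["variant"], n_unrolls=cfg["n_unrolls"],
                          n_cg=cfg["n_cg"],
                          lambda_init=cfg.get("lambda_init", 0.05),
                          denoiser_config=DenoiserConfig(**cfg["denoiser_config"]))
    model.load_state_dict(state)
    return model
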