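"""Unrolled-model oracles: dense update-equation iteration, fixed point,
weight sharing, checkpoint round-trip."""

import numpy as np
import pytest

from zsrecon import (DenoiserConfig, UnrolledModel, apply_denoiser,
                     unrolled_forward, forward_op, adjoint_op,
                     save_checkpoint, load_checkpoint)
from zsrecon.autodiff import Tensor, asarray
from conftest import random_instance, dense_forward_matrix


def zero_all_weights(model):
    denoisers = [model.image_denoiser] + (
        [model.kspace_denoiser] if model.kspace_denoiser is not None else [])
    for d in denoisers:
        for w in d.weights:
            w.data = np.zeros_like(w.data)
        for b in d.biases:
            b.data = np.zeros_like(b.data)


def dense_unrolled_iteration(y, S, mask, lam1, lam2, n_unrolls):
    """Independent dense implementation of the update equation with identity
    denoisers: x_{n+1} = (A^H A + (l1+l2) I)^{-1} (A^H y + l1 eta_n + l2 zeta_n),
    eta_n = zeta_n = x_n, x_0 = A^H y."""
    ny, nx = mask.shape
    A = dense_forward_matrix(S, mask)
    M = A.conj().T @ A + (lam1 + lam2) * np.eye(ny * nx)
    ahy = (A.conj().T @ np.asarray(y).ravel())
    x = ahy.copy()
    for _ in range(n_unrolls):
        x = np.linalg.solve(M, ahy + (lam1 + lam2) * x)
    return x.reshape(ny, nx)


@pytest.mark.parametrize("variant", ["zero_mirid", "zs_ssl"])
def test_matches_dense_update_equation(rng, variant):
    x, S, mask = random_instance(rng, 8, 8, 2)
    y = np.asarray(forward_op(x, S, mask))
    model = UnrolledModel(variant, n_unrolls=2, n_cg=150, lambda_init=0.05,
                          denoiser_config=DenoiserConfig(n_layers=3, channels=4,
                                                         in_channels=4 if variant == "zero_mirid" else 2),
                          seed=0)
    zero_all_weights(model)
    got = np.asarray(asarray(unrolled_forward(y, S, mask, model)))
    lam2 = model.lambda2          # 0 for zs_ssl
    want = dense_unrolled_iteration(y, S, mask, model.lambda1, lam2, 2)
    assert np.linalg.norm(got - want) / np.linalg.norm(want) < 1e-8


def test_full_sampling_fixed_point_exact(rng):
    """With RSS-normalized maps and a full mask, A^H A = I, so the untrained
    model (identity denoisers) returns A^H y exactly at any unroll depth."""
    x, S, _ = random_instance(rng, 8, 8, 3)
    mask = np.ones((8, 8))
    y = np.asarray(forward_op(x, S, mask))
    ahy = np.asarray(adjoint_op(y, S, mask))
    for n_unrolls in (1, 3):
        model = UnrolledModel("zero_mirid", n_unrolls=n_unrolls, n_cg=5,
                              denoiser_config=DenoiserConfig(n_layers=2, channels=2),
                              seed=0)
        zero_all_weights(model)
        got = np.asarray(asarray(unrolled_forward(y, S, mask, model)))
        np.testing.assert_allclose(got, ahy, atol=1e-12)


def test_zero_unrolls_returns_adjoint(rng):
    x, S, mask = random_instance(rng, 8, 8, 2)
    y = np.asarray(forward_op(x, S, mask))
    model = UnrolledModel("zero_mirid", n_unrolls=0, n_cg=5,
                          denoiser_config=DenoiserConfig(n_layers=2, channels=2))
    got = np.asarray(asarray(unrolled_forward(y, S, mask, model)))
    np.testing.assert_allclose(got, np.asarray(adjoint_op(y, S, mask)), atol=1e-14)


def test_untrained_denoiser_is_identity(rng):
    """Zero-initialized final layer makes the fresh residual CNN the identity."""
    x = rng.normal(size=(8, 8)) + 1j * rng.normal(size=(8, 8))
    model = UnrolledModel("zero_mirid", denoiser_config=DenoiserConfig(n_layers=3, channels=4))
    out = np.asarray(asarray(apply_denoiser(x, model.image_denoiser, "image", True)))
    np.testing.assert_allclose(out, x, atol=1e-14)
    out_k = np.asarray(asarray(apply_denoiser(x, model.kspace_denoiser, "kspace", True)))
    np.testing.assert_allclose(out_k, x, atol=1e-12)


def test_weight_sharing_param_count_independent_of_unrolls():
    cfg = DenoiserConfig(n_layers=3, channels=4)
    counts = {UnrolledModel("zero_mirid", n_unrolls=n, denoiser_config=cfg).n_parameters
              for n in (1, 5, 10)}
    assert len(counts) == 1


def test_zs_ssl_has_no_kspace_branch():
    model = UnrolledModel("zs_ssl", denoiser_config=DenoiserConfig(
        n_layers=3, channels=4, in_channels=2))
    assert model.kspace_denoiser is None
    assert model.lambda2 == 0.0


def test_lambda_init():
    m = UnrolledModel("zero_mirid", lambda_init=0.05,
                      denoiser_config=DenoiserConfig(n_layers=2, channels=2))
    assert m.lambda1 == pytest.approx(0.05)
    assert m.lambda2 == pytest.approx(0.05)
    with pytest.raises(ValueError):
        UnrolledModel("zero_mirid", lambda_init=0.0)


def test_checkpoint_roundtrip(tmp_path, rng):
    model = UnrolledModel("zero_mirid", n_unrolls=2, n_cg=3, lambda_init=0.2,
                          denoiser_config=DenoiserConfig(n_layers=3, channels=4), seed=5)
    path = tmp_path / "ckpt.npz"
    save_checkpoint(model, path)
    back = load_checkpoint(path)
    assert back.variant == "zero_mirid" and back.n_unrolls == 2 and back.n_cg == 3
    for k, v in model.state_dict().items():
        np.testing.assert_array_equal(np.asarray(back.state_dict()[k]), np.asarray(v))
    x, S, mask = random_instance(rng, 8, 8, 2)
    y = np.asarray(forward_op(x, S, mask))
    np.testing.assert_allclose(
        np.asarray(asarray(unrolled_forward(y, S, mask, back))),
        np.asarray(asarray(unrolled_forward(y, S, mask, model))), atol=1e-14)


def test_denoiser_channel_mismatch_errors(rng):
    x = rng.normal(size=(8, 8)).astype(complex)
    model = UnrolledModel("zero_mirid", denoiser_config=DenoiserConfig(n_layers=2, channels=2))
    with pytest.raises(ValueError):
        apply_denoiser(x, model.image_denoiser, "image", use_vc=False)
    with pytest.raises(ValueError):
        apply_denoiser(x, model.image_denoiser, "fourier", use_vc=True)
    with pytest.raises(ValueError):
        UnrolledModel("bogus")
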