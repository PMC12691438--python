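"""Training loop behavior on a tiny scan: determinism, checkpointing,
validation-driven early stopping, inference scaling."""

import numpy as np
import pytest

from zsrecon import (DenoiserConfig, LossSpec, TrainConfig, UnrolledModel,
                     make_1d_mask, partition_kspace, train_scan_specific,
                     reconstruct_inference, PhantomSpec, CoilSpec, NoiseSpec,
                     generate_phantom, simulate_coils, simulate_acquisition)
from zsrecon.trainer import Adam, _normalized_input
from zsrecon.autodiff import Tensor
from zsrecon.fourier_ops import adjoint_op


def tiny_scan(seed=0, ny=32, nx=32, n_coils=4):
    gt = generate_phantom(PhantomSpec(grid=(ny, nx), seed=seed))
    S = simulate_coils(CoilSpec(n_coils=n_coils, seed=seed + 7), np.abs(gt) > 0)
    mask = make_1d_mask(ny, nx, R=2, pf_fraction=6 / 8, acs_width=4)
    y = simulate_acquisition(gt, S, mask, NoiseSpec(sigma=0.005, seed=seed + 9))
    return y[None], S, gt[None], mask


def tiny_model(seed=0):
    return UnrolledModel("zero_mirid", n_unrolls=1, n_cg=3, lambda_init=0.05,
                         denoiser_config=DenoiserConfig(n_layers=3, channels=4),
                         seed=seed)


def test_training_runs_and_records_history():
    ksp, S, gt, mask = tiny_scan()
    parts = [partition_kspace(mask, n_pairs=2, seed=0)]
    cfg = TrainConfig(lr=1e-3, max_epochs=3, patience=3, seed=0,
                      loss=LossSpec(kind="conventional"))
    model, hist = train_scan_specific(ksp, S, mask, parts, tiny_model(), cfg)
    assert len(hist.train_loss) == len(hist.val_loss) == 3
    assert 0 <= hist.best_epoch < 3
    assert hist.best_val == min(hist.val_loss)
    assert all(np.isfinite(hist.train_loss)) and all(np.isfinite(hist.val_loss))


def test_training_deterministic():
    ksp, S, gt, mask = tiny_scan()
    outs = []
    for _ in range(2):
        parts = [partition_kspace(mask, n_pairs=2, seed=0)]
        cfg = TrainConfig(max_epochs=2, patience=2, seed=0,
                          loss=LossSpec(kind="log_scaled"))
        model, hist = train_scan_specific(ksp, S, mask, parts, tiny_model(), cfg)
        outs.append((np.array(hist.train_loss),
                     reconstruct_inference(ksp[0], S, mask, model)))
    np.testing.assert_array_equal(outs[0][0], outs[1][0])
    np.testing.assert_array_equal(outs[0][1], outs[1][1])


def test_best_validation_weights_restored():
    ksp, S, gt, mask = tiny_scan()
    parts = [partition_kspace(mask, n_pairs=2, seed=0)]
    cfg = TrainConfig(max_epochs=4, patience=4, seed=0,
                      loss=LossSpec(kind="conventional"))
    model, hist = train_scan_specific(ksp, S, mask, parts, tiny_model(), cfg)
    from zsrecon.trainer import _validation_loss
    revalidated = _validation_loss(ksp, S, parts, model, cfg.loss)
    assert revalidated == pytest.approx(hist.best_val, rel=1e-12)


def test_lambda_weights_are_trained():
    ksp, S, gt, mask = tiny_scan()
    parts = [partition_kspace(mask, n_pairs=2, seed=0)]
    model = tiny_model()
    lam_before = model.lambda1
    cfg = TrainConfig(max_epochs=2, patience=2, seed=0)
    model, hist = train_scan_specific(ksp, S, mask, parts, model, cfg)
    # rho receives gradient through the CG solve, so lambda moves off its init
    assert len(hist.lambda1) == 2
    assert hist.lambda1[0] != lam_before
    assert hist.lambda2[0] != lam_before


def test_normalized_input_scaling():
    ksp, S, gt, mask = tiny_scan()
    y_in, scale = _normalized_input(ksp[0], S, mask.as_float())
    peak = np.abs(np.asarray(adjoint_op(y_in, S, mask.as_float()))).max()
    assert peak == pytest.approx(1.0, rel=1e-12)
    with pytest.raises(ValueError):
        _normalized_input(np.zeros_like(ksp[0]), S, mask.as_float())


def test_inference_scale_inverted():
    ksp, S, gt, mask = tiny_scan()
    model = tiny_model()   # untrained: identity denoisers, near-SENSE output
    rec = reconstruct_inference(ksp[0], S, mask, model)
    # output is on the measurement scale: within a factor ~2 of |gt| peak
    assert 0.3 < np.abs(rec).max() / np.abs(gt[0]).max() < 3.0


def test_validation_requires_nonempty_subsets():
    ksp, S, gt, mask = tiny_scan()
    parts = [partition_kspace(mask, n_pairs=1, seed=0)]
    parts[0].psi = np.array([], dtype=np.int64)
    with pytest.raises(ValueError):
        train_scan_specific(ksp, S, mask, parts, tiny_model(), TrainConfig(max_epochs=1, patience=1))


def test_partition_slice_count_mismatch_errors():
    ksp, S, gt, mask = tiny_scan()
    with pytest.raises(ValueError):
        train_scan_specific(ksp, S, mask, [], tiny_model(), TrainConfig(max_epochs=1, patience=1))


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(lr=0)
    with pytest.raises(ValueError):
        TrainConfig(max_epochs=2, patience=5)


def test_adam_minimizes_quadratic():
    p = Tensor(np.array(5.0), requires_grad=True)
    opt = Adam([p], lr=0.3)
    for _ in range(200):
        p.grad = 2.0 * p.data      # d/dp p^2
        opt.step()
    assert abs(float(p.data)) < 1e-2
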