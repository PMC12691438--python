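"""Loss identities, scale invariance and log-compression properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from zsrecon import LossSpec, normalized_loss, log_scaled_loss, composite_loss
from zsrecon.autodiff import Tensor, asarray


def val(x):
    return float(asarray(x))


@pytest.fixture
def pair(rng):
    y = rng.normal(size=(8, 8)) + 1j * rng.normal(size=(8, 8))
    subset = np.flatnonzero(rng.random(64) < 0.5)
    if subset.size == 0:
        subset = np.array([0])
    return y, subset


@pytest.mark.parametrize("fn,p", [(normalized_loss, 1), (normalized_loss, 2),
                                  (log_scaled_loss, 1), (log_scaled_loss, 2)])
def test_perfect_prediction_is_zero(pair, fn, p):
    y, subset = pair
    assert val(fn(y, y, subset, p)) == 0.0


@pytest.mark.parametrize("fn,p", [(normalized_loss, 1), (normalized_loss, 2),
                                  (log_scaled_loss, 1), (log_scaled_loss, 2)])
def test_zero_prediction_is_exactly_one(pair, fn, p):
    y, subset = pair
    assert val(fn(np.zeros_like(y), y, subset, p)) == pytest.approx(1.0, abs=1e-14)


def test_combined_zero_prediction_is_four(pair):
    y, subset = pair
    assert val(composite_loss(np.zeros_like(y), y, subset,
                              LossSpec(kind="combined"))) == pytest.approx(4.0, abs=1e-13)


@pytest.mark.parametrize("p", [1, 2])
def test_conventional_scale_invariance(pair, rng, p):
    y, subset = pair
    y_hat = y + rng.normal(size=y.shape) + 1j * rng.normal(size=y.shape)
    base = val(normalized_loss(y_hat, y, subset, p))
    for alpha in (1e-3, 0.7, 42.0):
        scaled = val(normalized_loss(alpha * y_hat, alpha * y, subset, p))
        assert abs(scaled - base) < 1e-12


def test_log_loss_is_not_scale_invariant(pair, rng):
    y, subset = pair
    y_hat = y + rng.normal(size=y.shape)
    a = val(log_scaled_loss(y_hat, y, subset, 2))
    b = val(log_scaled_loss(100 * y_hat, 100 * y, subset, 2))
    assert abs(a - b) > 1e-6


def test_hand_computed_values():
    # subset = {0}; y = 3, y_hat = 3 + 4i  ->  |r| = 4
    y = np.zeros((2, 2), dtype=np.complex128); y[0, 0] = 3.0
    y_hat = y.copy(); y_hat[0, 0] += 4.0j
    subset = np.array([0])
    assert val(normalized_loss(y_hat, y, subset, 1)) == pytest.approx(4 / 3)
    assert val(normalized_loss(y_hat, y, subset, 2)) == pytest.approx(4 / 3)
    assert val(log_scaled_loss(y_hat, y, subset, 1)) == pytest.approx(
        np.log(5) / np.log(4))
    assert val(log_scaled_loss(y_hat, y, subset, 2)) == pytest.approx(
        np.log(5) ** 2 / np.log(4) ** 2)


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 10_000))
def test_log_compression_ratio(seed):
    """For residual magnitudes a < b: log1p(b)/log1p(a) < b/a (compression)."""
    rng = np.random.default_rng(seed)
    a, b = np.sort(rng.uniform(0.01, 10.0, size=2))
    if a == b:
        return
    assert np.log1p(b) / np.log1p(a) < b / a + 1e-12


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 10_000))
def test_log_spreading_beats_concentration(seed):
    """With total residual mass fixed, spread residuals give a larger p=1
    log loss than the same mass concentrated in one sample (concavity)."""
    rng = np.random.default_rng(seed)
    n = 16
    r = rng.uniform(0.0, 2.0, size=n)
    y = np.ones((4, 4), dtype=np.complex128)
    subset = np.arange(n)
    spread = val(log_scaled_loss((1 + r).reshape(4, 4).astype(complex), y, subset, 1))
    conc = np.zeros(n); conc[0] = r.sum()
    concentrated = val(log_scaled_loss((1 + conc).reshape(4, 4).astype(complex),
                                       y, subset, 1))
    assert spread >= concentrated - 1e-12


def test_subset_as_mask_or_indices_agree(pair, rng):
    y, subset = pair
    y_hat = y + rng.normal(size=y.shape)
    grid = np.zeros(64); grid[subset] = 1
    a = val(normalized_loss(y_hat, y, subset, 2))
    b = val(normalized_loss(y_hat, y, grid.reshape(8, 8), 2))
    assert a == pytest.approx(b, abs=1e-15)


def test_loss_gradients_flow(pair, rng):
    y, subset = pair
    y_hat = Tensor(y + rng.normal(size=y.shape), requires_grad=True)
    loss = composite_loss(y_hat, y, subset, LossSpec(kind="combined"))
    loss.backward()
    assert y_hat.grad is not None and np.all(np.isfinite(y_hat.grad))


def test_errors():
    y = np.ones((4, 4), dtype=np.complex128)
    with pytest.raises(ValueError):
        normalized_loss(y, y, np.array([], dtype=int), 2)
    with pytest.raises(ValueError):
        normalized_loss(y, np.zeros_like(y), np.array([0]), 2)
    with pytest.raises(ValueError):
        LossSpec(kind="bogus")
    with pytest.raises(ValueError):
        LossSpec(weights={"conventional_l1": -1.0})


def test_loss_spec_terms_and_weights():
    spec = LossSpec(kind="combined", weights={"log_scaled_l2": 2.0})
    terms = list(spec.terms())
    assert len(terms) == 4
    assert ("log_scaled", 2, 2.0) in terms
    assert ("conventional", 1, 1.0) in terms
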