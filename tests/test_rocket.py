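"""Random-kernel sampling rules, the dilated convolution, and pooling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurofp import (
    KernelBank,
    RocketKernel,
    convolve,
    global_max,
    ppv,
    rocket_transform,
    sample_kernel_bank,
)

from conftest import random_trialset
from naive import naive_convolve, naive_ppv, naive_rocket_features


def simple_kernel(weights, dilation=1, bias=0.0, padding=False, channels=(0,)):
    w = np.atleast_2d(np.asarray(weights, dtype=float))
    return RocketKernel(length=w.shape[1], dilation=dilation, weights=w,
                        bias=bias, padding=padding, channels=channels)


class TestSampling:
    def test_sampling_rules(self):
        bank = sample_kernel_bank(1000, input_length=300, n_channels=68, seed=7)
        assert len(bank) == 1000
        lengths = {k.length for k in bank.kernels}
        assert lengths == {7, 9, 11}
        for k in bank.kernels:
            assert (k.length - 1) * k.dilation <= 299
            assert k.dilation >= 1
            assert -1.0 <= k.bias <= 1.0
            # mean-centred per selected channel
            assert np.allclose(k.weights.mean(axis=1), 0.0, atol=1e-12)
            assert len(set(k.channels)) == len(k.channels)
            assert all(0 <= c < 68 for c in k.channels)
        assert {k.padding for k in bank.kernels} == {True, False}

    def test_dilation_range_matches_exponential_scale(self):
        # L=100, l_k=9: A = log2(99/8) so d = floor(2^x) ranges over 1..12
        admissible = {d for d in range(1, 100) if d <= (100 - 1) / (9 - 1)}
        assert admissible == set(range(1, 13))
        banks = [sample_kernel_bank(400, 100, 1, seed=s) for s in (0, 1)]
        seen = {k.dilation for b in banks for k in b.kernels if k.length == 9}
        assert seen <= admissible
        assert 1 in seen and max(seen) > 6  # spread across the scale

    def test_determinism_and_serialization(self, tmp_path):
        b1 = sample_kernel_bank(20, 64, 4, seed=5)
        b2 = sample_kernel_bank(20, 64, 4, seed=5)
        for k1, k2 in zip(b1.kernels, b2.kernels):
            assert k1.length == k2.length and k1.dilation == k2.dilation
            assert k1.channels == k2.channels and k1.padding == k2.padding
            assert np.array_equal(k1.weights, k2.weights) and k1.bias == k2.bias
        path = tmp_path / "bank.json"
        b1.to_json(path)
        b3 = KernelBank.from_json(path)
        assert len(b3) == len(b1) and b3.input_length == 64
        assert np.allclose(b3.kernels[7].weights, b1.kernels[7].weights)
        assert b3.kernels[7].channels == b1.kernels[7].channels

    @pytest.mark.parametrize("bad", [dict(input_length=11), dict(n_channels=0),
                                     dict(num_kernels=0)])
    def test_invalid_inputs_rejected(self, bad):
        kwargs = dict(num_kernels=5, input_length=50, n_channels=2, seed=0)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            sample_kernel_bank(**kwargs)


class TestConvolve:
    def test_hand_computed_sliding_dot_product(self):
        x = np.array([[1.0, 2, 3, 4, 5]])
        c = convolve(x, simple_kernel([1, 0, -1]))
        assert np.allclose(c, [-2, -2, -2])

    def test_hand_computed_dilated(self):
        x = np.array([[1.0, 2, 3, 4, 5, 6, 7]])
        c = convolve(x, simple_kernel([1, 0, -1], dilation=2))
        assert np.allclose(c, [-4, -4, -4])

    def test_zero_weights_yield_constant_bias(self, rng):
        x = rng.standard_normal((2, 30))
        k = simple_kernel(np.zeros((2, 7)), bias=0.37, channels=(0, 1))
        assert np.allclose(convolve(x, k), 0.37)

    def test_output_length_law(self, rng):
        x = rng.standard_normal((1, 40))
        for d, pad in [(1, False), (3, False), (1, True), (4, True)]:
            c = convolve(x, simple_kernel(rng.standard_normal((1, 7)), dilation=d, padding=pad))
            expected = 40 if pad else 40 - (7 - 1) * d
            assert len(c) == expected

    def test_too_short_input_raises(self):
        with pytest.raises(ValueError):
            convolve(np.ones((1, 5)), simple_kernel(np.ones((1, 7))))

    def test_bias_added_once_not_per_channel(self, rng):
        x = rng.standard_normal((3, 20))
        w = np.zeros((3, 7))
        k = simple_kernel(w, bias=1.0, channels=(0, 1, 2))
        assert np.allclose(convolve(x, k), 1.0)  # not 3.0


class TestPooling:
    def test_global_max(self):
        assert global_max(np.array([-2.0, -2, -2])) == -2.0
        assert global_max(np.array([0.1, 5.0, -3.0])) == 5.0
        assert global_max(np.array([1.5])) == 1.5

    def test_ppv_strict_positivity(self):
        assert ppv(np.array([-1.0, 0.0, 2.0, 3.0])) == 0.5  # zero not positive
        assert ppv(np.array([-1.0, -2.0])) == 0.0
        assert ppv(np.array([1.0, 2.0])) == 1.0

    def test_empty_output_rejected(self):
        with pytest.raises(ValueError):
            ppv(np.array([]))
        with pytest.raises(ValueError):
            global_max(np.array([]))


class TestTransform:
    def test_two_features_per_kernel(self, rng):
        trials = random_trialset(rng, n_trials=20, n_regions=3, n_samples=50)
        bank = sample_kernel_bank(500, 50, 3, seed=2)
        feats = rocket_transform(trials, bank)
        assert feats.values.shape == (20, 1000)
        assert feats.feature_names[:2] == ["k00000_ppv", "k00000_max"]

    def test_constant_positive_kernel_features(self):
        trials = random_trialset(np.random.default_rng(0), n_trials=1, n_regions=1, n_samples=20)
        bank = KernelBank(
            kernels=[simple_kernel(np.zeros((1, 7)), bias=1.0)],
            input_length=20, n_channels=1, seed=0,
        )
        feats = rocket_transform(trials, bank)
        assert np.allclose(feats.values, [[1.0, 1.0]])

    def test_matches_naive_oracle(self, rng):
        trials = random_trialset(rng, n_trials=5, n_regions=4, n_samples=64)
        bank = sample_kernel_bank(20, 64, 4, seed=9)
        fast = rocket_transform(trials, bank).values
        slow = naive_rocket_features(trials.data, bank)
        assert np.max(np.abs(fast - slow)) < 1e-9

    def test_ppv_columns_bounded_and_deterministic(self, rng):
        trials = random_trialset(rng, n_trials=8, n_regions=2, n_samples=40)
        bank = sample_kernel_bank(30, 40, 2, seed=4)
        f1 = rocket_transform(trials, bank).values
        f2 = rocket_transform(trials, bank).values
        assert np.array_equal(f1, f2)
        ppv_cols = f1[:, ::2]
        assert ppv_cols.min() >= 0.0 and ppv_cols.max() <= 1.0

    def test_shape_mismatch_rejected(self, rng):
        trials = random_trialset(rng, n_trials=3, n_regions=2, n_samples=40)
        with pytest.raises(ValueError):
            rocket_transform(trials, sample_kernel_bank(5, 41, 2, seed=0))
        with pytest.raises(ValueError):
            rocket_transform(trials, sample_kernel_bank(5, 40, 3, seed=0))


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    data=st.lists(st.floats(-10, 10, allow_nan=False), min_size=25, max_size=60),
    length=st.sampled_from([7, 9, 11]),
    dilation=st.integers(1, 2),
    padding=st.booleans(),
    seed=st.integers(0, 10_000),
)
def test_convolution_properties(data, length, dilation, padding, seed):
    """Output-length law, ppv bounds and the negation identity on random kernels."""
    x = np.array([data])
    rng = np.random.default_rng(seed)
    w = rng.standard_normal((1, length))
    w -= w.mean(axis=1, keepdims=True)
    k = simple_kernel(w, dilation=dilation, bias=float(rng.uniform(-1, 1)), padding=padding)
    c = convolve(x, k)
    expected = len(data) if padding else len(data) - (length - 1) * dilation
    assert len(c) == expected
    assert np.allclose(c, naive_convolve(x, k.channels, k.weights, k.bias, k.dilation, k.padding))
    p = ppv(c)
    assert 0.0 <= p <= 1.0
    if not np.any(c == 0):
        assert ppv(-c) == pytest.approx(1.0 - p)
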