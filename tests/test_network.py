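"""Unit tests for the CELM core: convolution, pooling, features, ELM."""

import numpy as np
import pytest

from celmfuse import (
    RunConfig,
    branch_features,
    conv_relu,
    elm_fit,
    elm_predict,
    global_avg_pool,
    init_kernel_bank,
    max_pool,
    pair_features,
    patch_trace,
)
from celmfuse.network import ConvLayer, batch_pair_features


def conv_relu_bruteforce(stack, layer):
    """Literal double-loop valid cross-correlation + ReLU oracle."""
    cin, h, w = stack.shape
    cout = layer.kernels.shape[0]
    r = layer.kernels.shape[-1]
    out = np.zeros((cout, h - r + 1, w - r + 1))
    for o in range(cout):
        for y in range(h - r + 1):
            for x in range(w - r + 1):
                acc = layer.biases[o]
                for i in range(cin):
                    for m in range(r):
                        for n in range(r):
                            acc += stack[i, y + m, x + n] * layer.kernels[o, i, m, n]
                out[o, y, x] = max(acc, 0.0)
    return out


class TestKernelBank:
    def test_default_architecture(self, config):
        bank = init_kernel_bank(config, seed=0)
        assert bank.channel_counts() == (64, 128, 256)
        in_c = 1
        for layer, out_c in zip(bank.layers, (64, 128, 256)):
            assert layer.kernels.shape == (out_c, in_c, 3, 3)
            assert np.all(layer.biases == 0.0)
            in_c = out_c

    def test_seed_determinism(self, config):
        b1 = init_kernel_bank(config, seed=42)
        b2 = init_kernel_bank(config, seed=42)
        for l1, l2 in zip(b1.layers, b2.layers):
            np.testing.assert_array_equal(l1.kernels, l2.kernels)
        b3 = init_kernel_bank(config, seed=43)
        assert not np.array_equal(b1.layers[0].kernels, b3.layers[0].kernels)

    def test_layer1_moments(self, config):
        # layer 1 fan_in = 9, so entries ~ N(0, 1/9); check first two
        # sample moments within 3 standard errors over >= 10^4 draws
        draws = init_kernel_bank(config, seed=7).layers[1].kernels.ravel()
        sigma = 1.0 / np.sqrt(64 * 9)
        n = draws.size
        assert n >= 10_000
        assert abs(draws.mean()) < 3 * sigma / np.sqrt(n)
        se_std = sigma / np.sqrt(2 * (n - 1))
        assert abs(draws.std(ddof=1) - sigma) < 3 * se_std


class TestConvRelu:
    def test_output_size(self):
        layer = ConvLayer(np.ones((2, 1, 3, 3)), np.zeros(2))
        out = conv_relu(np.ones((1, 32, 32)), layer)
        assert out.shape == (2, 30, 30)

    def test_zero_input_zero_bias(self):
        layer = ConvLayer(np.ones((4, 1, 3, 3)), np.zeros(4))
        out = conv_relu(np.zeros((1, 8, 8)), layer)
        assert np.all(out == 0.0)

    def test_single_window_product_sum(self, rng):
        x = rng.normal(size=(1, 3, 3))
        k = rng.normal(size=(1, 1, 3, 3))
        layer = ConvLayer(k, np.zeros(1))
        out = conv_relu(x, layer)
        expect = max(float((x[0] * k[0, 0]).sum()), 0.0)
        assert out.shape == (1, 1, 1)
        assert out[0, 0, 0] == pytest.approx(expect, abs=1e-12)

    def test_too_small_input_raises(self):
        layer = ConvLayer(np.ones((1, 1, 3, 3)), np.zeros(1))
        with pytest.raises(ValueError):
            conv_relu(np.ones((1, 2, 2)), layer)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        cin, cout = rng.integers(1, 4), rng.integers(1, 4)
        h, w = rng.integers(3, 9, size=2)
        x = rng.normal(size=(cin, h, w))
        layer = ConvLayer(
            rng.normal(size=(cout, cin, 3, 3)), rng.normal(size=cout)
        )
        np.testing.assert_allclose(
            conv_relu(x, layer), conv_relu_bruteforce(x, layer), atol=1e-12
        )


class TestPooling:
    def test_halves_dimensions(self):
        assert max_pool(np.zeros((1, 30, 30))).shape == (1, 15, 15)
        # odd inputs drop the trailing row/column
        assert max_pool(np.zeros((1, 13, 13))).shape == (1, 6, 6)

    def test_constant_map_unchanged(self):
        out = max_pool(np.full((2, 8, 8), 3.5))
        assert np.all(out == 3.5)

    def test_enumerated_blocks(self):
        x = np.arange(1, 17, dtype=float).reshape(1, 4, 4)
        np.testing.assert_array_equal(
            max_pool(x)[0], [[6.0, 8.0], [14.0, 16.0]]
        )

    def test_global_avg_pool(self):
        stack = np.stack(
            [np.array([[0.0, 1.0], [2.0, 3.0]]), np.full((2, 2), 4.0)]
        )
        np.testing.assert_allclose(global_avg_pool(stack), [1.5, 4.0])


class TestBranchFeatures:
    def test_spatial_trace_and_length(self, config):
        assert patch_trace(config) == (32, 30, 15, 13, 6, 4)
        bank = init_kernel_bank(config, seed=0)
        f = branch_features(np.random.default_rng(0).random((32, 32)), bank, config)
        assert f.shape == (256,)
        assert np.all(f >= 0.0)  # post-ReLU means

    def test_zero_patch_gives_zero_vector(self, config):
        bank = init_kernel_bank(config, seed=0)
        np.testing.assert_array_equal(
            branch_features(np.zeros((32, 32)), bank, config), np.zeros(256)
        )

    def test_wrong_size_raises(self, config):
        bank = init_kernel_bank(config, seed=0)
        with pytest.raises(ValueError):
            branch_features(np.zeros((16, 16)), bank, config)

    def test_pair_symmetry(self, config, rng):
        bank = init_kernel_bank(config, seed=0)
        pa, pb = rng.random((32, 32)), rng.random((32, 32))
        fab = pair_features(pa, pb, bank, config)
        fba = pair_features(pb, pa, bank, config)
        assert fab.shape == (512,)
        np.testing.assert_array_equal(fab[:256], fba[256:])
        np.testing.assert_array_equal(fab[256:], fba[:256])
        same = pair_features(pa, pa, bank, config)
        np.testing.assert_array_equal(same[:256], same[256:])

    def test_batch_matches_single(self, config, rng):
        bank = init_kernel_bank(config, seed=0)
        pa, pb = rng.random((3, 32, 32)), rng.random((3, 32, 32))
        batch = batch_pair_features(pa, pb, bank, config)
        for i in range(3):
            np.testing.assert_allclose(
                batch[i], pair_features(pa[i], pb[i], bank, config), atol=1e-12
            )


def ridge_svd_oracle(H, T, C):
    """Independent SVD solution of (I/C + H^T H) beta = H^T T."""
    U, s, Vt = np.linalg.svd(H, full_matrices=False)
    return Vt.T @ (s / (s**2 + 1.0 / C) * (U.T @ T))


class TestELM:
    def test_identity_design_closed_form(self, rng):
        T = rng.normal(size=6)
        model = elm_fit(np.eye(6), T, C=2.0)
        np.testing.assert_allclose(model.beta, (2.0 / 3.0) * T, atol=1e-12)

    def test_zero_targets(self, rng):
        model = elm_fit(rng.normal(size=(10, 4)), np.zeros(10), C=1.0)
        np.testing.assert_allclose(model.beta, np.zeros(4), atol=1e-12)

    def test_matches_svd_oracle(self):
        rng = np.random.default_rng(0)
        H = rng.normal(size=(20, 8))
        T = rng.normal(size=20)
        model = elm_fit(H, T, C=1.0)
        np.testing.assert_allclose(model.beta, ridge_svd_oracle(H, T, 1.0), atol=1e-8)

    def test_nonfinite_rejected(self):
        H = np.ones((4, 2))
        H[0, 0] = np.nan
        with pytest.raises(ValueError):
            elm_fit(H, np.ones(4), C=1.0)

    def test_predict_contracts(self, rng):
        model = elm_fit(np.eye(3), np.array([0.0, 0.5, 2.0]), C=1e6)
        assert elm_predict(np.zeros(3), model) == 0.0
        zero = elm_fit(np.eye(3), np.zeros(3), C=1.0)
        assert elm_predict(rng.normal(size=3), zero) == 0.0
        with pytest.raises(ValueError):
            elm_predict(np.zeros(5), model)

    def test_separable_toy_problem(self):
        # 10 separable points: class means far apart relative to noise
        rng = np.random.default_rng(3)
        H = np.vstack(
            [rng.normal(0.0, 0.05, size=(5, 4)), rng.normal(1.0, 0.05, size=(5, 4))]
        )
        T = np.array([0.0] * 5 + [1.0] * 5)
        model = elm_fit(H, T, C=100.0)
        scores = elm_predict(H, model)
        assert np.all((scores >= 0.5) == (T == 1.0))
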