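"""Scale-channel network: gradients, head geometry, causality, contracts."""

import numpy as np
import pytest

from covrf.network import (
    NetworkConfig,
    ScaleChannelNet,
    build_model,
    coordinate_transform,
    event_im2col,
    initialize_rf,
    initialize_uniform,
)
from covrf.spatial import build_bank
from covrf.temporal import log_time_constants
from covrf.training import _l2_loss_and_grad


def tiny_config(**kw):
    defaults = dict(
        n_scale_channels=2, kernels_per_block=3, kernel_size=3,
        n_output_shapes=2, variant="LI", init="uniform", resolution=16,
        strides=(2, 2, 2),
    )
    defaults.update(kw)
    return NetworkConfig(**defaults)


class TestCoordinateTransform:
    def test_point_mass(self):
        m = np.zeros((30, 30))
        m[20, 10] = 1.0
        coords, flags = coordinate_transform(m)
        assert np.allclose(coords, [10.0, 20.0])
        assert not flags

    def test_uniform_map_center(self):
        coords, _ = coordinate_transform(np.ones((300, 300)))
        assert np.allclose(coords, [149.5, 149.5])

    def test_two_equal_masses_midpoint(self):
        m = np.zeros((20, 20))
        m[0, 0] = m[0, 10] = 1.0
        coords, _ = coordinate_transform(m)
        assert np.allclose(coords, [5.0, 0.0])

    def test_all_zero_fallback_flagged(self):
        coords, flags = coordinate_transform(np.zeros((10, 10)))
        assert flags
        assert np.allclose(coords, [4.5, 4.5])

    def test_translation_equivariance(self, rng):
        m = np.zeros((40, 40))
        m[8:14, 6:12] = rng.random((6, 6)) + 0.1
        base, _ = coordinate_transform(m)
        for dx, dy in ((3, 0), (0, 5), (7, 9)):
            shifted = np.roll(np.roll(m, dy, axis=0), dx, axis=1)
            coords, _ = coordinate_transform(shifted)
            assert np.allclose(coords, base + [dx, dy], atol=1e-9)

    def test_softmax_equivariance(self, rng):
        # peak dominant enough that the wrapped-around background carries
        # no softmax mass
        m = np.zeros((30, 30))
        m[12, 17] = 30.0
        m[13, 17] = 28.0
        base, _ = coordinate_transform(m, weighting="softmax")
        shifted = np.roll(np.roll(m, 2, axis=0), 4, axis=1)
        coords, _ = coordinate_transform(shifted, weighting="softmax")
        assert np.allclose(coords, base + [4.0, 2.0], atol=1e-6)


class TestGradients:
    def test_backward_matches_finite_differences(self):
        """Hand-derived BPTT gradients agree with central differences."""
        model = ScaleChannelNet(tiny_config(), seed=0)
        model.dtype = np.float64
        for k in model.params:
            model.params[k] = model.params[k].astype(np.float64)
        rng = np.random.default_rng(1)
        frames = (rng.random((2, 6, 2, 16, 16)) < 0.1).astype(np.float64)
        labels = rng.uniform(2, 14, size=(2, 6, 2, 2))

        def loss_fn():
            return _l2_loss_and_grad(model.forward(frames), labels)[0]

        model.zero_grad()
        coords = model.forward(frames, train=True)
        _, gc = _l2_loss_and_grad(coords, labels)
        model.backward(gc)
        eps = 1e-6
        for name in ("W1.0", "W2.1", "W3.0", "W4"):
            w = model.params[name]
            for _ in range(3):
                ij = tuple(rng.integers(0, s) for s in w.shape)
                orig = w[ij]
                w[ij] = orig + eps
                lp = loss_fn()
                w[ij] = orig - eps
                lm = loss_fn()
                w[ij] = orig
                num = (lp - lm) / (2 * eps)
                ana = model.grads[name][ij]
                assert abs(num - ana) <= 1e-4 * (abs(num) + abs(ana) + 1e-8)
        for name in model.mus:
            orig = model.mus[name]
            model.mus[name] = orig + eps
            lp = loss_fn()
            model.mus[name] = orig - eps
            lm = loss_fn()
            model.mus[name] = orig
            num = (lp - lm) / (2 * eps)
            assert abs(num - model.mu_grads[name]) <= 1e-4 * (
                abs(num) + abs(model.mu_grads[name]) + 1e-8
            )

    def test_batchnorm_gradients(self, rng):
        """Finite-difference check of the optional normalization stage."""
        model = ScaleChannelNet(tiny_config(use_batchnorm=True), seed=0)
        model.dtype = np.float64
        for k in model.params:
            model.params[k] = model.params[k].astype(np.float64)
        frames = (rng.random((2, 5, 2, 16, 16)) < 0.15).astype(np.float64)
        labels = rng.uniform(2, 14, size=(2, 5, 2, 2))
        model.zero_grad()
        coords = model.forward(frames, train=True)
        _, gc = _l2_loss_and_grad(coords, labels)
        model.backward(gc)
        eps = 1e-6
        w = model.params["W2.0"]
        for _ in range(4):
            ij = tuple(rng.integers(0, s) for s in w.shape)
            orig = w[ij]
            w[ij] = orig + eps
            lp = _l2_loss_and_grad(model.forward(frames), labels)[0]
            w[ij] = orig - eps
            lm = _l2_loss_and_grad(model.forward(frames), labels)[0]
            w[ij] = orig
            num = (lp - lm) / (2 * eps)
            ana = model.grads["W2.0"][ij]
            assert abs(num - ana) <= 1e-4 * (abs(num) + abs(ana) + 1e-8)

    def test_sparse_first_layer_matches_dense(self, rng):
        from scipy import sparse

        cfg = tiny_config(kernel_size=3, strides=(2, 2, 2))
        model = ScaleChannelNet(cfg, seed=2)
        frames = (rng.random((3, 5, 2, 16, 16)) < 0.1).astype(np.float32)
        dense = model.forward(frames)
        cols = sparse.vstack(
            [event_im2col(f, 3, 2) for f in frames], format="csr"
        )
        sp = model.forward(block1_cols=cols, batch_shape=(3, 5))
        assert np.allclose(dense, sp, atol=1e-6)


class TestArchitecture:
    def test_default_configuration_shape(self, default_bank):
        cfg = NetworkConfig()
        model = build_model(cfg, bank=default_bank, seed=0)
        assert cfg.n_scale_channels == 4
        assert model.params["W1.0"].shape == (144, 2, 9, 9)
        assert model.params["W4"].shape == (3, 4 * 144, 1, 1)

    def test_single_path_degenerate_model_runs(self):
        cfg = tiny_config(n_scale_channels=1, kernels_per_block=1,
                          n_output_shapes=1)
        model = ScaleChannelNet(cfg, seed=0)
        frames = np.zeros((1, 4, 2, 16, 16), np.float32)
        frames[0, 1, 0, 8, 8] = 1
        coords = model.forward(frames)
        assert coords.shape == (1, 4, 1, 2)
        assert np.isfinite(coords).all()

    def test_mf_variant_consumes_eight_frames(self):
        cfg = tiny_config(variant="ReLU-MF")
        model = ScaleChannelNet(cfg, seed=0)
        assert model.params["W1.0"].shape[1] == 16  # 2 polarities x 8 frames
        frames = np.zeros((1, 10, 2, 16, 16), np.float32)
        assert model.forward(frames).shape == (1, 10, 2, 2)

    def test_input_shape_contract(self):
        model = ScaleChannelNet(tiny_config(), seed=0)
        with pytest.raises(ValueError):
            model.forward(np.zeros((1, 4, 3, 16, 16), np.float32))

    @pytest.mark.parametrize("variant", ["LI", "LIF", "ReLU-SF"])
    def test_forward_is_causal(self, variant, rng):
        """Outputs at frame t are unchanged by modifying frames > t."""
        # low LIF threshold so the sparse test input actually spikes
        model = ScaleChannelNet(
            tiny_config(variant=variant, theta_thr=0.05), seed=0
        )
        frames = (rng.random((1, 8, 2, 16, 16)) < 0.15).astype(np.float32)
        before = model.forward(frames)
        tampered = frames.copy()
        tampered[:, 5:] = rng.random(tampered[:, 5:].shape) < 0.5
        after = model.forward(tampered)
        assert np.allclose(before[:, :5], after[:, :5], atol=1e-6)
        assert not np.allclose(before[:, 5:], after[:, 5:], atol=1e-6)


class TestInitialization:
    def test_rf_assignment_contract(self, small_bank):
        cfg = NetworkConfig(
            n_scale_channels=2, kernels_per_block=8, variant="LI", init="rf",
            resolution=64, strides=(4, 2, 2),
        )
        mus = log_time_constants(2)
        model = build_model(cfg, bank=small_bank, mus=mus, seed=0)
        for ch in range(2):
            w1 = model.params[f"W1.{ch}"]
            for pol in range(2):
                assert np.allclose(w1[:, pol], small_bank.kernels)
            assert model.mus[f"mu1.{ch}"] == pytest.approx(mus.mus[ch])
            # block-3 time constant fixed to the fastest
            assert model.mus[f"mu3.{ch}"] == pytest.approx(mus.mus.min())
        assert model.mus["mu4"] == pytest.approx(mus.mus.min())

    def test_uniform_matches_parameter_domain(self, small_bank):
        cfg = NetworkConfig(
            n_scale_channels=2, kernels_per_block=8, variant="LI",
            init="uniform", resolution=64, strides=(4, 2, 2),
        )
        mus = log_time_constants(2)
        model = build_model(cfg, bank=small_bank, mus=mus, seed=3)
        lo, hi = small_bank.kernels.min(), small_bank.kernels.max()
        for ch in range(2):
            w1 = model.params[f"W1.{ch}"]
            assert w1.min() >= lo and w1.max() <= hi
            # roughly fills the domain
            assert w1.max() > 0.5 * hi and w1.min() < 0.5 * lo
            for b in (1, 2, 3):
                mu = model.mus[f"mu{b}.{ch}"]
                assert mus.mus.min() <= mu <= mus.mus.max()

    def test_bank_size_mismatch_rejected(self, small_bank):
        cfg = NetworkConfig(n_scale_channels=2, kernels_per_block=7,
                            init="rf", resolution=64)
        with pytest.raises(ValueError):
            build_model(cfg, bank=small_bank, mus=log_time_constants(2))


class TestPersistence:
    def test_checkpoint_roundtrip(self, tmp_path, small_bank):
        cfg = NetworkConfig(
            n_scale_channels=2, kernels_per_block=8, variant="LI", init="rf",
            resolution=64, strides=(4, 2, 2),
        )
        model = build_model(cfg, bank=small_bank,
                            mus=log_time_constants(2), seed=0)
        p = tmp_path / "model.npz"
        model.save(p)
        loaded = ScaleChannelNet.load(p)
        assert loaded.config == model.config
        assert loaded.mus == model.mus
        for k in model.params:
            assert np.allclose(loaded.params[k], model.params[k])
        assert "ScaleChannelNet" in loaded.describe()
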