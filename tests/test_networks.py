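"""Channel packing, U-Net construction contract, and training mechanics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from dualrecon.networks import (UNetConfig, build_unet, channels_to_complex,
                                complex_to_channels, forward_inet, forward_knet,
                                load_model, save_model)
from dualrecon.nn.layers import Conv2d
from dualrecon.nn.train import train_network


class TestChannelPacking:
    def test_constant_complex(self):
        z = np.full((8, 8), 3 + 4j)
        t = complex_to_channels(z)
        assert (t[0] == 3).all() and (t[1] == 4).all()

    def test_purely_real_has_zero_imag_channel(self):
        z = np.ones((4, 4), dtype=complex)
        assert not complex_to_channels(z)[1].any()

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(hnp.arrays(np.complex128, (6, 6),
                      elements=st.complex_numbers(max_magnitude=1e6,
                                                  allow_nan=False,
                                                  allow_infinity=False)))
    def test_round_trip_exact(self, z):
        assert np.array_equal(channels_to_complex(complex_to_channels(z)), z)

    def test_bad_shapes_rejected(self):
        with pytest.raises(ValueError):
            complex_to_channels(np.zeros((2, 2, 2), dtype=complex))
        with pytest.raises(ValueError):
            channels_to_complex(np.zeros((3, 4, 4)))


class TestUNetConstruction:
    def test_shape_contract(self):
        net = build_unet(UNetConfig(base_filters=8, seed=0))
        x = np.random.default_rng(0).normal(size=(1, 2, 64, 64)).astype(np.float32)
        assert net.forward(x).shape == (1, 2, 64, 64)

    def test_layer_census_matches_design(self):
        census = build_unet(UNetConfig(base_filters=4, seed=0)).conv_census()
        assert census == {"conv3x3": 10, "conv1x1": 1}

    def test_parameter_count_grows_with_width(self):
        n8 = build_unet(UNetConfig(base_filters=8, seed=0)).n_parameters()
        n16 = build_unet(UNetConfig(base_filters=16, seed=0)).n_parameters()
        assert n16 > n8

    def test_depth_census_coupling_enforced(self):
        with pytest.raises(ValueError, match="4\\*depth"):
            UNetConfig(n_conv3=12, depth=2)

    def test_indivisible_dims_rejected(self):
        net = build_unet(UNetConfig(base_filters=4, seed=0))
        with pytest.raises(ValueError, match="divisible"):
            net.forward(np.zeros((1, 2, 30, 30), dtype=np.float32))

    def test_convolutions_bias_free_normal_init(self):
        net = build_unet(UNetConfig(base_filters=16, init_sigma=0.05, seed=3))
        convs = [l for l in net._all_layers() if isinstance(l, Conv2d)]
        convs += [l.conv for l in net._all_layers() if hasattr(l, "conv")]
        assert all(not hasattr(c, "b") for c in convs)
        big = max(convs, key=lambda c: c.w.size).w
        assert abs(float(big.mean())) < 0.01
        assert abs(float(big.std()) - 0.05) < 0.01

    def test_seed_controls_weights(self):
        a = build_unet(UNetConfig(base_filters=4, seed=1))
        b = build_unet(UNetConfig(base_filters=4, seed=1))
        c = build_unet(UNetConfig(base_filters=4, seed=2))
        assert np.array_equal(a.params()[0][0], b.params()[0][0])
        assert not np.array_equal(a.params()[0][0], c.params()[0][0])


class TestInference:
    def test_repeated_inference_identical(self):
        net = build_unet(UNetConfig(base_filters=4, seed=0))
        rng = np.random.default_rng(5)
        k = rng.normal(size=(32, 32)) + 1j * rng.normal(size=(32, 32))
        assert np.array_equal(forward_knet(k, net), forward_knet(k, net))

    def test_output_finite_for_unit_scaled_input(self):
        net = build_unet(UNetConfig(base_filters=4, seed=0))
        rng = np.random.default_rng(6)
        img = rng.normal(size=(32, 32)) + 1j * rng.normal(size=(32, 32))
        img /= np.abs(img).max()
        assert np.isfinite(forward_inet(img, net)).all()

    def test_save_load_round_trip(self, tmp_path):
        net = build_unet(UNetConfig(base_filters=4, seed=9))
        rng = np.random.default_rng(1)
        x = rng.normal(size=(1, 2, 16, 16)).astype(np.float32)
        y0 = net.forward(x)
        save_model(net, tmp_path / "ckpt")
        net2 = load_model(tmp_path / "ckpt")
        assert np.array_equal(net2.forward(x), y0)


class TestTrainingMechanics:
    def test_identity_training_reduces_held_out_mse(self):
        """A few epochs on identity pairs (label = input) drop the held-out
        MSE below its initial value."""
        rng = np.random.default_rng(0)
        imgs = np.stack([complex_to_channels(
            (rng.normal(size=(32, 32)) + 1j * rng.normal(size=(32, 32))) * 0.2)
            for _ in range(9)]).astype(np.float32)
        net = build_unet(UNetConfig(base_filters=8, seed=1))
        hist = train_network(net, imgs[:8], imgs[:8], imgs[8:], imgs[8:],
                             max_epochs=8, batch_size=4, seed=0)
        assert hist.best_val_loss() < hist.initial_val_loss
        assert all(np.isfinite(e.val_loss) for e in hist.epochs)

    def test_lr_drops_after_ten_stale_epochs(self):
        """With a validation loss that can never improve, the plateau schedule
        cuts the learning rate from 1e-3 to 1e-4 after 10 stale epochs."""
        x = np.zeros((4, 2, 16, 16), dtype=np.float32)
        net = build_unet(UNetConfig(base_filters=4, seed=0))
        # zero inputs and zero labels: loss is exactly 0 every epoch
        hist = train_network(net, x, x, x, x, max_epochs=12, batch_size=4,
                             seed=0, lr0=1e-3, lr_factor=0.1, lr_patience=10,
                             early_patience=50)
        lrs = hist.lrs
        assert lrs[0] == pytest.approx(1e-3)
        assert lrs[10] == pytest.approx(1e-3)   # epoch 11: tenth stale epoch
        assert lrs[11] == pytest.approx(1e-4)   # reduction takes effect next epoch

    def test_empty_dataset_rejected(self):
        net = build_unet(UNetConfig(base_filters=4, seed=0))
        empty = np.zeros((0, 2, 16, 16), dtype=np.float32)
        with pytest.raises(ValueError, match="empty"):
            train_network(net, empty, empty, empty, empty)
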