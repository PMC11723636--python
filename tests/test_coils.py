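"""Walsh estimation, adaptive combination, and multi-coil data consistency."""

import numpy as np
import pytest

from dualrecon.coils import (AcquiredData, acquire, adaptive_combine, dc_single,
                             estimate_maps_from_center, mcdc, walsh_maps)
from dualrecon.synthetic import biot_savart_maps, CoilGeometry, make_phantom
from dualrecon.transforms import SamplingMask, fft2c, vd_mask


class TestWalsh:
    def test_single_coil_unit_magnitude(self):
        rng = np.random.default_rng(0)
        img = rng.normal(size=(1, 16, 16)) + 1j * rng.normal(size=(1, 16, 16))
        maps = walsh_maps(img, block_size=3)
        assert np.max(np.abs(np.abs(maps.maps[0]) - 1.0)) < 1e-12

    def test_recovers_true_maps_noise_free(self, maps64, phantom64):
        """On noise-free simulated coil images with a per-pixel (rank-1)
        correlation matrix, the principal eigenvector reproduces the true
        sensitivities up to a global phase."""
        m = phantom64.image + 0.2 * np.exp(0.3j)  # nonzero everywhere
        coil_images = maps64.maps * m[None]
        est = walsh_maps(coil_images, block_size=1)
        mag_err = np.abs(np.abs(est.maps) - np.abs(maps64.maps))
        assert mag_err.max() < 1e-3
        # relative inter-coil phase is also recovered
        rel_est = est.maps[3] * np.conj(est.maps[0])
        rel_true = maps64.maps[3] * np.conj(maps64.maps[0])
        assert np.max(np.abs(rel_est - rel_true)) < 1e-6

    def test_coil_permutation_equivariance(self, maps64, phantom64):
        m = phantom64.image + 0.1
        coil_images = maps64.maps * m[None]
        perm = [3, 0, 1, 2, 7, 6, 5, 4]
        a = walsh_maps(coil_images, 5).maps[perm]
        b = walsh_maps(coil_images[perm], 5).maps
        # same eigenvectors, possibly different per-pixel reference phase
        assert np.max(np.abs(np.abs(a) - np.abs(b))) < 1e-10

    def test_block_validation(self):
        img = np.ones((2, 8, 8), dtype=complex)
        with pytest.raises(ValueError, match="odd"):
            walsh_maps(img, block_size=4)
        with pytest.raises(ValueError, match="exceeds"):
            walsh_maps(img, block_size=9)

    def test_center_band_estimation_close_to_truth(self, maps64, multicoil64):
        mask = vd_mask(64, 2, seed=5)
        acq = acquire(multicoil64.frame_kspace(0), mask)
        est = estimate_maps_from_center(acq, block_size=7)
        inside = np.abs(multicoil64.frame_images(0)).sum(axis=0) > 0.1
        err = np.abs(np.abs(est.maps) - np.abs(maps64.maps))[:, inside]
        assert np.median(err) < 0.1  # low-resolution estimate, object region


class TestAdaptiveCombine:
    def test_exact_inverse_of_expansion(self, maps64, phantom64, multicoil64):
        rec = adaptive_combine(multicoil64.frame_images(0), maps64)
        assert np.max(np.abs(rec - phantom64.image)) < 1e-10

    def test_zero_and_linearity(self, maps64):
        zeros = np.zeros_like(maps64.maps)
        assert not adaptive_combine(zeros, maps64).any()
        rng = np.random.default_rng(1)
        c = rng.normal(size=maps64.maps.shape) + 1j * rng.normal(size=maps64.maps.shape)
        a = adaptive_combine(3.5j * c, maps64)
        b = 3.5j * adaptive_combine(c, maps64)
        assert np.max(np.abs(a - b)) < 1e-12

    def test_shape_mismatch_rejected(self, maps64):
        with pytest.raises(ValueError):
            adaptive_combine(np.zeros((3, 64, 64), dtype=complex), maps64)


class TestDcSingle:
    def test_full_and_empty_masks(self, full_mask64, empty_mask64):
        rng = np.random.default_rng(0)
        k_est = rng.normal(size=(64, 64)) + 0j
        acq = rng.normal(size=(64, 64)) + 0j
        assert np.array_equal(dc_single(k_est, acq, full_mask64), acq)
        assert np.array_equal(dc_single(k_est, np.zeros_like(acq), empty_mask64), k_est)

    def test_hand_enumerated_4x4(self):
        """4x4 grid, phase-encode lines {1, 2} sampled: output columns 1 and 2
        carry the acquired ones, all other entries stay at the estimate (0)."""
        mask = SamplingMask(lines=np.array([0, 1, 1, 0], dtype=np.uint8),
                            af_nominal=2.0, center_fraction=0.5, sigma=0.15, seed=0)
        acq = np.zeros((4, 4), dtype=complex)
        acq[:, 1:3] = 1.0
        out = dc_single(np.zeros((4, 4), dtype=complex), acq, mask)
        expected = np.zeros((4, 4), dtype=complex)
        expected[:, 1:3] = 1.0
        assert np.array_equal(out, expected)

    def test_soft_weight_blends(self, full_mask64):
        k_est = np.full((64, 64), 2.0 + 0j)
        acq = np.full((64, 64), 4.0 + 0j)
        out = dc_single(k_est, acq, full_mask64, weight=0.5)
        assert np.max(np.abs(out - 3.0)) < 1e-12


class TestMcdc:
    def test_full_sampling_returns_reference(self, maps64, phantom64, multicoil64,
                                             full_mask64):
        acq = acquire(multicoil64.frame_kspace(0), full_mask64)
        out = mcdc(np.zeros((64, 64), dtype=complex), maps64, acq)
        assert np.max(np.abs(out - phantom64.image)) < 1e-10

    def test_empty_mask_is_identity(self, maps64, empty_mask64):
        acq = AcquiredData(np.zeros((8, 64, 64), dtype=complex), empty_mask64)
        composite = make_phantom((64, 64), seed=11).image + 0.05
        out = mcdc(composite, maps64, acq)
        assert np.max(np.abs(out - composite)) < 1e-10

    def test_true_image_is_fixed_point(self, maps64, phantom64, acquired_af2):
        out = mcdc(phantom64.image, maps64, acquired_af2)
        assert np.max(np.abs(out - phantom64.image)) < 1e-10

    def test_sampled_residual_strictly_decreases(self, maps64, acquired_af2):
        """Each MCDC pass reduces the k-space misfit on the acquired lines —
        the operator moves the composite toward data consistency even though
        a single pass is not an exact projection."""
        lines = acquired_af2.mask.lines.astype(bool)

        def resid(x):
            total = 0.0
            for i in range(maps64.n_coils):
                diff = (fft2c(maps64.maps[i] * x)
                        - acquired_af2.coil_kspace_acq[i])[:, lines]
                total += float(np.sum(np.abs(diff) ** 2))
            return np.sqrt(total)

        x = adaptive_combine(acquired_af2.coil_images(), maps64)
        r_prev = resid(x)
        for _ in range(3):
            x = mcdc(x, maps64, acquired_af2)
            r = resid(x)
            assert r < r_prev
            r_prev = r

    def test_coil_count_mismatch_rejected(self, maps64, empty_mask64):
        acq = AcquiredData(np.zeros((4, 64, 64), dtype=complex), empty_mask64)
        with pytest.raises(ValueError, match="coils"):
            mcdc(np.zeros((64, 64), dtype=complex), maps64, acq)
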