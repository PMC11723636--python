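"""Phantom generation, Biot-Savart coil simulation, HDF5 round trips."""

import numpy as np
import pytest

from dualrecon.coils import adaptive_combine
from dualrecon.synthetic import (CoilGeometry, biot_savart_field,
                                 biot_savart_maps, count_examples,
                                 expand_to_coils, make_cine_volume,
                                 make_phantom, read_dataset, write_dataset)
from dualrecon.transforms import fft2c


class TestPhantom:
    def test_deterministic_and_seed_sensitive(self):
        a = make_phantom((64, 64), seed=7)
        b = make_phantom((64, 64), seed=7)
        c = make_phantom((64, 64), seed=8)
        assert np.array_equal(a.image, b.image)
        assert np.max(np.abs(a.image - c.image)) > 0

    def test_magnitude_range_and_background(self):
        ph = make_phantom((128, 128), seed=2)
        mag = np.abs(ph.image)
        assert mag.max() <= 1.0
        assert np.mean(mag == 0) >= 0.05  # exact-zero background

    def test_smooth_nontrivial_phase(self):
        ph = make_phantom((64, 64), seed=4)
        inside = np.abs(ph.image) > 0.1
        phase = np.angle(ph.image[inside])
        assert np.ptp(phase) > 0.1  # real/imag splitting is nontrivial

    @pytest.mark.parametrize("shape", [(30, 64), (64, 33), (16, 16)])
    def test_bad_shapes_rejected(self, shape):
        with pytest.raises(ValueError, match="even|32"):
            make_phantom(shape, seed=0)

    def test_shepp_logan_matches_reference_implementation(self):
        """The 400x400 rendering agrees with scikit-image's stored phantom
        and shows the classical intensity plateaus."""
        import skimage.data

        ref = skimage.data.shepp_logan_phantom()
        mine = np.abs(make_phantom((400, 400), seed=0, kind="shepp_logan").image)
        diff = np.abs(mine - ref)
        assert diff.mean() < 0.01
        assert (diff > 0.05).mean() < 0.01  # only anti-aliased edge pixels
        for level in (0.0, 0.1, 0.2, 0.3, 1.0):
            assert np.mean(np.abs(mine - level) < 0.005) > 1e-3

    def test_cardiac_phase_contracts_ventricle(self):
        rest = make_phantom((64, 64), seed=1, phase=0.0)
        systole = make_phantom((64, 64), seed=1, phase=0.5)
        # bright blood pool (magnitude > 0.8) shrinks at mid-cycle
        assert (np.abs(systole.image) > 0.8).sum() < (np.abs(rest.image) > 0.8).sum()


class TestBiotSavart:
    def test_single_coil_unit_magnitude(self):
        geo = CoilGeometry(1, 38.0, 16.0, (0.0,))
        maps = biot_savart_maps(geo, (64, 64))
        assert np.max(np.abs(np.abs(maps.maps[0]) - 1.0)) < 1e-12

    def test_unit_rss_normalization(self, maps64):
        assert np.max(np.abs(maps64.rss() - 1.0)) < 1e-12
        assert all(np.abs(m).max() > 0 for m in maps64.maps)

    def test_field_peaks_nearest_loop_center(self, geometry64):
        fields = biot_savart_field(geometry64, (64, 64))
        centers = geometry64.loop_centers()
        for c in range(geometry64.n_coils):
            i, j = np.unravel_index(np.argmax(np.abs(fields[c])), (64, 64))
            ci = int(np.clip(round(centers[c, 0]) + 32, 0, 63))
            cj = int(np.clip(round(centers[c, 1]) + 32, 0, 63))
            assert (i, j) == (ci, cj)

    def test_zero_radius_loop_rejected(self):
        with pytest.raises(ValueError, match="radius"):
            CoilGeometry(2, 38.0, 0.0, (0.0, np.pi))

    def test_geometry_validation(self):
        with pytest.raises(ValueError):
            CoilGeometry(0, 38.0, 16.0, ())
        with pytest.raises(ValueError, match="offset"):
            CoilGeometry(3, 38.0, 16.0, (0.0, 1.0))


class TestExpandToCoils:
    def test_unit_coil_identity(self):
        geo = CoilGeometry(1, 38.0, 16.0, (0.0,))
        maps = biot_savart_maps(geo, (64, 64))
        ones = np.ones((64, 64), dtype=complex)
        data = expand_to_coils(ones, maps, geo)
        assert np.max(np.abs(np.abs(data.frame_images(0)[0]) - 1.0)) < 1e-12

    def test_rss_preserves_magnitude(self, phantom64, maps64, geometry64):
        data = expand_to_coils(phantom64.image, maps64, geometry64)
        rss = np.sqrt(np.sum(np.abs(data.frame_images(0)) ** 2, axis=0))
        assert np.max(np.abs(rss - np.abs(phantom64.image))) < 1e-10

    def test_kspace_consistent_with_images(self, multicoil64):
        for i in range(multicoil64.n_coils):
            k = fft2c(multicoil64.frame_images(0)[i])
            assert np.max(np.abs(k - multicoil64.frame_kspace(0)[i])) < 1e-10

    def test_adaptive_combine_recovers_image(self, phantom64, maps64, multicoil64):
        rec = adaptive_combine(multicoil64.frame_images(0), maps64)
        err = np.abs(np.abs(rec) - np.abs(phantom64.image))
        assert err.max() < 1e-6

    def test_shape_mismatch_rejected(self, maps64):
        with pytest.raises(ValueError, match="shape"):
            expand_to_coils(np.ones((32, 32), dtype=complex), maps64)


class TestHdf5:
    def test_lossless_round_trip(self, tmp_path):
        vol = make_cine_volume((32, 32), seed=5, n_coils=2)
        path = tmp_path / "d.h5"
        write_dataset(path, [vol])
        back = read_dataset(path)[0]
        assert np.array_equal(back.coil_kspace, vol.coil_kspace)
        assert np.array_equal(back.maps.maps, vol.maps.maps)
        assert back.seed == vol.seed and back.kind == vol.kind
        assert np.max(np.abs(back.coil_images - vol.coil_images)) < 1e-12

    def test_missing_kspace_group_reported(self, tmp_path):
        import h5py

        path = tmp_path / "bad.h5"
        with h5py.File(path, "w") as f:
            f.create_group("volumes/0").create_dataset("maps", data=np.ones((1, 4, 4), complex))
        with pytest.raises(ValueError, match="kspace"):
            read_dataset(path)

    def test_missing_file_reports_path(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="nope.h5"):
            read_dataset(tmp_path / "nope.h5")

    def test_example_counting(self, tmp_path):
        vols = [make_cine_volume((32, 32), seed=v, n_coils=2, n_frames=4)
                for v in range(3)]
        path = tmp_path / "c.h5"
        write_dataset(path, vols)
        assert count_examples(read_dataset(path)) == 12
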