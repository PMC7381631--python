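"""Synthetic-data generators: determinism, bookkeeping, forward consistency."""

import numpy as np
import pytest

from aaampi.physics import FieldSequence
from aaampi.synth import (
    SFSample,
    VoxelGrid,
    make_elemental_scan,
    make_phantom,
    make_stain_image,
    mixing_orders,
    simulate_measurement,
    simulate_mps,
    simulate_system_function,
)


class TestVoxelGrid:
    def test_default_matches_scanner_grid(self):
        g = VoxelGrid()
        assert g.shape == (25, 25, 13)
        assert g.voxel_volume_ul == pytest.approx(1.0)
        assert g.n_voxels == 8125

    def test_positions_are_centred(self, grid9):
        pos = grid9.positions_mm()
        np.testing.assert_allclose(pos.mean(axis=0), 0.0, atol=1e-12)
        assert pos.shape == (grid9.n_voxels, 3)


class TestSFSample:
    def test_calibration_sample_iron_mass(self):
        # 100 mM x 13.5 µl x 55.845 g/mol = 75.4 µg
        assert SFSample().iron_mass_ug == pytest.approx(75.39, abs=0.01)


class TestMixingOrders:
    def test_drive_bins_have_order_one(self, seq):
        bins, orders = mixing_orders(seq, 25)
        lookup = dict(zip(bins, orders))
        for b in seq.drive_bins:
            assert lookup[b] == 1

    def test_third_harmonic_bin_present(self, seq):
        bins, orders = mixing_orders(seq, 25)
        lookup = dict(zip(bins, orders))
        assert lookup[3 * seq.drive_bins[0]] == 3


class TestSystemFunction:
    def test_rows_have_energy_and_mirror_symmetry(self, sf_im9, grid9):
        energies = np.sum(np.abs(sf_im9.matrix) ** 2, axis=1)
        assert np.all(energies > 0)
        # voxels mirrored in y see a time-shifted, y-negated drive, so
        # their rows agree in magnitude component by component
        resp = sf_im9.matrix.reshape(sf_im9.n_components, *grid9.shape)
        np.testing.assert_allclose(
            np.abs(resp), np.abs(resp[:, :, ::-1, :]), rtol=1e-5, atol=1e-11
        )

    def test_immobilized_has_fewer_high_order_components(self, sf_im9, sf_fl9):
        sigma = 1e-3  # common evaluation noise scale
        def count_high_order(sf):
            rms = np.sqrt(np.mean(np.abs(sf.matrix) ** 2, axis=1))
            high = sf.component_mixing_order >= 10
            return int(np.sum((rms / sigma >= 7) & high))

        assert count_high_order(sf_im9) < count_high_order(sf_fl9)

    def test_same_seed_is_bit_identical(self, grid9, seq, model_immobilized):
        kwargs = dict(noise_sigma=0.01, seed=42)
        a = simulate_system_function(grid9, seq, model_immobilized, **kwargs)
        b = simulate_system_function(grid9, seq, model_immobilized, **kwargs)
        assert np.array_equal(a.matrix, b.matrix)
        assert np.array_equal(a.component_snr, b.component_snr)

    def test_negative_noise_rejected(self, grid9, seq, model_immobilized):
        with pytest.raises(ValueError):
            simulate_system_function(grid9, seq, model_immobilized, noise_sigma=-1.0)


class TestPhantom:
    def test_mass_bookkeeping_exact(self, grid13):
        ph = make_phantom(grid13, 2.0, seed=3)
        assert ph.total_iron_mass_ug == pytest.approx(2.0, rel=1e-9)
        assert np.all(ph.concentration_mm >= 0)

    def test_zero_mass_rejected(self, grid13):
        with pytest.raises(ValueError):
            make_phantom(grid13, 0.0)

    def test_same_seed_identical(self, grid13):
        a = make_phantom(grid13, 1.0, seed=11)
        b = make_phantom(grid13, 1.0, seed=11)
        assert np.array_equal(a.concentration_mm, b.concentration_mm)

    def test_support_is_connected(self, grid13):
        from scipy import ndimage

        for seed in range(5, 15):
            ph = make_phantom(grid13, 2.0, seed=seed)
            _, n_components = ndimage.label(
                ph.concentration_mm > 0, structure=np.ones((3, 3, 3))
            )
            assert n_components == 1


class TestMeasurement:
    def test_noiseless_frames_equal_projection(self, sf_im9, grid9):
        ph = make_phantom(grid9, 1.0, center_jitter_mm=0.5, seed=2)
        meas = simulate_measurement(ph, sf_im9, n_repetitions=3, noise_sigma=0.0)
        expected = sf_im9.matrix @ ph.sample_equivalents(sf_im9.sf_sample)
        for frame in meas.frames:
            np.testing.assert_array_equal(frame, expected)

    def test_empty_phantom_zero_frames(self, sf_im9, grid9):
        from aaampi.synth import Phantom

        empty = Phantom(np.zeros(grid9.shape), grid9)
        meas = simulate_measurement(empty, sf_im9, noise_sigma=0.0)
        assert np.all(meas.frames == 0)

    def test_forward_superposition(self, sf_im9, grid9):
        # measurement of a sum of phantoms equals the sum of measurements
        a = make_phantom(grid9, 0.7, center_jitter_mm=0.5, seed=1)
        b = make_phantom(grid9, 1.3, center_jitter_mm=0.5, seed=9)
        from aaampi.synth import Phantom

        both = Phantom(a.concentration_mm + b.concentration_mm, grid9)
        ya = simulate_measurement(a, sf_im9, noise_sigma=0.0).frames[0]
        yb = simulate_measurement(b, sf_im9, noise_sigma=0.0).frames[0]
        yab = simulate_measurement(both, sf_im9, noise_sigma=0.0).frames[0]
        np.testing.assert_allclose(yab, ya + yb, rtol=1e-8)

    def test_block_mean_concentrates_like_clt(self, sf_im9, grid9):
        # the mean of 20 noisy frames approaches the noiseless projection
        ph = make_phantom(grid9, 2.0, center_jitter_mm=0.5, seed=4)
        sigma = 0.05
        y0 = sf_im9.matrix @ ph.sample_equivalents(sf_im9.sf_sample)
        errs = []
        for seed in range(30):
            meas = simulate_measurement(
                ph, sf_im9, n_repetitions=20, noise_sigma=sigma, seed=seed
            )
            errs.append(np.abs(meas.frames.mean(axis=0) - y0).mean())
        # per-component complex error has RMS sigma/sqrt(20)
        assert np.mean(errs) < 3 * sigma / np.sqrt(20)

    def test_grid_mismatch_rejected(self, sf_im9, grid13):
        ph = make_phantom(grid13, 1.0, seed=0)
        with pytest.raises(ValueError):
            simulate_measurement(ph, sf_im9)


class TestMPS:
    def test_zero_mass_zero_spectrum(self, model_immobilized):
        spec = simulate_mps(0.0, model_immobilized)
        assert np.all(spec.amplitudes == 0)

    def test_linearity_in_mass(self, model_immobilized):
        s1 = simulate_mps(1.0, model_immobilized)
        s2 = simulate_mps(2.0, model_immobilized)
        np.testing.assert_allclose(s2.amplitudes, 2.0 * s1.amplitudes, rtol=1e-12)

    def test_immobilized_ratio_below_fluid(self, model_immobilized, model_fluid):
        im = simulate_mps(1.0, model_immobilized)
        fl = simulate_mps(1.0, model_fluid)
        assert im.magnitude(5) / im.magnitude(3) < fl.magnitude(5) / fl.magnitude(3)

    def test_same_seed_identical_including_background(self, model_immobilized):
        a = simulate_mps(1.0, model_immobilized, noise_sigma=1e-5, seed=3)
        b = simulate_mps(1.0, model_immobilized, noise_sigma=1e-5, seed=3)
        assert np.array_equal(a.amplitudes, b.amplitudes)
        assert np.array_equal(a.background, b.background)


class TestStainImage:
    def test_zero_fraction_no_blue(self):
        _, iron, tissue = make_stain_image(0.0, seed=1)
        assert iron.sum() == 0 and tissue.sum() > 0

    @pytest.mark.parametrize("fraction", [0.05, 0.10, 0.25])
    def test_fraction_exact_to_pixel_quantum(self, fraction):
        _, iron, tissue = make_stain_image(fraction, seed=2)
        assert iron.sum() == round(fraction * tissue.sum())

    def test_same_seed_identical(self):
        a, _, _ = make_stain_image(0.1, seed=7)
        b, _, _ = make_stain_image(0.1, seed=7)
        assert np.array_equal(a, b)

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            make_stain_image(1.2)


class TestElementalScan:
    def test_noiseless_scan_is_exactly_linear(self):
        conc = np.linspace(0, 4000, 50).reshape(5, 10)
        scan, standards = make_elemental_scan(conc, blank_sigma=0.0, seed=0)
        from scipy import stats

        means = standards.groupby("concentration_ug_g")["intensity"].mean()
        fit = stats.linregress(means.index, means.values)
        assert fit.rvalue**2 == pytest.approx(1.0, abs=1e-12)
        blank = standards[standards["concentration_ug_g"] == 0.0]["intensity"]
        assert blank.nunique() == 1  # intensity equals the intercept

    def test_same_seed_identical(self):
        conc = np.full((4, 6), 100.0)
        a, _ = make_elemental_scan(conc, blank_sigma=5.0, seed=3)
        b, _ = make_elemental_scan(conc, blank_sigma=5.0, seed=3)
        assert a.equals(b)

    def test_uncovered_range_rejected(self):
        with pytest.raises(ValueError):
            make_elemental_scan(np.full((2, 2), 9000.0))
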