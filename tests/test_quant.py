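"""MPI cutoff-and-integrate and MPS A3-normalization quantification."""

import numpy as np
import pytest

from aaampi.mpiquant import apply_cutoff, integrate_iron, quantify_mpi
from aaampi.mpsquant import (
    ReferenceSample,
    harmonic_ratio,
    quantify_iron_mps,
    select_reference,
)
from aaampi.physics import FLUID, IMMOBILIZED, HarmonicSpectrum
from aaampi.recon import ReconConfig, ReconImage
from aaampi.synth import SFSample, VoxelGrid, simulate_mps


def image_from(values, grid):
    return ReconImage(np.asarray(values, dtype=float), grid, ReconConfig(), 1)


@pytest.fixture
def grid111():
    return VoxelGrid((5, 5, 3), (5.0, 5.0, 3.0))  # 1 µl voxels


class TestCutoff:
    def test_uniform_image_keeps_all_voxels(self, grid111):
        img = image_from(np.full(grid111.shape, 2.0), grid111)
        assert apply_cutoff(img).all()

    def test_single_dominant_voxel(self, grid111):
        values = np.full(grid111.shape, 4.0)
        values[2, 2, 1] = 10.0
        mask = apply_cutoff(image_from(values, grid111), 0.5)
        assert mask.sum() == 1 and mask[2, 2, 1]

    def test_ties_with_threshold_included(self, grid111):
        values = np.zeros(grid111.shape)
        values[0, 0, 0] = 10.0
        values[1, 1, 1] = 5.0
        assert apply_cutoff(image_from(values, grid111), 0.5).sum() == 2

    def test_all_zero_image_gives_empty_mask(self, grid111):
        assert not apply_cutoff(image_from(np.zeros(grid111.shape), grid111)).any()

    def test_invalid_fraction_rejected(self, grid111):
        img = image_from(np.ones(grid111.shape), grid111)
        for bad in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                apply_cutoff(img, bad)

    def test_lower_cutoff_never_decreases_mass(self, grid111, rng):
        values = rng.uniform(0, 5, grid111.shape)
        img = image_from(values, grid111)
        masses = [
            integrate_iron(img, apply_cutoff(img, f)) for f in (0.8, 0.5, 0.2, 0.05)
        ]
        assert all(b >= a for a, b in zip(masses, masses[1:]))


class TestIntegrate:
    def test_empty_mask_zero_mass(self, grid111):
        img = image_from(np.ones(grid111.shape), grid111)
        assert integrate_iron(img, np.zeros(grid111.shape, dtype=bool)) == 0.0

    def test_single_voxel_1mm_at_1ul(self, grid111):
        # 1 mM x 1 µl x 55.845 g/mol = 0.0558 µg
        values = np.zeros(grid111.shape)
        values[0, 0, 0] = 1.0
        img = image_from(values, grid111)
        mask = values > 0
        assert integrate_iron(img, mask) == pytest.approx(0.0558, abs=5e-5)

    def test_scale_equivariance(self, grid111, rng):
        values = rng.uniform(0, 3, grid111.shape)
        img = image_from(values, grid111)
        img3 = image_from(3.0 * values, grid111)
        assert np.array_equal(apply_cutoff(img), apply_cutoff(img3))
        assert integrate_iron(img3, apply_cutoff(img3)) == pytest.approx(
            3.0 * integrate_iron(img, apply_cutoff(img)), rel=1e-12
        )


class TestQuantifyMPI:
    def test_all_zero_image_undetected(self, grid111):
        res = quantify_mpi(image_from(np.zeros(grid111.shape), grid111))
        assert res.iron_mass_ug == 0.0 and not res.detected

    def test_detection_and_voi_count(self, grid111):
        values = np.zeros(grid111.shape)
        values[2, 2, 1] = 1.0
        res = quantify_mpi(image_from(values, grid111))
        assert res.detected and res.voi_voxel_count == 1

    def test_visibility_floor(self, grid111):
        values = np.zeros(grid111.shape)
        values[2, 2, 1] = 1.0  # 0.0558 µg
        res = quantify_mpi(image_from(values, grid111), visibility_floor_ug=0.3)
        assert not res.detected

    def test_mass_linearity_through_chain(self, sf_im9, grid9):
        # end-to-end: doubling the phantom doubles the quantified mass
        from aaampi.recon import reconstruct
        from aaampi.synth import Phantom, make_phantom, simulate_measurement

        ph1 = make_phantom(grid9, 1.0, center_jitter_mm=0.5, seed=6)
        ph2 = Phantom(2.0 * ph1.concentration_mm, grid9)
        masses = []
        for ph in (ph1, ph2):
            meas = simulate_measurement(ph, sf_im9, noise_sigma=0.0)
            masses.append(quantify_mpi(reconstruct(meas, sf_im9)).iron_mass_ug)
        assert masses[1] / masses[0] == pytest.approx(2.0, abs=0.05)


def spectrum(a3, a5, bg3=0.0, bg5=0.0):
    amps = np.zeros(5, dtype=complex)
    amps[2], amps[4] = a3, a5
    bg = np.zeros(5, dtype=complex)
    bg[2], bg[4] = bg3, bg5
    return HarmonicSpectrum(25e3, amps, background=bg)


class TestHarmonicRatio:
    def test_plain_ratio(self):
        assert harmonic_ratio(spectrum(10.0, 3.0)) == pytest.approx(0.3)

    def test_background_subtracted_first(self):
        assert harmonic_ratio(spectrum(12.0, 4.0, bg3=2.0, bg5=1.0)) == pytest.approx(0.3)

    def test_sample_at_background_rejected(self):
        with pytest.raises(ValueError):
            harmonic_ratio(spectrum(1.0, 0.5, bg3=2.0))

    def test_simulated_immobilized_below_fluid(self, model_immobilized, model_fluid):
        r_im = harmonic_ratio(simulate_mps(1.0, model_immobilized))
        r_fl = harmonic_ratio(simulate_mps(1.0, model_fluid))
        assert 0 < r_im < r_fl < 1


class TestSelectReference:
    def make_refs(self, model_immobilized, model_fluid):
        mass = SFSample().iron_mass_ug
        return [
            ReferenceSample(simulate_mps(mass, model_fluid), mass, FLUID),
            ReferenceSample(simulate_mps(mass, model_immobilized), mass, IMMOBILIZED),
        ]

    def test_exact_ratio_match(self, model_immobilized, model_fluid):
        refs = self.make_refs(model_immobilized, model_fluid)
        chosen = select_reference(refs[1].a5_a3_ratio, refs)
        assert chosen.mobility_state == IMMOBILIZED

    def test_single_reference_returned(self, model_fluid):
        refs = [ReferenceSample(simulate_mps(1.0, model_fluid), 1.0, FLUID)]
        assert select_reference(0.2, refs) is refs[0]

    def test_tissue_sample_selects_immobilized(self, model_immobilized, model_fluid):
        refs = self.make_refs(model_immobilized, model_fluid)
        tissue_ratio = harmonic_ratio(simulate_mps(0.5, model_immobilized))
        assert select_reference(tissue_ratio, refs).mobility_state == IMMOBILIZED

    def test_empty_reference_list_rejected(self):
        with pytest.raises(ValueError):
            select_reference(0.3, [])


class TestQuantifyMPS:
    def test_identical_spectrum_recovers_reference_mass(self, model_immobilized):
        spec = simulate_mps(75.39, model_immobilized)
        ref = ReferenceSample(spec, 75.39, IMMOBILIZED)
        res = quantify_iron_mps(spec, None, ref)
        assert res.iron_mass_ug == pytest.approx(75.39, rel=1e-12)

    def test_half_amplitude_half_mass(self):
        ref = ReferenceSample(spectrum(10.0, 3.0), 4.0, IMMOBILIZED)
        res = quantify_iron_mps(spectrum(5.0, 1.5), None, ref)
        assert res.iron_mass_ug == pytest.approx(2.0)

    def test_noiseless_simulated_mass_inverts_exactly(self, model_immobilized):
        # forward-simulate 2.000 µg, invert through the matched reference
        mass = SFSample().iron_mass_ug
        ref = ReferenceSample(simulate_mps(mass, model_immobilized), mass, IMMOBILIZED)
        sample = simulate_mps(2.0, model_immobilized)
        res = quantify_iron_mps(sample, None, ref)
        assert res.iron_mass_ug == pytest.approx(2.0, rel=1e-6)

    def test_reference_at_background_rejected(self):
        ref = ReferenceSample(spectrum(1.0, 0.3, bg3=1.5), 2.0, IMMOBILIZED)
        with pytest.raises(ValueError):
            quantify_iron_mps(spectrum(5.0, 1.5), None, ref)

    def test_model_mismatch_bias_is_systematic(self, model_immobilized, model_fluid):
        # quantifying immobilized samples against a fluid reference biases
        # all masses in the same direction
        mass = SFSample().iron_mass_ug
        wrong_ref = ReferenceSample(simulate_mps(mass, model_fluid), mass, FLUID)
        signs = set()
        for true_mass in (0.2, 1.0, 4.0):
            sample = simulate_mps(true_mass, model_immobilized)
            est = quantify_iron_mps(sample, None, wrong_ref).iron_mass_ug
            signs.add(np.sign(est - true_mass))
        assert len(signs) == 1

    def test_noise_robustness_at_high_snr(self, model_immobilized):
        # with harmonic noise at A3 SNR 150, the recovered mass stays
        # within 2% of truth on average over 200 seeds
        mass_true = 1.0
        a3 = simulate_mps(mass_true, model_immobilized).magnitude(3)
        sigma = a3 / 150.0
        ref_mass = SFSample().iron_mass_ug
        ref = ReferenceSample(
            simulate_mps(ref_mass, model_immobilized), ref_mass, IMMOBILIZED
        )
        estimates = [
            quantify_iron_mps(
                simulate_mps(mass_true, model_immobilized, noise_sigma=sigma, seed=s),
                None,
                ref,
            ).iron_mass_ug
            for s in range(200)
        ]
        assert np.mean(np.abs(np.array(estimates) - mass_true)) < 0.02 * mass_true
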