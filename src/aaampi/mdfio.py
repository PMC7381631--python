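"""File formats: HDF5 containers, NIfTI volumes, CSV spectra and scans.

System functions and measurements are stored in an HDF5 layout whose group
and field naming follows the Magnetic Particle Imaging Data Format (MDF)
conventions where they apply (/acquisition, /calibration, /measurement);
volumes go to NIfTI via nibabel, spectra and line scans to plain CSV.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .physics import FieldSequence, HarmonicSpectrum, ParticleModel
from .recon import ReconConfig, ReconImage
from .synth import MPIMeasurement, SFSample, SystemFunction, VoxelGrid


def save_system_function(path, sf: SystemFunction) -> None:
    with h5py.File(path, "w") as f:
        acq = f.create_group("acquisition")
        acq.attrs["driveFieldAmplitudes_mT"] = sf.sequence.drive_amplitudes_mt
        acq.attrs["driveFieldDividers"] = sf.sequence.frequency_dividers
        acq.attrs["baseFrequency_Hz"] = sf.sequence.base_frequency_hz
        acq.attrs["selectionFieldGradients_Tm"] = sf.sequence.gradients_t_per_m
        acq.attrs["samplesPerPeriod"] = sf.sequence.samples_per_period
        cal = f.create_group("calibration")
        cal.create_dataset("systemFunction", data=sf.matrix, compression="gzip")
        cal.create_dataset("frequencies_Hz", data=sf.component_freq_hz)
        cal.create_dataset("mixingOrder", data=sf.component_mixing_order)
        cal.create_dataset("receiveChannel", data=sf.component_channel)
        cal.create_dataset("snr", data=sf.component_snr)
        cal.attrs["gridShape"] = sf.grid.shape
        cal.attrs["fov_mm"] = sf.grid.fov_mm
        cal.attrs["noiseSigma"] = sf.noise_sigma
        smp = f.create_group("sample")
        smp.attrs["ironConcentration_mM"] = sf.sf_sample.iron_concentration_mm
        smp.attrs["volume_ul"] = sf.sf_sample.volume_ul
        smp.attrs["size_mm"] = sf.sf_sample.size_mm
        smp.attrs["mobilityState"] = sf.sf_sample.mobility_state
        mdl = f.create_group("tracer")
        mdl.attrs["coreDiameters_nm"] = sf.model.core_diameters_nm
        mdl.attrs["weightFractions"] = sf.model.weight_fractions
        mdl.attrs["saturationMagnetization_Am"] = sf.model.saturation_magnetization_am
        mdl.attrs["temperature_K"] = sf.model.temperature_k
        mdl.attrs["relaxationTime_s"] = sf.model.relaxation_time_s
        mdl.attrs["mobilityState"] = sf.model.mobility_state


def load_system_function(path) -> SystemFunction:
    with h5py.File(path, "r") as f:
        acq, cal, smp, mdl = (
            f["acquisition"],
            f["calibration"],
            f["sample"],
            f["tracer"],
        )
        seq = FieldSequence(
            tuple(acq.attrs["driveFieldAmplitudes_mT"]),
            tuple(int(d) for d in acq.attrs["driveFieldDividers"]),
            float(acq.attrs["baseFrequency_Hz"]),
            tuple(acq.attrs["selectionFieldGradients_Tm"]),
            int(acq.attrs["samplesPerPeriod"]),
        )
        grid = VoxelGrid(
            tuple(int(s) for s in cal.attrs["gridShape"]),
            tuple(float(v) for v in cal.attrs["fov_mm"]),
        )
        sample = SFSample(
            float(smp.attrs["ironConcentration_mM"]),
            float(smp.attrs["volume_ul"]),
            tuple(float(v) for v in smp.attrs["size_mm"]),
            str(smp.attrs["mobilityState"]),
        )
        model = ParticleModel(
            tuple(float(d) for d in mdl.attrs["coreDiameters_nm"]),
            tuple(float(w) for w in mdl.attrs["weightFractions"]),
            float(mdl.attrs["saturationMagnetization_Am"]),
            float(mdl.attrs["temperature_K"]),
            float(mdl.attrs["relaxationTime_s"]),
            str(mdl.attrs["mobilityState"]),
        )
        return SystemFunction(
            matrix=cal["systemFunction"][()],
            component_freq_hz=cal["frequencies_Hz"][()],
            component_mixing_order=cal["mixingOrder"][()],
            component_channel=cal["receiveChannel"][()],
            component_snr=cal["snr"][()],
            grid=grid,
            sequence=seq,
            model=model,
            sf_sample=sample,
            noise_sigma=float(cal.attrs["noiseSigma"]),
        )


def save_measurement(path, meas: MPIMeasurement) -> None:
    with h5py.File(path, "w") as f:
        grp = f.create_group("measurement")
        grp.create_dataset("frames", data=meas.frames, compression="gzip")
        grp.attrs["noiseSigma"] = meas.noise_sigma
        grp.attrs["seed"] = -1 if meas.seed is None else meas.seed


def load_measurement(path) -> MPIMeasurement:
    with h5py.File(path, "r") as f:
        grp = f["measurement"]
        seed = int(grp.attrs["seed"])
        return MPIMeasurement(
            grp["frames"][()],
            float(grp.attrs["noiseSigma"]),
            seed=None if seed < 0 else seed,
        )


def volume_to_nifti(path, values: np.ndarray, grid: VoxelGrid) -> None:
    """Write a voxel volume with the grid's physical spacing (mm)."""
    affine = np.diag([*grid.voxel_size_mm, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(values, dtype=np.float32), affine), str(path))


def nifti_to_volume(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=float)


def save_spectrum_csv(path, spec: HarmonicSpectrum) -> None:
    df = pd.DataFrame(
        {
            "harmonic_index": np.arange(1, spec.n_harmonics + 1),
            "real": spec.amplitudes.real,
            "imag": spec.amplitudes.imag,
            "bg_real": spec.background.real,
            "bg_imag": spec.background.imag,
        }
    )
    df.insert(0, "fundamental_hz", spec.fundamental_hz)
    df.to_csv(path, index=False)


def load_spectrum_csv(path) -> HarmonicSpectrum:
    df = pd.read_csv(path).sort_values("harmonic_index")
    amps = df["real"].to_numpy() + 1j * df["imag"].to_numpy()
    if {"bg_real", "bg_imag"}.issubset(df.columns):
        bg = df["bg_real"].to_numpy() + 1j * df["bg_imag"].to_numpy()
    else:
        bg = None
    return HarmonicSpectrum(float(df["fundamental_hz"].iloc[0]), amps, background=bg)
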