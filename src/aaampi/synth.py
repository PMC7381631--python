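"""Synthetic study data with known ground truth.

Everything the ex vivo study measured is generated here: system functions of
the field-free-point scanner, aneurysm-like phantoms, MPI measurement
frames, MPS harmonic spectra, Perls'-stained section images and LA-ICP-MS
line scans with gelatin calibration standards.  Every generator is a pure
function of its parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.fft import rfft, rfftfreq

from .physics import (
    FieldSequence,
    HarmonicSpectrum,
    ParticleModel,
    _debye_derivative_transfer,
    harmonic_spectrum,
    magnetization,
)

#: molar mass of iron, g/mol
FE_MOLAR_MASS_G_PER_MOL = 55.845
#: iron mass in µg contained in 1 µl at 1 mM Fe
UG_PER_MM_UL = FE_MOLAR_MASS_G_PER_MOL * 1e-3
#: magnetite volume per µg of iron (m^3); Fe fraction of gamma-Fe2O3 with
#: bulk density 4860 kg/m^3
M3_PER_UG_FE = 1e-9 / (0.6994 * 4860.0)

#: reference RGB of Perls' Prussian blue reaction product in the stain fixture
PERLS_BLUE_RGB = (45, 70, 155)

#: fixed receiver gain applied to simulated MPI signals; keeps matrix
#: entries of order one (signal units are arbitrary but shared between
#: system function and measurement, so quantification is unaffected)
RECEIVER_GAIN = 1e-9


@dataclass(frozen=True)
class VoxelGrid:
    """Voxel-centred reconstruction grid, axis order (x, y, z).

    Default is the scanner's measurement grid: 25 x 25 x 13 voxels over a
    25 x 25 x 13 mm^3 field of view (1 µl voxels), centred on the origin.
    """

    shape: tuple[int, int, int] = (25, 25, 13)
    fov_mm: tuple[float, float, float] = (25.0, 25.0, 13.0)

    def __post_init__(self) -> None:
        if any(int(s) != s or s < 1 for s in self.shape):
            raise ValueError("grid shape must be positive integers")
        if any(f <= 0 for f in self.fov_mm):
            raise ValueError("FOV extents must be positive")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.asarray(self.fov_mm) / np.asarray(self.shape)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    @property
    def voxel_volume_ul(self) -> float:
        # 1 mm^3 == 1 µl
        return self.voxel_volume_mm3

    def positions_mm(self) -> np.ndarray:
        """Voxel-centre coordinates, shape (n_voxels, 3), x-index fastest last.

        Flattening follows C order over (nx, ny, nz) index grids, matching
        ``values.reshape(grid.shape)`` for any flat voxel vector.
        """
        axes = [
            (np.arange(n) + 0.5) * v - f / 2.0
            for n, v, f in zip(self.shape, self.voxel_size_mm, self.fov_mm)
        ]
        xx, yy, zz = np.meshgrid(*axes, indexing="ij")
        return np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)


@dataclass(frozen=True)
class SFSample:
    """Calibration sample placed at every grid node during SF acquisition."""

    iron_concentration_mm: float = 100.0
    volume_ul: float = 13.5
    size_mm: tuple[float, float, float] = (3.0, 3.0, 1.5)
    mobility_state: str = "immobilized"

    @property
    def iron_mass_ug(self) -> float:
        """Total iron in the calibration sample (75.4 µg for the default)."""
        return self.iron_concentration_mm * self.volume_ul * UG_PER_MM_UL


@dataclass
class SystemFunction:
    """Calibration matrix of the scanner: components x voxels.

    Each row is the complex response of the calibration sample at one grid
    node, at one mixing frequency k_x f_x + k_y f_y + k_z f_z on one receive
    channel.  Row metadata carries the frequency, the minimal mixing order
    |k_x|+|k_y|+|k_z|, the receive channel and the SNR against the additive
    noise level.
    """

    matrix: np.ndarray
    component_freq_hz: np.ndarray
    component_mixing_order: np.ndarray
    component_channel: np.ndarray
    component_snr: np.ndarray
    grid: VoxelGrid
    sequence: FieldSequence
    model: ParticleModel
    sf_sample: SFSample
    noise_sigma: float

    @property
    def n_components(self) -> int:
        return self.matrix.shape[0]

    @property
    def calibration_mass_ug(self) -> float:
        return self.sf_sample.iron_mass_ug


@dataclass
class Phantom:
    """Ground-truth iron distribution of a synthetic aorta sample."""

    concentration_mm: np.ndarray
    grid: VoxelGrid
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.concentration_mm.shape != tuple(self.grid.shape):
            raise ValueError("concentration map does not match grid shape")
        if np.any(self.concentration_mm < 0):
            raise ValueError("concentrations must be nonnegative")

    @property
    def total_iron_mass_ug(self) -> float:
        return float(
            self.concentration_mm.sum() * self.grid.voxel_volume_ul * UG_PER_MM_UL
        )

    def sample_equivalents(self, sf_sample: SFSample) -> np.ndarray:
        """Flat voxel vector in units of calibration-sample equivalents."""
        per_voxel_ug = (
            self.concentration_mm.ravel() * self.grid.voxel_volume_ul * UG_PER_MM_UL
        )
        return per_voxel_ug / sf_sample.iron_mass_ug


@dataclass
class MPIMeasurement:
    """Repeated measurement frames on the component grid of a SystemFunction."""

    frames: np.ndarray  # (n_repetitions, n_components), complex
    noise_sigma: float
    seed: int | None = None

    def __post_init__(self) -> None:
        self.frames = np.atleast_2d(np.asarray(self.frames, dtype=complex))
        if self.n_repetitions < 1:
            raise ValueError("at least one repetition required")

    @property
    def n_repetitions(self) -> int:
        return self.frames.shape[0]

    @property
    def n_components(self) -> int:
        return self.frames.shape[1]


def mixing_orders(seq: FieldSequence, max_order: int) -> tuple[np.ndarray, np.ndarray]:
    """All DFT bins reachable as mixing products k . (drive bins).

    Returns (bins, orders): bin indices over one Lissajous period in
    1..Nyquist and the minimal L1 order |k_x|+|k_y|+|k_z| producing each.
    """
    b = seq.drive_bins.astype(np.int64)
    nyq = seq.samples_per_period // 2
    r = np.arange(-max_order, max_order + 1)
    kx, ky, kz = np.meshgrid(r, r, r, indexing="ij")
    order = np.abs(kx) + np.abs(ky) + np.abs(kz)
    ok = order <= max_order
    n = kx[ok] * b[0] + ky[ok] * b[1] + kz[ok] * b[2]
    order = order[ok]
    keep = (n >= 1) & (n <= nyq)
    n, order = n[keep], order[keep]
    best = np.full(nyq + 1, np.iinfo(np.int64).max, dtype=np.int64)
    np.minimum.at(best, n, order)
    bins = np.nonzero(best <= max_order)[0]
    return bins, best[bins]


def _magnetization_per_field(bmag_mt: np.ndarray, model: ParticleModel) -> np.ndarray:
    """M(|B|)/|B| in A/m per mT, vectorized for the simulation hot loop.

    Identical to ``magnetization`` up to ~1e-8 relative: populations with
    small Langevin arguments use the series branch (accurate to ~3e-9 at
    the 0.2 crossover), sparing the tanh evaluation that dominates cost.
    """
    b_t = bmag_mt * 1e-3
    acc = np.zeros_like(b_t)
    for w, slope in zip(model.weight_fractions, model.langevin_slopes_per_t):
        xi = slope * b_t
        l = np.empty_like(xi)
        small = xi < 0.2
        xs = xi[small]
        l[small] = xs / 3.0 - xs**3 / 45.0 + 2.0 * xs**5 / 945.0
        xl = xi[~small]
        l[~small] = 1.0 / np.tanh(xl) - 1.0 / xl
        acc += w * l
    return model.saturation_magnetization_am * acc / np.where(bmag_mt > 0, bmag_mt, 1.0)


def _response_spectra(
    positions_mm: np.ndarray,
    seq: FieldSequence,
    model: ParticleModel,
    bins: np.ndarray,
    offsets_mm: np.ndarray,
    moment_scale: float,
) -> np.ndarray:
    """Complex spectra (3 channels, len(bins), n_positions) of unit sources.

    Each source is the average of point responses at ``positions + offsets``
    (the sub-sampled calibration cuboid); amplitudes are peak-normalized
    (x 2/N) so they do not depend on the sampling density.
    """
    n = seq.samples_per_period
    t = np.arange(n) / seq.sample_rate_hz
    drive = np.asarray(
        np.sin(2.0 * math.pi * seq.drive_frequencies_hz * t[:, None])
        * np.asarray(seq.drive_amplitudes_mt),
        dtype=float,
    )  # (n, 3)
    grad = np.asarray(seq.gradients_t_per_m)  # mT/mm
    freqs = rfftfreq(n, d=1.0 / seq.sample_rate_hz)
    transfer = _debye_derivative_transfer(freqs[bins], model.relaxation_time_s)

    npos = positions_mm.shape[0]
    out = np.empty((3, len(bins), npos), dtype=complex)
    # chunk so the (m, n, 3) work arrays stay ~tens of MB
    chunk = max(1, int(6.0e6 / n))
    for start in range(0, npos, chunk):
        pos = positions_mm[start : start + chunk]
        m_vec = np.zeros((pos.shape[0], n, 3))
        for off in offsets_mm:
            static = grad * (pos + off)  # (m, 3) mT
            b = drive[None, :, :] + static[:, None, :]
            bmag = np.sqrt(np.einsum("ijk,ijk->ij", b, b))
            m_vec += _magnetization_per_field(bmag, model)[:, :, None] * b
        m_vec *= moment_scale / len(offsets_mm)
        spec = rfft(m_vec, axis=1)[:, bins, :] * (2.0 / n)  # (m, nb, 3)
        spec *= transfer[None, :, None]
        out[:, :, start : start + len(pos)] = np.transpose(spec, (2, 1, 0))
    return out


def _cuboid_offsets(size_mm, subdivisions) -> np.ndarray:
    axes = [
        (np.arange(s) + 0.5) / s * ext - ext / 2.0
        for s, ext in zip(subdivisions, size_mm)
    ]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    return np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)


def simulate_system_function(
    grid: VoxelGrid,
    seq: FieldSequence,
    model: ParticleModel,
    noise_sigma: float = 0.0,
    seed: int = 0,
    sf_sample: SFSample | None = None,
    source_subdivisions: tuple[int, int, int] = (2, 2, 1),
    max_stored_order: int = 30,
    stored_band_hz: tuple[float, float | None] = (50e3, None),
    store_rel_floor: float = 1e-4,
) -> SystemFunction:
    """Simulate acquisition of a system function on ``grid``.

    The calibration sample (a sub-sampled 3 x 3 x 1.5 mm^3 cuboid) is moved
    to every grid node and its response recorded; complex Gaussian noise of
    scale ``noise_sigma`` is added to every matrix entry.  Only mixing
    components inside ``stored_band_hz`` with order <= ``max_stored_order``
    whose probe response exceeds ``store_rel_floor`` of the strongest
    component are stored (the rest are orders of magnitude below any usable
    SNR); per-component SNR is the row RMS over noise_sigma.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be nonnegative")
    sf_sample = sf_sample or SFSample(mobility_state=model.mobility_state)

    bins, orders = mixing_orders(seq, max_stored_order)
    freqs = bins / seq.period_s
    lo, hi = stored_band_hz
    hi = hi if hi is not None else seq.sample_rate_hz / 2.0
    band = (freqs >= lo) & (freqs <= hi)
    bins, orders, freqs = bins[band], orders[band], freqs[band]
    if bins.size == 0:
        raise ValueError("no mixing components inside the stored band")

    offsets = _cuboid_offsets(sf_sample.size_mm, source_subdivisions)

    # probe pass: a sparse set of node positions bounds each row's scale
    pos = grid.positions_mm()
    idx = np.unique(
        np.linspace(0, pos.shape[0] - 1, min(27, pos.shape[0])).astype(int)
    )
    probe = _response_spectra(pos[idx], seq, model, bins, np.zeros((1, 3)), RECEIVER_GAIN)
    probe_rms = np.sqrt(np.mean(np.abs(probe) ** 2, axis=2))  # (3, nb)
    keep = probe_rms.max(axis=0) >= store_rel_floor * probe_rms.max()
    bins, orders, freqs = bins[keep], orders[keep], freqs[keep]

    spectra = _response_spectra(pos, seq, model, bins, offsets, RECEIVER_GAIN)
    nb = len(bins)
    matrix = spectra.reshape(3 * nb, grid.n_voxels)
    component_freq = np.tile(freqs, 3)
    component_order = np.tile(orders, 3)
    component_channel = np.repeat(np.arange(3), nb)

    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal(matrix.shape) + 1j * rng.standard_normal(
            matrix.shape
        )
        matrix = matrix + noise_sigma / math.sqrt(2.0) * noise

    rms = np.sqrt(np.mean(np.abs(matrix) ** 2, axis=1))
    snr = rms / noise_sigma if noise_sigma > 0 else np.full(3 * nb, np.inf)

    order_sort = np.lexsort((component_channel, component_freq))
    return SystemFunction(
        matrix=matrix[order_sort],
        component_freq_hz=component_freq[order_sort],
        component_mixing_order=component_order[order_sort],
        component_channel=component_channel[order_sort],
        component_snr=snr[order_sort],
        grid=grid,
        sequence=seq,
        model=model,
        sf_sample=sf_sample,
        noise_sigma=noise_sigma,
    )


def make_phantom(
    grid: VoxelGrid,
    total_iron_ug: float,
    outer_radius_mm: float | None = None,
    wall_thickness_mm: float = 0.9,
    length_mm: float | None = None,
    center_jitter_mm: float = 1.5,
    thrombus: bool = True,
    heterogeneity: float = 0.4,
    seed: int = 0,
) -> Phantom:
    """Aneurysm-segment phantom: an annular vessel wall plus mural thrombus.

    The support mimics a harvested mouse suprarenal aortic segment lying
    along the scanner's z axis: a tube of 5-7 mm length whose aneurysmal
    wall reaches 2-4 mm outer diameter, with an optional thrombus blob on
    one side and mild voxel-wise concentration heterogeneity.  The map is
    scaled so the integrated iron mass equals ``total_iron_ug`` exactly.
    """
    if total_iron_ug <= 0:
        raise ValueError("total iron mass must be positive")
    rng = np.random.default_rng(seed)
    r_out = outer_radius_mm if outer_radius_mm is not None else rng.uniform(1.0, 1.9)
    length = length_mm if length_mm is not None else rng.uniform(5.0, 7.0)
    center = rng.uniform(-center_jitter_mm, center_jitter_mm, size=3)
    pos = grid.positions_mm() - center
    r_in = max(r_out - wall_thickness_mm, 0.2)
    rho2 = pos[:, 0] ** 2 + pos[:, 1] ** 2
    in_length = np.abs(pos[:, 2]) <= length / 2.0
    mask = (rho2 <= r_out**2) & (rho2 >= r_in**2) & in_length
    if thrombus:
        # mural thrombus: a blob attached to the mid-wall on a random side
        theta = rng.uniform(0, 2 * math.pi)
        r_mid = (r_out + r_in) / 2.0
        site = np.array([
            r_mid * math.cos(theta),
            r_mid * math.sin(theta),
            rng.uniform(-0.4, 0.4) * length / 2.0,
        ])
        blob_r = rng.uniform(0.7, 1.1)
        mask |= np.sum((pos - site) ** 2, axis=1) <= blob_r**2
    if not mask.any():
        raise ValueError("requested mass not achievable: phantom support empty on grid")

    values = np.zeros(grid.n_voxels)
    weights = rng.uniform(1.0 - heterogeneity, 1.0, size=int(mask.sum()))
    values[mask] = weights
    per_voxel_factor = grid.voxel_volume_ul * UG_PER_MM_UL
    values *= total_iron_ug / (values.sum() * per_voxel_factor)
    return Phantom(values.reshape(grid.shape), grid, seed=seed)


def simulate_measurement(
    phantom: Phantom,
    sf: SystemFunction,
    n_repetitions: int = 20,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> MPIMeasurement:
    """Measure a phantom through the system function's forward model.

    Each frame is the SF matrix applied to the phantom's calibration-sample
    equivalents plus independent complex Gaussian noise, so the expectation
    over frames equals the noiseless projection.
    """
    if phantom.grid != sf.grid:
        raise ValueError("phantom and system function use different grids")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be nonnegative")
    y0 = sf.matrix @ phantom.sample_equivalents(sf.sf_sample)
    frames = np.tile(y0, (n_repetitions, 1))
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal(frames.shape) + 1j * rng.standard_normal(
            frames.shape
        )
        frames = frames + noise_sigma / math.sqrt(2.0) * noise
    return MPIMeasurement(frames, noise_sigma, seed=seed)


def simulate_mps(
    iron_mass_ug: float,
    model: ParticleModel,
    amplitude_mt: float = 25.0,
    frequency_hz: float = 25e3,
    noise_sigma: float = 0.0,
    seed: int = 0,
    n_harmonics: int = 25,
    samples_per_period: int = 1024,
) -> HarmonicSpectrum:
    """MPS spectrum of a point sample under sinusoidal excitation.

    Defaults follow the spectrometer settings used for the aorta samples:
    25 mT drive amplitude at 25 kHz, 37 degC sample temperature (carried by
    the particle model).  The returned spectrum is exactly linear in
    ``iron_mass_ug``; its ``background`` is an independent noise-only
    empty-holder spectrum with the same sigma.
    """
    if iron_mass_ug < 0:
        raise ValueError("iron mass must be nonnegative")
    fs = samples_per_period * frequency_hz
    t = np.arange(samples_per_period) / fs
    b = amplitude_mt * np.sin(2.0 * math.pi * frequency_hz * t)
    # signed Langevin response (odd), scaled to the sample's total moment
    m = iron_mass_ug * M3_PER_UG_FE * magnetization(b, model)
    spec = rfft(m)
    freqs = rfftfreq(samples_per_period, d=1.0 / fs)
    spec *= _debye_derivative_transfer(freqs, model.relaxation_time_s)
    u = np.fft.irfft(spec, n=samples_per_period)
    spectrum = harmonic_spectrum(u, frequency_hz, fs, n_harmonics=n_harmonics)
    rng = np.random.default_rng(seed)
    if noise_sigma > 0:
        shape = spectrum.amplitudes.shape
        spectrum.amplitudes = spectrum.amplitudes + noise_sigma / math.sqrt(2.0) * (
            rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        )
        spectrum.background = noise_sigma / math.sqrt(2.0) * (
            rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        )
    return spectrum


def make_stain_image(
    iron_area_fraction: float,
    shape: tuple[int, int] = (192, 192),
    seed: int = 0,
    n_deposit_sites: int | None = None,
):
    """Synthetic Perls'-stained cross-section with ground-truth masks.

    The tissue is an annular vessel wall; iron-positive pixels (Perls' blue)
    occupy exactly ``iron_area_fraction`` of the tissue area (to one pixel
    quantum), clustered into blob-like deposits.  Returns
    ``(rgb_image, iron_mask, tissue_mask)``.
    """
    if not 0.0 <= iron_area_fraction <= 1.0:
        raise ValueError("iron_area_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = h / 2 + rng.uniform(-3, 3), w / 2 + rng.uniform(-3, 3)
    r_out = min(h, w) * rng.uniform(0.33, 0.4)
    r_in = r_out * rng.uniform(0.35, 0.5)
    rr = np.hypot(yy - cy, xx - cx)
    tissue = (rr <= r_out) & (rr >= r_in)

    n_iron = int(round(iron_area_fraction * tissue.sum()))
    iron = np.zeros_like(tissue)
    if n_iron > 0:
        t_idx = np.argwhere(tissue)
        k = n_deposit_sites or rng.integers(1, 4)
        sites = t_idx[rng.integers(0, len(t_idx), size=k)]
        d = np.min(
            np.linalg.norm(t_idx[:, None, :] - sites[None, :, :], axis=2), axis=1
        )
        d = d + rng.normal(0, 1.5, size=d.shape)  # ragged deposit edges
        chosen = t_idx[np.argsort(d)[:n_iron]]
        iron[chosen[:, 0], chosen[:, 1]] = True

    img = np.empty((h, w, 3), dtype=float)
    img[:] = 244.0  # slide background
    img[tissue] = (226.0, 178.0, 192.0)  # eosinophilic tissue
    img[iron] = PERLS_BLUE_RGB
    img += rng.normal(0, 4.0, size=img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return img, iron, tissue


def make_elemental_scan(
    concentration_map: np.ndarray,
    standards_ug_g: tuple[float, ...] = (0.0, 1.0, 5.0, 10.0, 50.0, 100.0, 500.0, 1000.0, 5000.0),
    slope: float = 80.0,
    intercept: float = 400.0,
    blank_sigma: float = 0.0,
    seed: int = 0,
    lines_per_standard: int = 8,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """LA-ICP-MS line-by-line scan of a 2-D concentration section (µg/g).

    The detector response is linear, intensity = slope * c + intercept, with
    Gaussian noise of ``blank_sigma``; matrix-matched gelatin standards
    (blank included) are scanned line-wise alongside the sample.  Returns
    ``(scan, standards)`` tables; scan rows are (line, pixel, intensity).
    """
    conc = np.asarray(concentration_map, dtype=float)
    if conc.ndim != 2:
        raise ValueError("concentration map must be 2-D (lines x pixels)")
    if conc.max(initial=0.0) > max(standards_ug_g):
        raise ValueError("standards do not cover the sample concentration range")
    rng = np.random.default_rng(seed)
    intensity = slope * conc + intercept
    if blank_sigma > 0:
        intensity = intensity + rng.normal(0, blank_sigma, size=intensity.shape)
    lines, pixels = np.indices(conc.shape)
    scan = pd.DataFrame(
        {
            "line": lines.ravel(),
            "pixel": pixels.ravel(),
            "intensity": intensity.ravel(),
        }
    )
    rows = []
    for c in standards_ug_g:
        base = slope * c + intercept
        vals = base + (
            rng.normal(0, blank_sigma, size=lines_per_standard)
            if blank_sigma > 0
            else np.zeros(lines_per_standard)
        )
        for i, v in enumerate(vals):
            rows.append({"concentration_ug_g": c, "line": i, "intensity": v})
    standards = pd.DataFrame(rows)
    return scan, standards
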