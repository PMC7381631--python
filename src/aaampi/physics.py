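"""Nanoparticle signal physics for field-free-point MPI and MPS.

The tracer is modelled as an equilibrium Langevin mixture: ferucarbotran-like
iron-oxide particles with a bimodal core-size distribution respond to the
instantaneous applied field with the weighted sum of Langevin magnetization
curves, one per core population.  Finite response speed (Neel/Brown dynamics
collapsed into a single effective time constant) is represented by a
first-order Debye low-pass acting on the induced signal, which is what
produces the faster decay of higher harmonics for tissue-bound (immobilized)
particles compared with freely suspended (fluid) ones.

All fields are expressed in mT, gradients in T/m (equivalently mT/mm),
positions in mm, frequencies in Hz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.fft import irfft, rfft, rfftfreq

BOLTZMANN_J_PER_K = 1.380649e-23
#: saturation magnetization of bulk maghemite/magnetite cores, A/m
BULK_MAGNETITE_MS_AM = 476e3

FLUID = "fluid"
IMMOBILIZED = "immobilized"


@dataclass(frozen=True)
class ParticleModel:
    """Equilibrium magnetization model of a polydisperse iron-oxide tracer.

    Parameters
    ----------
    core_diameters_nm : tuple of float
        Mean magnetic core diameters of the size populations (nm).
    weight_fractions : tuple of float
        Magnetic-signal weight of each population; must sum to 1.
    saturation_magnetization_am : float
        Domain saturation magnetization M_s (A/m).
    temperature_k : float
        Sample temperature (K).
    relaxation_time_s : float
        Effective first-order (Debye) relaxation time (s).  Tissue-bound
        particles relax more slowly than freely rotating ones, which damps
        their higher harmonics.
    mobility_state : str
        ``"fluid"`` or ``"immobilized"``.
    """

    core_diameters_nm: tuple[float, ...] = (4.0, 16.0)
    weight_fractions: tuple[float, ...] = (0.3, 0.7)
    saturation_magnetization_am: float = BULK_MAGNETITE_MS_AM
    temperature_k: float = 310.0
    relaxation_time_s: float = 3e-6
    mobility_state: str = IMMOBILIZED

    def __post_init__(self) -> None:
        if len(self.core_diameters_nm) != len(self.weight_fractions):
            raise ValueError("one weight fraction per core diameter required")
        if abs(sum(self.weight_fractions) - 1.0) > 1e-12:
            raise ValueError("weight fractions must sum to 1")
        if any(d <= 0 for d in self.core_diameters_nm):
            raise ValueError("core diameters must be positive")
        if self.relaxation_time_s < 0:
            raise ValueError("relaxation time must be nonnegative")
        if self.mobility_state not in (FLUID, IMMOBILIZED):
            raise ValueError(f"unknown mobility state {self.mobility_state!r}")

    @classmethod
    def ferucarbotran_fluid(cls) -> "ParticleModel":
        """Aqueous-suspension tracer (fast effective relaxation)."""
        return cls(relaxation_time_s=1e-6, mobility_state=FLUID)

    @classmethod
    def ferucarbotran_immobilized(cls) -> "ParticleModel":
        """Tissue-bound / freeze-dried tracer (slow effective relaxation)."""
        return cls(relaxation_time_s=3e-6, mobility_state=IMMOBILIZED)

    @property
    def magnetic_moments_am2(self) -> np.ndarray:
        """Magnetic moment m = M_s * V_core of each population (A m^2)."""
        d_m = np.asarray(self.core_diameters_nm) * 1e-9
        return self.saturation_magnetization_am * (math.pi / 6.0) * d_m**3

    @property
    def langevin_slopes_per_t(self) -> np.ndarray:
        """xi/B = m / (k_B T) for each population (1/T)."""
        return self.magnetic_moments_am2 / (
            BOLTZMANN_J_PER_K * self.temperature_k
        )


def langevin(xi):
    """Langevin function L(xi) = coth(xi) - 1/xi.

    Odd, bounded by 1 in magnitude; a Taylor branch xi/3 - xi^3/45 is used
    for |xi| < 1e-4 where the direct form loses precision.
    """
    xi = np.asarray(xi, dtype=float)
    if np.any(np.isnan(xi)):
        raise ValueError("langevin: NaN argument")
    small = np.abs(xi) < 1e-4
    safe = np.where(small, 1.0, xi)
    direct = 1.0 / np.tanh(safe) - 1.0 / safe
    series = xi / 3.0 - xi**3 / 45.0
    out = np.where(small, series, direct)
    return out if out.ndim else float(out)


def magnetization(field_mt, model: ParticleModel):
    """Equilibrium magnetization (A/m) of the tracer at a given field (mT).

    Weighted Langevin mixture over the core populations; odd in the field
    and bounded by the saturation magnetization.
    """
    b_t = np.asarray(field_mt, dtype=float) * 1e-3
    w = np.asarray(model.weight_fractions)
    slopes = model.langevin_slopes_per_t
    xi = b_t[..., np.newaxis] * slopes
    m = model.saturation_magnetization_am * np.sum(w * langevin(xi), axis=-1)
    return m if np.ndim(m) else float(m)


@dataclass(frozen=True)
class FieldSequence:
    """Drive-field / selection-field configuration of an FFP scanner.

    Defaults are the preclinical scanner settings used throughout: three
    orthogonal 12 mT drive fields at 2.5 MHz divided by 102/96/99 (x/y/z)
    and a selection-field gradient of 1.25 T/m in x/y and 2.5 T/m in z.
    ``samples_per_period`` samples one full Lissajous period; the native
    rate (one sample per base-frequency tick) is lcm(102,96,99) = 53856.
    """

    drive_amplitudes_mt: tuple[float, float, float] = (12.0, 12.0, 12.0)
    frequency_dividers: tuple[int, int, int] = (102, 96, 99)
    base_frequency_hz: float = 2.5e6
    gradients_t_per_m: tuple[float, float, float] = (1.25, 1.25, 2.5)
    samples_per_period: int = 53856

    def __post_init__(self) -> None:
        if any(int(d) != d or d < 1 for d in self.frequency_dividers):
            raise ValueError("frequency dividers must be positive integers")
        if any(g <= 0 for g in self.gradients_t_per_m):
            raise ValueError("gradients must be positive")
        if self.samples_per_period < 2:
            raise ValueError("samples_per_period must be >= 2")

    @property
    def drive_frequencies_hz(self) -> np.ndarray:
        return self.base_frequency_hz / np.asarray(
            self.frequency_dividers, dtype=float
        )

    @property
    def dividers_lcm(self) -> int:
        a, b, c = (int(d) for d in self.frequency_dividers)
        return math.lcm(a, b, c)

    @property
    def period_s(self) -> float:
        return lissajous_period(self)

    @property
    def sample_rate_hz(self) -> float:
        return self.samples_per_period / self.period_s

    @property
    def drive_bins(self) -> np.ndarray:
        """DFT bin index of each drive frequency over one Lissajous period."""
        return self.dividers_lcm // np.asarray(self.frequency_dividers)

    def times(self, n_periods: int = 1) -> np.ndarray:
        n = self.samples_per_period * n_periods
        return np.arange(n) / self.sample_rate_hz

    def downsampled(self, samples_per_period: int) -> "FieldSequence":
        """Same scanner, coarser time sampling of the Lissajous period."""
        return replace(self, samples_per_period=samples_per_period)


def lissajous_period(seq: FieldSequence) -> float:
    """Repeat time of the 3D Lissajous trajectory: lcm(dividers) / f_base."""
    return seq.dividers_lcm / seq.base_frequency_hz


def drive_field(seq: FieldSequence, t) -> np.ndarray:
    """Drive-field vector (mT) at times t (s); shape (..., 3)."""
    t = np.asarray(t, dtype=float)
    a = np.asarray(seq.drive_amplitudes_mt)
    f = seq.drive_frequencies_hz
    return a * np.sin(2.0 * math.pi * f * t[..., np.newaxis])


def ffp_position(seq: FieldSequence, t) -> np.ndarray:
    """Field-free-point position (mm) on the Lissajous trajectory at t (s).

    Along axis i the FFP is where gradient and drive field cancel, so the
    excursion amplitude is A_i/G_i and the peak-to-peak extent 2 A_i/G_i
    (19.2 mm in x/y, 9.6 mm in z for the default scanner).
    """
    a = np.asarray(seq.drive_amplitudes_mt)  # mT
    g = np.asarray(seq.gradients_t_per_m)  # T/m == mT/mm
    return (a / g) * np.sin(
        2.0 * math.pi * seq.drive_frequencies_hz * np.asarray(t, float)[..., np.newaxis]
    )


def ffp_extent_mm(seq: FieldSequence) -> np.ndarray:
    """Peak-to-peak FFP coverage 2 A_i / G_i per axis (mm).

    This is the extent of the continuous trajectory (the sine reaches its
    turning points between time samples), i.e. the overscanned volume:
    19.2 x 19.2 x 9.6 mm^3 for the default scanner.
    """
    a = np.asarray(seq.drive_amplitudes_mt)
    g = np.asarray(seq.gradients_t_per_m)
    return 2.0 * a / g


def _debye_derivative_transfer(freq_hz: np.ndarray, tau_s: float) -> np.ndarray:
    """Receive-chain transfer: time derivative with first-order relaxation."""
    jw = 2j * math.pi * freq_hz
    return -jw / (1.0 + jw * tau_s)


def induced_signal(
    concentration,
    model: ParticleModel,
    seq: FieldSequence,
    offset_mt=(0.0, 0.0, 0.0),
    moment_scale: float = 1.0,
) -> np.ndarray:
    """Receive signal (arbitrary units) of tracer exposed to the drive field.

    ``concentration`` is either a scalar or a uniformly sampled time series
    covering an integer number of Lissajous periods (length must be a
    multiple of ``seq.samples_per_period``).  The induced voltage is the
    (negative) time derivative of the mixture magnetization along each
    receive axis, with the model's Debye relaxation applied as a first-order
    low-pass; it is exactly linear in concentration.

    Returns an array of shape (n_samples, 3), one column per receive axis.
    """
    n = seq.samples_per_period
    c = np.asarray(concentration, dtype=float)
    if c.ndim == 0:
        c = np.full(n, float(c))
    elif c.ndim != 1 or c.size % n != 0:
        raise ValueError(
            "concentration series must cover an integer number of "
            "Lissajous periods (length a multiple of samples_per_period)"
        )
    t = np.arange(c.size) / seq.sample_rate_hz
    b = drive_field(seq, t) + np.asarray(offset_mt, dtype=float)
    bmag = np.linalg.norm(b, axis=-1)
    m_scalar = magnetization(bmag, model)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(bmag[:, None] > 0, b / np.where(bmag[:, None] > 0, bmag[:, None], 1.0), 0.0)
    m_vec = moment_scale * c[:, None] * m_scalar[:, None] * unit
    spec = rfft(m_vec, axis=0)
    freqs = rfftfreq(c.size, d=1.0 / seq.sample_rate_hz)
    spec *= _debye_derivative_transfer(freqs, model.relaxation_time_s)[:, None]
    return irfft(spec, n=c.size, axis=0)


@dataclass
class HarmonicSpectrum:
    """Complex harmonic amplitudes of a periodic signal.

    ``amplitudes[k-1]`` is the complex amplitude at k times the fundamental
    (index 1 is the excitation fundamental).  ``background`` holds the
    empty-holder spectrum on the same harmonic grid (zeros when absent).
    """

    fundamental_hz: float
    amplitudes: np.ndarray
    background: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=complex)
        if self.background is None:
            self.background = np.zeros_like(self.amplitudes)
        else:
            self.background = np.asarray(self.background, dtype=complex)
            if self.background.shape != self.amplitudes.shape:
                raise ValueError("background must match amplitude shape")

    @property
    def n_harmonics(self) -> int:
        return len(self.amplitudes)

    def amplitude(self, k: int) -> complex:
        """Complex amplitude of harmonic k (1-based)."""
        if not 1 <= k <= self.n_harmonics:
            raise IndexError(f"harmonic {k} outside 1..{self.n_harmonics}")
        return complex(self.amplitudes[k - 1])

    def magnitude(self, k: int) -> float:
        return abs(self.amplitude(k))

    def net_magnitude(self, k: int) -> float:
        """|A_k - A_k,background|, floored at zero."""
        return abs(self.amplitude(k) - complex(self.background[k - 1]))


def harmonic_spectrum(
    signal,
    fundamental_hz: float,
    sample_rate_hz: float,
    n_harmonics: int | None = None,
    background=None,
) -> HarmonicSpectrum:
    """Decompose a periodic signal into harmonics of ``fundamental_hz``.

    The signal must span an integer number of fundamental periods (to 1e-6
    relative), so every harmonic falls exactly on a DFT bin.  Amplitudes are
    peak-normalized (a unit sine at the fundamental gives |A_1| = 1), which
    keeps them independent of the sampling density.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("harmonic_spectrum expects a 1-D signal")
    cycles = x.size * fundamental_hz / sample_rate_hz
    if abs(cycles - round(cycles)) > 1e-6 * max(1.0, cycles):
        raise ValueError(
            f"signal spans {cycles:g} fundamental periods; an integer "
            "number is required"
        )
    cycles = round(cycles)
    if cycles < 1:
        raise ValueError("signal shorter than one fundamental period")
    spec = rfft(x) * 2.0 / x.size
    kmax = (x.size // 2) // cycles
    if n_harmonics is not None:
        kmax = min(kmax, n_harmonics)
    amps = spec[np.arange(1, kmax + 1) * cycles]
    return HarmonicSpectrum(fundamental_hz, amps, background=background)
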