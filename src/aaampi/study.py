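"""End-to-end synthetic study: cohort simulation and agreement statistics.

Mirrors the animal study's design at desk scale: a cohort of aneurysm-like
samples carrying 0.1-5 µg of tissue-bound tracer plus tracer-free controls
is generated, each sample is quantified independently by the MPI chain
(reconstruction, 50% cutoff, VOI integration) and the MPS chain (A3
normalization against a mobility-matched reference), and the per-sample
estimates are compared: Pearson correlation, mean absolute percent
deviation of MPI from MPS (overall and stratified at 1 µg), and an
unpaired two-tailed t-test of aneurysm vs control masses.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .histo import (
    ColorProfile,
    fit_calibration,
    quantify_map,
    segment_by_profile,
    tissue_mask_from_image,
)
from .mpiquant import quantify_mpi
from .mpsquant import ReferenceSample, harmonic_ratio, quantify_iron_mps, select_reference
from .physics import FLUID, IMMOBILIZED, FieldSequence, ParticleModel
from .recon import ReconConfig, reconstruct
from .synth import (
    SFSample,
    VoxelGrid,
    make_elemental_scan,
    make_phantom,
    make_stain_image,
    simulate_measurement,
    simulate_mps,
    simulate_system_function,
)

log = logging.getLogger(__name__)

# Frozen noise calibration (scripts/calibrate_noise.py).  The SF sigma is
# set so that a few hundred frequency components of the default immobilized
# system function clear the SNR-7 selection threshold; the measurement and
# MPS sigmas place the MPI-vs-MPS agreement of the default cohort in the
# regime reported for the ex vivo samples.
SF_NOISE_SIGMA = 9.6072e-4
MEAS_NOISE_SIGMA = 4.0e-4
MPS_NOISE_SIGMA = 1.1684e-5

#: Perls'-positive area fraction per µg of sample iron in the stain fixture
STAIN_AREA_PER_UG = 0.05
#: µg/g per mM Fe at soft-tissue density 1.05 g/ml
UG_G_PER_MM = 55.845 / 1.05


class DeviationStrata(NamedTuple):
    """Mean absolute percent deviations; strata are None when empty."""

    overall: float
    above: float | None
    below: float | None


def pearson_r(x, y) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length vectors of at least 3 values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    return float(np.corrcoef(x, y)[0, 1])


def stratified_deviation(mpi, mps, cut_ug: float = 1.0) -> DeviationStrata:
    """Mean |MPI - MPS| / MPS x 100, overall and split at ``cut_ug``.

    The reference method (MPS) defines both the denominator and the
    stratification; an empty stratum is reported as absent rather than 0.
    """
    mpi = np.asarray(mpi, dtype=float)
    mps = np.asarray(mps, dtype=float)
    if mpi.shape != mps.shape:
        raise ValueError("mpi and mps vectors differ in length")
    if np.any(mps <= 0):
        raise ValueError("all MPS masses must be positive")
    dev = np.abs(mpi - mps) / mps * 100.0
    above = mps >= cut_ug
    return DeviationStrata(
        overall=float(dev.mean()),
        above=float(dev[above].mean()) if above.any() else None,
        below=float(dev[~above].mean()) if (~above).any() else None,
    )


def unpaired_t_test(group_a, group_b) -> float:
    """Two-tailed p of a Student's t test (unpaired, equal variance)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(a) == 0 and np.var(b) == 0:
        raise ValueError("degenerate: both groups have zero variance")
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue)


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a synthetic cohort run.

    The defaults mirror the animal study's group sizes (23 aneurysm
    samples, 9 sham controls) with log-uniform iron masses over 0.1-5 µg,
    tissue-bound (immobilized) tracer, and the frozen noise calibration.
    """

    n_samples: int = 23
    iron_mass_range_ug: tuple[float, float] = (0.1, 5.0)
    mass_distribution: str = "log-uniform"
    masses_ug: tuple[float, ...] | None = None
    n_controls: int = 9
    seed: int = 1
    grid: VoxelGrid = field(default_factory=VoxelGrid)
    sequence: FieldSequence = field(
        default_factory=lambda: FieldSequence().downsampled(13464)
    )
    sf_noise_sigma: float = SF_NOISE_SIGMA
    meas_noise_sigma: float = MEAS_NOISE_SIGMA
    mps_noise_sigma: float = MPS_NOISE_SIGMA
    recon: ReconConfig = field(default_factory=ReconConfig)
    n_repetitions: int = 20
    source_subdivisions: tuple[int, int, int] = (2, 2, 1)
    recovery_calibration: bool = True
    include_histology: bool = True
    include_elemental: bool = True

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        if not self.iron_mass_range_ug[0] < self.iron_mass_range_ug[1]:
            raise ValueError("mass range low must be below high")
        if self.mass_distribution not in ("log-uniform", "fixed-list"):
            raise ValueError("mass_distribution must be log-uniform or fixed-list")
        if self.mass_distribution == "fixed-list" and not self.masses_ug:
            raise ValueError("fixed-list distribution needs masses_ug")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(_config_dict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["grid"] = VoxelGrid(
            tuple(raw["grid"]["shape"]), tuple(raw["grid"]["fov_mm"])
        )
        seq = raw["sequence"]
        raw["sequence"] = FieldSequence(
            tuple(seq["drive_amplitudes_mt"]),
            tuple(seq["frequency_dividers"]),
            seq["base_frequency_hz"],
            tuple(seq["gradients_t_per_m"]),
            seq["samples_per_period"],
        )
        rc = raw["recon"]
        rc["band_hz"] = tuple(rc["band_hz"])
        raw["recon"] = ReconConfig(**rc)
        for key in ("iron_mass_range_ug", "source_subdivisions"):
            raw[key] = tuple(raw[key])
        if raw.get("masses_ug") is not None:
            raw["masses_ug"] = tuple(raw["masses_ug"])
        return cls(**raw)


def _config_dict(cfg: CohortConfig) -> dict:
    def plain(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: plain(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, tuple):
            return [plain(v) for v in obj]
        if isinstance(obj, np.generic):
            return obj.item()
        return obj

    return plain(cfg)


@dataclass
class AgreementReport:
    """Cohort-level agreement between the quantification methods."""

    per_sample: pd.DataFrame
    pearson_r_mpi_mps: float
    mean_abs_pct_dev: DeviationStrata
    correlations: dict
    t_test_p: float
    n_quantified: int
    config: CohortConfig
    mpi_recovery_factor: float = 1.0

    def to_dict(self) -> dict:
        return {
            "pearson_r_mpi_mps": self.pearson_r_mpi_mps,
            "mean_abs_pct_dev_overall": self.mean_abs_pct_dev.overall,
            "mean_abs_pct_dev_above_1ug": self.mean_abs_pct_dev.above,
            "mean_abs_pct_dev_below_1ug": self.mean_abs_pct_dev.below,
            "correlations": self.correlations,
            "t_test_p": self.t_test_p,
            "n_quantified": self.n_quantified,
            "mpi_recovery_factor": self.mpi_recovery_factor,
            "config": _config_dict(self.config),
        }

    def write(self, output_dir) -> None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(self.to_dict(), indent=2, sort_keys=True)
        )
        self.per_sample.to_csv(out / "per_sample.csv", index=False)


def mpi_recovery_factor(
    sf,
    recon_cfg: ReconConfig,
    n_phantoms: int = 5,
    mass_ug: float = 2.0,
    seed: int = 0,
    **phantom_kwargs,
) -> float:
    """Empirical mass-recovery coefficient of the MPI quantification chain.

    Reference phantoms of known iron mass are measured (noise-free) and
    quantified through the identical reconstruct / 50%-cutoff / integrate
    pipeline; the factor is the mean ratio of true to estimated mass.  It
    compensates the systematic cutoff loss of regularization blur, which
    is stable across phantom geometries (a few percent scatter) and, by
    linearity of the chain, independent of the sample mass.
    """
    ratios = []
    for i in range(n_phantoms):
        phantom = make_phantom(sf.grid, mass_ug, seed=seed + 1000 + i, **phantom_kwargs)
        meas = simulate_measurement(phantom, sf, noise_sigma=0.0)
        img = reconstruct(meas, sf, recon_cfg)
        est = quantify_mpi(img).iron_mass_ug
        if est <= 0:
            raise ValueError("recovery calibration phantom was not detected")
        ratios.append(mass_ug / est)
    return float(np.mean(ratios))


def _reference_library(cfg: CohortConfig) -> list[ReferenceSample]:
    refs = []
    for model, state in (
        (ParticleModel.ferucarbotran_fluid(), FLUID),
        (ParticleModel.ferucarbotran_immobilized(), IMMOBILIZED),
    ):
        spec = simulate_mps(SFSample().iron_mass_ug, model, noise_sigma=0.0)
        refs.append(
            ReferenceSample(
                spectrum=spec, iron_mass_ug=SFSample().iron_mass_ug, mobility_state=state
            )
        )
    return refs


def run_study(
    cfg: CohortConfig | None = None, output_dir=None, sf=None
) -> AgreementReport:
    """Simulate and quantify a full cohort; assemble the agreement report.

    Fully reproducible from (config, seed).  When ``output_dir`` is given,
    ``report.json`` and ``per_sample.csv`` are written there.  A
    pre-simulated system function may be passed via ``sf`` (scanners reuse
    one calibration across samples); the cohort draws are unaffected.
    """
    cfg = cfg or CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    model = ParticleModel.ferucarbotran_immobilized()

    t0 = time.perf_counter()
    sf_seed = int(rng.integers(2**31))
    if sf is None:
        log.info(
            "simulating system function (%s grid)", "x".join(map(str, cfg.grid.shape))
        )
        sf = simulate_system_function(
            cfg.grid,
            cfg.sequence,
            model,
            noise_sigma=cfg.sf_noise_sigma,
            seed=sf_seed,
            source_subdivisions=cfg.source_subdivisions,
        )
        log.info(
            "system function: %d stored components in %.1f s",
            sf.n_components,
            time.perf_counter() - t0,
        )
    elif sf.grid != cfg.grid:
        raise ValueError("provided system function does not match the cohort grid")
    refs = _reference_library(cfg)
    recovery = (
        mpi_recovery_factor(sf, cfg.recon, seed=cfg.seed)
        if cfg.recovery_calibration
        else 1.0
    )
    log.info("MPI recovery factor: %.3f", recovery)

    if cfg.mass_distribution == "fixed-list":
        masses = np.asarray(cfg.masses_ug, dtype=float)[: cfg.n_samples]
    else:
        lo, hi = cfg.iron_mass_range_ug
        masses = np.exp(rng.uniform(math.log(lo), math.log(hi), size=cfg.n_samples))
    groups = ["aneurysm"] * len(masses) + ["control"] * cfg.n_controls
    all_masses = np.concatenate([masses, np.zeros(cfg.n_controls)])

    rows = []
    for i, (group, mass) in enumerate(zip(groups, all_masses)):
        sid = f"{group[:3]}-{i:02d}"
        seeds = rng.integers(2**31, size=5)
        row: dict = {"sample_id": sid, "group": group, "true_mass_ug": mass}
        try:
            row.update(
                _quantify_sample(sid, group, mass, sf, cfg, model, refs, seeds, recovery)
            )
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"sample {sid} failed during {exc}") from exc
        rows.append(row)
    per_sample = pd.DataFrame(rows)

    exp = per_sample[per_sample["group"] == "aneurysm"]
    ok = exp["mps_mass_ug"].notna() & (exp["mps_mass_ug"] > 0)
    quantified = exp[ok]
    r = pearson_r(quantified["mpi_mass_ug"], quantified["mps_mass_ug"])
    dev = stratified_deviation(
        quantified["mpi_mass_ug"].to_numpy(), quantified["mps_mass_ug"].to_numpy()
    )
    correlations = {"mpi_vs_mps": r}
    for a, b in (
        ("mpi_mass_ug", "true_mass_ug"),
        ("mps_mass_ug", "true_mass_ug"),
        ("stain_area_ratio", "mps_mass_ug"),
        ("elemental_mean_ug_g", "mps_mass_ug"),
    ):
        if a in quantified and quantified[a].notna().all():
            correlations[f"{a.split('_')[0]}_vs_{b.split('_')[0]}"] = pearson_r(
                quantified[a], quantified[b]
            )
    ctrl = per_sample[per_sample["group"] == "control"]["mpi_mass_ug"]
    p = unpaired_t_test(exp["mpi_mass_ug"], ctrl) if len(ctrl) >= 2 else float("nan")

    report = AgreementReport(
        per_sample=per_sample,
        pearson_r_mpi_mps=r,
        mean_abs_pct_dev=dev,
        correlations=correlations,
        t_test_p=p,
        n_quantified=int(ok.sum()),
        config=cfg,
        mpi_recovery_factor=recovery,
    )
    if output_dir is not None:
        report.write(output_dir)
    log.info("cohort of %d samples finished in %.1f s", len(per_sample), time.perf_counter() - t0)
    return report


def _quantify_sample(sid, group, mass, sf, cfg, model, refs, seeds, recovery) -> dict:
    row: dict = {}

    # --- MPI chain -------------------------------------------------------
    if mass > 0:
        phantom = make_phantom(cfg.grid, mass, seed=int(seeds[0]))
    else:
        phantom = None
    if phantom is not None:
        meas = simulate_measurement(
            phantom,
            sf,
            n_repetitions=cfg.n_repetitions,
            noise_sigma=cfg.meas_noise_sigma,
            seed=int(seeds[1]),
        )
    else:
        from .synth import Phantom

        empty = Phantom(np.zeros(cfg.grid.shape), cfg.grid)
        meas = simulate_measurement(
            empty,
            sf,
            n_repetitions=cfg.n_repetitions,
            noise_sigma=cfg.meas_noise_sigma,
            seed=int(seeds[1]),
        )
    img = reconstruct(meas, sf, cfg.recon)
    q_mpi = quantify_mpi(img, sample_id=sid, recovery_factor=recovery)
    row["mpi_mass_ug"] = q_mpi.iron_mass_ug
    row["mpi_detected"] = q_mpi.detected
    row["voi_voxel_count"] = q_mpi.voi_voxel_count
    row["selected_components"] = img.selected_component_count

    # --- MPS chain -------------------------------------------------------
    spec = simulate_mps(
        mass, model, noise_sigma=cfg.mps_noise_sigma, seed=int(seeds[2])
    )
    try:
        ratio = harmonic_ratio(spec)
        ref = select_reference(ratio, refs)
        q_mps = quantify_iron_mps(spec, None, ref, sample_id=sid)
        row["mps_mass_ug"] = q_mps.iron_mass_ug
        row["mps_reference"] = ref.mobility_state
        row["a5_a3_ratio"] = ratio
    except ValueError:
        # signal indistinguishable from the empty holder
        row["mps_mass_ug"] = float("nan")
        row["mps_reference"] = ""
        row["a5_a3_ratio"] = float("nan")

    # --- histology -------------------------------------------------------
    if cfg.include_histology:
        fraction = min(0.3, STAIN_AREA_PER_UG * mass)
        img_rgb, _, _ = make_stain_image(fraction, seed=int(seeds[3]))
        tissue = tissue_mask_from_image(img_rgb)
        _, ratio_est = segment_by_profile(img_rgb, ColorProfile(), tissue)
        row["stain_area_ratio"] = ratio_est

    # --- elemental map ---------------------------------------------------
    if cfg.include_elemental and phantom is not None:
        mid = cfg.grid.shape[2] // 2
        section_ug_g = phantom.concentration_mm[:, :, mid] * UG_G_PER_MM
        scan, standards = make_elemental_scan(
            section_ug_g, blank_sigma=20.0, seed=int(seeds[4])
        )
        curve = fit_calibration(standards)
        conc, below = quantify_map(scan, curve)
        row["elemental_mean_ug_g"] = float(conc[~below].mean()) if (~below).any() else 0.0
        row["elemental_lod_ug_g"] = curve.lod_ug_g
    elif cfg.include_elemental:
        row["elemental_mean_ug_g"] = 0.0
        row["elemental_lod_ug_g"] = float("nan")

    return row
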