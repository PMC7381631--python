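"""One-time calibration of the synthetic study's noise levels.

Run from the repository root:

    python scripts/calibrate_noise.py

Three sigmas define the generator's default noise conditions; this script
derives them and prints the values frozen in ``aaampi.study``:

* System-function sigma — chosen so that a few hundred frequency
  components (target: 487, the number the scanner software selected
  automatically) of the default immobilized system function clear the
  SNR = 7 selection threshold.
* MPS sigma — anchored physically: harmonic-amplitude SNR of 20 on the
  third harmonic at the 0.05 µg bottom of the tracer-mass range the
  spectrometer handled, i.e. samples below that fade into the empty-holder
  background.
* Measurement sigma — the largest rung of a geometric ladder for which
  the cohort's MPI-vs-MPS deviations stay at or below the study's
  reported levels (8.3% above 1 µg, 20.6% below, 15.2% overall) on every
  validation seed.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import numpy as np

from aaampi.physics import ParticleModel
from aaampi.recon import ReconConfig, select_components
from aaampi.study import CohortConfig, run_study
from aaampi.synth import simulate_mps, simulate_system_function

TARGET_COMPONENTS = 487
DEVIATION_BOUNDS = {"above": 8.3, "below": 20.6, "overall": 15.2}
#: deviations must stay below the reported levels by this margin on every
#: validation seed, so that cohorts drawn with other seeds remain inside
SAFETY_FACTOR = 1.25
MEAS_SIGMA_LADDER = (5e-5, 1e-4, 2e-4, 4e-4, 8e-4)
VALIDATION_SEEDS = (1, 2, 3)


def main() -> None:
    cfg = CohortConfig()
    model = ParticleModel.ferucarbotran_immobilized()

    print("== system-function sigma ==")
    t0 = time.time()
    sf0 = simulate_system_function(
        cfg.grid, cfg.sequence, model, noise_sigma=0.0, seed=0,
        source_subdivisions=cfg.source_subdivisions,
    )
    rc = ReconConfig()
    eligible = (
        (sf0.component_freq_hz >= rc.band_hz[0])
        & (sf0.component_freq_hz <= rc.band_hz[1])
        & (sf0.component_mixing_order <= rc.max_mixing_order)
    )
    rms = np.sort(np.sqrt(np.mean(np.abs(sf0.matrix[eligible]) ** 2, axis=1)))[::-1]
    sf_sigma = float(rms[min(TARGET_COMPONENTS, len(rms)) - 1] / 7.0)
    print(f"noiseless SF: {sf0.n_components} stored rows ({time.time()-t0:.0f} s)")
    print(f"SF sigma for {TARGET_COMPONENTS} components at SNR 7: {sf_sigma:.4e}")

    print("== MPS sigma ==")
    a3_005 = simulate_mps(0.05, model).magnitude(3)
    mps_sigma = float(a3_005 / 20.0)
    print(f"A3(0.05 ug) = {a3_005:.3e}; sigma for SNR 20: {mps_sigma:.3e}")

    print("== measurement sigma ladder ==")
    results: dict[float, list] = {s: [] for s in MEAS_SIGMA_LADDER}
    for seed in VALIDATION_SEEDS:
        base = dataclasses.replace(cfg, seed=seed, sf_noise_sigma=sf_sigma,
                                   mps_noise_sigma=mps_sigma)
        rng = np.random.default_rng(seed)
        sf = simulate_system_function(
            cfg.grid, cfg.sequence, model, noise_sigma=sf_sigma,
            seed=int(rng.integers(2**31)),
            source_subdivisions=cfg.source_subdivisions,
        )
        n_sel = len(select_components(sf, ReconConfig()))
        print(f"seed {seed}: {n_sel} components selected at SNR 7")
        for sigma in MEAS_SIGMA_LADDER:
            run_cfg = dataclasses.replace(base, meas_noise_sigma=sigma)
            rep = run_study(run_cfg, sf=sf)
            dev = rep.mean_abs_pct_dev
            results[sigma].append(dev)
            print(
                f"  meas sigma {sigma:.0e}: R={rep.pearson_r_mpi_mps:.4f} "
                f"overall {dev.overall:.1f}% above {dev.above:.1f}% below {dev.below:.1f}%"
            )

    chosen = None
    for sigma in sorted(MEAS_SIGMA_LADDER, reverse=True):
        devs = results[sigma]
        if all(
            d.overall <= DEVIATION_BOUNDS["overall"] / SAFETY_FACTOR
            and d.above <= DEVIATION_BOUNDS["above"] / SAFETY_FACTOR
            and d.below <= DEVIATION_BOUNDS["below"] / SAFETY_FACTOR
            for d in devs
        ):
            chosen = sigma
            break
    print("== frozen values ==")
    print(f"SF_NOISE_SIGMA = {sf_sigma:.4e}")
    print(f"MEAS_NOISE_SIGMA = {chosen}")
    print(f"MPS_NOISE_SIGMA = {mps_sigma:.4e}")
    out = Path("scratch/noise_calibration.json")
    out.parent.mkdir(exist_ok=True)
    out.write_text(json.dumps({
        "sf_noise_sigma": sf_sigma,
        "meas_noise_sigma": chosen,
        "mps_noise_sigma": mps_sigma,
        "ladder": {
            str(s): [list(d) for d in devs] for s, devs in results.items()
        },
    }, indent=2))
    print(f"written to {out}")


if __name__ == "__main__":
    main()
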