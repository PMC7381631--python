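# Methods

`aaampi` reproduces, on fully synthetic data with known ground truth, an ex
vivo iron-quantification workflow for abdominal aortic aneurysm (AAA)
samples: field-free-point (FFP) magnetic particle imaging (MPI) with
system-function reconstruction, magnetic particle spectroscopy (MPS)
reference quantification, and two independent validation readouts
(Perls'-stain morphometry and LA-ICP-MS elemental mapping).  This note
documents the models, the parameters that matter, the numerical choices,
and what the synthetic study can and cannot show about real data.

## Tracer model

The tracer is a ferucarbotran-like iron-oxide nanoparticle formulation with
the bimodal core-size distribution reported for that agent (≈4 nm and
≈16 nm populations).  Its equilibrium response is a weighted Langevin
mixture

    M(B) = M_s · Σ_i w_i · L(m_i B / k_B T),   L(ξ) = coth ξ − 1/ξ,

with `m_i = M_s · (π/6) d_i³` the core moment.  Defaults: d = (4, 16) nm
with magnetic-signal weights (0.3, 0.7), `M_s` = 476 kA/m (bulk
magnetite/maghemite), T = 310 K.  At 12–25 mT drive amplitudes the 16 nm
population is well into the nonlinear regime (ξ ≈ 3) and generates the
harmonics; the 4 nm population is nearly linear and mostly dilutes the
signal — this is the physical reason multi-core tracers quantify well but
image with limited resolution.

Finite response speed is modelled as a single effective first-order (Debye)
relaxation applied to the induced signal, `H(f) = −2πif / (1 + 2πif τ)`
(derivative × low-pass).  Defaults: τ = 1 µs for freely suspended (fluid)
tracer, τ = 3 µs for tissue-bound/freeze-dried (immobilized) tracer.  The
larger τ damps higher harmonics more strongly, which reproduces the two
observable consequences of immobilization: a smaller A5/A3 harmonic ratio
in MPS, and fewer high-mixing-order components above a fixed SNR in the
system function.  Stochastic Néel/Brown dynamics, hysteresis and
inter-particle interactions are deliberately out of scope; τ is an
effective, config-exposed parameter, not a microscopic claim.

## Scanner model

The simulated preclinical FFP scanner drives three orthogonal 12 mT fields
at 2.5 MHz divided by 102/96/99 (x/y/z) inside a selection-field gradient
of 1.25 T/m (x, y) and 2.5 T/m (z).  The FFP therefore traces a 3-D
Lissajous trajectory with repeat period lcm(102,96,99)/2.5 MHz = 21.54 ms
and peak-to-peak coverage 2A/G = 19.2 × 19.2 × 9.6 mm³.  Every mixing
frequency k_x f_x + k_y f_y + k_z f_z falls exactly on a DFT bin of the
Lissajous period (bins 528/561/544 per unit k), and a component's mixing
order is the minimal |k_x|+|k_y|+|k_z| reaching its bin, found by
enumerating the ℓ₁ ball.

A system function (SF) is simulated by placing the calibration sample — a
100 mM Fe, 13.5 µl cuboid of 3 × 3 × 1.5 mm³, sub-sampled 2×2×1 — at every
node of the 25 × 25 × 13 voxel grid (25 × 25 × 13 mm³ FOV) and recording
the Debye-filtered derivative of its magnetization along the three receive
axes.  Matrix entries get additive complex Gaussian noise; per-component
SNR is row RMS over sigma.  Measurements of a phantom are `S·x` plus frame
noise, where `x` is the phantom expressed in calibration-sample
equivalents; a solution value of 1 therefore means 75.4 µg Fe
(= 0.1 mol/l × 13.5 µl × 55.845 g/mol) in a voxel, and all mass bookkeeping
uses the molar mass of iron, 55.845 g/mol.

Because forward simulation and reconstruction share the same matrix, the
study works in the "inverse-crime" regime: it probes the quantification
chain (selection, solver, cutoff, calibration, noise propagation), not
model mismatch between a real scanner and its SF.

### Time sampling at desk scale

The native sampling is one sample per base-frequency tick (53 856 per
Lissajous period).  The default simulations sample 13 464 points per period
(every 4th tick).  Mixing bins remain exactly resolved — bin indices are
independent of the sampling density — while the Nyquist limit drops to
312 kHz, which caps the usable receive band well above the SNR-limited
region; harmonic energy above Nyquist aliases identically into the SF and
the measurement, so the forward/inverse pair stays exactly consistent.
This cuts simulation cost ~4× with no effect on the quantification logic.

## Reconstruction

Components are selected from the SF by SNR ≥ 7, frequency inside
90 kHz–1.25 MHz (the low edge also removes the 3rd harmonic of the x drive
at 73.5 kHz), and mixing order ≤ 25; with the frozen SF noise level the
default SF yields ≈490 selected components, a few hundred as in the
scanner-software regime.  Measurement frames are block-averaged (20
repetitions), and the image is solved by regularized Kaczmarz row action on
the augmented Tikhonov system: per row
`α = (y_i − a_i·x − √λ_eff v_i)/(‖a_i‖² + λ_eff)`, `x += α a_i*`,
`v_i += α √λ_eff`, five full sweeps, rows visited in descending SNR, with
projection onto the nonnegative real orthant after each sweep.  λ = 0.1 is
interpreted relative to the mean squared row magnitude (absolute λ
available via config).  The solver is deterministic and, unregularized and
iterated, matches a dense least-squares solve to <1e-5 relative error.

## MPI quantification and the recovery coefficient

Following the study procedure, the 3-D image is thresholded at 50% of its
maximum voxel intensity (ties included) and the surviving volume of
interest integrated to an iron mass via voxel volume and the SF
calibration.  At these field parameters the point-spread function is
several millimetres wide, so regularized reconstruction inevitably pushes
20–30% of a compact sample's mass below the 50% cutoff.  The chain is
therefore calibrated as a whole: `mpi_recovery_factor` measures known-mass
reference phantoms noise-free through the identical
reconstruct → cutoff → integrate pipeline and returns the mean true/estimated
ratio (≈1.3 under the defaults).  Because every stage except the
scale-invariant cutoff mask is linear in tracer mass, one coefficient
serves all masses; its residual geometry dependence (CV ≈ 2.4% across
phantom shapes on the study grid) is the floor of MPI quantification
accuracy here, mirroring the partial-volume argument the modality itself
faces.  A configurable visibility floor supports the observation that only
samples above ≈0.3 µg image reliably.

## MPS quantification

A sample in a homogeneous 25 mT, 25 kHz sinusoidal excitation yields a
harmonic spectrum linear in iron mass.  Quantification normalizes the
background-subtracted third-harmonic magnitude to that of a reference of
known mass: `m = m_ref · |A3 − A3_bg| / |A3_ref − A3_ref,bg|`.  The
reference (fluid vs immobilized, default library: one of each at the
75.4 µg calibration-sample equivalent) is chosen by nearest A5/A3 ratio on
a log scale, ties preferring immobilized (the tissue-bound state of
phagocytosed tracer).  Magnitudes, not complex amplitudes, are normalized
(complex subtraction of the background is used inside the magnitude).  With
matched model and no noise the chain inverts the simulator exactly.

## Validation stages

*Perls' morphometry*: the synthetic section is an annular vessel wall with
blob-like iron deposits occupying an exact area fraction.  Tissue is
segmented against the slide background using the border-estimated
luminance (Otsu fails on strongly stained, trimodal sections); iron pixels
are those within a CIELAB Euclidean tolerance (default 18) of the
reference Perls'-blue RGB.  The readout is the iron/tissue area ratio.

*LA-ICP-MS*: line scans respond linearly (intensity = slope·c + intercept,
Gaussian detector noise); nine gelatin standards including a blank
(1–5000 µg/g) are fit by ordinary least squares, the blank's line-to-line
scatter gives sigma, and LOD/LOQ follow the 3σ/10σ criteria — their ratio
is 10/3 by construction.  Maps are inverted through the line, floored at
zero, with below-LOD pixels flagged.

*Colocalization* is the Dice coefficient of two masks (0 when both empty);
it is descriptive, matching the qualitative colocalization claim it
stands in for.

## Synthetic cohort and agreement statistics

The default cohort mirrors the animal study's arms: 23 aneurysm samples
with log-uniform iron masses in 0.1–5 µg plus 9 tracer-free controls, all
tissue-bound tracer.  Each phantom is a harvested-aortic-segment stand-in:
an annular cylinder along z (outer diameter 2–3.8 mm — aneurysmal
dilatation of a ~1 mm mouse aorta — length 5–7 mm, wall 0.9 mm) with an
attached mural thrombus blob and ±40% voxel-wise concentration
heterogeneity, position jittered ±1.5 mm.  Stain sections use an iron-area
fraction of 0.05 per µg (saturating at 0.30); elemental sections convert
mM to µg/g at tissue density 1.05 g/ml.

Per sample the report records truth, MPI and MPS masses, the A5/A3 ratio
and chosen reference, stain area ratio and elemental section statistics.
Agreement metrics: Pearson R between MPI and MPS masses; mean absolute
percent deviation |MPI − MPS|/MPS × 100 overall and stratified at 1 µg
(a sample exactly at 1 µg counts as "above"; an empty stratum is reported
absent); an unpaired two-tailed equal-variance t-test of aneurysm vs
control MPI masses (p < 0.05 significant, single comparison, no
multiplicity correction).

### Frozen noise calibration

The generator's noise levels are conditions of the study, fixed once by
`scripts/calibrate_noise.py` and frozen in `aaampi.study`:

* SF sigma = 9.607e-4 (arbitrary receiver units): the level at which 487
  band/order-eligible components of the default immobilized SF sit at
  SNR ≥ 7 — the component count regime of the scanner software.
* MPS sigma = 1.168e-5: anchored a priori at A3 SNR 20 for a 0.05 µg
  sample, the bottom of the tracer-mass range the spectrometer handled.
* Measurement sigma = 4e-4 per component per frame: the largest rung of a
  geometric ladder whose cohort deviations stay below the reported
  agreement levels with a 1.25 safety margin on three validation seeds,
  so cohorts drawn with other seeds remain inside.

With these levels MPS is the precise reference and MPI error grows as mass
shrinks, reproducing the reported ordering (below-1 µg deviation larger
than above-1 µg).

## What passing tests do and do not show

The generator emulates the study's *conditions* (field parameters, grids,
component counts, sample masses, group sizes) with known ground truth; it
does not emulate scanner hardware imperfections, SF model mismatch,
background drift, anatomical variability beyond the geometric phantom, or
operator steps (MRI co-registration, manual VOI drawing).  Agreement
numbers from the synthetic cohort therefore validate the *pipeline* — its
linearity, calibration and noise propagation — at the study's scale, not
the biological findings.

## Numerical choices and degenerate inputs

* Langevin evaluation switches to the series ξ/3 − ξ³/45 below |ξ| < 1e-4
  (hot simulation loops use the series below 0.2 with the ξ⁵ term,
  accurate to ~3e-9); NaN input is rejected.
* Spectra are peak-normalized (×2/N) so amplitudes are independent of
  sampling density; signals must span an integer number of fundamental
  periods (checked to 1e-6) so harmonics fall exactly on DFT bins.
* Stored SF components are pre-filtered by order ≤ 30, frequency ≥ 50 kHz
  and a probe-based relative floor of 1e-4 of the strongest response —
  everything discarded is orders of magnitude below any usable SNR.
* Kaczmarz skips zero rows with a log notice; an all-zero image yields an
  empty cutoff mask and an undetected sample rather than an error; an MPS
  sample whose A3 does not rise above background is reported
  unquantifiable (NaN in the cohort table).
* All generators are pure functions of (parameters, seed) using
  `numpy.random.default_rng`; reports are byte-identical across reruns.

## Problem sizes

Default cohort runs use the full 25 × 25 × 13 study grid with the
quarter-tick time sampling (SF simulation ≈ 2 min on one core; each
reconstruction < 1 s at ~490 components).  Unit tests exercise the same
code on 9 × 9 × 5 and 13 × 13 × 9 grids, where the tighter z coverage
slightly inflates partial-volume scatter — bounds in those tests are set
accordingly, and study-scale accuracy is asserted in the acceptance suite.
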