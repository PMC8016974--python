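# Methods

This note documents the physical model, the numerical choices and the known
limitations of `selfipsf`.  Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## 1. Physical model

### Analytic phase model (`selfipsf.phase`)

The on-axis interference between the direct and the mirror-reflected emission
of an emitter a distance Δz above the mirror is summarized by three phase
terms: the round-trip propagation phase `φ_z = 4πnΔz/λ`, the reflection phase
delay (the negative argument of the normal-incidence Fresnel coefficient,
quadrant-aware so that a positive-real coefficient gives 0, a negative-real
one π), and the Gouy phase `atan(2Δz/z_R)` of the diverging emission beam.
Even/odd multiples of π classify constructive/destructive interference.

* **Rayleigh range** `z_R = 351.4 nm` by default — back-solved once so that a
  154.9 nm spacing accrues a Gouy shift of 0.23π, the calibration point of
  the model; an alternative estimator `z_R = nλ/(π·NA_eff²)` gives the same
  order of magnitude.  Configurable.
* **Silver optical constants**: a bundled 380–800 nm n,k tabulation in the
  style of the classic thin-film measurements, linearly interpolated; the
  table identifier (`Ag-JC-style-bundled-v1`) is recorded in simulation
  metadata.  At 455 nm the interpolate is 0.05 + 2.47i.
* **Parity convention**: destructive = odd multiples of π, constructive =
  even; with the defaults the model gives Δφ(71.6 nm) ≈ 1.72π (constructive)
  and Δφ(154.9 nm) ≈ 2.93π (destructive), i.e. the expected opposite parity
  of the two canonical spacings, with totals within ~0.2π of the nominal
  1.9π/3.1π — the residual reflects the unpublished constants of the original
  configuration, and no constant is tuned to force exact agreement.

### PSF engine (`selfipsf.engine`)

The simulator follows the simple-model philosophy: three co-localized
orthogonal dipoles above a mirror, radiating at a single wavelength, summed
incoherently.  For each plane-wave direction inside the collection cone the
upward far field is the coherent sum of the direct wave and the reflected
wave (stack Fresnel coefficient × round-trip phase `2knΔz·cosθ`).  An
aplanatic high-NA system (apodization √cosθ, defocus phase `e^{iknd·cosθ}`)
maps the far field to the camera.  The azimuthal integrals are Bessel
functions, so the image collapses to three 1D polar integrals (orders 0, 1, 2)
evaluated by Gauss–Legendre quadrature (180 nodes by default; doubling the
grid changes profiles by <1%, verified in the tests).  The equal-weight
incoherent dipole sum is exactly rotationally symmetric, which makes
simulation of full calibration curves essentially free.

Validation inside the test suite:

* with the mirror off and NA ≤ 0.3 the transverse-dipole image matches the
  scalar Airy pattern to <2%;
* against a perfect mirror the upper-hemisphere radiated power reproduces the
  classical image-dipole emission-rate curves (parallel and perpendicular)
  to <1%;
* the layered-stack reflection coefficients match a brute-force
  multiple-reflection summation to 1e−6.

**Effective collection aperture.**  The weights of the x/y/z dipole fields at
the camera are modified by the effective numerical aperture of the collection
path: real high-NA objectives do not transmit the highest-angle rays with
full efficiency.  The engine truncates the cone at `NA_eff` (default 1.2 for
NA 1.4).  The default is calibrated once against the model's central anchor:
with `NA_eff = 1.2` the first on-axis destructive minimum of the simulated
intensity falls at ≈154 nm spacing, the canonical destructive spacing, and
the 71.6 nm PSF stays Gaussian-like while the 154.9 nm PSF is a deep
doughnut.  With the full cone (`NA_eff = NA`) the high-angle constructive
light fills the dip and no doughnut forms at any spacing — demonstrably the
wrong collection model for the measured system.

**Detection-plane convention.**  The interference dark region is axially
centred near the *mirror surface* (the midplane between the source and its
mirror image), not at the particle.  The sensing pipeline therefore fixes the
detection plane at the mirror surface (`focus_height_nm = 0`), which is also
the only workable convention for stair-structure scenes where particles at
several heights share one frame, and is experimentally locatable by
reflecting a beam off the mirror.  Display-style simulations of individual
PSFs can instead focus on the particle (`focus_height_nm = None`).
Defocus-sensitivity analyses are referenced to the *stationary plane* — the
axial centre of the interference structure, found by scanning the dip
contrast — because that is the operating point a drift-immune measurement
locks to.

**Particle model.**  Spacing is mirror-surface → particle-centre, so a
particle of radius 16.5 nm resting on a spacer of thickness t sits at
`t + 16.5 nm`.  Optional emitter averaging integrates the interference over
emitter heights within the particle sphere (7-node quadrature weighted by the
spherical cross-section); it blurs, and never sharpens, the dip.  Lateral
emitter offsets (≤16.5 nm, far below the PSF width) are neglected.  The
default is point emitters at the centre, matching the co-localized-dipole
simple model; spectral averaging over a 475 ± 12.5 nm bandpass is available
(3 samples, weights 0.25/0.5/0.25) with monochromatic 455 nm as the default.

## 2. Feature extraction (`selfipsf.features`)

The spot centre comes from radial-symmetry fitting (gradient-line
intersection), accurate to ≪0.1 px on noiseless symmetric spots and equally
valid for peaks and doughnuts.  The profile is the mean of 16 line profiles
through the centre (uniform angles over [0, π)), sampled at pitch/4 steps by
*cubic* interpolation — the image is band-limited by the optics, and linear
interpolation of a camera-sampled doughnut systematically underestimates the
dip (with cubic sampling all four features change by <2% when the pixel
pitch is halved, a test-suite invariant).  Background is the median of an
annulus at 3–4× the expected PSF radius and is subtracted with clipping at
zero.

Feature definitions and edge rules:

* FWHM: outermost half-maximum crossings, linear interpolation between
  samples; an error if the crossing leaves the profile support.
* iFWHM: width of the central dip at `I_centre + (I_max − I_centre)/2`,
  crossings nearest r = 0; undefined (NaN + validity flag) when the dip
  contrast is below 0.05 — the threshold that separates "no dip" from
  noise-induced dips at the default photon budgets.
* Area: equivalent width — profile integral divided by its maximum, over the
  support between the outermost half-max crossings extended outward to the
  first effectively-zero samples (relative floor 2×10⁻³ of the maximum, which
  makes the endpoint robust to the sampling step).  Normalizing by the
  maximum makes the feature photon-budget-invariant; the raw integral would
  scale with brightness and could not index a calibration curve.
* Depth: `(I_max − I_centre)/I_max`, clipped to [0, 1].

All four are invariant under intensity scaling and uniform offsets (property
tests), and agree with 20×-oversampled brute-force evaluation to <0.5%.

## 3. Calibration and inversion (`selfipsf.calibration`)

Calibration curves are cubic splines per feature on a 1 nm grid over
[30, 500] nm: interpolating splines for noiseless simulator samples, GCV
smoothing splines when samples are noisy replicates.  Features that exist
only piecewise (iFWHM) are fitted per contiguous region; regions with fewer
than 4 (interpolation) / 5 (smoothing) knots are dropped.  Per-feature noise
scales σ_k come from replicate scatter when available, else from a supplied
noise model, else default to 2% of the curve's dynamic range.

**Protocol matching matters.**  The descriptor estimators carry small biases
(~1σ at 10⁴ photons) that depend on the measurement protocol (photon budget,
background, sampling).  A calibration built from noisy replicates rendered
with the *same* protocol as the measurement cancels these biases; a noiseless
calibration used on noisy data leaves them in and degrades branch
discrimination.  `simulate_feature_samples(..., photons=…, n_rep=…)` builds
protocol-matched calibrations; `measure_noise_scales` measures empirical σ_k.

**Inversion.**  The estimate minimizes the mean standardized squared residual
over the features valid in both the measurement and the calibration (at least
two required), on the grid with parabolic refinement.  σ_z comes from the
local sensitivity, `σ_z = [Σ_k (f_k′/σ_k)²]^{−1/2}` — the same expression the
`resolution_curve` reports across the working range (infinity where all
slopes vanish).  The curves are periodic-ish in spacing, so all local minima
within 2× the global cost (plus an absolute slack of 4 in mean-χ² units) are
reported as candidates; leave-one-feature-out re-estimation flags estimates
whose support rests on a single feature.  At isolated spacings where the
no-dip regimes leave only three informative features, two branches can be
exactly degenerate; the contract is that the truth is always among the
candidates and a diagnostic flag is raised, never a silent wrong answer.
Without a dip (iFWHM undefined) the estimator simply drops that feature; a
mismatch in dip *presence* between measurement and curve is not penalized.

**Defocus sensitivity** simulates PSFs across a detection-plane sweep,
extracts features, and reports the maximum relative change per feature,
referenced by default to the stationary plane.  With the default model the
result at the 154.9 nm doughnut over ±100 nm is ≈12%, dominated by the dip
Depth (FWHM ≈2%, iFWHM ≈2%, Area ≈7%).  This is larger than the <5% the
measured system shows; see §6.

## 4. Tracking and diffusion (`selfipsf.tracking`)

Detection: difference-of-Gaussians band-pass tuned to the PSF radius (so both
doughnut lobes merge into one blob), robust-noise thresholding (k = 5 MADs),
sub-pixel refinement by radial-symmetry centring.  Linking: greedy
nearest-neighbour in ascending displacement order with gap bridging — the
appropriate tool for the sparse single-particle scenes of mirror-sensing
experiments; no global assignment solver.

Axial assignment inverts the calibration per frame and then selects among the
per-frame candidates by dynamic programming with a Gaussian motion penalty
`((z_t − z_{t−1})/s)²`, s = 100 nm by default (about 1.7× the per-axis rms
step of the reference diffusion conditions) — temporal continuity chooses the
interference branch globally rather than greedily, which prevents single-frame
cost flukes from cascading.  Frames where the selected branch is not the
per-frame global minimum are flagged.

MSD is the time-averaged mean over all point pairs per lag (verified exactly
against a double-loop oracle), with lags up to ¼ of the trajectory length.
The diffusion fit is log-log linear least squares of `MSD = 2·dim·D·τ^α`
over the first ¼ of the lags (at least 4).  The 95% interval on D comes from
a parametric bootstrap — Brownian trajectories regenerated at the fitted D
and refitted with the identical protocol — because neighbouring
time-averaged MSD points are strongly correlated and residual-based
intervals are far too narrow (bootstrap coverage ≈95% in the tests, residual
intervals ≈35%).  Viscosity uses Stokes–Einstein `η = k_BT/(6πD·r_h)`; the
hydrodynamic radius and the temperature dominate the result, are not
inferable from the tracking data, and are therefore mandatory, echoed inputs.

## 5. Synthetic data (`selfipsf.synth`, `selfipsf.fixtures`)

The generator emulates widefield camera frames of single nanoparticles:
expected photon image from the engine's radial profile (exact sub-pixel
placement), Poisson shot noise, linear camera with gain 1 and offset 100
counts, 16-bit clipping (photon budgets must respect the full well; the
default 10⁴ photons/frame does).  Default pixel pitch 65 nm at the sample
(a 100× magnification on a 6.5 µm camera), 64–96 px fields.  Brownian paths
have independent Gaussian increments of per-axis variance 2DΔt, with optional
reflecting z-boundaries to emulate a particle confined near the substrate —
free 3D diffusion at the reference D = 0.0174 µm²/s (130 frames at 10 Hz, the
glycerol-solution tracking conditions) would leave the 30–500 nm working
range within a second.  End-to-end tests therefore confine z to a
high-resolution band and fit the *lateral* (unconfined) MSD for D; the
axial coordinate is judged by its per-frame error against ground truth.

What the generator does **not** emulate: optical aberrations, excitation
non-uniformity and its axial elongation of the measured 3D PSF, camera read
noise and EMCCD excess noise, particle brightness fluctuations, and multiple
interacting particles.  Passing tests therefore validate the method's logic
and its noise behaviour under idealized imaging, not its performance on any
particular instrument.

## 6. Known limitations

* **Dip-contrast defocus sensitivity.**  In this emission-only model the
  doughnut's Depth varies by ~12% over a ±100 nm detection-plane sweep
  (other features ≤7%), whereas the measured system reports <5% for all
  features.  The measured 3D PSF is axially elongated by the non-parallel
  widefield excitation (the original authors' own attribution) and by system
  aberrations — physics deliberately outside this model.  Consequently large
  focus drifts toward the particle can alias the feature quadruple onto a
  neighbouring interference branch; the tracking layer flags such frames and
  the median axial readout remains accurate (test-suite property).
* **Single-trajectory D precision.**  At the reference conditions (130
  frames, free-α power-law fit) the intrinsic scatter of D̂ is ~15%, so a
  ±25% band captures ≈86% of seeds, not ≥90%; the bootstrap interval is the
  honest precision statement.
* **Branch degeneracy at isolated spacings** (three-feature regimes): handled
  by candidates + flags + temporal continuity, not eliminated.
* The layered-stack mode refines the reflection coefficients but still
  propagates the round-trip phase in the ambient index; for the
  oil/silica (1.5/1.46) contrast the difference is negligible.
* Silver constants are a bundled approximation; for quantitative work at
  other wavelengths supply a measured table via `OpticalMedium`.
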