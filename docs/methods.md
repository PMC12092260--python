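# Methods

This note records the models, numerical choices and study conditions
behind `fpscan`, and what the synthetic experiments do and do not show
about real scanner data.

## Sensor model

The interferometer transfer function (ITF) — reflected optical power
versus interrogation wavelength — is modelled as an Airy dip on a unit
background scaled by the fringe visibility V:

    R(λ) = 1 − V / (1 + F_c sin²(π (λ − λ_res)/FSR)),   F_c = (2F/π)²

with the phase linearized in wavelength so the model is exactly
FSR-periodic (an excellent approximation over the few-FSR operating
neighbourhood). The fringe FWHM is FSR/F to first order in 1/F; for the
default sensor (F = 76.6, FSR = 26.6 nm) it is 0.347 nm. The bias
wavelength is the point of peak |dR/dλ| on the positive-slope flank,
found by grid search plus bounded refinement. Acoustic sensitivity is
proportional to that slope; with the interrogation laser centred in a
0.08 nm bias-spread band, the worst-case ±0.04 nm detuning keeps the
Airy-model slope at ≈ 90 % of its peak, which motivates the
spacer-uniformity requirement dl = l·dλ_b/λ_b (≈ 1.3 nm for a 25 µm
spacer at 1550 nm).

The acoustic frequency response uses a sinc magnitude — the thickness
average of the pressure across the polymer film — calibrated per sensor
so its −3 dB point equals the stated value exactly (35/31.5/27.6 MHz
for the 24.6/26.6/29.6 µm spacers). This absorbs unmodelled mirror and
overcoat effects into one measured number. The spatial NEP distribution
is log-normal, parameterized in closed form by its density mode and
FWHM (σ = asinh(FWHM/2·mode)/√(2 ln 2)); the measured distributions are
skewed, unimodal and strictly positive, which this family reproduces
with two parameters.

## Acquisition

The rigid beam array (default 4 × 16, 324 µm pitch) tiles the detection
grid when the pitch is an integer multiple of the grid step; each beam
rasters its sub-cell in row-major order, and the randomized mode
permutes whole pulse positions. Consequences used elsewhere: any prefix
of a random acquisition is a spatially quasi-uniform random subset of
*pulse tiles* (not of individual nodes), which is exactly what the
subsampled reconstruction faces in practice, and any window of the
stream is a valid frame for sliding-window dynamic imaging. The
efficiency factor η in the A-line rate η·N·PRF defaults to 1 and is
never applied silently. Sliding-window frame counting uses
n_total/advance with end-truncated windows.

## Forward operator and its adjoint

An initial pressure p0 released at t = 0 in a homogeneous medium evolves
as p(r, t) = IFFT₃[P0(k) cos(c|k|t)], and the planar sensor samples
z = 0. The operator is realized spectrally:

1. zero-pad the volume axially to 2·nz (the cosine propagator creates a
   mirror copy below the sensor plane; padding delays its arrival past
   the cropped window);
2. 3D FFT and fold ±kz (cosine propagation is even in kz);
3. scatter each axial mode onto the regular temporal-frequency grid at
   ω = c|k| using phase-rotated Keys-cubic weights: the rotation is
   referenced to the centre of the time window so the four-tap surrogate
   reproduces cos(ωt) across the cropped window instead of beating
   against it; the time axis is padded 4×, keeping the residual phase
   mismatch at the window edges below π/8. Modes above the temporal
   Nyquist are dropped, not aliased;
4. inverse FFTs over ω → t and (kx, ky) → (x, y); crop; real part.

Every step is a sparse or unitary-scaled linear map, so the adjoint is
the reversed chain of conjugate transposes and the dot-product identity
holds at machine precision (~1e-15) — the property the variational
reconstruction relies on. Validity condition enforced at call time: the
recording window must end before the first axial mirror arrival,
nt·dt·c ≤ 2·nz·dz − z_top. Lateral periodic image sources impose an
analogous (unenforced) bound; simulations in this package keep the
window short of the lateral wrap path. Against the closed-form
spherical-source solution the on-axis waveform agrees to ~3 % L2 after
band-limiting at adequate resolution.

Units are µm/ns/kPa internally (1500 m/s = 1.5 µm/ns), so quantities
stay O(1) in double precision.

## Spectral reconstruction

The inverse maps the data spectrum from ω back to kz on the dispersion
shell with the angular Jacobian c·kz/ω (cosine of arrival angle), an
overall gain of 4 (a factor 2 for half-space detection, 2 for the
cosine→exponential split; the DFT normalizations cancel — verified as
unit round-trip gain across several grid geometries), explicit Hermitian
symmetrization (real output by construction), and the same
phase-derotated cubic interpolation as the forward. Evanescent content
(|k_par| > ω/c) carries no axial wavenumber and is discarded: planar
detection only determines spectral content inside the acceptance cone,
so round-trip fidelity (NCC ≥ 0.98) holds for cone-interior content and
degrades for laterally-propagating components of arbitrary scenes. The
native depth sampling is dz = c·dt; the temporal axis is padded to a
power of two ≥ 4·nt. Dual-sound-speed composites blend two full
reconstructions across the region seam with a 3-voxel cosine ramp.

The PSF probe measures line-spread functions (a line absorber per
depth), matching how planar-scanner resolution is characterized. Two
subtleties found during development and encoded in the probe: the
recording must continue until the farthest detector has received the
deepest target, otherwise truncated high-angle arrivals shrink the
effective aperture; and with point-like detectors a *point* target's
axial width genuinely sharpens at shallow depth (wide-angle solid-angle
coverage fills in low-kz content), an effect the line target suppresses
— with line targets the axial FWHM is depth-invariant to < 10 % while
the lateral FWHM grows monotonically with depth as the angular aperture
narrows.

## Variational (compressed-sensing) reconstruction

Objective: ½‖M A x − y‖² + λ_eff·TV(x) subject to x ≥ 0, with M the
measured-A-line projection (unmeasured lines are excluded, not
zero-filled), isotropic forward-difference TV, and
λ_eff = λ × retained fraction (regularization scaled down with the
shrinking data term, preserving the balance). Solver: monotone FISTA —
step 1/L with L from a 20-iteration seeded power method, TV+
non-negativity prox by 10 inner dual fast-gradient-projection steps, a
best-iterate safeguard that keeps the recorded objective non-increasing,
and an error if it rises for three consecutive iterations. Two
implementation-level normalizations (the package's own choices):

- the data term is scaled by 1/fraction, so the fixed 50-iteration
  budget reaches comparable convergence at every subsampling level (the
  masked operator's Lipschitz constant does not shrink with the
  fraction, so without this the subsampled problems are far less
  converged after equal iterations);
- λ is dimensionless: it is multiplied internally by the sup-norm of
  the fraction-compensated backprojected data. λ's absolute scale does
  not transfer between implementations; 12e-4 is the default for fully
  sampled data.

Initialization is the zero volume, making the monotonicity check
unambiguous. At λ = 0 on cone-interior data the solution matches the
spectral reconstruction (NCC ≥ 0.99 at 50 iterations); pushed further it
drifts toward the pseudo-inverse, which amplifies near-cone-edge
components the spectral inverse suppresses — that comparison is
therefore defined on well-posed content.

## Standard subsampling study

Scene: 96 × 96 × 192 voxels (108 µm lateral, dz = 25 µm at
c = 1500 m/s, dt = 16.67 ns); a branching tree (4 roots, 300 µm root
radius, Murray-ratio radius decay, 4 generations, 30 kPa blood initial
pressure — a realistic palm-like plexus) confined to the inner 72 × 72
lateral box at 1.2–4.0 mm depth; per-channel noise from the log-normal
NEP map (mode 0.2, FWHM 0.25 kPa) referenced to the 20 MHz measurement
band; 50 kHz–20 MHz zero-phase bandpass; random non-overlapping 4×16
multibeam scan; prefix subsampling at 100/50/25/12.5 %;
50-iteration reconstructions. CNR follows the plane-mean procedure:
background = mean of per-plane means, contrast = peak
background-subtracted plane mean *within the common anatomical ROI*
(the inner box, 1.0–4.4 mm; the final reconstruction plane is excluded
as a boundary artifact), noise = RMS in a feature-free lateral-corner
volume at the same depths. Under these conditions the CNR falls
strictly with the retained fraction at ≈ 3 dB per halving of the data
on the canonical acquisition, driven by missing-tile aliasing of the
strong vascular signals. The phantom scene and canonical acquisition
are fixed study inputs; when the noise realization and scan order are
reseeded, the per-halving drops spread by a few dB, and at 12.5 %
retention — where only 18 beam-array tiles remain — the CNR itself
varies by several dB with which tiles are kept; single-acquisition
results at deep subsampling should be read with that variance in mind.

What this does and does not show: the synthetic scenes share the real
data's geometry, sampling, noise statistics and dynamic structure, but
not optical fluence decay, acoustic attenuation or heterogeneity
(attenuation correction is tested as a pure image operator), sensor
directivity, tissue speckle or motion. Absolute CNR/resolution numbers
are therefore not comparable to hardware measurements; orderings,
drops, invariances and parameter-recovery accuracies are the meaningful
outputs.

## 2D mode and diameter tracking

Elevational receive focusing delays each of the 4 rows by
τ(z, y_e) = (√(z² + y_e²) − z)/c with the receive depth z = c·t tied to
the sample time (linear sub-sample interpolation, uniform apodization),
then sums; in-plane sources gain up to 4× coherently while out-of-plane
arrivals de-cohere. Simulation samples the 4 physical row positions
(±162, ±486 µm) from a finer elevation grid so the elevation structure
of the scene is represented. In-plane reconstruction reuses the 3D
spectral mapping with a singleton lateral axis. The tracked minor axis
is the separation of the envelope's steepest edges (the vessel walls)
within the ROI depth range; an envelope FWHM is nonlinear for a
resolved lumen and was found to misestimate modulation depth by ~2×.
The modulation depth is recovered by a lock-in estimate — a
least-squares sinusoid fit at the stimulus frequency — which is robust
to single-frame tracking outliers that would corrupt a max–min range.
With 30 frames at 33.3 fps the 70 beats/minute rhythm is identified at
the ~1.1 Hz spectral resolution of the window and the 5 % radius
modulation recovered within ±1 percentage point.

## Quantitation

CNR as above. V_s: intensity K-means (K = 2, fixed seeding; scale
equivariant) → highest-mean cluster → 3D medial-axis thinning → skeleton
voxels as a percentage of the volume. The 3D thinning implementation
returns empty skeletons for exactly even-width rectangular bars (a
degenerate symmetric case); realistic anti-aliased segmentations are
unaffected. V_I: voxels above background + 2×noise-RMS (rule
configurable) within the ROI. Tortuosity: arc length over endpoint
chord of a centreline polyline, rigid-motion invariant by construction.

## Dynamic sequences

Occlusion–reperfusion scenes scale vascular ROIs to 20 % of baseline
during occlusion and ramp them back with a smoothstep of configurable
duration (default 2.5 s, matching reperfusion over a few seconds) from
per-ROI onset times ordered artery-first; the epidermis label stays
constant (melanin, non-vascular contrast). Onset ordering is recovered
from 50 %-of-baseline crossings of the ROI mean-intensity time courses.

## Known limitations

- Homogeneous, lossless, linear acoustics; no directivity, dispersion
  or shear modes.
- Spectral periodicity: simulations must respect the axial-mirror
  window bound (enforced) and keep lateral wrap paths outside the
  window (caller's responsibility).
- λ's absolute scale is implementation-specific by construction.
- The CNR of sparse scenes is dominated by the plane-mean dilution of
  the contrast; comparisons are meaningful within a fixed scene only.
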