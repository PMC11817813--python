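# Methods

This note records the model as implemented, the conventions and numerical
choices that are not visible from the API, and the package's own design
decisions where the physics or the literature leaves room.

## Model and assumptions

The simulator evaluates the Debye–Wolf (Richards–Wolf) representation of a
tightly focused field: every direction (θ, φ) inside the aperture cone
contributes one homogeneous plane wave, and the focal field is their
weighted superposition.  Validity assumptions are the standard ones — a
spherical wavefront of focal radius *f* at the exit pupil, observation
points many wavelengths from the pupil, and `f·sinα ≫ λ`.  Within those
assumptions the treatment is fully vectorial: no paraxial or scalar
approximation, and the axial field component Ez is retained (it is what
fills the center of a badly polarized donut).

The stratified geometry is exactly three layers — immersion (n₁),
coverslip (n₂, thickness t), sample (n₃) — which covers the practical
microscope stack; absorbing or scattering media and additional layers are
out of scope.  Each plane wave acquires:

* Snell-chained angles `n₁ sinθ₁ = n₂ sinθ₂ = n₃ sinθ₃`, continued into the
  complex plane past critical angles (principal-branch `cosθ = √(1−sin²θ)`
  with Im ≥ 0, giving decaying evanescent components for z > 0 rather than
  a hard aperture clip);
* the coverslip operator `T = t⁽¹⁾t⁽²⁾e^{iβ} / (1 + r⁽¹⁾r⁽²⁾e^{2iβ})`,
  `β = k₂ t cosθ₂`, per polarization — the Airy summation of multiple
  internal reflections, verified in the tests against an independent 2×2
  transfer-matrix composition.  For matched indices it reduces to the pure
  propagation phase `e^{iβ}`;
* the polarization conversion `Λ = R_φ⁻¹ P⁽³⁾⁻¹ I⁽²⁾ P⁽¹⁾ L_θ R_φ`,
  implemented as the literal five-factor matrix product (the tests compose
  it factor by factor).  With the conventions used here `P⁽¹⁾L_θ` is the
  identity, so Λ reduces to the classic meridional-frame construction; it
  is unitary whenever |Tp| = |Ts| = 1;
* the stratification phase `Φ = k₀[n₃ d cosθ₃ − n₁(t+d)cosθ₁]`.  Note the
  bookkeeping: the coverslip's own propagation phase `k₂ t cosθ₂` lives in
  the coverslip operator, so the *total* stack phase is Török's aberration
  function and vanishes for matched indices — the focus then stays at the
  geometrical focus.  Φ alone is therefore `−k₀ n t cosθ` in the matched
  case, which is pure defocus-like bookkeeping, not a physical aberration.

The correction collar is modeled as perfect cancellation at a chosen depth:
the same Φ expression evaluated at `collar_depth` is subtracted, so the
residual vanishes identically when the collar matches the focusing depth.

## Pupil conventions

* Radial pupil coordinate by the sine condition, normalized to the pupil
  radius: `ρ = sinθ / sinα`.  Waist, beam/mask offsets and the ring radius
  are all fractions of the pupil radius, so no physical pupil calibration
  is needed (only ratios enter).
* Apodization defaults to `√cosθ`, the aplanatic energy-conservation
  factor; a `cos` option exists because part of the literature (and some
  rendered equations) print `cosθ`.
* Zernike modes use the `(n, m)` double index with `Rₙᵐ(1) = 1`
  normalization and `Gₘ = cos(mφ)` for m ≥ 0, `sin(|m|φ)` for m < 0.
  Coefficients are radians of phase at the pupil edge.
* Elliptical polarization is `(cos ε, i sin ε, 0)` rotated counter-clockwise
  by Ψ about the optical axis; ε = ±45° are the circular states (+ left,
  − right).  The sign convention of Ψ is a choice (not fixed by the GUI
  tools this mirrors) and is documented here once.
* The vortex/ring masks are evaluated about a possibly offset center in
  Cartesian pupil coordinates, matching how a physical mask decenters.
* Custom masks are square phase matrices (radians) over the pupil square
  [−1, 1]², bilinearly interpolated; text matrix or float TIFF.

## Tilted coverslip

Tilting the coverslip by γ is treated as rotating the objective by −γ
(Berning's rotated-objective method): the polar integration range expands
to α + |γ|, and every objective-frame quantity — Gaussian profile,
apodization, aberration phase, mask phase, input polarization, and the
collar/stratification phase — is evaluated at the back-rotated direction
(θ′, φ′), obtained by rotating the unit ray vector about the y axis
(the tilt plane is fixed to x–z; other tilt azimuths are a rotation of the
output volume).  Rays whose back-rotated direction falls outside the pupil
cap carry zero amplitude.  The sample-side quantities (Snell chain,
coverslip transmission, propagation phases, window mask) keep the
unrotated angles.  At γ = 0 the transform is an exact identity, which the
tests assert at float precision.

## Discretization and numerics

* Angular sampling: Nθ × Nφ equally spaced samples, Δθ = (α+|γ|)/Nθ,
  Δφ = 2π/Nφ, defaults 31 × 31.  θ uses **midpoint** samples by default:
  the integrand ends abruptly at the aperture edge, so left-endpoint
  sampling (`theta_sampling: left`, θ₁ = 0, also available) effectively
  shrinks the aperture by half a step and converges only first-order —
  measurably ~1% change in the normalized PSF when doubling 31→62 steps,
  versus ~0.02% for midpoints.  φ is periodic, where the rectangle rule is
  spectrally accurate; with the donut's charge q not a multiple of Nφ, the
  on-axis cancellation is exact even at coarse Nφ.
* The voxel grid is centered on the geometrical focus, default 31³ voxels
  over ±1 µm laterally and ±2 µm axially; coordinates are
  `(i − (n−1)/2)·Δ` per axis.
* Summation is double precision throughout.  The sum over the angular
  index runs in a fixed order (a non-BLAS einsum reduction), so results
  are bitwise independent of how the voxel set is partitioned into chunks
  — asserted in the tests by shrinking the chunk size.
* The z-propagation uses the sample-medium term `k₀ n₃ z cosθ₃` literally;
  z is not re-centered on the aberration-shifted focus.  The optional
  `refocus: axial_shift` convenience locates the on-axis intensity peak on
  a coarse 1-D scan (4× the axial extent, 4·nz+1 points) and shifts the
  evaluation window there.
* The prefactor `−i k₀ n₁ f / 2π` is applied with f = 1 length unit: the
  absolute field scale is arbitrary and only relative or max-normalized
  intensities are meaningful.
* FWHM metrics interpolate the half-max crossings linearly along principal
  axes through the global maximum; a profile that never crosses half-max
  inside the grid reports the width as missing rather than failing.
* Degenerate inputs: normalizing an identically zero field is an error;
  a closed window (θc = 0) produces exactly that; nz/nx/ny = 1 grids are
  supported (planes, lines, single points).

## STED combination

Donut and bottle depletion paths are combined incoherently,
`I = p·I_donut + (1−p)·I_bottle`, with the weight `p` multiplying the
donut term.  The opposite convention also circulates; `p_convention:
p_bottle` flips it.  The effective fluorescence PSF is
`I_eff = I_e · exp(−ln2 · S · I_d / max I_d)`.  The depletion map is
normalized to unit peak internally, which makes the saturation factor S a
scale-free user-facing number: S = 1 halves the fluorescence at the
depletion peak, and the surviving spot narrows approximately as
1/√(1+S).  No further photophysics (vibrational relaxation, time gating,
emission/detection optics, pinholes) is modeled — these are excitation
PSFs only.

## Synthetic samples and what the tests show

The sample generator emulates a field of point-like beads: unit-intensity
single voxels (optionally dilated to spherical beads) at seeded
uniform-random positions drawn without replacement, plus deterministic
line-grid / concentric-circle test patterns.  It reproduces exactly the
requested number of bright voxels and is bit-reproducible from its seed.
It does **not** emulate photon noise, background, refractive-index
structure inside the sample, or finite fluorophore size — so convolution
demos show geometric image formation only, and passing tests say nothing
about noise robustness on real data.

Test problem sizes were chosen as the smallest grids that exercise each
property: the brute-force oracle runs on 9³ voxels with 15×15 angular
samples; morphology and geometry checks use the 31³ defaults; the scalar
Airy comparison uses a 63² focal plane.

## Known limitations

* Three layers, planar interfaces, lossless dielectrics only.
* One tilt axis (x–z plane); combine with output-volume rotation for
  arbitrary tilt azimuth.
* The window aperture is a hard binary mask with a sharp edge; soft or
  apodized windows are not modeled, and the window half-angle θc is a
  direct input (it is not derived from window geometry).
* Fractional vortex charges are rejected: the charge is an integer, and a
  ring mask needs an odd charge to form a bottle.
* Absolute intensities are arbitrary; quantitative power throughput is out
  of scope.
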