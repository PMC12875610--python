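# Methods

This note records the models implemented in `lsfmkit`, their assumptions,
the defaults that matter, and the numerical choices made where the design
was genuinely open. Axis convention throughout: Y is the illumination
propagation direction, Z the detection axis (the sheet-thin direction), X
the in-sheet transverse direction; arrays are ordered (z, y, x).

## Illumination model (`lsfmkit.optics`)

Each transverse axis of the illumination beam is an independent Gaussian
beam propagated by ABCD transfer through ideal elements. The bundled
nominal train is: resonant galvo and fold mirror (plane mirrors in the
unfolded path), an f = 30 mm / f = 80 mm expanding telescope, a rectangular
slit, an f = 75 mm cylindrical lens with power on the thin axis, an
f = 250 mm relay whose back focal plane coincides with the objective pupil,
and a 20× NA 0.6 illumination objective modeled as an ideal thin lens with
f = 200 mm / 20 = 10 mm (vendor prescriptions are not public; the
instrument treats objectives as black boxes). Input: a collimated 2 mm,
488 nm beam; immersion water (n = 1.333).

The immersed objective is realized as the thin lens followed by a flat
interface into the medium (`q → n·q`), so a collimated input focuses at
`n·f` beyond the lens with waist `w₀ = λ_vac f / (π w_p)` for pupil fill
`w_p`; equivalently `NA_eff = λ_vac/(π w₀) = w_p/f`, and the axial scale
(Rayleigh range) is `z_R = π w₀² n / λ_vac`. Geometric NA is therefore
fill-radius over focal length, capped at the objective NA with a truncation
flag; clipped Gaussians are *not* given a full Fresnel treatment — the slit
is an idealized hard edge handed to the diffraction simulator.

The sheet simulator is a 1D coherent angular-spectrum computation in the
thin axis (the wide axis is separable): the pupil amplitude over transverse
frequency ν (Gaussian fill from the ABCD trace, hard-cut at the slit- and
objective-limited NA) is inverse-transformed for the focal field, and
defocus planes apply the propagator `exp(2πi y (√((n/λ)² − ν²) − n/λ))`.
The hard pupil edge is anti-aliased by fractional frequency-bin coverage so
that metrics vary continuously with slit width; without this, the FWHM is a
staircase in width and calibration cannot converge. Grid preconditions:
z spacing ≤ FWHM/8, extent ≥ 4×FWHM (defaults 20 nm over ±2 µm).

**Slit calibration.** The slit width is the one free parameter of the
design (it is set on the bench). `calibrate_aperture` solves
FWHM(width) = target by bisection (FWHM is monotone decreasing in width).
The default target is the 0.385 µm design thickness; the simulated train
bottoms out at 0.3847 µm with the slit fully open (objective-NA-limited
truncated-Gaussian pupil), so targets below that are reported as
unreachable rather than silently clipped. The calibrated effective NA —
defined by inverting `FWHM = √(2 ln 2) λ/(π NA)` on the simulated width —
is ≈ 0.475 and is written into profile metadata.

**Propagation length** is the contiguous region where the sheet stays
within √2 of its minimum thickness; for an analytic Gaussian this equals
the confocal parameter 2 z_R (≈ 1.84 µm at NA 0.475), and a boundary flag
marks profiles whose sub-√2 region reaches the grid edge.

## Tolerance Monte Carlo (`lsfmkit.tolerance`)

Each trial draws, per element: an axial offset and a lateral offset,
uniform over ±tol (a machining-tolerance band is a hard interval, hence
uniform rather than normal), and a tilt from two independent dowel-pin
offsets via `θ = atan(|δa − δb|·25.4/spacing)`. Pin spacing defaults to
10 mm — the value used by the named mount line, under which the worst case
atan(0.254/10) = 1.455° reproduces the published ~1.45°. Mirror tilts add
2θ to the beam angle (reflection doubling); refractive-element tilts map to
a decentration through a 25 mm mount lever arm, and decentration δ of a
lens deviates the beam by δ/f. Perturbation draws are unit draws scaled by
the tolerance, keyed by (seed, trial index), so different tolerance levels
share common random numbers and worst-case deviations compare cleanly.

Per-trial metrics: sheet thickness as the intensity FWHM at the perturbed
beam's own waist (thickness is a beam property; measuring it at a fixed
plane would conflate it with defocus), the lateral displacement of the
sheet at the nominal focal plane, and the axial focal shift. For speed, the
slit-truncated thin axis is replaced by the Gaussian of equal effective NA
(input beam scaled so the untruncated ABCD fill focuses at NA 0.48); the MC
measures *deviations* from nominal, for which this surrogate is accurate.
Two deterministic corner trials (all degrees of freedom at +tol and at
−tol, pins anti-symmetric) are appended to the random draws; the full 2^dof
corner set is not enumerated. A per-element sensitivity table (metric
spread when only that element is perturbed) is reported for inspection —
reflective elements dominate displacement sensitivity via the 2θ rule — but
no ranking is asserted.

## Detection calculators (`lsfmkit.detection`)

Closed forms only. The 6.5 µm pixel pitch is the vendor specification of
the assumed sCMOS camera, not a measured quantity, and is config-
overridable, as are the resolution constants (0.51 lateral,
0.88/(n − √(n² − NA²)) axial) since published targets are rounded. Dead
time is an input, not a prediction: 10 ms exposure with the ~7.25 ms
average dead time gives 58.0 Hz, while the quoted best case 62.5 Hz
corresponds to 6 ms; the calculator reports whichever it is given. The
4 kHz resonant galvo is carried as metadata for a non-rate-limiting check
(galvo period ≪ exposure).

## PSF models (`lsfmkit.psf`)

Two generators, both unit-sum on odd-sized grids (the peak sits on a voxel
center): a separable Gaussian with prescribed per-axis intensity FWHM (the
analytic kernel used by the synthetic pipeline), and a scalar-diffraction
PSF from the radial Debye integral
`E(r,z) = ∫₀^α √cosθ · J₀(k n r sinθ) · e^{i k n z cosθ} sinθ dθ`
(Gauss–Legendre quadrature, radial table interpolated onto the grid).
Scalar rather than vectorial diffraction is the default: at NA 1.1 in water
vectorial corrections exist, but the targeted numbers carry ~5 nm printed
precision at best; the model kind is recorded in metadata. Emission
defaults per excitation line: 510 nm (488), 580 nm (561), 670 nm (638),
460 nm (405) — conventional fluorophore peaks, overridable. A sheet's
axial envelope multiplies the detection PSF along z (with linear
resampling) to form the system PSF; for Gaussian × Gaussian this reproduces
the quadrature rule `1/F² = 1/F_det² + 1/F_sheet²`.

Sampling preconditions demand ≥ 2 voxels per FWHM and ≥ 4 FWHM of grid
extent — the instrument's own acquisition sampling (328 nm FWHM on 130 nm
pixels ≈ 2.5 samples per FWHM) must satisfy them.

## Synthetic imaging (`lsfmkit.imaging`)

The generator emulates 100 nm-bead test specimens: beads are point sources
(diameter ≪ PSF), placed uniformly with rejection sampling for a minimum
separation (default 2 µm ≈ 4× the axial FWHM, mirroring the practice of
measuring isolated beads), each carrying a photon budget (default 10 000,
giving a shot-noise-limited peak SNR ≈ 18 at the default PSF; ~3 000
corresponds to SNR 10). The band-limited scene is built on the orthogonal
lab grid with voxel (s·sinθ, p, p) — Gaussian PSFs are evaluated
analytically at each bead's exact sub-voxel position, so no interpolation
broadening enters at this stage — then sheared slice-by-slice into the
camera frame (`+k·s·cosθ/p` px on slice k) and passed through the camera
model: Poisson shot noise, Gaussian read noise, offset 100 counts, clipped
16-bit. All randomness flows through explicit seeds.

What the generator does *not* emulate: scattering and refractive-index
structure, aberrations (including the slight coma a real detection path can
show), photobleaching, sample motion, sCMOS fixed-pattern noise, and the
finite bead diameter. Passing tests therefore demonstrate the correctness
of the geometry and processing chain under the stated image-formation
model, not robustness to these real-data effects.

The shadowing demo is a ray-attenuation model: absorbers block bands of the
sheet; pivoting the sheet by ±φ about the focus sweeps the shadow by
`tanφ · lever` at the observation line, and incoherent averaging over the
sweep fills shadows in. The headline stripe contrast is the RMS modulation
std(I)/mean(I), which any nonzero angular averaging strictly reduces; the
Michelson ratio (Imax−Imin)/(Imax+Imin) is reported alongside but only
drops once the sweep exceeds an absorber's angular width.

## Processing (`lsfmkit.pipeline`)

**Deskew** shifts slice k back by `k·s·cosθ/p` px (linear interpolation by
default; nearest provided for lossless integer-shear checks), records
output voxel (s·sinθ, p, p) — (0.123, 0.130, 0.130) µm at the nominal
0.25 µm step and 29.5° — fills the shear padding with the camera offset,
and performs no edge erosion (a boundary-band width is written to metadata
instead). With the nominal geometry the per-slice shift is 1.674 px and
sub-pixel interpolation broadens the shear axis by a few percent, visible
in pre-deconvolution x widths.

**OMW deconvolution** implements the published parameterization
(background 100, α = 0.005, OTF cumulative threshold 0.6, Hann bounds
0.8–1, 2 iterations, clamped 16-bit output). Construction: the OTF of the
centered PSF (kernel center aligned to index N//2 before `ifftshift`, so
the transform is zero-phase); the support is the smallest frequency set
holding 60 % of the cumulative |OTF| magnitude, regularized into an
ellipsoid through the support's per-axis extents; the Wiener back-projector
`conj(H)/(|H|² + α)` is apodized by a Hann rolloff between 0.8 and 1.0 of
the ellipsoid radius (the mask-boundary reading of the bounds; configurable)
and normalized to unit DC gain, which preserves flux and makes a delta PSF
an exact identity. Updates are Richardson–Lucy-style multiplicative steps
with this back-projector; where the forward model predicts ≈ 0 the update
ratio is set to 1 (neutral) rather than 0, avoiding 0/0 ringing through the
band-limited back-projector. Exact numerical parity with other OMW
implementations is not claimed; the scheme's qualitative contract — a
20–30 % per-axis FWHM reduction in two iterations on matched-PSF bead data
— is what the tests pin down.

## Bead QC (`lsfmkit.beadqc`)

Detection: local maxima above threshold with greedy non-maximum suppression
(suppressor flagged "overlapping"), edge-adjacent candidates flagged. Per
bead, the peak is refined by 3-point parabolic interpolation, and each axis
line through the peak — averaged over the 3×3 transverse voxel
neighborhood, which leaves the on-axis Gaussian width unchanged while
suppressing shot noise — is fitted with Gaussian + constant offset by
least squares; FWHM = 2√(2 ln 2)·σ. Windows span ~4× the expected FWHM;
clipped windows and non-convergent fits are flagged, and population
statistics (per-axis Gaussian mean/σ of the FWHM histogram, i.e. the ML
normal fit) use unflagged fits only. The sheet cross-section tool averages
image columns and fits Gaussian + offset to the z profile.

## Problem sizes and determinism

The test suite and the acceptance script use 55-bead fields on
80 × 160 × 320 skewed stacks (lab volume ≈ 9.8 × 20.8 × 24.3 µm), 1000
Monte-Carlo trials per tolerance level, and 2¹⁰-point diffraction grids —
sizes chosen so every property is measured with comfortable statistics
while the whole suite runs in well under a minute on one CPU. Every random
quantity is keyed by an explicit integer seed; identical configurations and
seeds produce bit-identical stacks, trial tables and workflow manifests.

## Known limitations

- The aperture model is a hard NA cap plus diffraction of the clipped
  pupil; no Fresnel treatment of near-field slit effects.
- Sheet simulation is separable (thin × wide); full 2D pupil diffraction
  and the wide-axis/propagation-extent trade-off are reported only through
  the ABCD wide-axis beam.
- The tolerance model perturbs all illumination elements with a fixed
  lever-arm tilt-to-decenter mapping; real mounts differ per element.
- Scalar PSFs ignore vectorial high-NA effects (few-percent level at
  NA 1.1/water).
- Deconvolution quality metrics are defined on synthetic matched-PSF data;
  real-data PSF mismatch, noise floors and aberrations will lower them.
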