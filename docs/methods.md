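# Methods

## The instrument being modeled

`clm` simulates and reconstructs data from a correlation light-field
microscope: a conventional bright-field microscope (objective O, focal length
f_O; tube lens T, focal length f_T; spatial detector D_a at the image plane,
magnification M = f_T/f_O) augmented with a beam splitter after the objective
and a relay lens that images the **objective pupil** onto a second detector
D_b (magnification M_L).  The sample is illuminated by chaotic
(pseudo-thermal) light — a laser speckled by a rotating diffuser — and both
detectors are exposed for roughly one coherence time per frame, so each frame
pair is an independent speckle realization.

Because each pupil point corresponds to a viewing direction through the
sample, the covariance of intensity fluctuations over N frames,

    Gamma(rho_a, rho_b) = < dI_a(rho_a) dI_b(rho_b) >,

is a 4D light field: fixing rho_b selects a perspective view from the lens
point rho_O = -rho_b/M_L, and summing perspectives after the defocus-dependent
affine remap

    Sigma_ref(rho_a) = sum_b Gamma((f_O/f) rho_a + (1 - f_O/f)(M/M_L) rho_b, rho_b)

refocuses the plane at distance f from the objective.  In the geometrical
limit Gamma ~ F^2(-(f/f_T) rho_a - (1 - f/f_O) rho_b/M_L) P^2(-rho_b/M_L),
with F the sample intensity profile and P the pupil transmission; the remap
above inverts the F argument exactly, which is the correctness anchor for
both the refocus kernel and the `geometry` oracle module.

Key design formulas (module `clm.metrics`): diffraction limit
Dx0 = 0.61 λ/NA0; refocusing range 3.3 a²/λ at detail size a (quadratic in a,
independent of NA0); axial resolution a/NA0 (technique-independent);
viewpoint multiplicity a/Dx0; refocusable-plane count
(3.3 a²/λ)/(a/NA0) ≈ 2 a/Dx0.

## Default parameters

All defaults sit on `OpticalConfig` and reproduce the reference instrument:
λ = 532 nm, NA0 = 0.23, f_O = 30 mm, f_T = 125 mm (M = 4.17), relay
f_L = 150 mm, M_L = 0.31, source spot 8 mm at 10 mm from the sample,
coherence time 92.3 µs (metadata), camera pitch 6.5 µm.  The pupil radius
defaults to NA0·f_O (paraxial stop consistent with the stated aperture).
NA0 is an independent input: the instrument quotes an *effective* aperture
that is not derivable from the spot geometry, so we do not attempt to derive
it.  Likewise the instrument's measured resolution cell δ = 1.6 µm differs
from 0.61 λ/NA0 = 1.41 µm; the formulas implement the analytic value and the
discrepancy is simply documented.

## Wave-optics frame formation

One frame is formed as follows (module `clm.optics`):

1. **Illumination.**  The diffuser is modeled as delta-correlated: an i.i.d.
   circular complex Gaussian field.  For the default geometry the source
   coherence width at the sample, λz/D = 0.67 µm, is below the band-limit
   grid spacing λ/(2 NA0) = 1.16 µm, so the speckle field is drawn directly
   at the first sample plane — the exact limit of propagating the (much
   larger than the field of view) source.  If a configured source is small
   enough to resolve, the field is drawn at the source plane and propagated
   instead; both paths are exercised by tests.
2. **Multi-slice sample.**  Thick samples are ordered thin transmission
   planes; light traverses them from the farthest plane toward the objective,
   with exact scalar angular-spectrum propagation between planes (amplitude
   multiplication at each slice).  Occlusion between planes is therefore
   physical in the simulator; the geometric oracle deliberately composes
   planes additively instead, and this difference is part of what the
   wave-vs-oracle tests probe.
3. **Pupil and arms.**  The field is propagated to the focal plane and
   Fourier transformed; the objective iris (radius R) is applied on the
   Fourier-plane grid rho_O = λ f_O ν.  The same masked spectrum feeds both
   arms, mirroring the physical beam splitter: arm b records its squared
   modulus (the pupil image, coordinates x_b = -M_L rho_O), arm a records the
   squared modulus of the inverse transform (the ideal 4f image, coordinates
   x_a = -M rho_s).  Placing the stop at the Fourier plane rather than at the
   lens itself neglects field-dependent vignetting of order FOV/pupil ≈ 4 %,
   far below every tolerance used.
4. **Detection.**  Intensities are block-binned to the detector grids.
   Image inversion is applied as a periodic index flip, which is exact on an
   FFT grid.  Optional Poisson/read noise is available and off by default:
   the estimators are derived for ideal intensities.

Angular-spectrum propagation is unitary on these grids (no evanescent
content at sample-side spacings ≥ λ/2).  Periodic wraparound is accepted by
default because the fields of interest are statistically stationary speckle,
for which wraparound is harmless; `propagate(..., strict=True)` enforces the
wraparound-free criterion z_max = N dx²/λ and names the maximum safe distance
when violated, which is the right mode for coherent beam work.

Seeding: frame k of a stack uses `default_rng([master_seed, k])`, so stacks
are reproducible, restartable and parallelizable.

## Estimators

`estimate_gamma` computes the empirical covariance with 1/N normalization in
a single pass over frames, via chunked matrix products, so memory stays
O(tensor) rather than O(N·tensor).  `estimate_gamma_differential` subtracts
the component of each arm-b pixel's fluctuation explained by the **total**
arm-a intensity (the differential ghost-imaging correction), with the
per-pixel coefficient K(rho_b) = <dI_b dI_tot>/<dI_tot²> that minimizes the
estimator variance.  Its per-cell benefit scales as corr(dI_b, dI_tot)²,
i.e. inversely with the number of transmitted spatial modes: large for
point-like emitters (every arm-b pixel then acts as a strongly coupled
bucket detector), percent-level for extended samples.  The variance-reduction
test therefore uses a point-like transmitter, where the effect is measurable
above the sampling noise of twenty sub-stack variance estimates.  Both
estimators are verified exactly against definitional brute-force loops.

## Refocusing, viewpoints, depth

`refocus` implements the shift-and-sum remap with bilinear interpolation
along the arm-a axis (the remap is a pure shift/scale; bilinear keeps the
f = f_O case exact on grid-aligned points, where the output equals the summed
correlation image to machine precision).  Samples leaving the detector are
dropped and the sum is normalized per pixel by the count of contributing
viewpoints; this overlap correction is our edge-effect treatment and is
validated by the flat-field invariant (coefficient of variation ≤ 2 % for a
uniform object).  Refocused images are stored over the detector coordinate
rho_a; `RefocusedImage.upright()` returns the re-inverted object-side view.

`viewpoint` averages Gamma over a small arm-b patch (default 10×10 cells)
and records the lens point -rho_b/M_L.  Parallax sign convention (verified
against the geometric model): in detector coordinates, a detail between the
lens and the focal plane shifts in the same direction as the lens point, a
detail beyond the focal plane shifts oppositely, and a focused detail is
pinned.

`depth_map` assigns each window the z maximizing a local normalized-variance
focus metric, computed after a small Gaussian pre-smoothing (default 2 px).
The smoothing is essential with estimated (noisy) tensors: the pixel-scale
statistical noise of the correlation estimate is sharpest at the natural
focal plane and would otherwise hijack the variance metric.  Windows whose
local energy falls below a threshold (default 10 % of the mean) are NaN.
The metric choice is ours; nothing in the underlying theory prescribes one.

## Synthetic samples

`phantoms` generates the reference test objects: triple-slit masks (opaque
backing, three open slits of width d/2 at center-to-center distance d;
default field of view 0.54 mm), the two-plane 3D target (d = 49.6 µm at
∓1250 µm, each slide's opaque backing covering only its own half of the
field — separate physical slides are clear outside their pattern region, so
the far plane is spatially filtered by the near one but not extinguished),
and seeded random granule suspensions (opaque disks, default radii 10–40 µm
in a 1 mm³ volume, discretized to the nearest of n transmission slices).
Granules are pure amplitude objects: the intensity-correlation formalism
only sees intensity transmission, so birefringence contrast is out of scope.

What the generator does *not* emulate: partial temporal coherence within a
frame, detector saturation and readout artifacts, refractive-index variation
inside the volume, and scattering between slices other than occlusion.
Passing tests therefore demonstrate the estimator/reconstruction chain under
ideal chaotic illumination, not robustness to those real-world effects.

## Problem sizes and numerical choices

Simulations default to a 512² grid at the band-limit spacing λ/(2 NA0)
(field of view ≈ 0.59 mm), binned to 128² spatial pixels and 32² viewpoint
cells; tests and the acceptance script use 64²–512² grids and 1.5k–8k frames,
chosen so the full suite runs on a single CPU in a few minutes while keeping
every quantitative check at its stated tolerance.  Correlation tensors are
float64; fields are complex64 (speckle statistics are insensitive at this
precision, verified by the exact-oracle estimator tests).  Transfer functions
and pupil masks are cached per geometry.  Degenerate inputs (zero-variance
stacks, empty overlap, non-monotone coordinates, sub-resolution detail sizes)
raise or warn explicitly rather than returning silent nonsense.

## Known limitations

* Scalar, paraxial-consistent model: no polarization, no vectorial
  diffraction, no turbulence.
* The wave simulator and the geometric formula agree only to first order in
  z/f_O (the simulator maps viewpoints with f_O where the geometric formula
  uses f); at the largest defocus used (1.25 mm) the residual refocusing
  blur is ≈ 12 µm at the object, well below the 49.6 µm details refocused
  there, and it is invisible at the tolerances tested.
* The differential estimator can subtract genuine signal when the sample is
  so compact that the total intensity is dominated by it; it is an option,
  not the default.
* `refocusable_planes_in_volume` uses an explicit near-focus clamping
  convention (detail size floored at Dx0); absolute plane counts depend on
  that convention and should be read as indicative.
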