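# Methods

## Model

A birefringent fiber bundle is described per pixel by a *birefringence
vector* Δ**n** = Δn·**u**, where Δn ≥ 0 is the true (orientation-independent)
birefringence and **u** = [cosΘcosα, sinΘcosα, sinα]ᵀ the unit optic axis:
Θ is the in-plane orientation (azimuth in the imaging plane), α the
through-plane inclination (elevation toward the beam).  The laboratory frame
is right-handed with x–y in the imaging plane and z along the normal beam
into the tissue; α > 0 tips the fiber toward +z.  The optic axis is an
*axial* quantity (**u** ≡ −**u**); the canonical representative has its
first nonzero component of (ox, oy, oz) positive, and all public angles are
degrees (Θ wrapped to the half-open [−90°, 90°), α on the closed
[−90°, 90°]).

A beam with unit propagation **p** observes the apparent birefringence
vector

  **a**(Δ**n**, **p**) = (Δ**n** − (**p**ᵀΔ**n**)**p**) · √(1 − (**p**ᵀΔ**n**)²/|Δ**n**|²),

i.e. the projection of Δ**n** onto the plane orthogonal to **p** scaled by a
second factor of sinΨ, so |**a**| = Δn·sin²Ψ with cosΨ = **p**ᵀ**u**.  The
measured pair (Δn′, Θ′) is the magnitude of **a** and its azimuth in the
beam frame.  Three beams are modeled: normal **p**₁ = [0,0,1]ᵀ, y-tilted
**p**₂ = [sinΩ, 0, cosΩ]ᵀ and x-tilted **p**₃ = [0, −sinΩ, cosΩ]ᵀ, with
the beam-frame embeddings

* normal: Δn′[cosΘ′, sinΘ′, 0]
* y-tilt: Δn′[cosΩcosΘ′, sinΘ′, −sinΩcosΘ′]
* x-tilt: Δn′[cosΘ′, cosΩsinΘ′, sinΩsinΘ′]

A fiber parallel to a beam is invisible to it (Δn′ = 0, Θ′ undefined); this
is flagged, not raised.

Assumptions: the two acquisitions are registered to common pixels; the
tilt angle is the geometric beam direction (no refraction correction at the
tissue surface); each pixel is a single dominant fiber population.

## Estimation

Per pixel the three components of the trial vector Δ**ñ** are optimized by
Nelder-Mead simplex to minimize

  ‖**ã**₁ − **a**₁‖² + ‖**ã**₂ − **a**₂‖²,

where for each beam the residual is taken against ±**a**ᵢ and the smaller
kept: the measured Θ′ fixes the apparent vector only up to axial sign, and
resolving the sign inside the objective removes any dependence on the wrap
convention of Θ′.  Magnitudes are scaled by the larger apparent
birefringence so the simplex operates on order-one parameters; convergence
uses an absolute objective tolerance of 1e-20 (attainable in double
precision because the noiseless optimum is 0) with simplex size 1e-9 and a
2000-iteration cap.

**xy-swap.**  For |Θ₁| ≥ 45° the measurements are rotated 90° about z
before fitting (and the result rotated back), which maps the y-tilted beam
onto **p**₃ and moves the in-plane angle near 0.  With the sign-resolved
residual above, the two branches have identical optima on exact inputs —
the swap is an exact change of coordinates — but it keeps the initializer's
angle arithmetic away from the ±90° wrap, where bounded measurement noise
becomes U-shaped and plain averaging or naive residuals would bias the fit.
The boundary case |Θ₁| = 45° goes to the swapped branch.

**Initialization.**  The default start comes from a closed-form
inclination scan: Θ is fixed by the normal beam (Θ′₁ = Θ exactly under
**p**₁), and for each candidate α on a 1° comb the magnitude follows from
Δn′₁ = Δn·cos²α; the objective evaluated along this comb picks the starting
basin, with a second simplex start from the best opposite-sign α when the
scan cannot separate the two (the α-sign is weakly identified near 0 and
the objective is bimodal in the sign for axes co-planar with the beams).
A near-zero start ([ε,ε,ε], ε = 1e-8) is kept as a compatibility option;
the objective's closed form is singular at exactly zero magnitude.

**Degeneracy.**  Pixels whose apparent birefringence is below 1e-6 under
*both* beams are masked as unidentifiable.  The floor is configurable; 1e-6
is far below tissue-scale Δn′ (~1e-4) yet keeps steep fibers (α ≈ ±80° at
Δn = 2e-4, where Δn′ falls to ~2e-6) estimable on clean data.

**Oracle.**  A vectorized exhaustive grid search over (Θ, α, Δn) provides
an independent check that the simplex reaches the global basin: on noisy
pairs the simplex objective must not exceed the 1°-grid minimum.

Maps are processed pixel-independently; pixels with bitwise-identical
measurements share one solve (the estimate is a pure function of the four
measured values), which makes homogeneous phantoms cheap without affecting
results.

## Preprocessing

Apparent birefringence comes from an ordinary least-squares fit of the
single-pass retardance profile (degrees) against depth over a 150 µm window
below the surface: Δn′ = slope(deg/µm)·λ₀(µm)/360, λ₀ = 1300 nm by default.
A `double_pass` flag halves cumulative round-trip input first; negative
slopes clip to zero and windows with fewer than 3 samples are masked.  The
surface is supplied as an index map (z = 0 for flat-faced blocks) rather
than detected from intensity.

En-face orientation is the center of the maximal histogram bin of the
orientation samples in the same window.  Bins are period-180 wrap-aware and
*centered* on multiples of the 5° width, so the bin at ±90° collects samples
from both interval ends and a cluster straddling the wrap lands in one bin;
ties break toward the bin nearest the circular mean.

Registration of the tilted onto the normal acquisition is affine-only: at
Ω = 15° the dominant distortion is a cosΩ ≈ 0.966 foreshortening, so a
6-parameter affine fitted by maximizing normalized cross-correlation of the
birefringence maps (translation seeded by phase correlation, Powell
refinement with the linear part parameterized about the image center and
direction steps matched to parameter scales) suffices; deformable
registration is out of scope.  The transform is then applied to the
orientation map with nearest-neighbor resampling — angles are axial, and
linear interpolation across the ±90° wrap corrupts them — plus a rotation
correction of the values by the transform's polar-decomposition angle.
Validity is preserved by warping the finite-pixel footprint alongside the
data; a final correlation below a configurable floor raises a registration
error rather than returning a silent misalignment.

## Synthetic phantoms

The generator emulates the uniform white-matter blocks used for validation:
a ground-truth (Θ, α, Δn) field is pushed through the forward model under
**p**₁ and **p**₂, then wrapped-Gaussian noise (period 180°, independent
per beam) is added to Θ′ and truncated (at zero) Gaussian relative noise to
Δn′.  Defaults follow the physical designs: Ω = 15°, Δn of a few 1e-4,
noiseless for the accuracy experiments.  Three designs are provided —
wedge (presets {0, −30, +30}° added rigidly to α), tilt sweep (0–50° in 10°
steps; reported as the OLS slope of mean recovered α vs preset) and
in-plane rotation (0–90° in 30° steps added to Θ; reported as per-level
means and the summed wrapped per-step change).  What the phantoms do *not*
emulate: speckle, depolarization, depth-dependent SNR decay, within-pixel
fiber dispersion, tissue heterogeneity, or sample-intrinsic inclination
offsets (real blocks show a constant additive α offset from fibers not
lying flat; that is a property of the sample, representable through
`base_alpha`, not of the method).  Passing the synthetic validations
therefore demonstrates correctness of the geometry and optimization, not
robustness to every tissue artifact.

## FOD analysis

Orientation maps are summarized by histograms over non-overlapping windows
specified in millimetres (0.5 mm ≈ 50×50 pixels at 10 µm), bin width 5°.
In-plane FODs wrap with period 180; through-plane FODs live on the closed
interval and do not.  The primary peak is the maximal bin center refined by
a 3-point parabola (wrapped neighbors for Θ; zero-count virtual neighbors at
the closed ends for α) — without refinement, 5° bins would quantize
validation statistics reported at 0.1° precision.  FWHM is measured by
linear interpolation between bin centers at half the peak count, walking
outward from the peak (wrap-aware for Θ), capped at 180°; a distribution
that never drops below half is reported as 180°.  ROI summaries average
peaks circularly (period 180) for Θ and arithmetically for α, FWHMs
arithmetically, and record the fraction of fully-masked windows.
Low-birefringence exclusion reuses the estimator's mask/floor.

## Volumes, rendering, tracking

Blockface sectioning preserves inter-slice geometry, so per-slice maps
stack directly (default 10 µm in-plane, 150 µm slice pitch) with no
inter-slice registration.  NIfTI export writes the axis field as a
3-component float64 volume and Δn as a scalar volume, spacing in mm in the
header, masked voxels as zero vectors; the round trip is bit-exact.
Rendering maps angles onto a cyclic hue wheel and the 3D axis onto
|ox|,|oy|,|oz| → RGB, with brightness modulated by (apparent or true)
birefringence.

The streamline tracker is deliberately minimal — the reconstruction, not
tractography, is the contribution; NIfTI remains the interop path to
external trackers.  It integrates bidirectionally with a fixed step (default
half the in-plane voxel), nearest-neighbor axis lookup, and the axial sign
chosen at each step to minimize turning; a step is refused (termination
reason `angle`) when the unsigned turning angle exceeds the threshold
(default 60°), and tracks also stop at the mask, the volume bounds, or a
length cap.  No intensity threshold is applied by default.

## Numerical choices and problem sizes

* Angle wrap arithmetic is centralized (`wrap_theta`, `wrap_theta_diff`)
  with [−90, 90) and (−90, 90] conventions respectively; the Θ = ±90°
  boundary stores the (−90, −α) representative of the same axis.
* Test and validation runs use 32×32 phantoms for the experiment designs,
  a ~1100-point (Θ, α, Δn) recovery grid, and 50 noisy pairs against a
  1° oracle grid — sizes chosen so the full suite completes in well under a
  minute while exercising every branch (co-planar axes, the swap boundary,
  steep inclinations at the smallest Δn).
* Seeded `numpy` Generators drive all randomness; identical spec + seed is
  bit-reproducible.

## Known limitations

* Only two illumination geometries (normal + one small tilt) are supported;
  depth-resolved (tomographic) local-axis estimation is out of scope.
* The inclination sign is unidentifiable exactly at α = 0 and degrades
  gracefully near it under noise; near |α| → 90° both apparent signals
  vanish and noise inflates the estimate's variance (the regime behind
  tilt-sweep slopes exceeding 1 on real tissue at large presets).
* The affine registration assumes a rigid, flat-faced sample; it will not
  absorb local tissue deformation.
* The retardance-to-Δn′ conversion assumes the single-pass convention
  unless told otherwise; acquisitions differ, and the flag must be set
  correctly by the caller.
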