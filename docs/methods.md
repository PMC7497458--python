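# Methods

This note records the models implemented in `petsr`, the choices made
where the design was genuinely open, and what the synthetic testbed
does and does not establish about real data.

## Forward model and SR iteration (`srcore`)

Each gated frame is modelled as `Γ_i = B D M_i H + Ψ_i`: the reference
high-resolution activity is moved into the gate's cardiac phase,
decimated, blurred and corrupted by count noise. Operator order in the
implementation is warp → decimate → blur; the PSF FWHM is specified in
mm, so the physical blur is independent of the grid it is applied on.

* **Decimation `D`** is the block mean over `factor × factor` tiles
  (dimensions padded by edge replication when not divisible);
  **`D⁻¹`** is bilinear enlargement on pixel-centre-aligned
  coordinates. These are not exact inverses — `D⁻¹` is the standard
  interpolating right-inverse.
* **Motion `M_i`** is stored as the pull-back field of the
  registration convention: sampling frame *i* at `x + M_i(x)`
  reconstructs the reference frame. As an *operator on the reference
  image*, moving `H` into gate *i* therefore warps with the negated
  field, and the back-projection warp in the gradient uses `+M_i`;
  the negation is the standard small-deformation approximation of the
  field inverse. Fields estimated on the anatomical grid are resampled
  (bilinear, components rescaled) to whatever grid an operator needs.
* **Back-projector**: `B⁻¹` is a one-pixel delta. Inverting a Gaussian
  is ill-posed; a simplified backward operator leaves `B` in the
  forward model only, which turns the update into a (preconditioned)
  Landweber-style iteration that restores frequencies inside the PSF
  passband and leaves the rest at the initial (MoCo) estimate.
* **TV prior**: `TV(H) = Σ |∇H|` with forward differences and
  replicated borders; its descent direction is the divergence of the
  normalised gradient, with `|∇H|` stabilised as
  `sqrt(|∇H|² + ε²)`, ε defaulting to 1e-6 of the image dynamic
  range. The implementation is the exact negative adjoint of the
  forward-difference gradient, so it matches per-pixel numerical
  differentiation of the smoothed TV sum (this is asserted in the
  tests). The default weight λ = 1e-6 follows the source system's
  working value; at SUV-scale images it is a very light touch and the
  effective regularisation comes mostly from early stopping (below).
* **Initialisation and stopping**: `H¹` is the MoCo image (each gated
  frame warped to the reference phase with its field, averaged,
  upsampled). The loop stops at the first pair of consecutive
  iterations whose relative data-RMSE change is below
  `stop_rel_change` (default 5 %), or at `max_iters`; a ten-fold RMSE
  growth over the initial value aborts with a diagnostic. With noisy
  data the RMSE plateaus at the noise floor after a handful of
  iterations, which acts as the de-facto regulariser: deep
  (noise-free) convergence of the band-limited deconvolution exhibits
  mild Gibbs overshoot at the wall (a few percent of the wall value),
  whereas the noise-floor stop leaves the low-frequency content —
  including the ROI means — essentially converged and the overshoot
  unformed. A `step_size` multiplier (default 1, the plain update) is
  exposed because stability at other grid/PSF combinations is not
  guaranteed a priori.
* The static-PET baseline is the unwarped mean of the gated frames,
  upsampled to the reference grid.

## Motion registration (`registration`)

Per-frame motion is estimated on the anatomical cine by minimising a
windowed energy combining squared intensity and squared local-phase
differences, weighted `k` and `1−k` (default `k = 0.5`). Both images
are first normalised to [0, 1] so the balance is independent of input
brightness.

* **Local phase** is the monogenic phase
  `atan(I_e / sqrt((F_o1∗I_e)² + (F_o2∗I_e)² + ε))` with a log-Gabor
  radial even filter (relative log-frequency bandwidth 0.55, zero DC)
  and its Riesz-transform odd pair, evaluated in the Fourier domain.
  Values lie in (−π/2, π/2); phase differences use the raw values
  without angular wrapping, since this arctangent form cannot wrap.
  The phase is invariant to positive global rescaling of the image,
  which is what makes the term robust to speckle-induced brightness
  variability.
* **Forces**: each data term contributes the demons-regularised force
  `r ∇I_R / (|∇I_R|² + r² + ε)` with `r` the (warped-template)
  residual; the printed sign of the update in the source derivation is
  an ascent direction under the pull-back convention, so the
  implementation adds the force (verified on a 1-D toy where the force
  must push the field toward the true shift). ε defaults to 1e-12 of
  the squared dynamic range and only matters where residual and
  gradient vanish together.
* **Fluid regularisation** smooths each additive increment (not the
  accumulated field) with a normalised Gaussian of 10 px.
* **Pyramid**: 3 levels (Gaussian anti-alias σ = 1 then decimate by
  2), 10 iterations per level, band-pass centre wavelengths 16, 8 and
  2 px from coarse to fine; fields are upsampled bilinearly between
  levels with components doubled. Unit step length is used with the
  regularised force, which bounds each pre-smoothing increment by half
  a pixel.
* The window Υ defaults to the full image; a rectangular ventricle
  window can be configured. Constant (degenerate) images return a zero
  field with a warning. The energy is evaluated densely.

Measured on the default phantom, the registration recovers an imposed
3 px translation of a speckle image to ~0.005 px and the cyclic
contraction field to a mean endpoint error of ~0.06 px inside the
wall.

## Synthetic beating phantom (`phantom`)

The generator stands in for the excluded acquisition chain (Monte
Carlo transport, sinogram reconstruction, probe physics) and defines
the study conditions:

* Geometry: 128 × 128 grid at 0.1 mm/px (ultrasound-like), annulus
  inner/outer radii 2.0/3.5 mm — a 1.5 mm wall, equal to the PSF FWHM,
  which is the partial-volume regime of interest. Activity 4 in the
  wall, 1 in cavity and background; an optional angular sector paints
  a perfusion-defect value. Edges are quintic-smoothstep transitions
  1.5 px wide so that the eroded ROI masks read the nominal values
  exactly and warping is interpolation-clean.
* Motion: radial sinusoidal contraction about the grid centre,
  `s_k = 1 − A(1 − cos 2πk/n)/2` with `A = 0.05` (5 % of radius) over
  `n = 16` frames, plus an optional rigid craniocaudal translation
  emulating residual respiratory shift. Every frame is the reference
  profile evaluated at `r/s_k` (transition widths scaled too), so the
  analytic pull-back fields `(s_k − 1)x + t_k` are exact, not fitted.
  Warping is intensity-preserving (no Jacobian compensation),
  consistent with the image-domain treatment; at 5 % amplitude the
  contraction is far from collapse and the negated-field inverse is
  accurate to well under a tenth of a pixel.
* Anatomical rendering: brightness is a square-root remap of activity
  multiplied by a spatially correlated multiplicative speckle texture
  that is attached to material coordinates — it moves with the tissue,
  as real speckle largely does, so the anatomical frames genuinely
  carry the motion. The texture's coefficient of variation in a
  homogeneous region equals `speckle_contrast` (default 0.3, a
  moderate B-mode granularity after compounding/filtering).
* Degradation: the reference frame is warped with the negated true
  field (the same approximate inverse the SR stage uses), decimated by
  2, blurred with the 1.5 mm PSF and hit with Poisson count noise,
  `counts_scale` expected counts per unit activity per low-res pixel,
  rescaled back to activity units. A Gaussian mode with matched
  variance is provided for the literal additive-noise reading of the
  model, and `"none"` for noise-free studies. `counts_scale = 40` was
  calibrated once so a single gated frame shows ~6.5 % relative STD in
  the wall ROI, matching the published gated-frame statistics the
  phantom emulates; it is an explicit stand-in for the ~65 M
  counts/frame of the original Monte-Carlo experiment, whose scanner
  geometry is not reproducible here.

What the phantom does **not** emulate: attenuation, scatter and
randoms; reconstruction-correlated noise (counts are white at the
low-res pixel scale); out-of-plane (3-D) motion; wall thickening mass
conservation; realistic ultrasound physics (shadowing, reverberation,
depth-dependent resolution). Passing tests therefore establish the
correctness and self-consistency of the chain and its behaviour under
known motion, blur and counting noise — not performance on scanner
data.

## Quality metrics (`metrics`)

* ROI statistics use the arithmetic mean and the **population** STD
  (the sample/population difference is negligible at the ROI sizes
  used, but one convention is fixed). SNR is `10 log10(MEAN/STD)` in
  dB, evaluated on the wall ROI; contrast is Weber's fraction between
  wall and cavity means. Low-resolution images are upsampled to the
  reference grid first so every image is scored with identical masks.
* Wall resolution: five profiles cross the wall orthogonally (sites
  named after the clinical convention, basal lateral … basal septal);
  on each, the samples external to the outer wall edge — the edge
  position comes from the anatomical truth, not the image under test —
  are mirrored about the edge and a Gaussian with fixed centre, free
  amplitude, width and offset is least-squares fitted (σ₀ = 2 px,
  ≤ 200 evaluations); the resolution is the mean FWHM over the five
  fits, with more than two failed fits reported as missing. The
  mirrored-peak construction measures a *line-spread* width: it is
  exact for a thin (line-like) wall or a half-Gaussian tail, and for a
  thick ideal step edge it reads systematically narrow (~0.6× the edge
  blur); on the annular phantom, whose wall thickness equals the PSF,
  it behaves as a consistent relative resolution score across images,
  which is how it is used.

## Numerical and interface choices

* All images are float64 in memory; stacks on disk are float32
  multi-page TIFF (spacing in the shaped metadata and resolution tags)
  or NIfTI-1 (spacing in the affine), which round-trip values and
  spacing exactly at that precision. Motion fields travel as 2-channel
  stacks (u, v per frame), masks as 8-bit labels.
* One integer seed drives the whole pipeline; per-stage generators are
  spawned from it, so runs are bit-reproducible.
* Warping is bilinear with replicated borders throughout; gradients
  are central differences (`np.gradient`); all Gaussian filters use
  replicated borders and normalised kernels.
* Default problem sizes (128² high-res grid, 16 gates, factor 2) keep
  a full simulate–register–reconstruct–evaluate cycle at a few seconds
  on one CPU core, which is the scale all shipped studies use.

## Known limitations

* The SNR of the SR image on this phantom does not exceed the static
  baseline's: the static average is doubly smoothed (motion + PSF), so
  its wall-band STD is small relative to its depressed mean, while the
  SR estimate carries back-projected count noise and the partially
  recovered radial profile. On the original system the gated frames
  carry reconstruction-smoothed noise and the reported SNR improved;
  reproducing that requires the excluded reconstruction chain.
* Deep noise-free convergence overshoots the wall mean by a few
  percent (band-limited Gibbs effect); quantitative recovery is
  reported under the default noisy conditions where the noise-floor
  stop applies.
* The cyclic contraction dwells near end-diastole (cosine phase
  sampling), so the static image's outer edge retains much of the
  reference sharpness; motion-blur removal by MoCo is best seen in its
  distance to the motion-free degraded reference and in its
  quantification, not in a single edge-width number.
* The approximate field inverse `−M` restricts validity to small
  deformations (a few pixels); large-amplitude motion would need a
  fixed-point or diffeomorphic inverse, which is out of scope.
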