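# Methods

## Problem

Focused ultrasound (FUS) concentrates acoustic energy into a sub-millimetre
focal volume and is used to stimulate cortex non-invasively while a
widefield fluorescence camera records GCaMP calcium activity.  The absorbed
acoustic power heats the focal volume during the 150 ms pulse, and
GCaMP-class indicators dim as temperature rises, so each sonication stamps
a transient focal fluorescence dip — a fluoro-thermal tag (FTT) — on top
of any genuine calcium response.  The dip and the evoked response overlap
in space and in time (the response peaks only a few hundred milliseconds
after the pulse), so the thermal confound must be modelled and removed
before the response can be quantified.  `fttclean` implements the full
chain: a forward model that predicts the FTT from physics, the image
processing that isolates stimulus-locked activity from the much larger
spontaneous background, the model-based dip subtraction, and a synthetic
generator that makes every stage testable without any recorded data.

## Forward model

**Acoustic field.**  The focal intensity distribution is a separable
anisotropic Gaussian ellipsoid.  Its lateral full-width at half maximum
defaults to 350 µm (the measured trans-skull focal spot at 3 MHz); the
axial extent is not measured, so it defaults to 3× the lateral width and
is exposed in configuration.  Peak intensity comes from the plane-wave
relation I = p²/(2ρc) with water-like soft tissue defaults
ρ = 1000 kg/m³, c = 1500 m/s.  Scalar summaries: the mechanical index
MI = p[MPa]/√f[MHz] (1.6 for 2.8 MPa at 3 MHz, under the 1.9 diagnostic
limit).  The transducer array itself (hundreds of elements, hydrophone
calibration) is deliberately out of scope: the bioheat stage consumes only
the intensity distribution.

**Bioheat.**  Temperature rise obeys the Pennes equation
∂ΔT/∂t = α∇²ΔT − ΔT/τ + Q/(ρC) with diffusivity α = κ/(ρC), a blood
perfusion sink with time constant τ, and plane-wave absorption heating
Q = 2·α_abs·I while the pulse is on.  Defaults (all config-overridable,
since the literature constants behind the original experiments are not
printed): κ = 0.52 W/(m·K), ρC = 3.8×10⁶ J/(m³·K), τ = 300 s,
α_abs = 5 Np/m at 3 MHz.  The solver is explicit forward Euler with a
7-point Laplacian on a uniform grid, zero-ΔT Dirichlet boundaries, and an
internal step chosen at half the stability bound
1/(2α·Σ1/h² + 1/τ) (further capped at τ/50 so the perfusion decay is
resolved below a percent).  With the default constants and 2.8 MPa the
focal heating reaches roughly 0.6 K at pulse end and relaxes diffusively
within a few hundred milliseconds.  The solver is verified against closed
forms: Gaussian initial conditions spread with variance σ₀² + 2αt
(relative L2 < 2%), κ→0 decays as exp(−t/τ), the solution is linear in
the source to 10⁻⁶, non-negative, and conserves energy without perfusion.

**Quench.**  Over the few-kelvin range relevant here the
brightness–temperature relation of GCaMP tissue is affine with negative
slope; `fit_affine_quench` estimates it from bath calibration data by
ordinary least squares.  There is no universal slope constant — it is a
calibration input.  The synthetic defaults use −2 %ΔF/F₀ per K, inside
the −1…−3 %/°C range reported for GCaMP-family indicators.  The FTT
signature is slope·ΔT per voxel, projected to the camera plane (default:
the x–y plane through the focus depth; an exponential depth-weighted
projection is available) and resampled to the camera pixel grid.  The
affine intercept is ignored: baseline-referenced ΔF/F₀ data have zero
offset by construction.  Because the Pennes equation is linear in the
source, one reference simulation per geometry is cached and rescaled
analytically for pressure and slope.

## Processing chain

Stage order: Kalman denoise → temporal low-pass (0–8 Hz) → moving-baseline
ΔF/F₀ → epoch average → pre-onset re-referencing → spatial Gaussian
(σ = 1 px) → inter-hemispheric subtraction → FTT subtraction →
Savitzky–Golay (window 11, order 2) → peak quantification (max ΔF/F₀ and
its latency within 2 s of onset).

Notes on individual stages, in order:

* **Kalman stack denoiser.**  Per-pixel causal recursion
  est_t = g·est_{t−1} + (1−g)·obs_t.  The gain starts at the configured
  bias (0.5) and is bounded above by it; per pixel and per frame it is
  scaled by min(1, 2N/V)², where V is an exponential moving average
  (forgetting 0.95) of squared innovations and N a second-difference
  noise-power estimate (Var(x_t − 2x_{t−1} + x_{t−2})/6 equals σ² for
  white noise, making 2N/V → 1).  White noise is therefore smoothed at the
  configured bias (variance ratio ≈ 0.34 at bias 0.5) while coherent
  signal passes through essentially untouched — the causal stage adds no
  group delay to the transients the rest of the chain must quantify.  The
  recursion is frozen by a regression test.
* **Band 0–8 Hz.**  The band starts at DC, so this is a zero-phase
  low-pass: 4th-order Butterworth run forward–backward.  Drift removal is
  the moving baseline's job, not this filter's.
* **Moving baseline.**  F₀ is the per-pixel content below 0.05 Hz;
  ΔF/F₀ = 100·(F − F₀)/F₀.  Since the baseline holds only sub-0.05 Hz
  content, it is computed on a block-mean-decimated series (≈8× the corner
  frequency) and interpolated back — numerically equivalent in the
  retained band and an order of magnitude cheaper.  Recordings shorter
  than three baseline cycles (60 s) fall back to a per-pixel linear trend.
  A non-positive baseline anywhere raises an error naming the pixel.
* **Epoch averaging and re-referencing.**  Onsets map to the nearest frame
  (ties to the earlier frame); all epochs need full pre/post support.
  Because the moving baseline absorbs a small share of the stimulus-locked
  transients, the averaged epoch carries a constant percent offset; each
  pixel is re-referenced to its pre-onset mean, which is what "relative
  change with respect to baseline" means operationally.
* **Inter-hemispheric (IH) subtraction.**  Each pixel minus its
  column-mirror across the midline.  Bilaterally mirrored background
  cancels exactly; pixels whose mirror falls outside the frame keep their
  value and are flagged in a validity mask.  The output is antisymmetric:
  every focal transient acquires a sign-flipped ghost at the mirrored
  position (this is handled consistently downstream, and means the mirror
  region carries no independent information).
* **Focus localisation.**  The focus is found from the observed dip: each
  pixel of the IH-subtracted epoch is projected onto the model-predicted
  dip time course over the sonication window, the map is matched-filtered
  at the focal-spot scale, and its minimum taken.  When the steering
  target is known — always, in a navigated experiment — the search is
  restricted to a radius (default 20 px) around it.  At the default study
  conditions the dip's z-score over the full hemisphere is only ≈ 3.5, so
  an unrestricted search can lock onto a background fluctuation roughly
  half the time; restricted search is the intended workflow, and an
  explicit focus override exists.
* **FTT subtraction.**  The processed dip is *not* the clean model
  signature: the adaptive denoiser, the filters and the baseline all act
  on it (measurably — subtracting the clean signature leaves ~30% of the
  dip behind under realistic photon noise).  The template is therefore
  measured in situ: one unit of the model signature is subtracted from the
  raw counts at every onset (scaled by the movie's own slow baseline,
  additively — a multiplicative probe has an O(s²) cross-term that biases
  the fit), the identical chain is run on both movies, and the difference
  of the processed epochs is the template as the pipeline sees it.  The
  template is denoised by a rank-3 space–time SVD over the model support
  (the diffusive transient is near-separable).  In `fitted` mode the scale
  β ≥ 0 is least-squares fitted over the sonication window and a focal
  disk of radius 2× the focal FWHM — the response has not yet begun
  there, so the fit is response-blind; `fixed` mode subtracts the model
  prediction as-is (β = 1).  The fit window is deliberately *not*
  extended into the thermal decay: the evoked response rises there and
  leaks into the scale with spatial leverage ≈ 1.8, biasing β low.
* **Trace extraction.**  Focal traces are Gaussian-weighted
  (matched-filter) ROI estimates that deconvolve the pipeline's spatial
  smoothing: for a transient with a Gaussian footprint of the configured
  width, the trace peak is an unbiased estimate of the injected peak
  amplitude rather than an ROI-area-diluted mean.  The response trace uses
  the expected activation footprint (default FWHM 1 mm); the dip trace
  uses the focal-spot width.
* **Quantification.**  Peak amplitude is the maximum of the corrected,
  Savitzky–Golay-smoothed focal trace over (0, 2 s]; latency is the time
  of that maximum, ties to the earliest frame.  The smoother uses
  polynomial edge continuation so it is exact on quadratics everywhere.

## Synthetic data

A generated recording is
F = baseline·bleach(t)·(1 + (resting + ftt + response)/100) + photon noise,
with the components in percent ΔF/F₀:

* **Resting background** — the dominant nuisance, by default 10× the
  evoked response's peak (as observed in vivo) and temporally band-limited
  below 1 Hz.  Its mirror-symmetric part is mesoscale (Gaussian σ = 8 px,
  generated on a coarse grid and upsampled); its hemispherically
  asymmetric part is pixel-scale.  This split encodes a modelling claim:
  homotopic correlation is a property of mesoscale dynamics, while the
  residual asymmetry lives at fine (vascular/pixel) spatial scales.  The
  variance split realises the configured IH correlation (default 0.95).
  Consequence worth stating plainly: if the asymmetric residual were
  instead mesoscale-smooth, no spatial averaging could suppress it, and
  after IH subtraction and 20-epoch averaging it would stand at ≈ 0.65×
  the response peak — no pipeline could then recover latency to one frame.
  Passing tests therefore validate the method *under the stated
  background model*, not against arbitrarily structured asymmetry.
* **FTT** — the forward-model signature (bioheat + quench on the camera
  grid) inserted at every onset, scaled by `ftt_scale` (default 1: the
  physics is taken at face value).
* **Response** — a spatial Gaussian (FWHM 1 mm, wider than the focal
  spot, on the stimulated side only) times an alpha-function time kernel.
  The kernel starts at the *end* of the sonication pulse — the thermal tag
  precedes the activation — and peaks 500 ms after onset (peak amplitude
  1%).  `resting_amplitude=None` derives the background as 10× this
  amplitude, so a zero-response scenario is also background-free unless
  resting is set explicitly.
* **Bleach and noise** — exponential photobleaching (τ = 300 s) and
  additive Gaussian photon noise (SD 0.5% of the 1000-count baseline,
  consistent with the ~10⁴–10⁵ photons a large widefield pixel collects
  per 40 ms frame).

Defaults: 128×128 pixels at 88 µm (2× binning of the 44 µm optical
resolution), 25 Hz, 20 stimuli 10 s apart starting at 5 s, 204 s total.
All randomness derives from one seed; the same seed is bit-reproducible,
and the per-component movies (plus noise) reconstruct the emitted movie
exactly when requested.

What the generator does **not** emulate: hemodynamic contamination,
spreading depolarisations, motion, non-Gaussian sensor noise, atlas
geometry (the midline is a straight column), non-affine quench, and any
mesoscale structure in the hemispheric asymmetry (see above).  Results on
real recordings depend on how closely these assumptions hold.

## Numerical and design notes

* Explicit Euler was chosen over implicit schemes for verifiability
  against closed forms at desk scale; the stability bound is enforced and
  surfaced in errors.
* The bioheat simulation for the signature runs to 3 s (the dip has
  decayed to ~2% of its peak by then) on a grid extending 4σ beyond the
  focus plus 2.5 diffusion lengths, step = FWHM/5 per axis.
* The 4f/4g-style end-to-end checks run at the full default scale
  (128×128, 20 epochs); the forward simulation is cached across seeds via
  source linearity.
* Pearson correlation uses the sample convention; p-values are out of
  scope.
* Degenerate inputs raise typed errors (degenerate calibration design,
  constant correlation vectors, non-positive baselines, truncated epochs,
  unstable time steps, out-of-grid sampling), each naming the offending
  quantity.

## Known limitations

* The fitted FTT scale has standard error ≈ 0.03 under default noise
  (sonication-window-only fit); the residual after subtraction is
  therefore not exactly zero, and a null-scenario corrected peak sits at
  2–3× the trace noise SD — close to, but below, the 3σ level used as the
  artifact-removal check.
* Unrestricted dip localisation is unreliable when the background is at
  its default 10:1 dominance (see above); use the steering target.
* The camera projection treats the brain as optically thin at the focus
  depth (or exponentially weighted); true widefield depth integration is
  more complex.
* The IH convention is a straight vertical midline; real midlines bend,
  and atlas registration is explicitly out of scope.
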