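# Methods

## Pipeline model and assumptions

The screening pipeline assumes a single macular B-scan in which the retina
appears as a bright, roughly horizontal, internally layered band on a dark
background, with the hyper-reflective RPE stripe near its base. Pathology
is assumed to manifest as (a) thickening of the band (edema, serous
detachment), (b) hypo-reflective fluid pockets inside it (cysts, serous
fluid, sub-RPE deposit), or (c) deformation of the RPE stripe away from
its smooth physiological curvature (drusen). All stages operate per
A-scan column after normalization to 480 x 1280 pixels; no 3-D context is
used.

### Denoising

The adaptive Wiener filter interpolates per pixel between the local window
mean and the raw value, with gain `(v - v_n)/v` where `v` is the local
variance and the noise floor `v_n` is the image-wide mean of the local
variances, computed over reflective padding so border kernels are full.
Where `v <= v_n` (including the `v = 0` degenerate case) the output is the
local mean; the output therefore always lies inside each window's value
range and constants are fixed points. Window default 5 x 5 px: large
enough to estimate a variance, small enough to preserve the ~4 px RPE
stripe at the 480-row working scale. The global noise estimate assumes
spatially stationary noise; strongly intensity-dependent speckle makes the
filter over-smooth darker structures, which is visible in (and handled by)
the segmentation stages.

### Structure-tensor segmentation

Gradients are 3 x 3 Sobel (central differences available via config). The
tensor is smoothed with a Gaussian of σ = 2 px (truncated at 3σ): wide
enough to fuse the speckle-broken edge response, narrow enough to keep
adjacent sublayers separate. Eigenvalues come from the closed form for a
symmetric 2 x 2 matrix with λ2 clipped at 0; coherency uses the 0/0 → 0
convention so empty background is "isotropic", and is clipped to [0, 1].

The scalar **coherent image** is `sqrt(H · (λ1 + λ2))`, rescaled to
[0, 1]. The square root is deliberate: squared-gradient energy spans so
many decades that a histogram threshold on it separates *strong* edges
from *weak* edges rather than tissue from background, and the downstream
fluid fusion then misreads tissue interior as fluid. Amplitude scale puts
weakly and strongly contrasted layer interfaces in the same foreground
class. The raw energy product and the single-channel Γ_SS variant remain
available through `PipelineConfig.coherent_mode`.

Otsu thresholding is implemented explicitly on a 256-bin histogram with
exhaustive evaluation of every candidate split and ties broken toward the
lowest threshold, so it is checkable against a brute-force oracle
bin-for-bin. A constant image has no split; the thresholder warns and
returns an empty foreground. Canny on the binary map uses σ = 1 and fixed
thresholds (high 0.5, low = 0.4 · high) — on an already-binary input any
positive pair works, the fixed values only pin determinism.

### Layer tracing

Per column: ILM = first edge pixel from the top, choroid boundary = last
edge pixel, RPE = brightest pixel of the denoised scan strictly between
them (the first of tied maxima, i.e. the top of the stripe response).
Columns without a usable edge pair are linearly interpolated from their
neighbours; more than 50% unusable columns raises a segmentation failure.
Traces are median-filtered (width 15 columns, reflected at the borders so
edge outliers do not self-replicate).

Two robustness refinements are applied on top of the raw rule:

- **Gradient snap.** The Otsu'd coherency ridge extends ~3 px beyond the
  true intensity step, so raw first/last-edge traces carry a systematic
  outward offset. ILM and choroid are therefore snapped to the strongest
  positive (ILM) or negative (choroid) axial-gradient row within ±6 px,
  skipping columns whose window is gradient-free (so synthetic
  fixtures with literal edge rows are returned exactly).
- **RPE despike.** Narrow argmax excursions (border artifacts in skewed
  scans, specular spots) are replaced by a wide-window (31-column) median
  wherever they deviate from it by more than 10 px. Genuine drusen domes
  are 60–120 columns wide and pass through unchanged.

Ordering ilm < rpe < choroid is enforced by clipping, and clipped columns
are flagged invalid. Inner-layer tracing (ranked zero crossings of the
axial gradient between ILM and RPE) is best-effort; it feeds only the
separation statistics, never the 9-feature descriptor.

### Features

Thickness is `|choroid - ILM|` per column (the absolute value makes the
depth-axis convention irrelevant), in µm when axial calibration is
present. The cyst fusion keeps `R_M AND NOT tissue`: fluid is
hypo-reflective, so it is background *inside* the retinal mask. A literal
exclusive-or is retained behind `cyst_fusion="xor"` but would also keep
bright tissue outside the mask. Holes in the tissue map smaller than
256 px are treated as residual speckle and filled before fusion; connected
components below 25 px are dropped afterwards. Both limits sit well below
the smallest rendered pathology component (≈500 px).

Cyst energy uses an orthonormal 2-D Haar decomposition, 2 levels, summed
squared approximation coefficients. For solid regions this tracks total
area; fragmentation leaks energy into the detail bands. Its absolute
magnitude depends on wavelet convention and is treated as ordinal, not
physical.

The RPE profile is the deviation of the RPE trace from its least-squares
quadratic baseline, positive toward the ILM. A quadratic absorbs the
physiological curvature of the posterior pole (and any residual tilt of a
skewed acquisition) while drusen appear as localized positive bumps; this
also explains why the minimum deviation `f7` is naturally negative.
`f3` and `f8` are absolute differences so both are nonnegative regardless
of which extremum dominates.

### Classifier cascade

Three binary SVM stages, each an independent `StandardScaler + SVC`
pipeline (z-scoring is necessary because `f4`/`f5` span four orders of
magnitude relative to the thickness features). Routing: healthy vs
abnormal on `(f1..f4)`; among abnormal, ARMD vs fluid disease on
`(f6..f9)` — the RPE features isolate drusen most cleanly; among fluid
disease, RE vs CSCR on `(f4, f5)` — scattered edema cysts and a single
serous detachment differ in cyst energy. Which disease pair stage 2
splits first is configurable via `CascadeConfig.stage_features`.
Hyperparameters (C ∈ {0.1, 1, 10, 100}, γ ∈ {scale, 0.01, 0.1, 1}) are
chosen by an inner stratified grid search (3 folds, reduced when a class
is smaller), seeded for determinism. The default kernel is RBF; the
sigmoid ("MLP") kernel is available but not default since it is not
positive semidefinite. A scan rejected at stage 1 can never receive a
disease label.

Evaluation reports 4-class accuracy plus binary sensitivity (any diseased
scan flagged with any disease label) and specificity
(healthy-as-healthy), and stratified k-fold cross-validation refits the
entire training pipeline per fold.

## The phantom generator

Each phantom renders, on a 0.05 background: a neurosensory band of
6-px constant-intensity sublayers cycling through (0.60, 0.36, 0.58,
0.34), a 4-px RPE stripe at 0.92 placed 78% of the way down the band, and
a striated outer band (0.62/0.34) to the choroid boundary. Boundaries are
a quadratic bow (default 18 px) plus a small sinusoid (3 px), both
configurable to zero for degenerate flat fixtures. The striation is
essential, not cosmetic: a homogeneous band has zero interior gradient
energy, so a coherency pipeline would classify its interior as background;
layered texture is exactly the property the structure tensor exploits in
clinical scans, which segment 7–8 sublayers.

Pathology: RE renders 8–12 hypo-reflective (0.12) elliptical cysts, one
per lateral slot so component counts are exact; CSCR lifts the
neurosensory band off the RPE over a parabolic dome (height 40–60 px) and
fills the gap with fluid at 0.10; ARMD elevates the RPE stripe over 4–7
parabolic drusen (height 18–35 px) with hypo-reflective deposit (0.14)
beneath each dome. Cohort geometry is jittered per scan from seeded,
class-conditional ranges: edema scans are thickened (175–230 px vs
115–150 px otherwise), drusen scans match healthy thickness. These
defaults reproduce the qualitative clinical feature structure: fluid-free
healthy scans, RE cyst energy above CSCR, ARMD separated by its RPE
features rather than thickness.

Noise is pixel-wise multiplication by `1 + a(G - 1)` with `G ~`
Gamma(k, 1/k) (unit mean; k = 4, amplitude a = 0.5 by default), followed
by additive Gaussian noise (σ = 0.015) — both disabled together at
a = 0, so amplitude 0 reproduces the noiseless template bit-exactly.
Rotation is applied last (bilinear) with edge replication rather than a
flat fill: a skewed acquisition brings adjacent tissue into the frame, it
does not truncate the retina, and a flat fill would clip the band at the
lateral extremes and corrupt the min-thickness feature.

What the phantom does **not** emulate: physical A-scan interferometry,
vascular shadowing, motion artifacts, vendor-specific intensity response,
type-2 CSCR (fluid breaching the RPE), geographic atrophy, or
choroidal neovascularization. Passing tests therefore demonstrate that
the pipeline recovers known geometry and separates the four rendered
phenotypes under speckle and skew — not clinical-grade performance on
scanner data. Default calibration on phantoms (3.5 µm axial, 11 µm
lateral per pixel) matches typical spectral-domain scanner resolution and
only scales feature units.

## Problem sizes

The bundled checks run at sizes chosen to exercise every stage at full
image resolution while staying interactive on one CPU: 20-phantom cohorts
for the boundary-recovery bounds (mean error ≤ 2 px noiseless, ≤ 4 px at
default speckle), a 200-scan cohort for 10-fold cross-validation
(accuracy ≥ 0.95), a 40-scan cohort for ±5° rotation stability (≥ 90%
unchanged labels), 100 random quantized images for exact Otsu/brute-force
agreement, and 1000 random PSD matrices for the coherency closed form
(max deviation ≤ 1e-10).

## Known limitations

- The column-wise first/last-edge tracer has no shape prior; pathologies
  that silence the coherency response over >50% of columns abort rather
  than degrade gracefully. A graph-based shortest-path tracer is the
  natural upgrade.
- The quadratic RPE baseline under-fits eyes with strong non-quadratic
  curvature, inflating `f6`–`f9` for them.
- Feature magnitudes (`f5` especially) are convention-dependent; models
  trained on one wavelet/normalization setting do not transfer.
- The reference feature table bundled for arithmetic cross-checks contains
  printed class summaries whose `f3` means are inconsistent with their own
  five cases; summaries here are always recomputed from the case rows, and
  only the internally consistent printed values are asserted in tests.
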