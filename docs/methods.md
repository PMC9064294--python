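# Methods

This package quantifies live-cell fluorescence microscopy of budding yeast
endocytosis: FRAP recovery of bleached structures, the density and lifetime
of endocytic patches, per-cell intensity measurements that reveal
concentration buffering by condensate formation, and two-channel
colocalization. Because raw microscopy of this kind is rarely
redistributable, every estimator is validated against a built-in simulator
whose event log is exact ground truth. This note records the models, the
parameters that matter, and the design choices made where the procedures
admit more than one reading.

## FRAP model and protocols

The recovery model is the single exponential

    value(t) = M · (1 − exp(−ln2 · t / τ½)),   t ≥ 0 after the bleach,

with mobile fraction M (the plateau: the proportion of molecules that
exchange during the experiment) and half-time τ½; the rate k = ln2/τ½ is
reported alongside and the identity k·τ½ = ln2 holds exactly by
construction. Fitting is nonlinear least squares (scipy `curve_fit`) on the
post-bleach samples, initialised from the tail mean (M₀) and a log-linear
fit of the residual amplitude (τ½,₀), bounded M ∈ [0, 1.5] and τ½ ∈
(0, 10·t_max]. M may exceed 1 for endocytic sites because ongoing site
maturation adds signal on top of recovery; the reference-channel filter
(below) is the guard against the worst of it.

Two normalisation protocols are implemented:

* **Condensate protocol.** Three ROI traces per event: background, whole
  cell, bleached structure. The corrected signal is
  F_corr = (roi − bg)/(cell − bg), which removes both background and
  acquisition photobleaching (the whole-cell signal decays under the same
  illumination). F_corr is then double-normalized: 0 at the first acquired
  post-bleach sample, 1 at the mean of the 5 s pre-bleach window.
  "Immediately after photobleaching" is read as the first acquired
  post-bleach sample, not an extrapolation to the bleach instant. The
  normalization is invariant to affine rescaling of the raw camera signal
  (tested). Individual normalized curves are aligned to bleach time,
  interpolated onto a common grid (step = median frame interval), and
  averaged pointwise; grid points covered by fewer than half the traces are
  dropped. Normalisation is per trace, before averaging. Events whose
  structure moves are excluded by an automated surrogate for visual QC:
  net lateral centroid displacement ≤ 0.3 µm, with an optional pre-bleach
  intensity-stability check (CV ≤ 10%) standing in for axial movement,
  which a 2D trace cannot observe.

* **Endocytic-site (TIRF) protocol.** Traces are the per-frame mean over
  pixels whose centers lie within 3 px of the patch centroid (29 pixels at
  integer centroids, by exhaustive enumeration) from background-subtracted
  movies; no further corrections are applied before the same 0-1
  normalization. Events are kept only when the actin-reporter channel
  peaks ≥ 60 s after the bleach, excluding sites already disassembling.

The bleach frame is detected as the largest single-step fractional drop of
the ROI trace (≥ 20% required), which on simulated noisy traces (noise sd
0.05, depth 0.8) lands within ±1 frame of truth in >99% of draws.

## Patch density and lifetime

Patches are detected per frame with a difference-of-Gaussians band-pass
(σ, 2σ with σ = 1.3 px, matched to the PSF), thresholded at
median + 8·MAD of the response — about 5.4σ of the band-passed noise, so
false positives are negligible while a nominal spot responds at ~10σ —
followed by local-maximum selection with a 2 px separation and sub-pixel
refinement by intensity-weighted centroid over a 5×5 window. The 2 px
separation (rather than 3) resolves spot pairs down to ~3 px apart, which
matters because projecting a sphere's surface onto the image plane
compresses positions near the cell rim.

Density follows the spherical-cell approximation: for a single unbudded
cell, membrane surface S = 4A where A is the projected cross-section area,
so density = N/(4A). Budding cells violate the approximation and are
excluded; a shape heuristic (solidity < 0.92 or eccentricity > 0.8) flags
them, overridable per cell. Counts come from a single time point by
default; a movie-averaged variant exists behind a flag.

Tracking links per-frame detections by solving, between consecutive
frames, the assignment problem "maximise the number of links with
displacement ≤ gate, then minimise total displacement" exactly
(Hungarian algorithm, `scipy.optimize.linear_sum_assignment`), with gap
closing for briefly undetected spots. Spots are first sorted canonically
so the result is deterministic and invariant to input order; the tests
verify equivalence with an exhaustive enumeration oracle on small
instances. Defaults are gate 2 px/frame, gap 1 frame. Lifetime is frames
spanned × frame interval; trajectories touching the first or last movie
frame are censored and excluded by default, and trajectories spanning
fewer than 3 frames are treated as detection flicker when Δt ≪ expected
lifetime. "Trajectory length × frame rate" is implemented as frame count ×
frame interval (the literal product with a rate has the wrong units).

In the closed-loop lifetime study the linking gate is widened to 3 px with
gap 2: when two patches come within the PSF scale they are detected as one
spot lying between them, and the gate must absorb that apparent centroid
jump (up to ~1.7 px plus localization noise) or tracks fragment, biasing
the mean lifetime down by ~4%. With the widened gate the residual bias is
the censoring exclusion alone (≈ −1.3% for gamma lifetimes, mean 90 s,
movie 1800 s), and five independent study seeds recover the mean within
±2.7%.

Condition comparisons use replicate means: the grand mean of a condition
is the mean of its per-dataset means, spread is the SD over replicate
means, and percent change is computed between grand means — reported as a
reduction, (1 − mean/mean_ref)·100. Formal inference (mixed models,
multiple-comparison procedures) is deliberately out of scope.

## Intensity measurements and classification

Cytosolic intensity is the mean of up to n 5×5-px box means, boxes sampled
(seeded, reproducibly) fully inside the cell mask and at a margin from any
excluded pixel. Exclusions are bright structures (smoothed image above the
within-cell median by an offset) and vacuoles (large dark intracellular
regions: below 0.5× the cell median, ≥ 0.5 µm²). The default margin is
3 px; the buffering study uses 6 px because condensate Gaussian tails at
high expression otherwise leak measurable intensity into nearby boxes.
Cellular intensity is the mean over the whole masked cell (whole volume
for stacks), after background subtraction.

Condensates are distinguished from normal patches by brightness: an object
is a condensate when its integrated intensity is ≥ 5× the dataset median
patch intensity, or its diameter ≥ a size threshold. Cells are classified
diffuse (no membrane objects), patches (discrete objects), or networks
(connected object area above a fraction of the cell area); the
patches/networks boundary is an exposed parameter, not a claim about any
particular dataset.

Colocalization: a green object colocalizes when any red centroid lies
within 0.25 µm (≈ 2 px at 0.1 µm/px; visual criteria in the field are
rarely quantified, so the distance is exposed). Fractions carry
Clopper-Pearson binomial intervals. Chance colocalization follows the
spatial Poisson null 1 − exp(−λπd²) and the tests verify that a decoupled
channel falls to that level.

## Preprocessing

Background subtraction uses the rolling-ball algorithm
(`skimage.restoration.rolling_ball`), radius 10 px by default (the radius
is rarely reported in practice; it is exposed in config). Movie
photobleaching is corrected by fitting a mono-exponential a·exp(−kt) to
within-mask frame means and dividing each frame by its fitted relative
decay; a fitted k ≤ 0 means nothing to correct and the movie is returned
unchanged with a warning. Mono-exponential was chosen over bi-exponential
for robustness on short movies. Cell masks come from a reference channel:
Gaussian smooth (σ = 2 px), Otsu threshold, hole filling, labelling,
small-object removal — a documented surrogate for threshold-based manual
masking; the threshold is data-derived, so masks are invariant to gain
changes. Coordinates are 0-based, pixel centers at integer positions,
row-major (y, x); config distances are physical (µm) and converted through
the pixel size.

## The simulator

The simulator emulates the statistical structure the analyses assume, not
optical realism. Spherical cells (radius 2–2.5 µm) are placed without
overlap; endocytic patches are born on the membrane as a homogeneous
Poisson process (uniform on the sphere), live i.i.d. lifetimes — gamma
with shape 4 and mean 90 s by default, matching sites that typically
persist one to two minutes — and are rendered as isotropic Gaussian spots
(σ = 1.3 px) at their orthographic projection. Patches on the far
hemisphere can be attenuated (default: none) or omitted entirely (TIRF
emulation). Condensates are brighter, wider Gaussians placed on the
membrane. The camera chain is bleaching → Poisson shot noise → additive
Gaussian read noise → clip at 0. A fixed seed makes stacks and truth
tables bit-identical.

Default study conditions, chosen once: pixel size 0.1 µm, frame interval
2 s, background 100 AU, read noise 2 AU, patch amplitude 50 AU (peak SNR 5
over the shot-noise floor of the background). The default birth rate is
5×10⁻⁴ µm⁻² s⁻¹ (steady-state density ≈ 0.045 µm⁻², about 2.3 live sites
per cell): a validation regime in which projected spots are typically
resolvable, chosen for estimator testing. Real cells are denser; at
realistic densities the projection of both hemispheres makes a fraction of
spot pairs closer than the diffraction scale, which no detector separates,
so counts there are lower bounds. Passing the closed-loop tests therefore
demonstrates estimator correctness in the regime where ground truth is
recoverable, not detector performance on arbitrarily crowded cells.

FRAP simulation maps the ideal corrected curve (plateau 1, drop by the
bleach depth, exponential recovery) back to raw camera units through a
whole-cell acquisition-bleaching channel and a constant background
channel, with Gaussian noise of sd 0.05 applied on the corrected scale.
The endocytic-site loop renders actual single-patch movies whose amplitude
follows the curve and calibrates pixel noise so the 3-px ROI trace carries
the same normalized noise level; these movies carry no global acquisition
bleaching, because the TIRF protocol applies no correction that could
remove it (TIRF illumination bleaches little outside the evanescent
field). The expression-series generator caps the cytosol at a saturation
level and deposits the excess into condensates with exact intensity
bookkeeping, reproducing the signature of concentration buffering by
phase separation: cytosolic mean flat, cellular mean rising.

What the simulator does not model — and what passing tests therefore do
not show about real data: defocus and depth-dependent aberrations, Airy
rings, patch motility and internalization motion, condensate
fusion/fission, uneven illumination, camera fixed-pattern noise,
segmentation on crowded or budding morphologies.

## Numerical choices and limitations

Tolerances follow the quantity's precision: model round trips are exact to
1e-6; Monte-Carlo checks use 3-standard-error bands or explicit binomial
intervals. Tie-breaks in tracking are deterministic (canonical spot order;
assignment on a fixed cost matrix). Degenerate inputs raise early with
named fields (config validation reports all violations at once). Problem
sizes in the studies — 36 and 14 FRAP events (matching the reference
ensembles), 60 snapshot fields for detection, six 1800 s movies for
lifetimes, 2×3×40 fields for the strain comparison — give each estimator
sampling error several times smaller than the band it is judged against.

Known limitations: the greedy-free but frame-local tracker is not a global
(LAP/Kalman) tracker and will mislink during dense crossing events; the
budding-cell heuristic is shape-based and should be reviewed on real
masks; the mobile fraction of endocytic sites conflates exchange with site
maturation; and replicate-mean comparisons provide point estimates and
spread, not hypothesis tests.
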