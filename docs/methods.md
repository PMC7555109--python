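# Methods

`meatmsi` predicts biochemical and microstructural parameters of beef
muscle from 19-band visible/near-infrared (405–1050 nm) multispectral
images. The pipeline is: reflectance calibration → per-band segmentation of
the intramuscular connective tissue (IMCT) and marbling → per-object shape
descriptors → size-class frequency histograms → PLS compression → small
neural-network regression. Because no public multispectral meat dataset
with matched ground truth exists, the package ships a synthetic-scene
simulator whose ground truth is exact by construction; everything below
documents both the model and what the simulator does and does not emulate.

## Synthetic scenes

A scene is a labeled tissue map rendered through per-tissue reflectance
spectra:

- **Perimysium** — a random branching polyline network, rasterized and
  dilated to `perimysium_width_px` (default 5 px). Strand count scales
  with `perimysium_density`; strands are drawn sequentially from a single
  stream so that increasing the density with a fixed seed only appends
  strands (this makes area monotone in density, a tested invariant).
- **Endomysium** — the boundary graph of a nearest-seed (Voronoi)
  tessellation with `n_fibers` cells, drawn 1–2 px wide. Parameter sets
  whose mean cell area falls below 4 px are rejected as degenerate.
- **Marbling fat** — round deposits seeded near the perimysium (fat is
  anatomically hosted in perimysial seams), drawn until the requested
  `fat_fraction` of the image area is covered.

Where tissues overlap, fat wins over perimysium, which wins over
endomysium; the lean/connective/fat masks therefore partition the image
exactly. Every geometric target is *computed from the masks*: area as
percentage of image pixels; network length as skeleton pixel count ×
pixel size per mm² of image; width as twice the mean Euclidean distance
transform sampled along the skeleton; fiber density as tessellation cell
count per mm². The biochemical targets (intramuscular fat in g/100 g DM,
total and insoluble collagen in mg OH-Prol/g DM) are affine maps of
`fat_fraction` and `perimysium_density` calibrated so that the default
parameter ranges reproduce the dataset ranges of the reference study
population (IMF 3.61–22.82, total collagen 2.94–10.45, insoluble collagen
2.01–6.87); `fat_fraction = 0` maps to the IMF minimum.

Rendering uses three smooth tissue spectra chosen to match the optics of
cut beef qualitatively: lean muscle is dark in the visible (myoglobin)
with a small reflectance maximum near 500 nm, bright in the NIR with a
maximum near 850 nm and a water dip at 970 nm; collagenous connective
tissue is whitish and brighter across the visible; marbling fat is
near-white in the visible but close to lean in the NIR apart from a
CH-related dip near 930 nm. The area-normalized mean spectrum of a scene
therefore shows the two-peak shape (local maximum 450–550 nm, global
maximum 800–900 nm) expected of such images, which is tested. Because a
real endomysium sheath (~1 µm) is far below the 86 µm/px sampling, the
endomysium is rendered as a partial-volume blend of connective and lean
reflectance (`endomysium_opacity`, default 0.35); without this, its
boundary web segments into one image-spanning component and the object
statistics collapse. Pixel noise is additive Gaussian with
`noise_sd = 0.01` reflectance.

The default pixel size, 86 µm/px, follows from imaging a 6 × 5 cm cut
face onto 700 × 575 px. At that scale the *histology-scale* geometry of
the reference population (e.g. hundreds of fibers per mm²) is physically
unresolvable, so the simulator's geometric ground truths are
self-consistent with its own masks rather than forced onto
histology-scale numbers; only the biochemical targets are mapped onto the
reference ranges. Per-sample parameters are drawn uniformly from
configurable ranges; per-sample seeds are the first word of
`SeedSequence([master_seed, index])`, giving independent, reproducible
streams below 2³¹.

**What the simulator does not emulate:** specular highlights and surface
moisture, breed- or muscle-specific spectral differences, spatially
correlated texture inside each tissue, non-uniform LED illumination
(available only as an optional linear gradient), and any covariance
between geometry and biochemistry beyond the generating parameters.
Passing recovery tests therefore demonstrate that the pipeline can invert
*this* image-formation model, not that it attains the same accuracy on
real muscle cubes.

## Segmentation

Each band is processed independently and deterministically:
contrast-limited adaptive histogram equalization (clip limit 0.01, 8 × 8
tiles), Prewitt gradient magnitude `sqrt(Gx² + Gy²)` with replicated
borders, thresholding, a morphological closing with disk structuring
elements, removal of components smaller than `min_object_area` (20 px),
and 8-connected component labeling (8-connectivity keeps thin diagonal
strands connected). The threshold is an exact Otsu: the between-class
variance is maximized over the *unique gradient values* rather than a
256-bin histogram, which makes the foreground set reproducible against a
brute-force oracle for float-valued gradients; gradients that are zero up
to floating-point cancellation (≤ 1e-12) yield an empty mask with a
warning rather than a spurious threshold. The closing is symmetric
(dilate 2 / erode 2): an asymmetric 2/1 closing net-grows every detected
edge by about a pixel, inflating the per-band foreground enough to pull
the across-band Dice against the true connective+fat mask below 0.6,
while the symmetric closing reaches ≈ 0.66 with near-identical recall.
All radii, the tile grid, the clip limit, the threshold method and the
minimum object area are exposed in `SegmentationParams`.

## Shape features and histogram cubes

For every labeled object, eight descriptors are measured with standard
moment/convex-hull definitions: area, major and minor axis lengths of the
second-moment ellipse, eccentricity, orientation, solidity (area / convex
hull area), extent (area / bounding box area), and perimeter (the
weighted boundary estimator of `regionprops`; perimeter estimators differ
by up to ~10 % and the choice is deliberately pinned by tests).
Orientation is reported in degrees in (−90°, 90°], measured from the
horizontal axis, positive when the major axis climbs to the right with
row 0 displayed on top — the MATLAB `regionprops` convention, chosen
because orientation histograms are the best-performing input feature.

Per sample and band, each descriptor's values are binned into B
equal-width classes between a minimum and maximum; B ranges over
100–1000 in steps of 100 in the study design, read as *bin counts*, which
is the only reading consistent with a report column like "900 classes".
The bin range defaults to the global (min, max) of the feature per band
across all samples, so bins are comparable between samples; a per-image
range policy is available, as is restriction of the range to training
samples. Values outside the range clip into the end bins; the last bin is
closed so the maximum lands inside. Histograms stack into a
samples × B × 19 cube, the regression input.

## Regression

Each sample's unfolded histogram vector (band-major order) is scaled to
unit area and mean-centered, then compressed to 10 PLS1 latent variables
fitted against one target at a time (10 LVs gather well over 90 % of X
variance on these cubes). The regressor is a 10–n1–n2–1 feed-forward
network with tanh hidden units and a linear output, trained by
Levenberg–Marquardt: the exact residual Jacobian is formed analytically
(the network has at most a few hundred weights) and each epoch solves
`(JᵀJ + λI)δ = −Jᵀr`, accepting the step only when the training SSE
decreases and adapting λ by factors of 10, so the training loss is
monotone non-increasing by construction. Targets are standardized to zero
mean/unit variance on the training set for conditioning and
back-transformed for reporting. Early stopping tracks validation RMSE
with a patience of 6 accepted epochs (the common Levenberg–Marquardt
`max_fail` default) and restores the best-validation weights; the epoch
they were recorded at is reported.

Data are split 70/15/15 into training/validation/test by a seeded random
permutation (train and validation sizes rounded, test takes the
remainder: 240 → 168/36/36, 10 → 7/2/1). The model grid scans n1, n2 ∈
{2, …, 8} (49 combinations — the literal reading of "2 to 8"; the
occasionally quoted 8 × 8 = 64 grid is available by widening the
configurable range). Selection is two-stage: the minimum-RMSEP
configuration per bin count, then the global minimum across bin counts,
ties broken toward fewer neurons and then fewer bins.

### Selection bias, and why the headline metric is optimistic

The default protocol — unit-area normalization and PLS fitted on **all**
samples, final model chosen by the **test-set** RMSE — replicates common
practice in the source literature of this pipeline. It is statistically
leaky: with tens of thousands of histogram columns and ~200 samples, PLS
weights computed from all samples effectively encode the response, and
test-set selection then rewards chance. On our synthetic datasets this
protocol yields test R² ≈ 1.0 for intramuscular fat, reproducing the
reported performance level of such studies almost regardless of how much
genuine image signal is present. The package therefore also implements
`strict=True`: centering means, histogram ranges and PLS are fitted on
the training set only, and selection uses validation RMSE. Strict-mode
scores on the same data are far lower (near zero at small sample sizes)
and are the honest measure of image-derived signal. Both modes are
first-class and tested; the default mirrors the published protocol, and
this paragraph is the caveat.

## Problem sizes

The packaged recovery study (`meatmsi.study.run_recovery_study`, used by
`scripts/acceptance.py` and the acceptance test) simulates 240 scenes at
320 × 392 px — the acquisition aspect ratio at roughly a third of the
full 575 × 700 pixel count, with `n_fibers` scaled with image area — and
runs orientation histograms at B = 900 with the full 49-point grid. This
size was chosen so the complete study, segmentation included, runs in a
few minutes on one CPU; all other conditions stay at their defaults.
Unit tests use 64 × 80 to 192 × 232 scenes for the same reason.

## Numerical choices and degenerate inputs

- Reflectance correction is `(raw − dark)/(white − dark)` clipped to
  [0, 1]; a white reference not exceeding the dark reference anywhere is
  an error, not a silent NaN.
- Constant images pass through contrast enhancement unchanged; an image
  smaller than one CLAHE tile is rejected.
- A degenerate histogram range (max = min) produces a single bin holding
  every value; a band with no objects anywhere gets unit-interval edges
  and all-zero counts.
- Samples with empty histograms stay at zero through unit-area
  normalization (with a warning) instead of dividing by zero.
- `fit_pls` refuses more latent variables than the achievable rank of the
  training matrix, naming the rank.
- Non-finite training loss aborts network training with the offending
  configuration in the message; a Levenberg–Marquardt λ overflowing 1e10
  ends training at the current weights.
- Every stage is bit-reproducible under fixed seeds; segmentation carries
  no random state at all.

## Known limitations

- Real acquisition effects (specularities, moisture, illumination
  non-uniformity, registration error between the two cube acquisitions
  per muscle) are not modeled.
- The geometric ground-truth scale is the simulator's own 86 µm/px
  raster, not histology scale (see above).
- The default selection protocol is optimistically biased by design (see
  above); use `strict=True` for defensible generalization estimates.
- Segmentation quality is assessed against the simulator's own masks
  (Dice ≈ 0.66 at default settings); no histology-verified benchmark
  exists in the package.
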