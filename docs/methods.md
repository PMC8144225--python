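# Methods

This note describes the models and numerical choices behind `cytoquant`: a
pipeline that quantifies cytoskeletal fiber orientation, punctate adhesion
sites and cell-migration behavior, together with a synthetic-data generator
that provides ground truth for validating every stage.

## Orientation analysis

### Model

Local fiber orientation is read from the 2-D structure tensor. For a
normalized image *I*, gradients are computed with derivative-of-Gaussian
filters at scale σ_g (default 1 px), and the tensor components ⟨I_x²⟩,
⟨I_x I_y⟩, ⟨I_y²⟩ are smoothed with a Gaussian at the integration scale σ_T
(default 2 px, i.e. 60 nm at the default 30 nm pixel size). With eigenvalues
λ₁ ≥ λ₂ ≥ 0:

* **orientation** θ — the axis of the λ₂ eigenvector (along the structure),
  axial degrees in [−90°, 90°), counter-clockwise from the image x-axis with
  y pointing up;
* **coherency** C = (λ₁ − λ₂)/(λ₁ + λ₂) ∈ [0, 1] — 1 for perfectly aligned
  local structure, 0 for isotropic neighborhoods;
* **energy** E = λ₁ + λ₂ — the smoothed squared gradient magnitude.

Only one smoothing scale governs orientation locality; it is assigned to the
integration scale, with the derivative scale fixed at 1 px, following
standard two-scale structure-tensor practice. Both are configurable.
Energy is defined as the tensor trace rather than its square root; since the
exclusion rule below is a fraction-of-maximum threshold, any monotone
transform applied consistently selects a similar pixel set, and the trace
convention is fixed and documented here.

Images are min/max-normalized to [0, 1] before tensor computation (constant
images normalize to zeros with a warning). Gaussian filtering uses reflect
padding; this is part of the bit-exactness contract of the pipeline.

### Histograms, alignment, spread

Within a (manually provided) cell mask, pixels whose coherency **or** energy
falls below 10 % of the respective per-image masked maximum are excluded.
Pixels with exactly zero energy are always excluded, so a structureless
(constant) image is rejected entirely by the energy criterion rather than
passing vacuous 0 ≥ 0 thresholds. The maxima are taken per image over mask
pixels, not over a whole dataset.

Surviving pixels contribute their coherency as weight to a 180-bin, 1°-wide
axial histogram on [−90°, 90°). 1° granularity sits below the PSF-limited
angular resolution of the rendered fibers, so binning does not dominate the
spread estimate.

The **dominant orientation** of a reference channel (microtubules) is the
coherency-weighted axial circular mean: angles are doubled onto the full
circle, averaged as weighted unit vectors, and halved back. This is invariant
to the ±90° wrap (e.g. equal weight at +80° and −80° averages to ±90°, not
0°). A plain arithmetic-mean variant is provided for comparison
(`mean_orientation_arithmetic`); the circular mean is the default because the
arithmetic mean is wrap-sensitive.

Each actin histogram is aligned to the tubulin dominant orientation by a
circular shift of a whole number of bins (nearest bin to the reference
angle). Whole-bin shifting conserves total weight exactly; the residual
alignment error is at most half a bin (0.5°).

The **spread** of an aligned histogram is the weighted standard deviation of
bin-center angles, computed linearly on the (−90°, 90°] support: after
alignment the mass is centered near 0°, so a linear (non-circular) dispersion
is the natural statistic and equals the std of the sample in which each bin
center is repeated proportionally to its weight.

Group histograms average unit-normalized per-cell histograms; the per-bin
95 % confidence interval is mean ± t(0.975, n−1)·SEM. Orientation fields can
be rendered in HSB space (hue = angle, saturation = coherency, brightness =
normalized intensity).

## Adhesion-site analysis

The adhesion channel is normalized by subtracting the minimum and dividing by
the 99.9th-percentile of the shifted intensities (values above the percentile
exceed 1 and are not clipped). A scale space of Laplacian-of-Gaussian
responses is computed at σ = 3, 4, 5, 6, 7 px (90–210 nm at 30 nm/px). Each
slice is scale-normalized (multiplied by σ²) and sign-flipped so bright blobs
give positive maxima comparable across scales; a scale-normalized LoG peaks
for a bright disk of radius r at σ ≈ r/√2, i.e. it reports blobs of radius
√2 σ. The truncated discrete LoG kernel does not sum exactly to zero; the
implementation subtracts this DC leak (kernel-sum × Gaussian-smoothed image)
so constant images give exactly zero response.

Detections are local maxima of the joint (scale, row, col) stack: a candidate
must dominate its up-to-26 neighbors; plateaus of equal value whose exterior
neighbors are all strictly lower are collapsed to the lexicographically
smallest coordinate, making the output deterministic under ties. A detection
is kept if its response exceeds 0.25, its center lies inside the mask, and
its exact Euclidean distance-transform value is at least the boundary
exclusion radius (default 1 µm; "closer than 1 µm" is read as strictly less,
so a site exactly at 1 µm is kept). The per-cell density is the count divided
by the mask area (pixel count × pixel area). No minimum inter-detection
distance is imposed beyond maximum uniqueness.

## Migration analysis

For a track of ≥ 2 samples with strictly increasing times: displacement is
the first-to-last Euclidean distance; path length (= cumulative distance) is
the sum of per-interval displacements; track velocity is displacement over
duration; mean instantaneous speed is the mean of per-interval speeds, which
generalizes cleanly to irregular frame intervals (regular-interval data are a
special case); persistence is displacement over path length, set to 0 with a
`stationary` flag when the path length is 0, keeping summary tables total.
Missing frames are treated as single longer intervals, never interpolated,
matching manual-tracking exports. Neurosphere radial outgrowth is the radius
of the furthest migrated cell at each timepoint divided by the initial sphere
radius.

The CSV reader accepts the native dialect
(`track_id,frame,t_min,x_um,y_um`) and a tracking-tool export dialect with up
to 3 preamble rows, pixel coordinates (converted via a pixel-size argument)
and a time column reconstructed from the frame index when absent.

## Two-sample statistics

Welch's two-tailed t-test uses t = (x̄ − ȳ)/√(s²ₓ/nₓ + s²ᵧ/nᵧ) with
Welch–Satterthwaite degrees of freedom; the implementation broadcasts over
leading axes so large null-calibration studies run vectorized. The
Mann–Whitney/Wilcoxon rank-sum test uses midranks for ties; for combined
n ≤ 12 the null is enumerated exactly over all group assignments (the
two-tailed p is the null probability of a U at least as extreme in either
tail, which reproduces p = 2/6 for the fully separated 2-vs-2 case), and
larger samples use the normal approximation with tie correction and a
continuity correction. The exact/approximate switch at n = 12 is
deterministic and documented. No multiple-testing correction is applied:
the pipeline makes single planned comparisons, and p-values are returned raw.

## Synthetic data

The generator renders the statistical structure the analyses assume, with
complete ground truth:

* **Fiber scenes** — straight anti-aliased segments (clipped distance-ramp
  profile of the requested width, additive where fibers cross) whose axial
  angles are μ + N(0, s) wrapped to the 180° axial period. A wrapped normal
  is used rather than a von Mises so the dispersion is parameterized directly
  by an angular standard deviation. The noise-free scene is blurred with a
  Gaussian PSF (default 45 nm, a STED-like effective PSF at 30 nm pixels),
  scaled so the brightest point has expectation `photons_peak` (default 200)
  over a `background` offset (default 10), Poisson-sampled per pixel and
  quantized to 16 bits; counts above 65535 saturate with a logged warning,
  mirroring detector behavior. Defaults (40 fibers of length 120 px and
  width 3 px in a 256² frame) give dense, overlapping bundles at an SNR
  comparable to photon-counting super-resolution data.
* **Blob scenes** — non-overlapping Gaussian puncta with σ sampled in a
  configurable range, placed by rejection sampling (budget 100 × n_blobs
  attempts, with an error naming the achievable count on failure). Planted
  centers keep a configurable clearance from the mask boundary (default
  34 px ≈ 1.02 µm at 30 nm/px) so ground truth is recoverable under the
  detector's default 1 µm boundary exclusion; setting the clearance to 0
  plants blobs near the border to exercise the exclusion rule itself.
* **Tracks** — persistent random walks: the heading accumulates Gaussian
  increments of variance 2·Δt/τ per step (rotational diffusion with
  correlation time τ), step length = speed × Δt, with optional positional
  noise added to the reported coordinates only. τ = ∞ (`BALLISTIC`) gives
  straight lines; τ = 0 draws a fresh uniform heading each step. Defaults
  (10 min frame interval, 1 µm/min, τ = 60 min) mimic progenitor-cell random
  migration assays; 15 min sampling mirrors slower slice-imaging protocols.

Each generator draws from `numpy.random.default_rng([stream_id, seed])` with
a fixed per-operation stream id, so outputs are bit-reproducible and adding a
call to one generator never reshuffles another.

**What passing on synthetic data does not show:** the scenes contain no
curved or branching filaments, no depletion-beam or detector physics beyond
Poisson shot noise, no drift, bleaching, crosstalk or 3-D structure, and the
masks are simple rectangles. Recovery results demonstrate correctness of the
estimators under the stated model, not instrument-level fidelity.

## Pipeline and reproducibility

`run_compare` executes the two-group workflow per cell (normalize → tensor
fields for both channels → tubulin dominant orientation → aligned actin
histogram → spread), averages histograms per group with CIs, and compares
spreads with Welch's test. Per-cell failures are recorded in the report and
the run continues; at least 2 analyzable cells per group are required. All
writers are deterministic (no timestamps, sorted JSON keys, fixed float
formatting, TIFF datetime disabled), so reruns with the same seed and inputs
are byte-identical. The manifest records the full configuration, seed and
software version and is sufficient to re-run any result. When a configured
pixel size conflicts with TIFF resolution tags, the configuration wins with a
warning, because exported microscopy metadata is frequently wrong.

## Problem sizes in the validation suite

The test and acceptance runs use 256² fiber scenes (40 fibers, peak 500
photons; 10 cells per dispersion group), one 512² blob scene with 50 planted
spots, 10–1000-walk track sweeps, and a 10,000-replicate Welch null
calibration at n = 43 per group. These sizes give stable statistics (e.g.
the null rejection-rate standard error is ≈ 0.2 %) while keeping a full run
in the low minutes on one CPU.

## Known limitations

* Masks are inputs; no segmentation is provided.
* The spread statistic assumes unimodal, roughly centered aligned
  distributions; strongly bimodal orientation fields are summarized poorly
  by a single standard deviation.
* The LoG detector reports grid scales only (no sub-scale interpolation), so
  detected σ is accurate to one grid step.
* Blob ground truth stores integer pixel centers; sub-pixel localization is
  out of scope.
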