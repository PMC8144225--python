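# cytoquant

Quantification of cytoskeletal organization and cell motility from
super-resolution fluorescence microscopy, for cell biologists comparing
genotypes or treatments at the level of single cells:

* **Fiber orientation** — per-pixel orientation θ, coherency
  C = (λ₁ − λ₂)/(λ₁ + λ₂) and energy E = λ₁ + λ₂ from the structure tensor
  of a normalized image (integration scale 2 px = 60 nm at 30 nm pixels);
  coherency-weighted axial orientation histograms over [−90°, 90°), excluding
  pixels whose coherency or energy falls below 10 % of the per-cell maximum;
  alignment of each actin histogram to the dominant (coherency-weighted axial
  circular mean) orientation of the microtubule channel; group averages with
  t-based 95 % confidence bands; and a weighted-standard-deviation **spread**
  statistic per cell, compared between groups with a two-tailed Welch t-test.
* **Adhesion sites** — bright puncta detected as local maxima of a
  scale-normalized Laplacian-of-Gaussian scale space (σ = 3–7 px; a blob of
  radius r peaks at σ ≈ r/√2), with a response threshold of 0.25, a 1 µm
  cell-boundary exclusion zone, and density = count / cell area.
* **Migration** — per-track velocity (displacement/duration), mean
  instantaneous speed, path length (= cumulative distance), persistence
  (displacement/path length), and neurosphere radial outgrowth normalized to
  the initial sphere radius; Welch and exact/asymptotic Mann–Whitney
  rank-sum tests for group comparisons.
* **Synthetic ground truth** — fiber fields with controlled axial-angle
  dispersion, Gaussian-PSF blur and Poisson photon noise on 16-bit counts;
  non-overlapping Gaussian puncta at known positions and scales; persistent
  random-walk tracks — so every estimator is validated by parameter
  recovery, not by eye.

## Worked example

```python
from cytoquant import *

# a synthetic actin field: 40 fibers at 20 deg +/- 10 deg, 30 nm pixels
spec = FiberSceneSpec(image_shape=(256, 256), n_fibers=40,
                      mean_angle_deg=20.0, angular_std_deg=10.0,
                      photons_peak=500)
frame, mask, truth = make_fiber_image(spec, seed=7)

field = structure_tensor_field(normalize_minmax(frame))
ref = dominant_orientation(field, mask)
hist = align_histogram(orientation_histogram(field, mask), ref)
print(f"dominant orientation: {ref:.2f} deg")
print(f"orientation spread:   {orientation_spread(hist):.2f} deg")
```

prints

```
dominant orientation: 23.70 deg
orientation spread:   8.58 deg
```

The dominant orientation estimates the mean fiber angle of this finite
40-fiber sample (generator mean 20°), and the spread of 8.58° recovers the
generator's 10° angular dispersion slightly shrunk by coherency weighting of
overlapping fibers. Adhesion detection on a 50-puncta scene and track
metrics on persistent random walks work the same way:

```python
bspec = BlobSceneSpec(n_blobs=50, blob_sigma_range_px=(3.0, 6.0),
                      min_separation_px=16, photons_peak=300)
bframe, bmask, btruth = make_blob_image(bspec, seed=7)
blobs = detect_adhesion_sites(log_response_stack(normalize_percentile(bframe)), bmask)
dens = adhesion_density(blobs, bmask)
# -> 50 detected of 50 planted; density 0.2977 sites/um^2 over 168.0 um^2

tracks = make_tracks(TrackSceneSpec(n_tracks=30, n_frames=90,
                                    frame_interval_min=10.0,
                                    speed_um_min=1.0,
                                    persistence_time_min=60.0), seed=7)
metrics_table(tracks)[["velocity_um_min", "persistence"]].mean()
# -> velocity 0.345 um/min, persistence 0.345 (meandering walks cover less
#    net distance than their 1 um/min instantaneous speed)
```

A command-line interface mirrors the library:

```sh
cytoquant simulate fibers --seed 1 --out scene/
cytoquant orient --actin scene/fibers.tif --tubulin scene/fibers.tif \
                 --mask scene/mask.tif --out results/
cytoquant adhesions --image cell.tif --mask mask.tif --out adh/
cytoquant tracks --in tracks.csv --out motility/
cytoquant compare --group-a a.csv --group-b b.csv --test welch --out report.json
```

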