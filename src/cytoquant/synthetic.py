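"""Synthetic microscopy scenes and migration tracks with known ground truth.

Three generators emulate the data the analysis modules consume:

* :func:`make_fiber_image` -- fields of straight, anti-aliased fiber
  segments whose axial angles are drawn from a wrapped normal around a mean
  orientation, blurred with a Gaussian PSF and corrupted with per-pixel
  Poisson photon noise on 16-bit counts.  The sampled angles are the ground
  truth the orientation analysis should recover.
* :func:`make_blob_image` -- non-overlapping Gaussian puncta (adhesion-site
  stand-ins) at known positions and scales inside a mask.
* :func:`make_tracks` -- persistent random walks sampled at a fixed frame
  interval (10 or 15 min in the live-imaging protocols this mirrors), with
  optional positional noise.

Determinism: each generator derives its own random stream from the user seed
via ``numpy.random.default_rng([STREAM_ID, seed])`` with a fixed per-operation
stream id, so adding a call to one generator never reshuffles another.

What the scenes do NOT model: depletion-beam physics, detector read noise or
afterpulsing, drift, bleaching, 3-D structure, or fiber curvature.  Photon
shot noise is Poisson-only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .orientation import ImageFrame, wrap_axial

logger = logging.getLogger("cytoquant")

# fixed per-operation stream ids for seed splitting
_STREAM_FIBERS = 101
_STREAM_BLOBS = 102
_STREAM_TRACKS = 103

U16_MAX = 65535


def _rng(stream: int, seed: int) -> np.random.Generator:
    return np.random.default_rng([stream, int(seed)])


# ---------------------------------------------------------------------------
# scene specifications
# ---------------------------------------------------------------------------

@dataclass
class FiberSceneSpec:
    """A field of straight fibers with controlled axial-angle dispersion.

    ``mean_angle_deg`` (mu) and ``angular_std_deg`` (s) parameterize the
    wrapped-normal (period 180 deg) from which fiber axial angles are drawn;
    they are the ground truth recovered downstream.  Intensities are photon
    counts: fibers peak near ``photons_peak`` on a ``background`` offset.
    """

    image_shape: tuple[int, int] = (256, 256)
    pixel_size_nm: float = 30.0
    n_fibers: int = 40
    mean_angle_deg: float = 0.0
    angular_std_deg: float = 10.0
    fiber_length_px: float = 120.0
    fiber_width_px: float = 3.0
    psf_sigma_nm: float = 45.0
    photons_peak: float = 200.0
    background: float = 10.0
    mask_margin_px: int = 8

    def __post_init__(self) -> None:
        rows, cols = self.image_shape
        if rows <= 0 or cols <= 0:
            raise ValueError("image_shape must be positive")
        if self.n_fibers < 0:
            raise ValueError("n_fibers must be >= 0")
        if self.angular_std_deg < 0:
            raise ValueError("angular_std_deg must be >= 0")
        if not -90.0 <= self.mean_angle_deg < 90.0:
            raise ValueError("mean_angle_deg must lie in [-90, 90)")
        if not self.photons_peak > self.background >= 0:
            raise ValueError("require photons_peak > background >= 0")
        if self.fiber_length_px <= 0 or self.fiber_width_px <= 0:
            raise ValueError("fiber geometry must be positive")
        if self.psf_sigma_nm < 0 or self.pixel_size_nm <= 0:
            raise ValueError("psf_sigma_nm >= 0 and pixel_size_nm > 0 required")
        if 2 * self.mask_margin_px >= min(rows, cols):
            raise ValueError("mask_margin_px leaves no interior")


@dataclass
class BlobSceneSpec:
    """Bright Gaussian puncta at random non-overlapping positions.

    ``boundary_clearance_px`` keeps planted centers that far inside the mask
    boundary; the default (34 px = 1.02 um at 30 nm/px) clears the detector's
    default 1 um boundary-exclusion zone so every planted blob is recoverable.
    Set it to 0 to plant blobs near the border (e.g. to exercise the
    exclusion rule itself).
    """

    image_shape: tuple[int, int] = (512, 512)
    pixel_size_nm: float = 30.0
    n_blobs: int = 50
    blob_sigma_range_px: tuple[float, float] = (3.0, 7.0)
    min_separation_px: float = 15.0
    photons_peak: float = 200.0
    background: float = 10.0
    mask_margin_px: int = 40
    boundary_clearance_px: float = 34.0

    def __post_init__(self) -> None:
        rows, cols = self.image_shape
        if rows <= 0 or cols <= 0:
            raise ValueError("image_shape must be positive")
        if self.n_blobs < 0:
            raise ValueError("n_blobs must be >= 0")
        lo, hi = self.blob_sigma_range_px
        if not 0 < lo <= hi:
            raise ValueError("blob_sigma_range_px must satisfy 0 < min <= max")
        if self.min_separation_px <= 2 * hi:
            raise ValueError("min_separation_px must exceed 2 x max blob sigma "
                             "(non-overlap)")
        if not self.photons_peak > self.background >= 0:
            raise ValueError("require photons_peak > background >= 0")
        if self.boundary_clearance_px < 0:
            raise ValueError("boundary_clearance_px must be >= 0")
        if 2 * (self.mask_margin_px + self.boundary_clearance_px) >= min(rows, cols):
            raise ValueError("margins leave no interior for blob centers")


BALLISTIC = float("inf")  # sentinel: no turning, straight-line motion


@dataclass
class TrackSceneSpec:
    """Persistent random walks at a fixed frame interval.

    ``persistence_time_min`` is the directional correlation time of the
    heading; ``BALLISTIC`` (infinity) gives straight lines.  The default
    10 min frame interval matches routine live-imaging protocols (15 min for
    slower acquisitions).
    """

    n_tracks: int = 30
    n_frames: int = 90
    frame_interval_min: float = 10.0
    speed_um_min: float = 1.0
    persistence_time_min: float = 60.0
    positional_noise_um: float = 0.0

    def __post_init__(self) -> None:
        if self.n_tracks < 0 or self.n_frames < 2:
            raise ValueError("need n_tracks >= 0 and n_frames >= 2")
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be positive")
        if self.speed_um_min < 0 or self.positional_noise_um < 0:
            raise ValueError("speed and noise must be >= 0")
        if self.persistence_time_min < 0:
            raise ValueError("persistence_time_min must be >= 0")


@dataclass
class GroundTruth:
    """What was rendered: the quantities downstream analyses should recover."""

    fiber_angles_deg: list[float] = field(default_factory=list)
    label_map: np.ndarray | None = None  # per-pixel fiber angle, NaN = background
    blobs: list[tuple[int, int, float]] = field(default_factory=list)  # (row, col, sigma)
    track_params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        d = {
            "fiber_angles_deg": [float(a) for a in self.fiber_angles_deg],
            "blobs": [[int(r), int(c), float(s)] for r, c, s in self.blobs],
            "track_params": self.track_params,
        }
        if self.label_map is not None:
            lm = np.where(np.isnan(self.label_map), None, self.label_map)
            d["label_map"] = lm.tolist()
        return json.dumps(d, sort_keys=True)


# ---------------------------------------------------------------------------
# rendering helpers
# ---------------------------------------------------------------------------

def _render_segment(canvas: np.ndarray, r0: float, c0: float, r1: float,
                    c1: float, width: float) -> np.ndarray:
    """Add an anti-aliased segment of the given width to ``canvas`` and return
    the contribution of this segment alone.

    The intensity profile is a clipped distance ramp: 1 on the segment core,
    falling linearly to 0 over the last pixel of the half-width, which gives
    sub-pixel-smooth edges without modeling filament physics.
    """
    rows, cols = canvas.shape
    pad = width / 2.0 + 1.5
    rmin = max(int(np.floor(min(r0, r1) - pad)), 0)
    rmax = min(int(np.ceil(max(r0, r1) + pad)) + 1, rows)
    cmin = max(int(np.floor(min(c0, c1) - pad)), 0)
    cmax = min(int(np.ceil(max(c0, c1) + pad)) + 1, cols)
    if rmin >= rmax or cmin >= cmax:
        return np.zeros((0, 0))
    rr, cc = np.mgrid[rmin:rmax, cmin:cmax]
    dr, dc = r1 - r0, c1 - c0
    seg_len2 = dr * dr + dc * dc
    if seg_len2 == 0:
        dist = np.hypot(rr - r0, cc - c0)
    else:
        t = ((rr - r0) * dr + (cc - c0) * dc) / seg_len2
        t = np.clip(t, 0.0, 1.0)
        dist = np.hypot(rr - (r0 + t * dr), cc - (c0 + t * dc))
    contrib = np.clip(width / 2.0 + 0.5 - dist, 0.0, 1.0)
    canvas[rmin:rmax, cmin:cmax] += contrib
    full = np.zeros_like(canvas)
    full[rmin:rmax, cmin:cmax] = contrib
    return full


def _to_counts(expected: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Poisson-sample expected photon counts and quantize to 16 bit."""
    counts = rng.poisson(expected)
    n_sat = int(np.count_nonzero(counts > U16_MAX))
    if n_sat:
        logger.warning("16-bit saturation: clipping %d pixels to %d", n_sat, U16_MAX)
        counts = np.minimum(counts, U16_MAX)
    return counts.astype(np.uint16)


def _margin_mask(shape: tuple[int, int], margin: int) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    mask[margin:shape[0] - margin, margin:shape[1] - margin] = True
    return mask


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def make_fiber_image(spec: FiberSceneSpec, seed: int):
    """Render a fiber scene; returns ``(frame, mask, truth)``.

    Fiber axial angles are mu + N(0, s) wrapped to the 180-degree axial
    domain; fiber centers are uniform inside the masked region.  The noise-free
    scene is blurred with the PSF, scaled so its brightest point has expectation
    ``photons_peak`` over a ``background`` offset, then Poisson-sampled.
    """
    rng = _rng(_STREAM_FIBERS, seed)
    rows, cols = spec.image_shape
    canvas = np.zeros((rows, cols), dtype=float)
    best = np.zeros_like(canvas)  # strongest single-fiber contribution
    label_map = np.full((rows, cols), np.nan)

    angles = wrap_axial(spec.mean_angle_deg
                        + rng.normal(0.0, spec.angular_std_deg, size=spec.n_fibers))
    m = spec.mask_margin_px
    for ang in angles:
        r0c = rng.uniform(m, rows - m)
        c0c = rng.uniform(m, cols - m)
        # axial angle CCW from x-axis with y up => array direction (-sin, cos)
        a = np.radians(ang)
        dr, dc = -np.sin(a), np.cos(a)
        half = spec.fiber_length_px / 2.0
        contrib = _render_segment(canvas, r0c - half * dr, c0c - half * dc,
                                  r0c + half * dr, c0c + half * dc,
                                  spec.fiber_width_px)
        if contrib.size:
            better = contrib > best
            label_map[better] = ang
            best = np.maximum(best, contrib)

    psf_px = spec.psf_sigma_nm / spec.pixel_size_nm
    blurred = ndimage.gaussian_filter(canvas, psf_px, mode="reflect") if psf_px > 0 else canvas
    peak = blurred.max()
    if peak > 0:
        expected = spec.background + (spec.photons_peak - spec.background) * blurred / peak
    else:
        expected = np.full_like(blurred, spec.background)

    frame = ImageFrame(_to_counts(expected, rng), spec.pixel_size_nm, 16)
    mask = _margin_mask((rows, cols), m)
    truth = GroundTruth(fiber_angles_deg=[float(a) for a in angles],
                        label_map=label_map)
    return frame, mask, truth


def make_blob_image(spec: BlobSceneSpec, seed: int):
    """Render non-overlapping Gaussian puncta; returns ``(frame, mask, truth)``.

    Centers are rejection-sampled uniformly inside the mask with a retry
    budget of ``100 * n_blobs``; if the packing is infeasible the error names
    the count that was achievable.
    """
    rng = _rng(_STREAM_BLOBS, seed)
    rows, cols = spec.image_shape
    m = spec.mask_margin_px
    inner = m + spec.boundary_clearance_px
    lo, hi = spec.blob_sigma_range_px

    centers: list[tuple[float, float]] = []
    sigmas: list[float] = []
    budget = 100 * max(spec.n_blobs, 1)
    attempts = 0
    while len(centers) < spec.n_blobs and attempts < budget:
        attempts += 1
        r = rng.uniform(inner, rows - inner)
        c = rng.uniform(inner, cols - inner)
        if all(np.hypot(r - rr, c - cc) >= spec.min_separation_px
               for rr, cc in centers):
            centers.append((r, c))
            sigmas.append(float(rng.uniform(lo, hi)))
    if len(centers) < spec.n_blobs:
        raise ValueError(
            f"blob packing infeasible: placed {len(centers)} of {spec.n_blobs} "
            f"blobs within {budget} attempts; reduce n_blobs or min_separation")

    expected = np.full((rows, cols), float(spec.background))
    amp = spec.photons_peak - spec.background
    rr, cc = np.mgrid[0:rows, 0:cols]
    for (r, c), s in zip(centers, sigmas):
        expected += amp * np.exp(-((rr - r) ** 2 + (cc - c) ** 2) / (2 * s * s))

    frame = ImageFrame(_to_counts(expected, rng), spec.pixel_size_nm, 16)
    mask = _margin_mask((rows, cols), m)
    truth = GroundTruth(blobs=[(int(round(r)), int(round(c)), s)
                               for (r, c), s in zip(centers, sigmas)])
    return frame, mask, truth


def make_tracks(spec: TrackSceneSpec, seed: int) -> "list":
    """Persistent random walks; returns a list of :class:`~cytoquant.tracks.Track`.

    The heading turns by Gaussian increments with variance
    ``2 * dt / persistence_time`` per step (rotational diffusion with the
    requested correlation time); ``persistence_time = BALLISTIC`` freezes the
    heading.  Step length is ``speed * dt``; positional noise is added to the
    reported coordinates only (it does not feed back into the walk).
    """
    from .tracks import Track  # local import avoids a cycle at import time

    rng = _rng(_STREAM_TRACKS, seed)
    dt = spec.frame_interval_min
    n_steps = spec.n_frames - 1
    if np.isinf(spec.persistence_time_min):
        turn_sd = 0.0
    elif spec.persistence_time_min == 0:
        turn_sd = None  # uncorrelated: fresh uniform heading each step
    else:
        turn_sd = np.sqrt(2.0 * dt / spec.persistence_time_min)

    out = []
    t = np.arange(spec.n_frames, dtype=float) * dt
    for tid in range(spec.n_tracks):
        heading = rng.uniform(0.0, 2 * np.pi)
        x = np.zeros(spec.n_frames)
        y = np.zeros(spec.n_frames)
        for k in range(n_steps):
            if turn_sd is None:
                heading = rng.uniform(0.0, 2 * np.pi)
            elif turn_sd > 0:
                heading += rng.normal(0.0, turn_sd)
            x[k + 1] = x[k] + spec.speed_um_min * dt * np.cos(heading)
            y[k + 1] = y[k] + spec.speed_um_min * dt * np.sin(heading)
        if spec.positional_noise_um > 0:
            x = x + rng.normal(0.0, spec.positional_noise_um, size=spec.n_frames)
            y = y + rng.normal(0.0, spec.positional_noise_um, size=spec.n_frames)
        out.append(Track(track_id=tid, t_min=t, x_um=x, y_um=y,
                         frame=np.arange(spec.n_frames)))
    return out
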