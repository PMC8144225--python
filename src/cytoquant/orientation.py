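"""Structure-tensor orientation analysis of cytoskeletal fibers.

Per-pixel local orientation, coherency and energy are extracted from the
structure tensor of a normalized fluorescence image; orientations within a
cell mask are summarized as coherency-weighted axial histograms, aligned to a
reference (microtubule) dominant orientation, averaged across cells, and
reduced to a weighted angular-spread statistic.

Angle convention (shared by the whole package): axial angles in degrees on
[-90, 90), measured counter-clockwise from the image x-axis (increasing
column index), with the y-axis pointing up (decreasing row index).  A fiber
running left-to-right is at 0 degrees; a vertical fiber is at -90 (equivalent
to +90 modulo 180).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from matplotlib.colors import hsv_to_rgb
from scipy import ndimage, stats

logger = logging.getLogger("cytoquant")

_EPS = 1e-12


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ImageFrame:
    """A 2-D single-channel raster with physical pixel size.

    ``values`` holds photon counts (integers) or normalized intensities
    (floats); ``pixel_size_nm`` is the edge length of one pixel in nm.
    """

    values: np.ndarray
    pixel_size_nm: float = 30.0
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("ImageFrame requires a non-empty 2-D array")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def as_mask(mask: np.ndarray, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Validate a binary cell mask and return it as boolean."""
    m = np.asarray(mask)
    if m.ndim != 2:
        raise ValueError("mask must be 2-D")
    m = m.astype(bool)
    if shape is not None and m.shape != tuple(shape):
        raise ValueError(f"mask shape {m.shape} does not match image shape {tuple(shape)}")
    if not m.any():
        raise ValueError("mask has no interior pixels")
    return m


@dataclass
class OrientationField:
    """Per-pixel axial orientation theta (deg, [-90, 90)), coherency C in
    [0, 1] and energy E (structure-tensor trace, >= 0)."""

    theta: np.ndarray
    coherency: np.ndarray
    energy: np.ndarray
    sigma_gradient_px: float = 1.0
    sigma_tensor_px: float = 2.0

    def __post_init__(self) -> None:
        if not (self.theta.shape == self.coherency.shape == self.energy.shape):
            raise ValueError("field components must share one shape")


@dataclass
class OrientationHistogram:
    """Coherency-weighted axial orientation histogram on [-90, 90)."""

    bin_centers: np.ndarray
    weights: np.ndarray
    alignment_offset: float | None = None

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.bin_centers.shape != self.weights.shape:
            raise ValueError("bin_centers and weights must have equal length")
        if np.any(self.weights < 0):
            raise ValueError("histogram weights must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.weights.size

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())

    def normalized(self) -> "OrientationHistogram":
        tot = self.total_weight
        if tot <= 0:
            raise ValueError("cannot normalize a zero-weight histogram")
        return OrientationHistogram(self.bin_centers, self.weights / tot,
                                    self.alignment_offset)


@dataclass
class GroupHistogram:
    """Bin-wise mean and 95% confidence band of per-cell histograms."""

    bin_centers: np.ndarray
    mean: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_cells: int


# ---------------------------------------------------------------------------
# normalization and structure tensor
# ---------------------------------------------------------------------------

def normalize_minmax(image: ImageFrame) -> ImageFrame:
    """Map intensities linearly to [0, 1]: subtract the minimum, divide by the
    (shifted) maximum.  A constant image yields all zeros with a warning."""
    v = np.asarray(image.values, dtype=float)
    lo = v.min()
    hi = v.max()
    if hi == lo:
        logger.warning("normalize_minmax: constant image, returning zeros")
        out = np.zeros_like(v)
    else:
        out = (v - lo) / (hi - lo)
    return ImageFrame(out, image.pixel_size_nm, image.bit_depth)


def structure_tensor_field(
    image: ImageFrame,
    sigma_gradient: float = 1.0,
    sigma_tensor: float = 2.0,
) -> OrientationField:
    """Compute the orientation field from the 2-D structure tensor.

    Gradients are derivative-of-Gaussian filters at scale ``sigma_gradient``;
    the tensor components <gx^2>, <gx gy>, <gy^2> are smoothed with a Gaussian
    of scale ``sigma_tensor`` (reflect boundary).  With eigenvalues
    l1 >= l2 >= 0:

    * ``theta``  -- orientation of the l2 eigenvector (the along-structure
      axis), degrees in [-90, 90);
    * ``coherency`` -- (l1 - l2)/(l1 + l2), 0 where the trace vanishes;
    * ``energy`` -- the trace l1 + l2 (smoothed squared gradient magnitude).
    """
    if sigma_gradient <= 0 or sigma_tensor <= 0:
        raise ValueError("Gaussian scales must be positive")
    v = np.asarray(image.values, dtype=float)
    if v.max(initial=0.0) > 1.0 + 1e-6 or v.min(initial=0.0) < -1e-6:
        raise ValueError("structure_tensor_field expects an image normalized to [0, 1]")

    # gradients in array coordinates: gc along columns (x), gr along rows
    gc = ndimage.gaussian_filter(v, sigma_gradient, order=(0, 1), mode="reflect")
    gr = ndimage.gaussian_filter(v, sigma_gradient, order=(1, 0), mode="reflect")

    jcc = ndimage.gaussian_filter(gc * gc, sigma_tensor, mode="reflect")
    jrr = ndimage.gaussian_filter(gr * gr, sigma_tensor, mode="reflect")
    jcr = ndimage.gaussian_filter(gc * gr, sigma_tensor, mode="reflect")

    trace = jcc + jrr
    diff = jcc - jrr
    # eigenvalue gap; trace and gap give C without explicit eigendecomposition
    gap = np.sqrt(diff * diff + 4.0 * jcr * jcr)
    coherency = np.where(trace > _EPS, gap / np.maximum(trace, _EPS), 0.0)
    coherency = np.clip(coherency, 0.0, 1.0)

    # along-structure axis, CCW-positive with y pointing up (row index down):
    # double angle of the minor eigenvector = atan2(2*Jcr, Jrr - Jcc)
    theta = 0.5 * np.degrees(np.arctan2(2.0 * jcr, jrr - jcc))
    theta = wrap_axial(theta)

    return OrientationField(theta, coherency, trace,
                            sigma_gradient_px=sigma_gradient,
                            sigma_tensor_px=sigma_tensor)


def wrap_axial(angle_deg: np.ndarray | float):
    """Wrap axial angles (period 180 degrees) into [-90, 90)."""
    return (np.asarray(angle_deg, dtype=float) + 90.0) % 180.0 - 90.0


# ---------------------------------------------------------------------------
# exclusion, histogram, dominant orientation
# ---------------------------------------------------------------------------

def _valid_pixels(field: OrientationField, mask: np.ndarray,
                  exclusion_fraction: float) -> np.ndarray:
    """Boolean map of mask pixels passing the coherency AND energy criteria.

    Thresholds are ``exclusion_fraction`` times the per-image maxima over mask
    pixels.  Pixels with zero energy never pass: an image without any gradient
    structure (constant image) is excluded entirely by the energy criterion.
    """
    mask = as_mask(mask, field.theta.shape)
    c = field.coherency
    e = field.energy
    cmax = c[mask].max()
    emax = e[mask].max()
    return mask & (c >= exclusion_fraction * cmax) & (e >= exclusion_fraction * emax) & (e > 0)


def orientation_histogram(
    field: OrientationField,
    mask: np.ndarray,
    exclusion_fraction: float = 0.10,
    n_bins: int = 180,
) -> OrientationHistogram:
    """Coherency-weighted histogram of orientations inside the mask.

    Pixels whose coherency or energy falls below ``exclusion_fraction`` of the
    respective masked maximum are excluded; surviving pixels contribute their
    coherency as weight to the bin containing their angle.
    """
    valid = _valid_pixels(field, mask, exclusion_fraction)
    if not valid.any():
        mask = as_mask(mask, field.theta.shape)
        if field.energy[mask].max() <= 0:
            raise ValueError("all pixels excluded by the energy criterion "
                             "(no image structure inside the mask)")
        raise ValueError("all pixels excluded by the coherency/energy criteria")
    edges = np.linspace(-90.0, 90.0, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    weights, _ = np.histogram(field.theta[valid], bins=edges,
                              weights=field.coherency[valid])
    return OrientationHistogram(centers, weights)


def dominant_orientation(
    field: OrientationField,
    mask: np.ndarray,
    exclusion_fraction: float = 0.10,
) -> float:
    """Coherency-weighted axial circular mean orientation inside the mask.

    Angles are doubled onto the full circle, averaged as coherency-weighted
    unit vectors over pixels passing the same 10%-of-maximum exclusion as the
    histogram, and the resultant angle is halved back to [-90, 90).
    """
    valid = _valid_pixels(field, mask, exclusion_fraction)
    if not valid.any():
        raise ValueError("no pixels survive the exclusion criteria")
    w = field.coherency[valid]
    doubled = np.radians(2.0 * field.theta[valid])
    sx = float(np.sum(w * np.cos(doubled)))
    sy = float(np.sum(w * np.sin(doubled)))
    if np.hypot(sx, sy) < 1e-9:
        raise ValueError("no dominant orientation (zero resultant vector)")
    return float(wrap_axial(0.5 * np.degrees(np.arctan2(sy, sx))))


def mean_orientation_arithmetic(
    field: OrientationField,
    mask: np.ndarray,
    exclusion_fraction: float = 0.10,
) -> float:
    """Plain coherency-weighted arithmetic mean of angles (wrap-sensitive).

    Provided for comparison with :func:`dominant_orientation`; the axial
    circular mean is the recommended default because it is invariant to the
    +/-90-degree wrap of the axial domain.
    """
    valid = _valid_pixels(field, mask, exclusion_fraction)
    if not valid.any():
        raise ValueError("no pixels survive the exclusion criteria")
    w = field.coherency[valid]
    return float(np.sum(w * field.theta[valid]) / np.sum(w))


# ---------------------------------------------------------------------------
# alignment, group averaging, spread
# ---------------------------------------------------------------------------

def align_histogram(hist: OrientationHistogram, ref_angle: float) -> OrientationHistogram:
    """Circularly shift the histogram (period 180 deg) so the reference angle
    maps to the bin nearest 0 degrees.

    The shift is a whole number of bins (nearest bin to ``ref_angle``), so the
    total weight is conserved exactly.
    """
    if not -90.0 <= ref_angle < 90.0:
        raise ValueError("ref_angle must lie in [-90, 90)")
    bin_width = 180.0 / hist.n_bins
    shift = int(np.rint(ref_angle / bin_width))
    return OrientationHistogram(hist.bin_centers, np.roll(hist.weights, -shift),
                                alignment_offset=float(ref_angle))


def group_average(hists: list[OrientationHistogram]) -> GroupHistogram:
    """Average unit-normalized histograms across cells with t-based 95% CIs.

    Each histogram is normalized to unit total weight before averaging; the
    per-bin confidence interval is mean +/- t(0.975, n-1) * SEM.
    """
    if len(hists) < 2:
        raise ValueError("group_average requires >= 2 histograms")
    centers = hists[0].bin_centers
    for h in hists[1:]:
        if h.n_bins != hists[0].n_bins or not np.allclose(h.bin_centers, centers):
            raise ValueError("histograms are on different bin grids")
    mat = np.stack([h.normalized().weights for h in hists])
    n = mat.shape[0]
    mean = mat.mean(axis=0)
    sem = mat.std(axis=0, ddof=1) / np.sqrt(n)
    tcrit = stats.t.ppf(0.975, n - 1)
    return GroupHistogram(centers, mean, mean - tcrit * sem, mean + tcrit * sem, n)


def orientation_spread(hist: OrientationHistogram) -> float:
    """Weighted standard deviation of angles of an aligned histogram, degrees.

    Computed linearly on the (-90, 90] support: with bin centers t_b and
    weights w_b, spread = sqrt(sum w_b (t_b - tbar)^2 / sum w_b) where
    tbar is the weighted mean.  After alignment the mass is centered near 0,
    so the linear statistic is the natural dispersion measure.
    """
    w = hist.weights
    tot = w.sum()
    if tot <= 0:
        raise ValueError("orientation_spread requires positive total weight")
    t = hist.bin_centers
    tbar = float(np.sum(w * t) / tot)
    return float(np.sqrt(np.sum(w * (t - tbar) ** 2) / tot))


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_hsb(field: OrientationField, image: ImageFrame) -> np.ndarray:
    """Orientation map in HSB space: hue = angle, saturation = coherency,
    brightness = normalized intensity.  Returns float RGB in [0, 1],
    shape (rows, cols, 3)."""
    v = np.asarray(image.values, dtype=float)
    if v.max(initial=0.0) > 1.0 + 1e-6:
        raise ValueError("render_hsb expects a normalized image")
    hsv = np.stack([
        (field.theta + 90.0) / 180.0,
        np.clip(field.coherency, 0.0, 1.0),
        np.clip(v, 0.0, 1.0),
    ], axis=-1)
    return hsv_to_rgb(hsv)
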