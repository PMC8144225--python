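"""Adhesion-site detection via Laplacian-of-Gaussian scale space.

Bright punctate adhesion sites are detected as local maxima of a stack of
scale-normalized LoG responses (sigma = 3..7 px by default, i.e. 90..210 nm
at 30 nm/px).  A scale-normalized LoG responds maximally to a bright blob of
radius sqrt(2)*sigma.  Detections below a response threshold, outside the
cell mask, or within a boundary exclusion zone (1 um by default) are
discarded; the per-cell density is the count divided by the mask area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .orientation import ImageFrame, as_mask


@dataclass
class ScaleSpaceStack:
    """LoG responses, one slice per scale: shape (n_scales, rows, cols)."""

    responses: np.ndarray
    sigmas: tuple[float, ...]

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        self.sigmas = tuple(float(s) for s in self.sigmas)
        if self.responses.ndim != 3 or self.responses.shape[0] != len(self.sigmas):
            raise ValueError("responses must be (n_scales, rows, cols) with one slice per sigma")
        if not np.all(np.isfinite(self.responses)):
            raise ValueError("non-finite LoG responses")


@dataclass
class Blob:
    row: int
    col: int
    sigma_px: float
    response: float
    radius_nm: float


@dataclass
class AdhesionResult:
    n_sites: int
    cell_area_um2: float
    density_per_um2: float


def normalize_percentile(image: ImageFrame, percentile: float = 99.9) -> ImageFrame:
    """Subtract the minimum and divide by the given upper percentile of the
    shifted intensities.  Values above the percentile exceed 1 (no clipping);
    a flat image is an error."""
    v = np.asarray(image.values, dtype=float)
    lo = v.min()
    scale = np.percentile(v, percentile) - lo
    if scale <= 0:
        raise ValueError(f"flat image: the {percentile}th percentile equals the minimum")
    return ImageFrame((v - lo) / scale, image.pixel_size_nm, image.bit_depth)


def log_response_stack(image: ImageFrame, sigmas=(3.0, 4.0, 5.0, 6.0, 7.0)) -> ScaleSpaceStack:
    """Scale-normalized, sign-flipped LoG responses of the normalized image.

    Each slice is -sigma^2 * (LoG_sigma * image), so bright blobs produce
    positive maxima and responses are comparable across scales.
    """
    sigmas = tuple(float(s) for s in sigmas)
    if len(sigmas) == 0:
        raise ValueError("sigma list must be non-empty")
    if any(s <= 0 for s in sigmas):
        raise ValueError("sigmas must be positive")
    v = np.asarray(image.values, dtype=float)
    slices = []
    for s in sigmas:
        # the truncated discrete LoG kernel does not sum exactly to zero;
        # subtract the DC leak so constant images give exactly zero response
        ksum = float(ndimage.gaussian_laplace(np.ones((1, 1)), s, mode="reflect")[0, 0])
        raw = ndimage.gaussian_laplace(v, s, mode="reflect")
        raw -= ksum * ndimage.gaussian_filter(v, s, mode="reflect")
        slices.append(-s * s * raw)
    return ScaleSpaceStack(np.stack(slices), sigmas)


def _scale_space_maxima(responses: np.ndarray) -> np.ndarray:
    """Coordinates of local maxima in the joint (scale, row, col) stack.

    A candidate must be >= all of its up-to-26 neighbors (fewer at stack
    boundaries); plateaus of equal value are collapsed to the
    lexicographically smallest coordinate, so single-pixel strict maxima are
    returned as-is and ties are resolved deterministically.
    """
    footprint = np.ones((3, 3, 3), dtype=bool)
    neigh_max = ndimage.maximum_filter(responses, footprint=footprint,
                                       mode="constant", cval=-np.inf)
    peaks = responses >= neigh_max
    if not peaks.any():
        return np.empty((0, 3), dtype=int)
    # adjacent peak pixels necessarily share one value -> label plateaus
    labels, n_labels = ndimage.label(peaks, structure=footprint)
    objects = ndimage.find_objects(labels)
    coords = []
    for lab, sl in zip(range(1, n_labels + 1), objects):
        # pad the bounding box so the exterior ring is visible
        padded = tuple(slice(max(s.start - 1, 0), min(s.stop + 1, dim))
                       for s, dim in zip(sl, responses.shape))
        comp = labels[padded] == lab
        value = responses[padded][comp].max()
        exterior = ndimage.binary_dilation(comp, structure=footprint) & ~comp
        # a true plateau maximum dominates every exterior neighbor strictly
        if exterior.any() and responses[padded][exterior].max() >= value:
            continue
        pts = np.stack(np.nonzero(comp), axis=1)
        offset = np.array([p.start for p in padded])
        coords.append(tuple(offset + np.array(min(map(tuple, pts)))))
    return np.array(sorted(coords), dtype=int).reshape(-1, 3)


def detect_adhesion_sites(
    stack: ScaleSpaceStack,
    mask: np.ndarray,
    threshold: float = 0.25,
    border_exclusion_um: float = 1.0,
    pixel_size_nm: float = 30.0,
) -> list[Blob]:
    """Adhesion sites: scale-space maxima above ``threshold`` inside the mask
    and at least ``border_exclusion_um`` from the mask boundary.

    Boundary distance is the exact Euclidean distance transform of the mask;
    a site is kept when its distance is >= the exclusion radius.
    """
    mask = as_mask(mask, stack.responses.shape[1:])
    px_um = pixel_size_nm / 1000.0
    min_dist_px = border_exclusion_um / px_um
    dist = ndimage.distance_transform_edt(mask)

    blobs: list[Blob] = []
    for s_idx, r, c in _scale_space_maxima(stack.responses):
        resp = float(stack.responses[s_idx, r, c])
        if resp <= threshold:
            continue
        if not mask[r, c] or dist[r, c] < min_dist_px:
            continue
        sigma = stack.sigmas[s_idx]
        blobs.append(Blob(int(r), int(c), sigma, resp,
                          radius_nm=float(np.sqrt(2.0) * sigma * pixel_size_nm)))
    return blobs


def adhesion_density(blobs: list[Blob], mask: np.ndarray,
                     pixel_size_nm: float = 30.0) -> AdhesionResult:
    """Sites per square micron of cell area (mask pixel count times the pixel
    area)."""
    mask = as_mask(mask)
    area_um2 = float(mask.sum()) * (pixel_size_nm / 1000.0) ** 2
    if area_um2 <= 0:
        raise ValueError("zero-area mask")
    n = len(blobs)
    return AdhesionResult(n, area_um2, n / area_um2)
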