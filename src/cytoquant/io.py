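"""File formats: 16-bit grayscale TIFF images, 8-bit masks, float field maps,
RGB renders, histogram CSVs, JSON summaries.

All writers are deterministic (no timestamps, sorted JSON keys, fixed float
formatting) so a rerun with the same seed produces byte-identical files.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .orientation import ImageFrame, OrientationHistogram

logger = logging.getLogger("cytoquant")


def write_image_tiff(frame: ImageFrame, path) -> None:
    """16-bit grayscale TIFF with resolution tags from the pixel size."""
    px_cm = 1e7 / frame.pixel_size_nm  # pixels per centimeter
    tifffile.imwrite(path, np.asarray(frame.values, dtype=np.uint16),
                     resolution=(px_cm, px_cm), resolutionunit="CENTIMETER",
                     datetime=False)


def write_field_tiff(values: np.ndarray, path) -> None:
    """32-bit float TIFF for field maps (orientation, coherency, energy)."""
    tifffile.imwrite(path, np.asarray(values, dtype=np.float32), datetime=False)


def write_mask_tiff(mask: np.ndarray, path) -> None:
    """8-bit mask TIFF: 255 inside the cell, 0 outside."""
    tifffile.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)), datetime=False)


def read_image_tiff(path, pixel_size_nm: float | None = None) -> ImageFrame:
    """Read a single-channel TIFF.  If ``pixel_size_nm`` is given it wins over
    the file's resolution tags (with a warning on conflict); otherwise the
    tags are used when present."""
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        values = page.asarray()
        tag_px = _pixel_size_from_tags(page)
    if values.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel 2-D image")
    if pixel_size_nm is not None:
        if tag_px is not None and abs(tag_px - pixel_size_nm) > 0.01 * pixel_size_nm:
            logger.warning("%s: TIFF resolution tag (%.3g nm) conflicts with "
                           "configured pixel size (%.3g nm); config wins",
                           path, tag_px, pixel_size_nm)
        px = pixel_size_nm
    else:
        px = tag_px if tag_px is not None else 30.0
    return ImageFrame(values, px, 16)


def _pixel_size_from_tags(page) -> float | None:
    try:
        xres = page.tags["XResolution"].value
        unit = page.tags["ResolutionUnit"].value
    except KeyError:
        return None
    num, den = (xres if isinstance(xres, tuple) else (xres, 1))
    if num == 0:
        return None
    per_unit = num / den
    unit_nm = {2: 2.54e7, 3: 1e7}.get(int(unit))  # inch, centimeter
    if unit_nm is None:
        return None
    return unit_nm / per_unit


def read_mask(path, shape=None) -> np.ndarray:
    """Read a binary mask from TIFF or PNG (nonzero = inside)."""
    p = Path(path)
    if p.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(p)
    else:
        arr = np.asarray(Image.open(p).convert("L"))
    mask = arr > 0
    if shape is not None and mask.shape != tuple(shape):
        raise ValueError(f"{path}: mask shape {mask.shape} != image shape {tuple(shape)}")
    return mask


def write_rgb_png(rgb: np.ndarray, path) -> None:
    """8-bit RGB PNG from a float [0, 1] (rows, cols, 3) array."""
    arr = np.clip(np.asarray(rgb, dtype=float), 0.0, 1.0)
    Image.fromarray((arr * 255.0 + 0.5).astype(np.uint8), mode="RGB").save(path)


def write_histogram_csv(hist: OrientationHistogram, path) -> None:
    pd.DataFrame({"bin_center_deg": hist.bin_centers,
                  "weight": hist.weights}).to_csv(path, index=False,
                                                  float_format="%.17g")


def read_histogram_csv(path) -> OrientationHistogram:
    df = pd.read_csv(path, float_precision="round_trip")
    return OrientationHistogram(df["bin_center_deg"].to_numpy(float),
                                df["weight"].to_numpy(float))


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, sort_keys=True, indent=2) + "\n")
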