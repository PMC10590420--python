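"""Nuclear immunofluorescence quantification.

Workflow mirrors common nuclear-marker analysis on two-channel confocal
images: the DNA counterstain (DAPI) channel is converted to 8-bit, a
threshold derived from the background level demarcates the nuclear mask,
per-nucleus marker intensity is measured inside the mask and normalized to
the image-average DAPI intensity, and cytoplasmic marker intensity is read
from a ring around each nucleus.  A cell whose nuclear marker intensity is
at least 10% above its cytoplasmic intensity is classified nuclear-positive
(the YAP translocation readout).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import dilation, disk, remove_small_objects

__all__ = ["NucleusRecord", "to_8bit", "nuclear_mask", "quantify_marker",
           "yap_positive_fraction", "YAP_RATIO_THRESHOLD"]

YAP_RATIO_THRESHOLD = 1.1   # nuclear >= 1.1x cytoplasmic => positive


@dataclass
class NucleusRecord:
    """Per-nucleus intensity measurements and classification."""

    label: int
    centroid: tuple[float, float]       # (row, col)
    area: int                           # pixels
    mean_dapi: float
    mean_marker_nuclear: float
    mean_marker_cytoplasmic: float
    normalized_marker: float            # nuclear marker / image-mean DAPI
    nuclear_cyto_ratio: float
    yap_positive: bool


def to_8bit(image: np.ndarray) -> np.ndarray:
    """Linear min–max rescale of an image to uint8 [0, 255].

    Endpoints map to endpoints; rounding is half-up.  A constant image maps
    to all zeros.
    """
    img = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite pixels")
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros(img.shape, dtype=np.uint8)
    scaled = (img - lo) / (hi - lo) * 255.0
    return np.floor(scaled + 0.5).astype(np.uint8)


def nuclear_mask(dapi_8bit: np.ndarray, k: float = 3.0,
                 min_area: int = 25) -> np.ndarray:
    """Labelled nuclear mask from an 8-bit DAPI image.

    The background level is the mode of the intensity histogram and its
    spread a robust MAD-based sigma of the sub-mode pixels; the threshold is
    ``mode + k*spread``.  When that rule fails to separate foreground (no
    pixels above threshold, or the spread collapses to zero on a noise-free
    image), Otsu's threshold is used instead.  Connected components smaller
    than ``min_area`` are removed and holes filled.
    """
    img = np.asarray(dapi_8bit)
    if img.dtype != np.uint8:
        raise ValueError("nuclear_mask expects an 8-bit image (use to_8bit)")
    counts = np.bincount(img.ravel(), minlength=256)
    mode = int(np.argmax(counts))
    below = img[img <= mode].astype(float)
    spread = 1.4826 * np.median(np.abs(below - mode)) if below.size else 0.0
    threshold = mode + k * max(spread, 0.0)
    fg = img > threshold
    if spread == 0.0 or not fg.any() or fg.all():
        if img.min() == img.max():
            warnings.warn("blank image: no nuclei found", stacklevel=2)
            return np.zeros(img.shape, dtype=np.int32)
        threshold = threshold_otsu(img)
        fg = img > threshold
    fg = ndimage.binary_fill_holes(fg)
    fg = remove_small_objects(fg, max_size=min_area - 1)
    if not fg.any():
        warnings.warn("no nuclei above threshold", stacklevel=2)
    labels, _ = ndimage.label(fg)
    return labels.astype(np.int32)


def quantify_marker(marker_image: np.ndarray, mask: np.ndarray,
                    dapi_image: np.ndarray,
                    ring_width: int = 3) -> list[NucleusRecord]:
    """Per-nucleus marker quantification over a labelled nuclear mask.

    For each nucleus: mean marker intensity inside its mask pixels;
    ``normalized_marker`` divides that by the mean DAPI intensity over the
    whole image (per-image normalization absorbs staining-batch variation);
    the cytoplasmic intensity is the mean marker in a ``ring_width``-pixel
    dilation ring around the nucleus excluding all nuclear pixels.
    """
    marker = np.asarray(marker_image, dtype=float)
    dapi = np.asarray(dapi_image, dtype=float)
    mask = np.asarray(mask)
    if not (marker.shape == dapi.shape == mask.shape):
        raise ValueError("marker, DAPI, and mask must share a shape")
    if not mask.any():
        return []
    image_mean_dapi = float(dapi.mean())
    any_nucleus = mask > 0
    selem = disk(ring_width)
    pad = ring_width + 1
    records: list[NucleusRecord] = []
    for prop in regionprops(mask):
        # work on a padded crop around the nucleus for speed
        (r0, c0, r1, c1) = prop.bbox
        r0, c0 = max(r0 - pad, 0), max(c0 - pad, 0)
        r1, c1 = min(r1 + pad, mask.shape[0]), min(c1 + pad, mask.shape[1])
        crop = np.s_[r0:r1, c0:c1]
        nucleus = mask[crop] == prop.label
        ring = dilation(nucleus, selem) & ~any_nucleus[crop]
        marker_c, dapi_c = marker[crop], dapi[crop]
        mean_marker = float(marker_c[nucleus].mean())
        mean_cyto = float(marker_c[ring].mean()) if ring.any() else np.nan
        ratio = (mean_marker / mean_cyto
                 if np.isfinite(mean_cyto) and mean_cyto > 0 else np.inf)
        records.append(NucleusRecord(
            label=int(prop.label),
            centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
            area=int(prop.area),
            mean_dapi=float(dapi_c[nucleus].mean()),
            mean_marker_nuclear=mean_marker,
            mean_marker_cytoplasmic=mean_cyto,
            normalized_marker=(mean_marker / image_mean_dapi
                               if image_mean_dapi > 0 else np.nan),
            nuclear_cyto_ratio=float(ratio),
            yap_positive=bool(ratio >= YAP_RATIO_THRESHOLD),
        ))
    return records


def yap_positive_fraction(records: list[NucleusRecord]
                          ) -> tuple[float, int]:
    """Fraction (and count) of nuclei with nuclear/cytoplasmic ratio >= 1.1.

    The 10%-higher boundary is inclusive.
    """
    if not records:
        raise ValueError("no nucleus records")
    n_pos = sum(r.yap_positive for r in records)
    return n_pos / len(records), n_pos


def records_to_frame(records: list[NucleusRecord]) -> pd.DataFrame:
    """Tidy table of nucleus records (one row per nucleus)."""
    return pd.DataFrame([{
        "label": r.label, "centroid_y": r.centroid[0],
        "centroid_x": r.centroid[1], "area_px": r.area,
        "mean_dapi": r.mean_dapi,
        "mean_marker_nuclear": r.mean_marker_nuclear,
        "mean_marker_cytoplasmic": r.mean_marker_cytoplasmic,
        "normalized_marker": r.normalized_marker,
        "nuclear_cyto_ratio": r.nuclear_cyto_ratio,
        "yap_positive": r.yap_positive,
    } for r in records])
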