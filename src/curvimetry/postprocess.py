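"""Post-processing of predicted segmentation masks.

The chain that turns a raw predicted mask into a clean shaft region:
flood-fill hole closure, a 2x2 median filter, a 3x3 Gaussian smoothing
kernel with variance 0.25, and re-binarization at 0.5.  Also houses the
cropping helpers used around the localization stage.

Conventions the underlying formulas leave open are fixed here once:

* 2x2 median — even kernels have no center pixel, so the window is
  anchored at its top-left pixel, and the 2-2 tie of a four-element
  boolean median resolves to background (False).  Equivalently the
  output is True iff at least 3 of the 4 window pixels are True.
* Gaussian — sampled from the continuous kernel with sigma = 0.5
  (variance 0.25) on the 3x3 grid and normalized to sum 1.
* Borders — reflect padding for both filters.
* Hole identification uses 4-connectivity; component labeling uses
  8-connectivity (the standard complementary pair).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

from .errors import EmptyMaskError, InvalidBoxError
from .types import BoundingBox, as_mask

# 4-connected structuring element: holes are background regions not
# 4-connected to the image border.
_CROSS = ndi.generate_binary_structure(2, 1)
_SQUARE = ndi.generate_binary_structure(2, 2)

# 1-D Gaussian with sigma = 0.5 sampled at {-1, 0, 1}, normalized.
_G1 = np.exp(-np.array([1.0, 0.0, 1.0]) / (2 * 0.25))
_G1 /= _G1.sum()
_GAUSS_3X3 = np.outer(_G1, _G1)


def _require_nonempty(mask: np.ndarray) -> np.ndarray:
    mask = as_mask(mask)
    if not mask.any():
        raise EmptyMaskError("mask has no foreground pixels")
    return mask


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Close interior holes by flood-filling from the image border.

    Every background region not 4-connected to the border becomes
    foreground.  Foreground pixels are never removed, so the operation
    is monotone and idempotent.
    """
    mask = _require_nonempty(mask)
    return ndi.binary_fill_holes(mask, structure=_CROSS)


def median_2x2(mask: np.ndarray, passes: int = 1) -> np.ndarray:
    """Multi-pass 2x2 boolean median filter, top-left anchored.

    With the background tie rule, each output pixel is True iff >= 3 of
    the 4 pixels in its window are True.  Reflect padding on the high
    edges keeps solid interiors and the all-True mask unchanged.
    """
    mask = _require_nonempty(mask)
    out = mask
    for _ in range(passes):
        padded = np.pad(out, ((0, 1), (0, 1)), mode="reflect").astype(np.uint8)
        votes = (
            padded[:-1, :-1] + padded[:-1, 1:] + padded[1:, :-1] + padded[1:, 1:]
        )
        out = votes >= 3
    return out


def smooth_mask(mask: np.ndarray, median_passes: int = 1) -> np.ndarray:
    """2x2 median filter, then 3x3 Gaussian (variance 0.25), then re-binarize.

    Large solid interiors are unchanged; the chain only nibbles at
    single-pixel protrusions and softens staircase edges.
    """
    mask = median_2x2(mask, passes=median_passes)
    blurred = ndi.correlate(mask.astype(float), _GAUSS_3X3, mode="reflect")
    return blurred >= 0.5


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 8-connected foreground component."""
    mask = _require_nonempty(mask)
    labels, n = ndi.label(mask, structure=_SQUARE)
    if n <= 1:
        return mask.copy()
    sizes = ndi.sum_labels(mask, labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def postprocess_mask(mask: np.ndarray, median_passes: int = 1) -> np.ndarray:
    """Full chain: fill holes, smooth, keep the largest component."""
    return largest_component(smooth_mask(fill_holes(mask), median_passes))


def crop_to_bbox(
    image: np.ndarray, box: BoundingBox, margin_px: int = 0
) -> np.ndarray:
    """Sub-image of ``box`` expanded by ``margin_px`` and clipped to bounds."""
    if margin_px < 0:
        raise InvalidBoxError(f"margin_px={margin_px} must be >= 0")
    h, w = image.shape[:2]
    if box.x_min >= w or box.y_min >= h or box.x_max <= 0 or box.y_max <= 0:
        raise InvalidBoxError(f"box {box} lies fully outside a {h}x{w} image")
    x0 = max(0, box.x_min - margin_px)
    y0 = max(0, box.y_min - margin_px)
    x1 = min(w, box.x_max + margin_px)
    y1 = min(h, box.y_max + margin_px)
    return image[y0:y1, x0:x1]


def center_crop_square(image: np.ndarray) -> np.ndarray:
    """Center-crop to a 1:1 aspect ratio (side = min(height, width)).

    Even trim is split equally between the two sides; an odd remainder
    gives the extra pixel to the low-index side.
    """
    h, w = image.shape[:2]
    side = min(h, w)
    y0 = (h - side) // 2
    x0 = (w - side) // 2
    return image[y0 : y0 + side, x0 : x0 + side]
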