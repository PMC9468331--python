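"""Shared lightweight containers.

Images and masks are plain numpy arrays throughout the package:

* *RasterImage* — 2-D ``uint8`` grayscale (H, W) or RGB (H, W, 3),
  origin at the top-left, row index increasing downward.
* *BinaryMask* — 2-D boolean array, ``True`` = shaft pixel, same
  coordinate convention.

Only structured values get dataclasses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidBoxError


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in pixel coordinates, 0-based, half-open.

    Covers columns ``[x_min, x_max)`` and rows ``[y_min, y_max)``.
    """

    x_min: int
    y_min: int
    x_max: int
    y_max: int

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise InvalidBoxError(
                f"degenerate box ({self.x_min},{self.y_min},{self.x_max},{self.y_max})"
            )

    @property
    def width(self) -> int:
        return self.x_max - self.x_min

    @property
    def height(self) -> int:
        return self.y_max - self.y_min

    def area(self) -> int:
        return self.width * self.height

    def intersection_over_union(self, other: "BoundingBox") -> float:
        """IoU of two boxes; 0.0 when they do not overlap."""
        ix = max(0, min(self.x_max, other.x_max) - max(self.x_min, other.x_min))
        iy = max(0, min(self.y_max, other.y_max) - max(self.y_min, other.y_min))
        inter = ix * iy
        if inter == 0:
            return 0.0
        return inter / (self.area() + other.area() - inter)

    @classmethod
    def from_mask(cls, mask: np.ndarray) -> "BoundingBox":
        """Tight box around the true pixels of a boolean mask."""
        rows = np.flatnonzero(mask.any(axis=1))
        cols = np.flatnonzero(mask.any(axis=0))
        if rows.size == 0:
            raise InvalidBoxError("mask has no foreground pixels")
        return cls(int(cols[0]), int(rows[0]), int(cols[-1]) + 1, int(rows[-1]) + 1)


@dataclass(frozen=True)
class DetectionResult:
    """One detector output: a predicted box with a confidence score."""

    predicted_box: BoundingBox
    confidence: float
    class_id: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise InvalidBoxError(f"confidence {self.confidence} outside [0, 1]")


def as_mask(arr: np.ndarray) -> np.ndarray:
    """Coerce an array to a 2-D boolean mask (any nonzero = True)."""
    a = np.asarray(arr)
    if a.ndim == 3:  # collapse color channels
        a = a.any(axis=-1) if a.dtype == bool else a.max(axis=-1)
    if a.ndim != 2:
        raise ValueError(f"expected a 2-D mask, got shape {a.shape}")
    return a.astype(bool) if a.dtype != bool else a
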