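"""Core in-memory containers shared by every stage of the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ImageSlice:
    """A single 2-D grayscale CT slice.

    Parameters
    ----------
    pixels
        Real-valued 2-D array, (row, col) order.
    spacing
        Physical pixel spacing in mm as ``(row_spacing, col_spacing)``.
    origin
        Tag describing the origin convention; informational only.
    """

    pixels: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)
    origin: str = "upper-left"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("ImageSlice requires a 2-D array")
        if not (self.spacing[0] > 0 and self.spacing[1] > 0):
            raise ValueError("pixel spacing must be positive in both axes")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("ImageSlice pixels must be finite")


@dataclass
class QuantizedROI:
    """A masked, min-max normalized, B-level integer image patch.

    ``levels`` holds integers in ``1..n_levels`` inside the mask and 0
    (sentinel) outside.  This is the substrate of all co-occurrence and
    run-length texture features.
    """

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int = 8
    normalization_bounds: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=int)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.levels.shape != self.mask.shape:
            raise ValueError("levels and mask must share a shape")
        if self.n_levels < 2:
            raise ValueError("need at least 2 gray levels")
        if not self.mask.any():
            raise ValueError("mask must be nonempty")
        inside = self.levels[self.mask]
        if inside.min() < 1 or inside.max() > self.n_levels:
            raise ValueError("in-mask levels must lie in 1..n_levels")


@dataclass
class CaseRecord:
    """One lymph node: image + mask + demographics + histology label."""

    case_id: str
    image: ImageSlice
    mask: np.ndarray
    age: float
    gender: str  # "M" / "F"
    tumor_location: str  # "left" / "right"
    histological_grade: str  # "well" / "poor"
    short_axis: float  # mm
    long_axis: float  # mm
    label: int  # 0 normal, 1 metastatic
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("case mask must be nonempty")
        if self.mask.shape != self.image.pixels.shape:
            raise ValueError("mask must match image shape")
        if not (self.long_axis >= self.short_axis > 0):
            raise ValueError("need long_axis >= short_axis > 0")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
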