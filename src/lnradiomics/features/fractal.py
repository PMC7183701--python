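"""Box-counting fractal dimension of the ROI texture."""

from __future__ import annotations

import warnings

import numpy as np

from ..types import QuantizedROI


def box_counting_dimension(binary: np.ndarray) -> float:
    """Box-counting dimension of a binary set.

    Occupied boxes are counted at dyadic sizes 1, 2, 4, ... up to half the
    bounding-box side, and the dimension is the least-squares slope of
    log N(s) against log(1/s).  A set too small to count (fewer than two
    occupied boxes at the coarsest scale, or fewer than two scales) returns
    0 with a warning.
    """
    binary = np.asarray(binary) > 0
    if not binary.any():
        warnings.warn("empty set: box-counting dimension undefined, returning 0",
                      stacklevel=2)
        return 0.0
    rows = np.any(binary, axis=1)
    cols = np.any(binary, axis=0)
    sub = binary[rows][:, cols]
    side = max(sub.shape)
    sizes = []
    s = 1
    while s <= max(1, side // 2):
        sizes.append(s)
        s *= 2
    if len(sizes) < 2:
        warnings.warn("set too small for a box-count fit, returning 0", stacklevel=2)
        return 0.0
    counts = []
    for s in sizes:
        h = int(np.ceil(sub.shape[0] / s)) * s
        w = int(np.ceil(sub.shape[1] / s)) * s
        padded = np.zeros((h, w), dtype=bool)
        padded[: sub.shape[0], : sub.shape[1]] = sub
        boxes = padded.reshape(h // s, s, w // s, s).any(axis=(1, 3))
        counts.append(int(boxes.sum()))
    if counts[-1] < 2:
        warnings.warn("fewer than two occupied boxes at the coarsest scale; "
                      "returning 0", stacklevel=2)
        return 0.0
    log_inv_s = -np.log(np.asarray(sizes, float))
    log_n = np.log(np.asarray(counts, float))
    slope = np.polyfit(log_inv_s, log_n, 1)[0]
    return float(slope)


def fractal_dimension(roi: QuantizedROI) -> float:
    """Box-counting dimension of the supra-median set of the ROI.

    The quantized ROI is thresholded at its in-mask median (pixels strictly
    above the median are "occupied"); a flat ROI has an empty supra-median
    set and returns 0 through the degenerate-input warning path.
    """
    inside = roi.levels[roi.mask]
    med = np.median(inside)
    occupied = (roi.levels > med) & roi.mask
    return box_counting_dimension(occupied)
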