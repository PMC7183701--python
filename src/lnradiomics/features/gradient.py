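"""Gradient-domain texture features.

The Sobel gradient-magnitude image measures directional intensity change.
It is re-normalized and 8-bin re-quantized within the mask eroded by one
pixel (the Sobel stencil needs a full 3x3 in-ROI neighbourhood), and yields
the FoS(6) + GLCM(6) + GLRLM(7) panels: 19 features.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ..types import ImageSlice, QuantizedROI
from .firstorder import first_order_stats
from .glcm import glcm_panel
from .glrlm import glrlm_panel


def gradient_magnitude(px: np.ndarray) -> np.ndarray:
    gy = ndimage.sobel(px, axis=0, mode="nearest")
    gx = ndimage.sobel(px, axis=1, mode="nearest")
    return np.hypot(gx, gy)


def _has_pair(mask: np.ndarray) -> bool:
    return (np.any(mask[:, :-1] & mask[:, 1:]) or np.any(mask[:-1] & mask[1:])
            or np.any(mask[:-1, :-1] & mask[1:, 1:])
            or np.any(mask[:-1, 1:] & mask[1:, :-1]))


def gradient_features(slice_: ImageSlice | np.ndarray, mask: np.ndarray,
                      n_levels: int = 8) -> dict[str, float]:
    """19 texture features of the Sobel gradient-magnitude image."""
    px = slice_.pixels if isinstance(slice_, ImageSlice) else np.asarray(slice_, float)
    mask = np.asarray(mask) > 0
    eroded = ndimage.binary_erosion(mask, structure=np.ones((3, 3)))
    if not eroded.any():
        raise ValueError("mask erodes to empty: gradient ROI undefined")
    mag = gradient_magnitude(px)
    if not _has_pair(eroded):
        # very small nodes: the eroded interior holds no pixel pair in any
        # direction, so the co-occurrence substrate falls back to the full mask
        eroded = mask
    lo, hi = float(mag[eroded].min()), float(mag[eroded].max())
    levels = np.zeros(mag.shape, dtype=int)
    if hi > lo:
        v = np.clip((mag - lo) / (hi - lo), 0.0, 1.0)
        q = np.floor(v * n_levels).astype(int) + 1
        q[q > n_levels] = n_levels
        levels[eroded] = q[eroded]
    else:
        levels[eroded] = 1
    roi = QuantizedROI(levels, eroded, n_levels, (lo, hi))
    out: dict[str, float] = {}
    for k, v in first_order_stats(roi).items():
        out["gradient_" + k] = v
    for k, v in glcm_panel(roi).items():
        out["gradient_glcm_" + k] = v
    for k, v in glrlm_panel(roi).items():
        out["gradient_glrlm_" + k] = v
    return out
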