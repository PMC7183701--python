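"""Rotation-invariant uniform local binary patterns (P=8, R=1).

The riu2 variant is the only standard LBP whose histogram has exactly ten
bins for eight neighbours: codes 0-8 (number of "on" neighbours in a
uniform pattern) plus one bin for all non-uniform patterns.  Codes are
computed on the continuous (pre-quantization) intensity image; only pixels
whose full 8-neighbourhood lies inside the ROI contribute.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.feature import local_binary_pattern

from ..types import ImageSlice

N_LBP_BINS = 10
LBP_FEATURE_NAMES = tuple(f"lbp_{k}" for k in range(9)) + ("lbp_nonuniform",)


def lbp_features(slice_: ImageSlice | np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """Normalized 10-bin riu2 LBP histogram over interior ROI pixels."""
    px = slice_.pixels if isinstance(slice_, ImageSlice) else np.asarray(slice_, float)
    mask = np.asarray(mask) > 0
    interior = ndimage.binary_erosion(mask, structure=np.ones((3, 3)))
    if not interior.any():
        raise ValueError("mask erodes to empty: no pixel with a full 8-neighbourhood")
    # skimage 'uniform' with P=8 is the rotation-invariant uniform mapping:
    # uniform patterns -> number of ones (0..8), everything else -> 9
    import warnings

    with warnings.catch_warnings():
        # float input is intentional (codes only depend on >= comparisons)
        warnings.simplefilter("ignore", UserWarning)
        codes = local_binary_pattern(px, P=8, R=1, method="uniform")
    vals = codes[interior].astype(int)
    hist = np.bincount(vals, minlength=N_LBP_BINS).astype(float)
    hist /= hist.sum()
    return {k: float(v) for k, v in zip(LBP_FEATURE_NAMES, hist)}
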