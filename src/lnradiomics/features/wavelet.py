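"""Wavelet-domain texture features.

One level of the 2-D Daubechies-2 transform (symmetric boundary extension)
splits the ROI bounding-box image into approximation (LL) and detail
(LH, HL, HH) subbands.  Each subband is min-max re-normalized and 8-bin
re-quantized inside the downsampled mask — its dynamic range differs from
the intensity image — and yields the FoS(6) + GLCM(6) + GLRLM(7) panels,
plus three subband summaries (relative energy, log-energy, mean absolute
coefficient): 22 features per subband, 88 in total.
"""

from __future__ import annotations

import numpy as np
import pywt

from ..types import ImageSlice, QuantizedROI
from .firstorder import first_order_stats
from .glcm import glcm_panel
from .glrlm import glrlm_panel

SUBBANDS = ("ll", "lh", "hl", "hh")
WAVELET_SUMMARY_NAMES = ("relative_energy", "log_energy", "mean_abs")


def _quantize_subband(coeffs: np.ndarray, mask: np.ndarray, n_levels: int = 8) -> QuantizedROI:
    lo, hi = float(coeffs[mask].min()), float(coeffs[mask].max())
    levels = np.zeros(coeffs.shape, dtype=int)
    if hi > lo:
        v = np.clip((coeffs - lo) / (hi - lo), 0.0, 1.0)
        q = np.floor(v * n_levels).astype(int) + 1
        q[q > n_levels] = n_levels
        levels[mask] = q[mask]
    else:
        levels[mask] = 1
    return QuantizedROI(levels, mask, n_levels, (lo, hi))


def _grow_span(lo: int, hi: int, min_len: int, limit: int) -> tuple[int, int]:
    while hi - lo + 1 < min_len:
        if lo > 0:
            lo -= 1
        if hi - lo + 1 < min_len and hi < limit - 1:
            hi += 1
        if lo == 0 and hi == limit - 1:
            break
    return lo, hi


def wavelet_features(slice_: ImageSlice | np.ndarray, mask: np.ndarray,
                     wavelet: str = "db2", n_levels: int = 8) -> dict[str, float]:
    """88 features from the four first-level Daubechies subbands."""
    px = slice_.pixels if isinstance(slice_, ImageSlice) else np.asarray(slice_, float)
    mask = np.asarray(mask) > 0
    if not mask.any():
        raise ValueError("empty mask")
    if px.shape[0] < 4 or px.shape[1] < 4:
        raise ValueError("image smaller than the 4x4 minimum for a db2 transform")
    rows = np.any(mask, axis=1)
    cols = np.any(mask, axis=0)
    r0, r1 = np.flatnonzero(rows)[[0, -1]]
    c0, c1 = np.flatnonzero(cols)[[0, -1]]
    # expand the crop window (not the mask) to the 4x4 transform minimum
    r0, r1 = _grow_span(r0, r1, 4, px.shape[0])
    c0, c1 = _grow_span(c0, c1, 4, px.shape[1])
    box = px[r0:r1 + 1, c0:c1 + 1].copy()
    boxmask = mask[r0:r1 + 1, c0:c1 + 1]
    # fill outside-mask pixels with the in-mask mean so mask edges do not
    # leak spurious detail energy into the subbands
    box[~boxmask] = box[boxmask].mean()

    ll, (lh, hl, hh) = pywt.dwt2(box, wavelet, mode="symmetric")
    coeffs = {"ll": ll, "lh": lh, "hl": hl, "hh": hh}
    energies = {k: float((c**2).sum()) for k, c in coeffs.items()}
    total = sum(energies.values())

    out: dict[str, float] = {}
    for name in SUBBANDS:
        c = coeffs[name]
        # nearest-neighbour downsampling of the mask to the subband grid
        ir = np.round(np.linspace(0, boxmask.shape[0] - 1, c.shape[0])).astype(int)
        ic = np.round(np.linspace(0, boxmask.shape[1] - 1, c.shape[1])).astype(int)
        sub_mask = boxmask[np.ix_(ir, ic)]
        if not sub_mask.any():
            sub_mask = np.ones(c.shape, dtype=bool)
        roi = _quantize_subband(c, sub_mask, n_levels)
        prefix = f"wavelet_{name}_"
        for k, v in first_order_stats(roi).items():
            out[prefix + k] = v
        for k, v in glcm_panel(roi).items():
            out[prefix + "glcm_" + k] = v
        for k, v in glrlm_panel(roi).items():
            out[prefix + "glrlm_" + k] = v
        rel = energies[name] / total if total > 0 else (1.0 if name == "ll" else 0.0)
        out[prefix + "relative_energy"] = rel
        # log1p keeps the feature finite for identically-zero detail subbands
        out[prefix + "log_energy"] = float(np.log1p(energies[name]))
        out[prefix + "mean_abs"] = float(np.abs(c).mean())
    return out
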