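"""Gray-level run-length matrices and Galloway-style features.

A run is a maximal segment of equal gray level along one of the four
directions (0/45/90/135 degrees), truncated wherever the line leaves the
ROI mask.  Run extraction is vectorized: all lines of a direction are
concatenated into one 1-D array with sentinel breaks at line boundaries and
out-of-mask pixels, and a single run-length encoding pass counts the runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..types import QuantizedROI

GLRLM_FEATURE_NAMES = ("sre", "lre", "gln", "rp", "rln", "lglre", "hglre")

_SENTINEL = -1


@dataclass
class GLRLMatrix:
    counts: np.ndarray  # B x Rmax integer run counts
    direction: int
    n_pixels: int  # in-mask pixels (RP denominator)


def _direction_lines(lev: np.ndarray, mask: np.ndarray, direction: int):
    """Yield the scan lines of a direction as (values, in_mask) 1-D arrays."""
    h, w = lev.shape
    if direction == 0:
        for r in range(h):
            yield lev[r], mask[r]
    elif direction == 90:
        for c in range(w):
            yield lev[:, c], mask[:, c]
    elif direction == 45:
        # bottom-left to top-right diagonals: flip rows, take main diagonals
        fl, fm = lev[::-1], mask[::-1]
        for off in range(-h + 1, w):
            yield np.diagonal(fl, off), np.diagonal(fm, off)
    elif direction == 135:
        for off in range(-h + 1, w):
            yield np.diagonal(lev, off), np.diagonal(mask, off)
    else:
        raise ValueError("direction must be one of 0, 45, 90, 135")


def glrlm(roi: QuantizedROI, direction: int) -> GLRLMatrix:
    """Run-length matrix for one direction (levels x run length)."""
    lev, mask = roi.levels, roi.mask
    if not mask.any():
        raise ValueError("empty mask")
    pieces = []
    for vals, inm in _direction_lines(lev, mask, direction):
        v = np.where(inm, vals, _SENTINEL)
        pieces.append(v)
        pieces.append([_SENTINEL])
    flat = np.concatenate(pieces)
    # run-length encode: boundaries where the value changes
    change = np.flatnonzero(np.diff(flat)) + 1
    starts = np.concatenate(([0], change))
    lengths = np.diff(np.concatenate((starts, [flat.size])))
    values = flat[starts]
    keep = values != _SENTINEL
    values, lengths = values[keep], lengths[keep]
    b = roi.n_levels
    rmax = max(lev.shape)
    counts = np.zeros((b, rmax), dtype=int)
    np.add.at(counts, (values - 1, lengths - 1), 1)
    return GLRLMatrix(counts, direction, int(mask.sum()))


def _single_matrix_features(m: GLRLMatrix) -> dict[str, float]:
    p = m.counts.astype(float)
    nr = p.sum()
    if nr == 0:
        raise ValueError("run-length matrix holds no runs")
    b, rmax = p.shape
    i = np.arange(1, b + 1)[:, None].astype(float)
    r = np.arange(1, rmax + 1)[None, :].astype(float)
    return {
        "sre": float((p / r**2).sum() / nr),
        "lre": float((p * r**2).sum() / nr),
        "gln": float((p.sum(axis=1) ** 2).sum() / nr),
        "rln": float((p.sum(axis=0) ** 2).sum() / nr),
        "rp": float(nr / m.n_pixels),
        "lglre": float((p / i**2).sum() / nr),
        "hglre": float((p * i**2).sum() / nr),
    }


def glrlm_features(matrices) -> dict[str, float]:
    """Average the seven run-length features over direction matrices."""
    mats = list(matrices)
    if not mats:
        raise ValueError("need at least one run-length matrix")
    per_dir = [_single_matrix_features(m) for m in mats]
    return {k: float(np.mean([d[k] for d in per_dir])) for k in GLRLM_FEATURE_NAMES}


def glrlm_panel(roi: QuantizedROI) -> dict[str, float]:
    """Direction-averaged GLRLM features over the four standard directions."""
    return glrlm_features(glrlm(roi, d) for d in (0, 45, 90, 135))
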