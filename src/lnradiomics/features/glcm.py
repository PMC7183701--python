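"""Gray-level co-occurrence matrices and Haralick-style features.

Computed by hand rather than via ``skimage.feature.graycomatrix`` because
only pairs with *both* pixels inside the (generally non-rectangular) ROI
mask may be counted.  Matrices are symmetric (each ordered pair counted in
both orders) and normalized to sum 1, the Haralick convention; the default
offset distance is 1 pixel and features are averaged over the four standard
directions 0/45/90/135 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..types import QuantizedROI

GLCM_FEATURE_NAMES = ("energy", "contrast", "correlation", "homogeneity",
                      "entropy", "dissimilarity")

# (row, col) offsets; angles measured counter-clockwise, image rows increase
# downwards, so 45 degrees pairs a pixel with its upper-right neighbour.
_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass
class GLCMatrix:
    probabilities: np.ndarray  # B x B, symmetric, sums to 1
    direction: int
    distance: int
    n_pairs: int

    @property
    def symmetric(self) -> bool:
        return bool(np.allclose(self.probabilities, self.probabilities.T))


def glcm(roi: QuantizedROI, direction: int, distance: int = 1) -> GLCMatrix:
    """Symmetric, normalized co-occurrence matrix for one direction."""
    if direction not in _OFFSETS:
        raise ValueError(f"direction must be one of {sorted(_OFFSETS)}")
    if distance < 1:
        raise ValueError("distance must be >= 1")
    b = roi.n_levels
    dr, dc = (distance * d for d in _OFFSETS[direction])
    lev, mask = roi.levels, roi.mask
    h, w = lev.shape

    r0 = slice(max(0, -dr), min(h, h - dr))
    c0 = slice(max(0, -dc), min(w, w - dc))
    r1 = slice(r0.start + dr, r0.stop + dr)
    c1 = slice(c0.start + dc, c0.stop + dc)

    a = lev[r0, c0]
    bb = lev[r1, c1]
    valid = mask[r0, c0] & mask[r1, c1]
    n_pairs = int(valid.sum())
    if n_pairs == 0:
        raise ValueError(f"no in-mask pixel pair in direction {direction}")
    idx = (a[valid] - 1) * b + (bb[valid] - 1)
    counts = np.bincount(idx, minlength=b * b).reshape(b, b).astype(float)
    counts = counts + counts.T  # symmetrize: count each pair in both orders
    return GLCMatrix(counts / counts.sum(), direction, distance, n_pairs)


def _single_matrix_features(p: np.ndarray) -> dict[str, float]:
    b = p.shape[0]
    i = np.arange(1, b + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    contrast = float(((ii - jj) ** 2 * p).sum())
    dissim = float((np.abs(ii - jj) * p).sum())
    homog = float((p / (1.0 + np.abs(ii - jj))).sum())
    energy = float((p**2).sum())
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    pi = p.sum(axis=1)
    mu = float((i * pi).sum())
    var = float(((i - mu) ** 2 * pi).sum())
    if var > 0:
        corr = float((((ii - mu) * (jj - mu) * p).sum()) / var)
    else:
        corr = 1.0  # degenerate single-level matrix: perfectly correlated
    return {
        "energy": energy,
        "contrast": contrast,
        "correlation": corr,
        "homogeneity": homog,
        "entropy": entropy,
        "dissimilarity": dissim,
    }


def glcm_features(matrices) -> dict[str, float]:
    """Average the six Haralick features over the supplied direction matrices.

    Directions for which no in-mask pair exists should simply be omitted by
    the caller (they raise in :func:`glcm`); the average runs over whatever
    valid matrices are passed.
    """
    mats = list(matrices)
    if not mats:
        raise ValueError("need at least one co-occurrence matrix")
    per_dir = [_single_matrix_features(m.probabilities) for m in mats]
    return {k: float(np.mean([d[k] for d in per_dir])) for k in GLCM_FEATURE_NAMES}


def glcm_panel(roi: QuantizedROI, distance: int = 1) -> dict[str, float]:
    """Direction-averaged GLCM features, skipping pair-less directions."""
    mats = []
    for d in _OFFSETS:
        try:
            mats.append(glcm(roi, d, distance))
        except ValueError:
            continue
    return glcm_features(mats)
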