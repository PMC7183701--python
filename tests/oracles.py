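"""Brute-force reference implementations used only as test oracles.

Everything here is deliberately naive — explicit Python loops over pixels,
pairs and runs — and independent of the vectorized implementations under
test.
"""

from __future__ import annotations

import numpy as np

OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def brute_glcm(levels, mask, direction, distance=1):
    """Symmetric normalized co-occurrence matrix by explicit pair walking."""
    levels = np.asarray(levels)
    mask = np.asarray(mask) > 0
    b = int(levels[mask].max())
    dr, dc = (distance * d for d in OFFSETS[direction])
    counts = np.zeros((b, b), dtype=float)
    h, w = levels.shape
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                counts[levels[r, c] - 1, levels[r2, c2] - 1] += 1
                counts[levels[r2, c2] - 1, levels[r, c] - 1] += 1
    if counts.sum() == 0:
        raise ValueError("no pairs")
    return counts / counts.sum()


def brute_glcm_features(p):
    """Haralick features from a normalized matrix by direct summation."""
    b = p.shape[0]
    feats = dict.fromkeys(
        ("energy", "contrast", "correlation", "homogeneity", "entropy",
         "dissimilarity"), 0.0)
    mu = sum((i + 1) * p[i, :].sum() for i in range(b))
    var = sum((i + 1 - mu) ** 2 * p[i, :].sum() for i in range(b))
    for i in range(b):
        for j in range(b):
            v = p[i, j]
            feats["energy"] += v * v
            feats["contrast"] += (i - j) ** 2 * v
            feats["dissimilarity"] += abs(i - j) * v
            feats["homogeneity"] += v / (1 + abs(i - j))
            if v > 0:
                feats["entropy"] -= v * np.log2(v)
            if var > 0:
                feats["correlation"] += (i + 1 - mu) * (j + 1 - mu) * v / var
    if var == 0:
        feats["correlation"] = 1.0
    return feats


def brute_runs(levels, mask, direction):
    """All maximal constant-level in-mask runs as (level, length) tuples."""
    levels = np.asarray(levels)
    mask = np.asarray(mask) > 0
    h, w = levels.shape
    step = OFFSETS[direction]
    # collect the maximal lines of the direction
    starts = []
    if direction == 0:
        starts = [(r, 0) for r in range(h)]
    elif direction == 90:
        starts = [(h - 1, c) for c in range(w)]
    elif direction == 45:
        starts = [(h - 1, c) for c in range(w)] + [(r, 0) for r in range(h - 1)]
    elif direction == 135:
        starts = [(h - 1, c) for c in range(w)] + [(r, w - 1) for r in range(h - 1)]
    runs = []
    for r0, c0 in starts:
        line = []
        r, c = r0, c0
        while 0 <= r < h and 0 <= c < w:
            line.append((levels[r, c], mask[r, c]))
            r += step[0]
            c += step[1]
        cur = None
        length = 0
        for val, inm in line + [(None, False)]:
            key = val if inm else None
            if key is not None and key == cur:
                length += 1
            else:
                if cur is not None:
                    runs.append((int(cur), length))
                cur = key
                length = 1 if key is not None else 0
    return runs


def brute_glrlm_features(levels, mask, direction):
    """Galloway features from the explicit run list."""
    runs = brute_runs(levels, mask, direction)
    n_px = int((np.asarray(mask) > 0).sum())
    nr = len(runs)
    feats = {
        "sre": sum(1.0 / ln**2 for _, ln in runs) / nr,
        "lre": sum(float(ln**2) for _, ln in runs) / nr,
        "rp": nr / n_px,
        "lglre": sum(1.0 / lv**2 for lv, _ in runs) / nr,
        "hglre": sum(float(lv**2) for lv, _ in runs) / nr,
    }
    by_level: dict[int, int] = {}
    by_len: dict[int, int] = {}
    for lv, ln in runs:
        by_level[lv] = by_level.get(lv, 0) + 1
        by_len[ln] = by_len.get(ln, 0) + 1
    feats["gln"] = sum(v**2 for v in by_level.values()) / nr
    feats["rln"] = sum(v**2 for v in by_len.values()) / nr
    return feats


def brute_lbp_code(image, r, c):
    """riu2 LBP code of one pixel by explicit 8-neighbour comparison."""
    image = np.asarray(image, dtype=float)
    # skimage neighbour order: angles 0, 45, ..., 315 (col offset first)
    nbrs = [(0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1)]
    bits = [1 if image[r + dr, c + dc] >= image[r, c] else 0 for dr, dc in nbrs]
    transitions = sum(bits[i] != bits[(i + 1) % 8] for i in range(8))
    return sum(bits) if transitions <= 2 else 9


def brute_auc(scores, labels):
    """AUC by exhaustive positive-negative pair enumeration (ties = 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for x in pos:
        for y in neg:
            total += 1.0 if x > y else (0.5 if x == y else 0.0)
    return total / (len(pos) * len(neg))
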