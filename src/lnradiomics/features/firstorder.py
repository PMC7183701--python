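"""First-order (histogram) statistics of the quantized ROI."""

from __future__ import annotations

import numpy as np

from ..types import QuantizedROI

FOS_FEATURE_NAMES = ("mean", "variance", "skewness", "kurtosis", "energy", "entropy")


def first_order_stats(roi: QuantizedROI) -> dict[str, float]:
    """Six first-order statistics of the in-mask gray-level histogram.

    Returns mean, (population) variance, skewness, excess kurtosis, energy
    (sum of squared level probabilities) and entropy in bits over the B
    quantized levels.  Skewness and kurtosis of a degenerate (zero-variance)
    distribution are defined as 0 so every feature stays finite.
    """
    x = roi.levels[roi.mask].astype(float)
    if x.size == 0:
        raise ValueError("empty mask")
    mean = x.mean()
    var = x.var()
    if var > 0:
        sd = np.sqrt(var)
        skew = float(np.mean((x - mean) ** 3) / sd**3)
        kurt = float(np.mean((x - mean) ** 4) / var**2 - 3.0)
    else:
        skew = 0.0
        kurt = 0.0
    counts = np.bincount(x.astype(int), minlength=roi.n_levels + 1)[1:]
    p = counts / counts.sum()
    nz = p[p > 0]
    energy = float((p**2).sum())
    entropy = float(-(nz * np.log2(nz)).sum())
    return {
        "mean": float(mean),
        "variance": float(var),
        "skewness": skew,
        "kurtosis": kurt,
        "energy": energy,
        "entropy": entropy,
    }
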