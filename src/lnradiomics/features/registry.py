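"""Canonical ordering, naming and assembly of the 146-feature panel.

The panel layout (1-based indices):

====== ======================= =====================================
Index  Domain                  Features
====== ======================= =====================================
1-6    intensity               FoS: mean, variance, skewness,
                               kurtosis, energy, entropy
7-12   intensity               GLCM: energy, contrast, correlation,
                               homogeneity, entropy, dissimilarity
13-19  intensity               GLRLM: SRE, LRE, GLN, RP, RLN,
                               LGLRE, HGLRE
20-29  intensity               LBP riu2 histogram (10 bins)
30     intensity               box-counting fractal dimension
31-118 wavelet (LL,LH,HL,HH)   per subband: FoS(6) + GLCM(6) +
                               GLRLM(7) + 3 summaries = 22
119-137 gradient               FoS(6) + GLCM(6) + GLRLM(7)
138-146 shape                  area ... circularity
====== ======================= =====================================

This ordering places the named landmark features at their published
positions: feature 8 is the GLCM contrast and feature 16 the run
percentage of the intensity image; features 126 and 129 are the GLCM
contrast and entropy of the gradient image.  The approximation-subband
(LL) block is placed first within the wavelet block; its low gray level
run emphasis is addressed by alias rather than by a fixed index.
"""

from __future__ import annotations

import json
from collections import OrderedDict

import numpy as np

from ..imaging import normalize_quantize
from ..types import CaseRecord, ImageSlice
from .firstorder import FOS_FEATURE_NAMES, first_order_stats
from .fractal import fractal_dimension
from .glcm import GLCM_FEATURE_NAMES, glcm_panel
from .glrlm import GLRLM_FEATURE_NAMES, glrlm_panel
from .gradient import gradient_features
from .lbp import LBP_FEATURE_NAMES, lbp_features
from .shape import SHAPE_FEATURE_NAMES, shape_features
from .wavelet import SUBBANDS, WAVELET_SUMMARY_NAMES, wavelet_features

N_FEATURES = 146


def _build_names() -> tuple[str, ...]:
    names: list[str] = []
    names += [f"fos_{k}" for k in FOS_FEATURE_NAMES]
    names += [f"glcm_{k}" for k in GLCM_FEATURE_NAMES]
    names += [f"glrlm_{k}" for k in GLRLM_FEATURE_NAMES]
    names += list(LBP_FEATURE_NAMES)
    names.append("fractal_dimension")
    for band in SUBBANDS:
        p = f"wavelet_{band}_"
        names += [p + k for k in FOS_FEATURE_NAMES]
        names += [p + "glcm_" + k for k in GLCM_FEATURE_NAMES]
        names += [p + "glrlm_" + k for k in GLRLM_FEATURE_NAMES]
        names += [p + k for k in WAVELET_SUMMARY_NAMES]
    names += ["gradient_" + k for k in FOS_FEATURE_NAMES]
    names += ["gradient_glcm_" + k for k in GLCM_FEATURE_NAMES]
    names += ["gradient_glrlm_" + k for k in GLRLM_FEATURE_NAMES]
    names += ["shape_" + k for k in SHAPE_FEATURE_NAMES]
    assert len(names) == N_FEATURES
    return tuple(names)


FEATURE_NAMES: tuple[str, ...] = _build_names()
_INDEX = {name: i + 1 for i, name in enumerate(FEATURE_NAMES)}  # 1-based

#: Published aliases of the landmark features.
FEATURE_ALIASES = {
    "Contrast": "glcm_contrast",
    "Run percentage": "glrlm_rp",
    "Low gray level run emphasis of approximate wavelet image": "wavelet_ll_glrlm_lglre",
    "Contrast of gradient image": "gradient_glcm_contrast",
    "Entropy of the gradient image": "gradient_glcm_entropy",
}


def feature_names() -> tuple[str, ...]:
    """The canonical, versioned feature order (146 names)."""
    return FEATURE_NAMES


def feature_index(name: str) -> int:
    """1-based index of a canonical feature name or published alias."""
    if name in FEATURE_ALIASES:
        name = FEATURE_ALIASES[name]
    if name not in _INDEX:
        raise KeyError(f"unknown feature {name!r}")
    return _INDEX[name]


def _domain(name: str) -> str:
    if name.startswith("wavelet_"):
        return "wavelet"
    if name.startswith("gradient_"):
        return "gradient"
    if name.startswith("shape_"):
        return "shape"
    return "intensity"


def feature_registry() -> list[dict]:
    """Machine-readable registry: index, name, domain, family, aliases."""
    alias_rev: dict[str, str] = {v: k for k, v in FEATURE_ALIASES.items()}
    out = []
    for name in FEATURE_NAMES:
        if "glcm" in name:
            family = "glcm"
        elif "glrlm" in name:
            family = "glrlm"
        elif name.startswith("lbp"):
            family = "lbp"
        elif name == "fractal_dimension":
            family = "fractal"
        elif name.startswith("shape_"):
            family = "shape"
        elif any(name.endswith("_" + s) for s in WAVELET_SUMMARY_NAMES):
            family = "wavelet_summary"
        else:
            family = "fos"
        entry = {"index": _INDEX[name], "name": name, "domain": _domain(name),
                 "family": family}
        if name in alias_rev:
            entry["alias"] = alias_rev[name]
        out.append(entry)
    return out


def write_registry_json(path) -> None:
    with open(path, "w") as fh:
        json.dump(feature_registry(), fh, indent=1)


def assemble_feature_vector(case: CaseRecord, n_levels: int = 8) -> OrderedDict:
    """Extract the full, ordered 146-feature panel for one case.

    Raises with the failing feature family named if any extractor fails.
    """
    img, mask = case.image, case.mask
    values: OrderedDict[str, float] = OrderedDict()

    def run(family, fn):
        try:
            return fn()
        except Exception as exc:  # re-raise with the family named
            raise RuntimeError(f"feature family '{family}' failed for case "
                               f"{case.case_id}: {exc}") from exc

    roi = run("quantization", lambda: normalize_quantize(img, mask, n_levels))
    for k, v in run("fos", lambda: first_order_stats(roi)).items():
        values[f"fos_{k}"] = v
    for k, v in run("glcm", lambda: glcm_panel(roi)).items():
        values[f"glcm_{k}"] = v
    for k, v in run("glrlm", lambda: glrlm_panel(roi)).items():
        values[f"glrlm_{k}"] = v

    px = img.pixels
    lo, hi = float(px[mask].min()), float(px[mask].max())
    norm = (px - lo) / (hi - lo) if hi > lo else np.zeros_like(px)
    values.update(run("lbp", lambda: lbp_features(norm, mask)))
    values["fractal_dimension"] = run("fractal", lambda: fractal_dimension(roi))
    values.update(run("wavelet", lambda: wavelet_features(img, mask, n_levels=n_levels)))
    values.update(run("gradient", lambda: gradient_features(img, mask, n_levels=n_levels)))
    for k, v in run("shape", lambda: shape_features(mask, img.spacing[0])).items():
        values[f"shape_{k}"] = v

    assert tuple(values) == FEATURE_NAMES
    vec = np.array(list(values.values()), dtype=float)
    if not np.all(np.isfinite(vec)):
        bad = [n for n, v in values.items() if not np.isfinite(v)]
        raise RuntimeError(f"non-finite features for case {case.case_id}: {bad}")
    return values


# ---------------------------------------------------------------------------
# feature table I/O


def write_feature_table(rows: list[tuple[str, int, OrderedDict]], path) -> None:
    """Write (case_id, label, features) rows as a canonical-header CSV."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["case_id", "label", *FEATURE_NAMES])
        for case_id, label, feats in rows:
            w.writerow([case_id, label, *(repr(float(feats[n])) for n in FEATURE_NAMES)])


def read_feature_table(path):
    """Read a feature CSV into (case_ids, labels, X, names)."""
    import csv

    with open(path, newline="") as fh:
        r = csv.reader(fh)
        header = next(r)
        names = tuple(header[2:])
        ids, labels, data = [], [], []
        for row in r:
            ids.append(row[0])
            labels.append(int(row[1]))
            data.append([float(v) for v in row[2:]])
    return ids, np.asarray(labels), np.asarray(data), names
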