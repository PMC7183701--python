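"""Image I/O, resampling, slice selection and gray-level quantization.

All texture features operate on a :class:`~lnradiomics.types.QuantizedROI`
produced here: intensities are min-max normalized over the ROI and mapped to
8 discrete gray levels, mirroring the preprocessing used for CT lymph-node
texture analysis (slices resampled to 1 mm in-plane with cubic b-splines,
one slice per node — the slice of maximal in-plane diameter).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .types import ImageSlice, QuantizedROI

__all__ = [
    "resample_inplane",
    "resample_mask_inplane",
    "select_max_diameter_slice",
    "normalize_quantize",
    "read_nifti_slice",
    "write_nifti_case",
    "read_matrix",
    "write_quantized_csv",
]


def resample_inplane(slice_: ImageSlice, target_spacing: float = 1.0) -> ImageSlice:
    """Resample a slice to isotropic in-plane spacing with cubic b-splines.

    The physical extent (shape x spacing) is preserved to within one output
    pixel.  A slice already at the target spacing is returned unchanged.
    """
    if target_spacing <= 0:
        raise ValueError("target spacing must be positive")
    if not np.all(np.isfinite(slice_.pixels)):
        raise ValueError("cannot resample non-finite pixels")
    if slice_.spacing == (target_spacing, target_spacing):
        return slice_
    factors = (slice_.spacing[0] / target_spacing, slice_.spacing[1] / target_spacing)
    out = ndimage.zoom(slice_.pixels, factors, order=3, mode="mirror", grid_mode=True)
    return ImageSlice(out, (target_spacing, target_spacing), slice_.origin)


def resample_mask_inplane(mask: np.ndarray, spacing: tuple[float, float],
                          target_spacing: float = 1.0) -> np.ndarray:
    """Nearest-neighbour mask resampling; pixels > 0.5 are in-ROI."""
    mask = np.asarray(mask)
    if spacing == (target_spacing, target_spacing):
        return mask > 0.5
    factors = (spacing[0] / target_spacing, spacing[1] / target_spacing)
    out = ndimage.zoom(mask.astype(float), factors, order=0, mode="nearest",
                       grid_mode=True)
    return out > 0.5


def _max_feret(mask: np.ndarray) -> float:
    props = regionprops(cc_label(mask.astype(int) > 0))
    if not props:
        return 0.0
    return max(p.feret_diameter_max for p in props)


def select_max_diameter_slice(volume, mask_volume):
    """Pick the slice whose mask has the largest maximal (Feret) diameter.

    ``volume`` is a sequence of :class:`ImageSlice`, ``mask_volume`` the
    matching sequence of binary masks.  Ties break to the lowest slice index.
    """
    best = None
    best_d = -1.0
    for idx, (sl, m) in enumerate(zip(volume, mask_volume)):
        m = np.asarray(m) > 0
        if not m.any():
            continue
        d = _max_feret(m)
        if d > best_d:
            best_d = d
            best = (sl, m)
    if best is None:
        raise ValueError("mask is empty on every slice")
    return best


def normalize_quantize(slice_: ImageSlice, mask: np.ndarray, n_levels: int = 8,
                       bounds: str = "roi") -> QuantizedROI:
    """Min-max normalize and quantize to ``n_levels`` gray levels.

    Normalization bounds come from in-mask pixels only (``bounds="roi"``,
    default) so the gray levels describe the node rather than surrounding
    tissue; ``bounds="slice"`` uses the whole slice instead.  The normalized
    value v in [0, 1] maps to level ``floor(v * B) + 1`` with v = 1 mapped to
    level B; a flat region maps everything to level 1.
    """
    mask = np.asarray(mask) > 0
    if not mask.any():
        raise ValueError("empty mask")
    if n_levels < 2:
        raise ValueError("need at least 2 levels")
    px = slice_.pixels
    ref = px[mask] if bounds == "roi" else px
    lo, hi = float(ref.min()), float(ref.max())
    levels = np.zeros(px.shape, dtype=int)
    if hi > lo:
        v = np.clip((px - lo) / (hi - lo), 0.0, 1.0)
        q = np.floor(v * n_levels).astype(int) + 1
        q[q > n_levels] = n_levels  # v == 1 belongs to the top bin
        levels[mask] = q[mask]
    else:
        levels[mask] = 1
    return QuantizedROI(levels, mask, n_levels, (lo, hi))


# ---------------------------------------------------------------------------
# file I/O


def read_nifti_slice(image_path, mask_path, slice_axis: int = 2):
    """Read a NIfTI image/mask pair and return (slices, masks, spacing).

    2-D files yield single-element lists.  Spacing is taken from the affine
    zooms of the in-plane axes.
    """
    import nibabel as nib

    img = nib.load(str(image_path))
    msk = nib.load(str(mask_path))
    data = np.asanyarray(img.dataobj, dtype=float)
    mdata = np.asanyarray(msk.dataobj, dtype=float)
    zooms = img.header.get_zooms()
    if data.ndim == 2:
        spacing = (float(zooms[0]), float(zooms[1]))
        return [ImageSlice(data, spacing)], [mdata > 0.5], spacing
    inplane = [ax for ax in range(3) if ax != slice_axis]
    spacing = (float(zooms[inplane[0]]), float(zooms[inplane[1]]))
    slices, masks = [], []
    for k in range(data.shape[slice_axis]):
        sl = np.take(data, k, axis=slice_axis)
        mk = np.take(mdata, k, axis=slice_axis)
        slices.append(ImageSlice(sl, spacing))
        masks.append(mk > 0.5)
    return slices, masks, spacing


def write_nifti_case(case, image_path, mask_path) -> None:
    """Write one case's image and mask as 2-D NIfTI files (1 mm affine)."""
    import nibabel as nib

    aff = np.diag([case.image.spacing[0], case.image.spacing[1], 1.0, 1.0])
    nib.save(nib.Nifti1Image(case.image.pixels.astype(np.float32), aff), str(image_path))
    nib.save(nib.Nifti1Image(case.mask.astype(np.uint8), aff), str(mask_path))


def read_matrix(path) -> np.ndarray:
    """Read a plain whitespace/CSV matrix fixture."""
    return np.loadtxt(str(path), delimiter=None if _is_whitespace(path) else ",")


def _is_whitespace(path) -> bool:
    with open(path) as fh:
        first = fh.readline()
    return "," not in first


def write_quantized_csv(roi: QuantizedROI, path) -> None:
    """Dump a QuantizedROI's level matrix (0 outside mask) to CSV."""
    np.savetxt(str(path), roi.levels, fmt="%d", delimiter=",")
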