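"""Whole-brain ROI segmentation.

The brain mask is obtained from a scalar map by Gaussian smoothing (to fill
holes before thresholding), threshold segmentation (Otsu by default),
keeping the largest 26-connected component (an automated replacement for
manual removal of extracranial noise), and 3-D hole filling.
"""
from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .core import BrainMask, ScalarMap

log = logging.getLogger(__name__)

_STRUCT26 = np.ones((3, 3, 3), dtype=int)


def smooth_map(map_: ScalarMap, sigma_mm: float) -> ScalarMap:
    """Gaussian-smoothed copy; sigma is physical (mm), converted per axis."""
    if sigma_mm <= 0:
        raise ValueError("sigma_mm must be positive")
    sigma_vox = [sigma_mm / s for s in map_.spacing]
    for ax, (sv, n) in enumerate(zip(sigma_vox, map_.shape)):
        if int(4.0 * sv + 0.5) >= n:
            raise ValueError(
                f"sigma {sigma_mm} mm gives a kernel radius exceeding axis {ax} "
                f"(size {n})"
            )
    out = ndimage.gaussian_filter(map_.data, sigma=sigma_vox)
    return ScalarMap(out, map_.kind, spacing=map_.spacing, subject_id=map_.subject_id)


def threshold_segment(map_: ScalarMap, method: str = "otsu",
                      fixed_value: float | None = None) -> np.ndarray:
    """Binary foreground of voxels strictly above the threshold."""
    if method == "otsu":
        thr = float(threshold_otsu(map_.data))
    elif method == "fixed":
        if fixed_value is None:
            raise ValueError("method='fixed' requires fixed_value")
        thr = float(fixed_value)
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    fg = map_.data > thr
    if not fg.any():
        raise ValueError(
            f"threshold {thr:g} leaves an empty foreground; use a lower threshold"
        )
    log.info("threshold_segment: method=%s threshold=%g foreground=%d voxels",
             method, thr, int(fg.sum()))
    return fg


def clean_mask(raw: np.ndarray, spacing=(1.0, 1.0, 1.0), source_kind="FA") -> BrainMask:
    """Largest 26-connected component, with enclosed cavities filled."""
    raw = np.asarray(raw, dtype=bool)
    if not raw.any():
        raise ValueError("raw mask has no foreground voxels")
    lab, n = ndimage.label(raw, structure=_STRUCT26)
    if n > 1:
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        keep = lab == sizes.argmax()
    else:
        keep = raw
    filled = ndimage.binary_fill_holes(keep)
    return BrainMask(filled, spacing=spacing, source_kind=source_kind).validate()


def make_brain_mask(map_: ScalarMap, sigma_mm: float = 1.0, method: str = "otsu",
                    fixed_value: float | None = None) -> BrainMask:
    """Full segmentation pipeline: smooth, threshold, clean."""
    smoothed = smooth_map(map_, sigma_mm)
    raw = threshold_segment(smoothed, method=method, fixed_value=fixed_value)
    return clean_mask(raw, spacing=map_.spacing, source_kind=map_.kind)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    return 2.0 * np.logical_and(a, b).sum() / denom if denom else 1.0
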