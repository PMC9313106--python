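"""Core in-memory containers shared by the pipeline stages.

Volumes are plain 3-D ``numpy`` arrays indexed ``(x, y, z)`` with axial
slices along the last axis; physical voxel spacing travels alongside the
data in millimetres.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

Spacing = Tuple[float, float, float]

FA = "FA"
MD = "MD"
MAP_KINDS = (FA, MD)


def _as_volume(a, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 3:
        raise ValueError(f"{name} must be a 3-D volume, got shape {a.shape}")
    return a


@dataclass
class EigenvalueVolume:
    """Co-registered diffusion-tensor eigenvalue maps (mm^2/s).

    ``lam1 >= lam2 >= lam3`` voxel-wise after :meth:`sorted_clamped`; raw
    scanner fits may violate this (noise can produce negative eigenvalues),
    so the constructor accepts any finite input.
    """

    lam1: np.ndarray
    lam2: np.ndarray
    lam3: np.ndarray
    spacing: Spacing = (1.0, 1.0, 1.0)
    subject_id: Optional[str] = None

    def __post_init__(self):
        self.lam1 = _as_volume(self.lam1, "lam1")
        self.lam2 = _as_volume(self.lam2, "lam2")
        self.lam3 = _as_volume(self.lam3, "lam3")
        for name, v in (("lam2", self.lam2), ("lam3", self.lam3)):
            if v.shape != self.lam1.shape:
                raise ValueError(
                    f"eigenvalue volume {name} has shape {v.shape}, "
                    f"expected {self.lam1.shape} (lam1)"
                )
        for name, v in (("lam1", self.lam1), ("lam2", self.lam2), ("lam3", self.lam3)):
            if not np.all(np.isfinite(v)):
                raise ValueError(f"eigenvalue volume {name} contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.lam1.shape

    def stacked(self) -> np.ndarray:
        """Eigenvalues as a (..., 3) array."""
        return np.stack([self.lam1, self.lam2, self.lam3], axis=-1)

    def sorted_clamped(self) -> Tuple["EigenvalueVolume", float]:
        """Sort eigenvalues descending per voxel and clamp negatives to 0.

        Returns the cleaned volume and the fraction of voxels in which at
        least one eigenvalue was clamped.
        """
        lam = np.sort(self.stacked(), axis=-1)[..., ::-1]
        clamped = np.any(lam < 0, axis=-1)
        lam = np.clip(lam, 0.0, None)
        out = EigenvalueVolume(
            lam[..., 0], lam[..., 1], lam[..., 2],
            spacing=self.spacing, subject_id=self.subject_id,
        )
        return out, float(clamped.mean())


@dataclass
class ScalarMap:
    """One scalar DTI map: FA (dimensionless, [0, 1]) or MD (mm^2/s, >= 0)."""

    data: np.ndarray
    kind: str
    spacing: Spacing = (1.0, 1.0, 1.0)
    subject_id: Optional[str] = None

    def __post_init__(self):
        self.data = _as_volume(self.data, "map data")
        if self.kind not in MAP_KINDS:
            raise ValueError(f"map kind must be one of {MAP_KINDS}, got {self.kind!r}")
        self.spacing = tuple(float(s) for s in self.spacing)

    def validate(self) -> "ScalarMap":
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"{self.kind} map contains non-finite values")
        if self.kind == FA:
            if self.data.min() < -1e-9 or self.data.max() > 1 + 1e-9:
                raise ValueError("FA map must lie in [0, 1]")
        else:
            if self.data.min() < -1e-12:
                raise ValueError("MD map must be non-negative")
        return self

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class BrainMask:
    """Whole-brain ROI: one 26-connected component with no enclosed cavities."""

    data: np.ndarray
    spacing: Spacing = (1.0, 1.0, 1.0)
    source_kind: str = FA

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"mask must be 3-D, got shape {data.shape}")
        self.data = data.astype(bool)
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    def validate(self) -> "BrainMask":
        from scipy import ndimage

        if self.voxel_count == 0:
            raise ValueError("brain mask is empty")
        _, n = ndimage.label(self.data, structure=np.ones((3, 3, 3), dtype=int))
        if n != 1:
            raise ValueError(f"brain mask has {n} connected components, expected 1")
        if ndimage.binary_fill_holes(self.data).sum() != self.voxel_count:
            raise ValueError("brain mask contains enclosed cavities")
        return self


@dataclass
class TransformedVolume:
    """A derived image form together with the ROI mask valid on its grid.

    Wavelet subbands live on a decimated grid, so the mask (and spacing)
    may differ from the source map's.
    """

    data: np.ndarray
    mask: np.ndarray
    descriptor: "object"
    source_kind: str = FA
    spacing: Spacing = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = _as_volume(self.data, "transformed data")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape:
            raise ValueError("transformed volume and its mask must share a grid")


@dataclass
class DiscretizedROI:
    """Gray-level discretization of a masked volume.

    ``levels`` holds integer levels 1..Ng inside the mask and 0 outside.
    ``degenerate`` flags a constant masked region (all voxels level 1).
    """

    levels: np.ndarray
    Ng: int
    bin_edges: np.ndarray
    Np: int
    degenerate: bool = False

    def masked_levels(self) -> np.ndarray:
        return self.levels[self.levels > 0]


@dataclass
class ROCResult:
    """ROC summary: AUC, full curve, and the Youden-optimal operating point."""

    auc: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    youden_cutpoint: Tuple[float, float, float]  # (score, specificity, sensitivity)

    def curve(self):
        return list(zip(self.thresholds, self.sensitivity, self.specificity))
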