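"""Gray-level texture matrices and feature sets.

For every image form the masked intensities are discretized into ``Ng``
equal-width levels and four matrix classes are built in 3-D:

* GLCM  — joint distribution of level pairs at a fixed voxel offset,
  accumulated over the 13 unique 3-D directions, symmetrized and pooled
  across directions before normalization;
* GLRLM — counts of consecutive same-level runs per direction; features
  are averaged over the 13 directions;
* GLSZM — counts of 26-connected same-level zones by size;
* GLDM  — counts of voxels by (level, number of 26-neighbours within
  ``alpha`` levels); matrix columns are indexed by dependence + 1.

All entropy-type features use the natural logarithm with the convention
0 * ln 0 = 0.  Features whose defining formula degenerates to 0/0 on a
constant region are emitted as 0 (never NaN) and counted in a logged
warning, so downstream selection never sees missing values.
"""
from __future__ import annotations

import logging
from collections import OrderedDict
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import label as _sklabel

from .core import BrainMask, DiscretizedROI, ScalarMap, TransformedVolume
from .registry import CLASS_ORDER, feature_id, feature_registry
from .transforms import TransformDescriptor, apply_transform, default_manifest

log = logging.getLogger(__name__)

#: the 13 unique displacement directions of a 26-neighbourhood
DIRECTIONS_13: Tuple[Tuple[int, int, int], ...] = (
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)


# ---------------------------------------------------------------------------
# discretization


def discretize(vol, mask=None, Ng: int = 32) -> DiscretizedROI:
    """Equal-width discretization of masked intensities into levels 1..Ng.

    Bins are half-open with the maximum value closed into the top bin.
    A constant masked region maps every voxel to level 1 and sets the
    degenerate flag.
    """
    if isinstance(vol, TransformedVolume):
        data, mask = vol.data, vol.mask
    else:
        data = np.asarray(vol, dtype=float)
        mask = np.asarray(mask, dtype=bool)
    if Ng < 2:
        raise ValueError("Ng must be >= 2")
    if not mask.any():
        raise ValueError("mask has no foreground voxels")
    vals = data[mask]
    mn, mx = float(vals.min()), float(vals.max())
    levels = np.zeros(data.shape, dtype=np.int32)
    if mx == mn:
        levels[mask] = 1
        edges = np.linspace(mn, mn + 1.0, Ng + 1)
        return DiscretizedROI(levels, Ng, edges, int(mask.sum()), degenerate=True)
    width = (mx - mn) / Ng
    lv = np.floor((vals - mn) / width).astype(np.int32) + 1
    np.clip(lv, 1, Ng, out=lv)
    levels[mask] = lv
    edges = mn + width * np.arange(Ng + 1)
    return DiscretizedROI(levels, Ng, edges, int(mask.sum()), degenerate=False)


def roi_from_levels(levels) -> DiscretizedROI:
    """Wrap an explicit integer level array (0 = background) as a ROI."""
    levels = np.asarray(levels, dtype=np.int32)
    if levels.ndim < 3:
        levels = levels.reshape(levels.shape + (1,) * (3 - levels.ndim))
    ng = max(int(levels.max()), 1)
    npx = int((levels > 0).sum())
    return DiscretizedROI(levels, ng, np.arange(ng + 1, dtype=float), npx,
                          degenerate=(len(np.unique(levels[levels > 0])) <= 1))


# ---------------------------------------------------------------------------
# geometry helpers


def _offset_pairs(shape, off):
    """Slice pair (sl_a, sl_b) such that volume[sl_b] = volume[sl_a] shifted by off."""
    sl_a, sl_b = [], []
    for n, o in zip(shape, off):
        if o >= 0:
            sl_a.append(slice(0, n - o))
            sl_b.append(slice(o, n))
        else:
            sl_a.append(slice(-o, n))
            sl_b.append(slice(0, n + o))
    return tuple(sl_a), tuple(sl_b)


@lru_cache(maxsize=512)
def _line_order(shape: Tuple[int, int, int], d: Tuple[int, int, int]):
    """Permutation putting voxels in line-major order along direction d.

    Voxels on a common digital line p0 + k*d are contiguous and ordered by
    k; ``new_line`` marks the first voxel of each line.  Cached per
    (shape, direction) since the ordering is data-independent.
    """
    idx = np.indices(shape).reshape(3, -1)
    dv = np.asarray(d)
    dd = int(dv @ dv)
    t = dv @ idx
    q = idx * dd - dv[:, None] * t
    perm = np.lexsort((t, q[2], q[1], q[0]))
    qs = q[:, perm]
    new_line = np.empty(perm.size, dtype=bool)
    new_line[0] = True
    new_line[1:] = (np.diff(qs, axis=1) != 0).any(axis=0)
    return perm, new_line


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum()) if p.size else 0.0


# ---------------------------------------------------------------------------
# matrix containers


@dataclass
class GLCMatrix:
    p: np.ndarray               # Ng x Ng, symmetric, sums to 1 (unless degenerate)
    Ng: int
    distance: int = 1
    direction_policy: str = "pooled-13"
    degenerate: bool = False


@dataclass
class GLRLMatrix:
    per_direction: List[np.ndarray]  # count matrices Ng x max_run_length
    Ng: int
    Np: int
    degenerate: bool = False


@dataclass
class GLSZMatrix:
    P: np.ndarray               # Ng x max_zone_size counts
    Ng: int
    Np: int
    Nz: int
    degenerate: bool = False


@dataclass
class GLDMatrix:
    P: np.ndarray               # Ng x (Nd + 1) counts, columns = dependence 0..Nd
    Ng: int
    Np: int
    alpha: int = 0
    degenerate: bool = False


# ---------------------------------------------------------------------------
# matrix builders


def build_glcm(d: DiscretizedROI, distance: int = 1,
               directions: Optional[Sequence[Tuple[int, int, int]]] = None
               ) -> GLCMatrix:
    if distance < 1:
        raise ValueError("distance must be >= 1")
    dirs = DIRECTIONS_13 if directions is None else tuple(directions)
    lv = d.levels
    Ng = d.Ng
    counts = np.zeros(Ng * Ng)
    for direc in dirs:
        off = tuple(distance * o for o in direc)
        sl_a, sl_b = _offset_pairs(lv.shape, off)
        a = lv[sl_a].ravel()
        b = lv[sl_b].ravel()
        ok = (a > 0) & (b > 0)
        if ok.any():
            counts += np.bincount((a[ok] - 1) * Ng + (b[ok] - 1),
                                  minlength=Ng * Ng)
    C = counts.reshape(Ng, Ng)
    C = C + C.T
    tot = C.sum()
    if tot == 0:
        return GLCMatrix(C, Ng, distance, degenerate=True)
    return GLCMatrix(C / tot, Ng, distance)


def build_glrlm(d: DiscretizedROI,
                directions: Optional[Sequence[Tuple[int, int, int]]] = None
                ) -> GLRLMatrix:
    dirs = DIRECTIONS_13 if directions is None else tuple(directions)
    lv = d.levels
    Ng = d.Ng
    maxlen = max(lv.shape)
    flat = lv.ravel()
    mats = []
    for direc in dirs:
        perm, new_line = _line_order(lv.shape, tuple(direc))
        v = flat[perm]
        start = new_line.copy()
        start[1:] |= v[1:] != v[:-1]
        sidx = np.flatnonzero(start)
        lengths = np.diff(np.append(sidx, v.size))
        glv = v[sidx]
        keep = glv > 0
        G, L = glv[keep], lengths[keep]
        M = np.bincount((G - 1) * maxlen + (L - 1),
                        minlength=Ng * maxlen).reshape(Ng, maxlen)
        mats.append(M.astype(float))
    return GLRLMatrix(mats, Ng, d.Np, degenerate=d.Np == 0)


def build_glszm(d: DiscretizedROI) -> GLSZMatrix:
    lv = d.levels
    Ng = d.Ng
    lab = _sklabel(lv, background=0, connectivity=3)
    nz = int(lab.max())
    if nz == 0:
        return GLSZMatrix(np.zeros((Ng, 1)), Ng, d.Np, 0, degenerate=True)
    sizes = np.bincount(lab.ravel())[1:]
    lvl_of = np.zeros(nz + 1, dtype=np.int64)
    lvl_of[lab.ravel()] = lv.ravel()       # all voxels of a zone share a level
    zlevels = lvl_of[1:]
    maxsize = int(sizes.max())
    P = np.bincount((zlevels - 1) * maxsize + (sizes - 1),
                    minlength=Ng * maxsize).reshape(Ng, maxsize).astype(float)
    return GLSZMatrix(P, Ng, d.Np, nz)


def build_gldm(d: DiscretizedROI, alpha: int = 0) -> GLDMatrix:
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    lv = d.levels
    Ng = d.Ng
    dep = np.zeros(lv.shape, dtype=np.int32)
    for direc in DIRECTIONS_13:
        sl_a, sl_b = _offset_pairs(lv.shape, direc)
        a = lv[sl_a]
        b = lv[sl_b]
        ok = (a > 0) & (b > 0) & (np.abs(a - b) <= alpha)
        dep[sl_a] += ok
        dep[sl_b] += ok
    inm = lv > 0
    g = lv[inm]
    k = dep[inm]
    ncol = int(k.max()) + 1 if k.size else 1
    P = np.bincount((g - 1) * ncol + k,
                    minlength=Ng * ncol).reshape(Ng, ncol).astype(float)
    return GLDMatrix(P, Ng, d.Np, alpha=alpha)


# ---------------------------------------------------------------------------
# feature sets


def glcm_contrast(g: GLCMatrix) -> float:
    i = np.arange(1, g.Ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    return float((((ii - jj) ** 2) * g.p).sum())


def glcm_imc1(g: GLCMatrix) -> float:
    p = g.p
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    hx, hy = _entropy(px), _entropy(py)
    denom = max(hx, hy)
    if denom == 0:
        return 0.0
    hxy = _entropy(p.ravel())
    outer = np.outer(px, py)
    nzm = p > 0
    hxy1 = float(-(p[nzm] * np.log(outer[nzm])).sum())
    return (hxy - hxy1) / denom


def glcm_feature_set(g: GLCMatrix) -> "OrderedDict[str, float]":
    Ng = g.Ng
    p = g.p
    names = feature_registry()["GLCM"]
    if g.degenerate or p.sum() == 0:
        return OrderedDict((n, np.nan) for n in names)
    i = np.arange(1, Ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mux = float((i * px).sum())
    muy = float((i * py).sum())
    sigx = float(np.sqrt(((i - mux) ** 2 * px).sum()))
    sigy = float(np.sqrt(((i - muy) ** 2 * py).sum()))

    kdiff = np.arange(Ng, dtype=float)
    pdiff = np.bincount(np.abs(ii - jj).astype(int).ravel(), weights=p.ravel(),
                        minlength=Ng)
    ksum = np.arange(2, 2 * Ng + 1, dtype=float)
    psum = np.bincount((ii + jj).astype(int).ravel(), weights=p.ravel(),
                       minlength=2 * Ng + 1)[2:]

    hx, hy = _entropy(px), _entropy(py)
    hxy = _entropy(p.ravel())
    outer = np.outer(px, py)
    nzm = p > 0
    hxy1 = float(-(p[nzm] * np.log(outer[nzm])).sum())
    hxy2 = _entropy(outer.ravel())

    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (float((ii * jj * p).sum()) - mux * muy) / (sigx * sigy) \
            if sigx > 0 and sigy > 0 else np.nan
        da = float((kdiff * pdiff).sum())
        offdiag = ii != jj
        inv_var = float((p[offdiag] / (ii - jj)[offdiag] ** 2).sum())

    # maximal correlation coefficient: sqrt of the second-largest eigenvalue
    # of Q(i,j) = sum_k p(i,k) p(j,k) / (px_i py_k)
    rows = px > 0
    if rows.sum() < 2:
        mcc = np.nan
    else:
        A = p[np.ix_(rows, rows)]
        pxr = px[rows]
        B = A / py[rows][None, :]
        Q = (B @ A.T) / pxr[:, None]
        ev = np.sort(np.real(np.linalg.eigvals(Q)))[::-1]
        mcc = float(np.sqrt(max(ev[1], 0.0)))

    f = OrderedDict()
    f["Autocorrelation"] = float((ii * jj * p).sum())
    f["ClusterProminence"] = float(((ii + jj - mux - muy) ** 4 * p).sum())
    f["ClusterShade"] = float(((ii + jj - mux - muy) ** 3 * p).sum())
    f["ClusterTendency"] = float(((ii + jj - mux - muy) ** 2 * p).sum())
    f["Contrast"] = float(((ii - jj) ** 2 * p).sum())
    f["Correlation"] = corr
    f["DifferenceAverage"] = da
    f["DifferenceEntropy"] = _entropy(pdiff)
    f["DifferenceVariance"] = float(((kdiff - da) ** 2 * pdiff).sum())
    f["Id"] = float((p / (1.0 + np.abs(ii - jj))).sum())
    f["Idm"] = float((p / (1.0 + (ii - jj) ** 2)).sum())
    f["Idmn"] = float((p / (1.0 + (ii - jj) ** 2 / Ng ** 2)).sum())
    f["Idn"] = float((p / (1.0 + np.abs(ii - jj) / Ng)).sum())
    f["Imc1"] = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else np.nan
    f["Imc2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    f["InverseVariance"] = inv_var
    f["JointAverage"] = mux
    f["JointEnergy"] = float((p ** 2).sum())
    f["JointEntropy"] = hxy
    f["MCC"] = mcc
    f["MaximumProbability"] = float(p.max())
    f["SumAverage"] = float((ksum * psum).sum())
    f["SumEntropy"] = _entropy(psum)
    f["SumSquares"] = float(((ii - mux) ** 2 * p).sum())
    assert list(f) == names
    return f


def _glrlm_dir_features(P: np.ndarray, Np: int) -> "OrderedDict[str, float]":
    Ng, maxlen = P.shape
    Nr = P.sum()
    f = OrderedDict()
    names = feature_registry()["GLRLM"]
    if Nr == 0:
        return OrderedDict((n, np.nan) for n in names)
    i = np.arange(1, Ng + 1, dtype=float)[:, None]
    j = np.arange(1, maxlen + 1, dtype=float)[None, :]
    p = P / Nr
    pg = P.sum(axis=1)
    pr = P.sum(axis=0)
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    f["ShortRunEmphasis"] = float((P / j ** 2).sum() / Nr)
    f["LongRunEmphasis"] = float((P * j ** 2).sum() / Nr)
    f["GrayLevelNonUniformity"] = float((pg ** 2).sum() / Nr)
    f["GrayLevelNonUniformityNormalized"] = float((pg ** 2).sum() / Nr ** 2)
    f["RunLengthNonUniformity"] = float((pr ** 2).sum() / Nr)
    f["RunLengthNonUniformityNormalized"] = float((pr ** 2).sum() / Nr ** 2)
    f["RunPercentage"] = float(Nr / Np) if Np else np.nan
    f["GrayLevelVariance"] = float((p * (i - mu_i) ** 2).sum())
    f["RunVariance"] = float((p * (j - mu_j) ** 2).sum())
    f["RunEntropy"] = _entropy(p.ravel())
    f["LowGrayLevelRunEmphasis"] = float((P / i ** 2).sum() / Nr)
    f["HighGrayLevelRunEmphasis"] = float((P * i ** 2).sum() / Nr)
    f["ShortRunLowGrayLevelEmphasis"] = float((P / (i ** 2 * j ** 2)).sum() / Nr)
    f["ShortRunHighGrayLevelEmphasis"] = float((P * i ** 2 / j ** 2).sum() / Nr)
    f["LongRunLowGrayLevelEmphasis"] = float((P * j ** 2 / i ** 2).sum() / Nr)
    f["LongRunHighGrayLevelEmphasis"] = float((P * i ** 2 * j ** 2).sum() / Nr)
    assert list(f) == names
    return f


def glrlm_feature_set(m: GLRLMatrix) -> "OrderedDict[str, float]":
    """Per-direction features averaged over the direction set."""
    per_dir = [_glrlm_dir_features(P, m.Np) for P in m.per_direction]
    names = list(per_dir[0])
    return OrderedDict(
        (n, float(np.mean([d[n] for d in per_dir]))) for n in names
    )


def glrlm_long_run_low_gray_level_emphasis(m: GLRLMatrix) -> float:
    return glrlm_feature_set(m)["LongRunLowGrayLevelEmphasis"]


def glszm_feature_set(m: GLSZMatrix) -> "OrderedDict[str, float]":
    names = feature_registry()["GLSZM"]
    if m.Nz == 0:
        return OrderedDict((n, np.nan) for n in names)
    P = m.P
    Ng, maxsize = P.shape
    Nz = m.Nz
    i = np.arange(1, Ng + 1, dtype=float)[:, None]
    j = np.arange(1, maxsize + 1, dtype=float)[None, :]
    p = P / Nz
    pg = P.sum(axis=1)
    ps = P.sum(axis=0)
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    f = OrderedDict()
    f["SmallAreaEmphasis"] = float((P / j ** 2).sum() / Nz)
    f["LargeAreaEmphasis"] = float((P * j ** 2).sum() / Nz)
    f["GrayLevelNonUniformity"] = float((pg ** 2).sum() / Nz)
    f["GrayLevelNonUniformityNormalized"] = float((pg ** 2).sum() / Nz ** 2)
    f["SizeZoneNonUniformity"] = float((ps ** 2).sum() / Nz)
    f["SizeZoneNonUniformityNormalized"] = float((ps ** 2).sum() / Nz ** 2)
    f["ZonePercentage"] = float(Nz / m.Np) if m.Np else np.nan
    f["GrayLevelVariance"] = float((p * (i - mu_i) ** 2).sum())
    f["ZoneVariance"] = float((p * (j - mu_j) ** 2).sum())
    f["ZoneEntropy"] = _entropy(p.ravel())
    f["LowGrayLevelZoneEmphasis"] = float((P / i ** 2).sum() / Nz)
    f["HighGrayLevelZoneEmphasis"] = float((P * i ** 2).sum() / Nz)
    f["SmallAreaLowGrayLevelEmphasis"] = float((P / (i ** 2 * j ** 2)).sum() / Nz)
    f["SmallAreaHighGrayLevelEmphasis"] = float((P * i ** 2 / j ** 2).sum() / Nz)
    f["LargeAreaLowGrayLevelEmphasis"] = float((P * j ** 2 / i ** 2).sum() / Nz)
    f["LargeAreaHighGrayLevelEmphasis"] = float((P * i ** 2 * j ** 2).sum() / Nz)
    assert list(f) == names
    return f


def glszm_zone_variance(m: GLSZMatrix) -> float:
    return glszm_feature_set(m)["ZoneVariance"]


def glszm_small_area_low_gray_level_emphasis(m: GLSZMatrix) -> float:
    return glszm_feature_set(m)["SmallAreaLowGrayLevelEmphasis"]


def gldm_feature_set(m: GLDMatrix) -> "OrderedDict[str, float]":
    names = feature_registry()["GLDM"]
    P = m.P
    Nz = P.sum()
    if Nz == 0:
        return OrderedDict((n, np.nan) for n in names)
    Ng, ncol = P.shape
    i = np.arange(1, Ng + 1, dtype=float)[:, None]
    j = np.arange(1, ncol + 1, dtype=float)[None, :]   # dependence + 1
    p = P / Nz
    pg = P.sum(axis=1)
    pd_ = P.sum(axis=0)
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    f = OrderedDict()
    f["SmallDependenceEmphasis"] = float((P / j ** 2).sum() / Nz)
    f["LargeDependenceEmphasis"] = float((P * j ** 2).sum() / Nz)
    f["GrayLevelNonUniformity"] = float((pg ** 2).sum() / Nz)
    f["DependenceNonUniformity"] = float((pd_ ** 2).sum() / Nz)
    f["GrayLevelVariance"] = float((p * (i - mu_i) ** 2).sum())
    f["DependenceVariance"] = float((p * (j - mu_j) ** 2).sum())
    f["DependenceEntropy"] = _entropy(p.ravel())
    f["LowGrayLevelEmphasis"] = float((P / i ** 2).sum() / Nz)
    f["HighGrayLevelEmphasis"] = float((P * i ** 2).sum() / Nz)
    f["SmallDependenceLowGrayLevelEmphasis"] = float((P / (i ** 2 * j ** 2)).sum() / Nz)
    f["SmallDependenceHighGrayLevelEmphasis"] = float((P * i ** 2 / j ** 2).sum() / Nz)
    f["LargeDependenceLowGrayLevelEmphasis"] = float((P * j ** 2 / i ** 2).sum() / Nz)
    f["LargeDependenceHighGrayLevelEmphasis"] = float((P * i ** 2 * j ** 2).sum() / Nz)
    assert list(f) == names
    return f


def histogram_feature_set(vol, mask=None, Ng: int = 32,
                          voxel_volume: float = 1.0) -> "OrderedDict[str, float]":
    """First-order statistics of the masked intensities.

    Kurtosis is the Pearson (non-excess) moment ratio m4 / m2^2 with
    population moments; Entropy and Uniformity are computed on the Ng-bin
    equal-width discretized histogram.
    """
    if isinstance(vol, TransformedVolume):
        data, mask = vol.data, vol.mask
    else:
        data = np.asarray(vol, dtype=float)
        mask = np.asarray(mask, dtype=bool)
    x = data[mask]
    names = feature_registry()["Histogram"]
    if x.size == 0:
        return OrderedDict((n, np.nan) for n in names)
    mean = float(x.mean())
    m2 = float(((x - mean) ** 2).mean())
    m3 = float(((x - mean) ** 3).mean())
    m4 = float(((x - mean) ** 4).mean())
    p10, p25, med, p75, p90 = (float(np.percentile(x, q))
                               for q in (10, 25, 50, 75, 90))
    sub = x[(x >= p10) & (x <= p90)]
    d = discretize(data, mask, Ng=max(Ng, 2))
    counts = np.bincount(d.masked_levels(), minlength=d.Ng + 1)[1:]
    ph = counts / counts.sum()

    f = OrderedDict()
    f["Mean"] = mean
    f["Median"] = med
    f["Minimum"] = float(x.min())
    f["Maximum"] = float(x.max())
    f["Range"] = float(x.max() - x.min())
    f["Percentile10"] = p10
    f["Percentile25"] = p25
    f["Percentile75"] = p75
    f["Percentile90"] = p90
    f["InterquartileRange"] = p75 - p25
    f["Variance"] = m2
    f["StandardDeviation"] = float(np.sqrt(m2))
    f["Skewness"] = m3 / m2 ** 1.5 if m2 > 0 else np.nan
    f["Kurtosis"] = m4 / m2 ** 2 if m2 > 0 else np.nan
    f["Energy"] = float((x ** 2).sum())
    f["TotalEnergy"] = float(voxel_volume * (x ** 2).sum())
    f["RootMeanSquared"] = float(np.sqrt((x ** 2).mean()))
    f["MeanAbsoluteDeviation"] = float(np.abs(x - mean).mean())
    f["RobustMeanAbsoluteDeviation"] = (
        float(np.abs(sub - sub.mean()).mean()) if sub.size else np.nan)
    f["MedianAbsoluteDeviation"] = float(np.median(np.abs(x - med)))
    f["CoefficientOfVariation"] = (float(np.sqrt(m2)) / mean
                                   if mean != 0 else np.nan)
    f["Entropy"] = _entropy(ph)
    f["Uniformity"] = float((ph ** 2).sum())
    assert list(f) == names
    return f


def shape_feature_set(mask: BrainMask) -> "OrderedDict[str, float]":
    """Morphology of the ROI itself (computed once per map, original form)."""
    m = mask.data
    sx, sy, sz = mask.spacing
    n = mask.voxel_count
    eroded = ndimage.binary_erosion(m, structure=ndimage.generate_binary_structure(3, 1),
                                    border_value=0)
    surface = int((m & ~eroded).sum())
    idx = np.nonzero(m)
    extents = [(int(i.max()) - int(i.min()) + 1) * s
               for i, s in zip(idx, mask.spacing)]
    coords = np.stack([idx[0] * sx, idx[1] * sy, idx[2] * sz], axis=1).astype(float)
    cov = np.cov(coords, rowvar=False) if n > 1 else np.zeros((3, 3))
    ev = np.sort(np.abs(np.linalg.eigvalsh(cov)))[::-1]
    f = OrderedDict()
    f["VoxelVolume"] = n * float(sx * sy * sz)
    f["SurfaceVoxelCount"] = float(surface)
    f["SurfaceToVolumeRatio"] = surface / n if n else np.nan
    f["BoundingBoxExtentX"] = float(extents[0])
    f["BoundingBoxExtentY"] = float(extents[1])
    f["BoundingBoxExtentZ"] = float(extents[2])
    f["Elongation"] = float(np.sqrt(ev[1] / ev[0])) if ev[0] > 0 else np.nan
    f["Flatness"] = float(np.sqrt(ev[2] / ev[0])) if ev[0] > 0 else np.nan
    return f


# ---------------------------------------------------------------------------
# extraction


def _form_features(tv: TransformedVolume, Ng: int, glcm_distance: int,
                   gldm_alpha: int) -> "OrderedDict[Tuple[str, str], float]":
    reg = feature_registry()
    out: "OrderedDict[Tuple[str, str], float]" = OrderedDict()
    if not tv.mask.any():
        for cls in CLASS_ORDER:
            for name in reg[cls]:
                out[(cls, name)] = np.nan
        return out
    voxvol = float(np.prod(tv.spacing))
    d = discretize(tv, Ng=Ng)
    sets = {
        "Histogram": histogram_feature_set(tv, Ng=Ng, voxel_volume=voxvol),
        "GLCM": glcm_feature_set(build_glcm(d, distance=glcm_distance)),
        "GLRLM": glrlm_feature_set(build_glrlm(d)),
        "GLSZM": glszm_feature_set(build_glszm(d)),
        "GLDM": gldm_feature_set(build_gldm(d, alpha=gldm_alpha)),
    }
    for cls in CLASS_ORDER:
        for name in reg[cls]:
            out[(cls, name)] = sets[cls][name]
    return out


def extract_map_features(map_: ScalarMap, mask: BrainMask,
                         manifest: Optional[Sequence[TransformDescriptor]] = None,
                         Ng: int = 32, glcm_distance: int = 1, gldm_alpha: int = 0,
                         include_shape: bool = False,
                         gabor_wavelength_vox: float = 4.0) -> pd.Series:
    """All features of one scalar map across the transform manifest.

    Returns a Series indexed by canonical feature ids; 2300 entries for the
    default manifest.  Non-finite (degenerate) values are emitted as 0.
    """
    if manifest is None:
        manifest = default_manifest()
    if len(manifest) == 0:
        raise ValueError("transform manifest is empty")
    ids, vals = [], []
    n_degenerate = 0
    for desc in manifest:
        tv = apply_transform(map_, mask, desc,
                             gabor_wavelength_vox=gabor_wavelength_vox)
        row = _form_features(tv, Ng, glcm_distance, gldm_alpha)
        for (cls, name), v in row.items():
            if not np.isfinite(v):
                n_degenerate += 1
                v = 0.0
            ids.append(feature_id(map_.kind, desc.canonical, cls, name))
            vals.append(float(v))
    if include_shape:
        for name, v in shape_feature_set(mask).items():
            ids.append(feature_id(map_.kind, "original", "Shape", name))
            vals.append(float(v) if np.isfinite(v) else 0.0)
    if n_degenerate:
        log.warning("subject %s %s map: %d degenerate feature values emitted as 0",
                    map_.subject_id, map_.kind, n_degenerate)
    return pd.Series(vals, index=ids, name=map_.subject_id)


def extract_feature_vector(fa: Optional[ScalarMap], md: Optional[ScalarMap],
                           mask: BrainMask,
                           manifest: Optional[Sequence[TransformDescriptor]] = None,
                           **kwargs) -> pd.Series:
    """Per-subject feature vector: FA block then MD block (4600 by default)."""
    parts = []
    for m in (fa, md):
        if m is not None:
            parts.append(extract_map_features(m, mask, manifest=manifest, **kwargs))
    if not parts:
        raise ValueError("at least one of fa, md must be supplied")
    out = pd.concat(parts)
    out.name = parts[0].name
    return out
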