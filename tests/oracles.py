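"""Brute-force reference implementations used only by the test suite.

Everything here is written as naive explicit enumeration (voxel-pair loops,
run scanning, flood fill, neighbour counting, term-by-term formula sums) so
it stays independent of the vectorized implementations it checks.
"""
from __future__ import annotations

import math
from collections import OrderedDict

import numpy as np

DIRS_13 = [
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]

NEIGHBOURS_26 = [(dx, dy, dz)
                 for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
                 if (dx, dy, dz) != (0, 0, 0)]


def _as3d(levels):
    a = np.asarray(levels, dtype=int)
    while a.ndim < 3:
        a = a[..., None]
    return a


def _inb(shape, p):
    return all(0 <= c < n for c, n in zip(p, shape))


def glcm_counts(levels, Ng, distance=1, directions=None):
    """Symmetric pair counts by exhaustive voxel-pair enumeration."""
    lv = _as3d(levels)
    dirs = DIRS_13 if directions is None else directions
    C = np.zeros((Ng, Ng))
    for x in range(lv.shape[0]):
        for y in range(lv.shape[1]):
            for z in range(lv.shape[2]):
                a = lv[x, y, z]
                if a == 0:
                    continue
                for dx, dy, dz in dirs:
                    q = (x + dx * distance, y + dy * distance, z + dz * distance)
                    if not _inb(lv.shape, q):
                        continue
                    b = lv[q]
                    if b == 0:
                        continue
                    C[a - 1, b - 1] += 1
                    C[b - 1, a - 1] += 1
    return C


def glrlm_counts(levels, Ng, direction, maxlen):
    """Run counts for one direction by scanning every maximal line."""
    lv = _as3d(levels)
    d = np.array(direction)
    shape = lv.shape
    P = np.zeros((Ng, maxlen))
    starts = []
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                prev = (x - d[0], y - d[1], z - d[2])
                if not _inb(shape, prev):
                    starts.append((x, y, z))
    for p0 in starts:
        line = []
        p = p0
        while _inb(shape, p):
            line.append(lv[p])
            p = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
        k = 0
        while k < len(line):
            j = k
            while j < len(line) and line[j] == line[k]:
                j += 1
            if line[k] > 0:
                P[line[k] - 1, (j - k) - 1] += 1
            k = j
    return P


def glszm_counts(levels, Ng):
    """Zone counts via explicit 26-connected flood fill per gray level."""
    lv = _as3d(levels)
    seen = np.zeros(lv.shape, dtype=bool)
    zones = []
    for x in range(lv.shape[0]):
        for y in range(lv.shape[1]):
            for z in range(lv.shape[2]):
                if lv[x, y, z] == 0 or seen[x, y, z]:
                    continue
                g = lv[x, y, z]
                stack = [(x, y, z)]
                seen[x, y, z] = True
                size = 0
                while stack:
                    p = stack.pop()
                    size += 1
                    for off in NEIGHBOURS_26:
                        q = tuple(c + o for c, o in zip(p, off))
                        if _inb(lv.shape, q) and not seen[q] and lv[q] == g:
                            seen[q] = True
                            stack.append(q)
                zones.append((g, size))
    if not zones:
        return np.zeros((Ng, 1)), 0
    maxsize = max(s for _, s in zones)
    P = np.zeros((Ng, maxsize))
    for g, s in zones:
        P[g - 1, s - 1] += 1
    return P, len(zones)


def gldm_counts(levels, Ng, alpha=0):
    """Dependence counts via explicit 26-neighbour scan per voxel."""
    lv = _as3d(levels)
    deps = []
    for x in range(lv.shape[0]):
        for y in range(lv.shape[1]):
            for z in range(lv.shape[2]):
                g = lv[x, y, z]
                if g == 0:
                    continue
                dep = 0
                for off in NEIGHBOURS_26:
                    q = (x + off[0], y + off[1], z + off[2])
                    if _inb(lv.shape, q) and lv[q] > 0 and abs(int(lv[q]) - int(g)) <= alpha:
                        dep += 1
                deps.append((g, dep))
    ncol = max(d for _, d in deps) + 1 if deps else 1
    P = np.zeros((Ng, ncol))
    for g, dep in deps:
        P[g - 1, dep] += 1
    return P


# ---------------------------------------------------------------------------
# naive feature formulas (term-by-term sums)


def _ent(values):
    return -sum(v * math.log(v) for v in values if v > 0)


def glcm_features_naive(C):
    """All 24 co-occurrence features from a raw symmetric count matrix."""
    Ng = C.shape[0]
    tot = C.sum()
    p = C / tot
    px = [sum(p[i, j] for j in range(Ng)) for i in range(Ng)]
    py = [sum(p[i, j] for i in range(Ng)) for j in range(Ng)]
    mux = sum((i + 1) * px[i] for i in range(Ng))
    muy = sum((j + 1) * py[j] for j in range(Ng))
    sigx = math.sqrt(sum((i + 1 - mux) ** 2 * px[i] for i in range(Ng)))
    sigy = math.sqrt(sum((j + 1 - muy) ** 2 * py[j] for j in range(Ng)))
    pdiff = [0.0] * Ng
    psum = [0.0] * (2 * Ng - 1)
    for i in range(Ng):
        for j in range(Ng):
            pdiff[abs(i - j)] += p[i, j]
            psum[i + j] += p[i, j]
    hx, hy = _ent(px), _ent(py)
    hxy = _ent(p.ravel())
    hxy1 = -sum(p[i, j] * math.log(px[i] * py[j])
                for i in range(Ng) for j in range(Ng) if p[i, j] > 0)
    hxy2 = _ent([px[i] * py[j] for i in range(Ng) for j in range(Ng)])
    da = sum(k * pdiff[k] for k in range(Ng))

    f = {}
    f["Autocorrelation"] = sum((i + 1) * (j + 1) * p[i, j]
                               for i in range(Ng) for j in range(Ng))
    for name, e in (("ClusterProminence", 4), ("ClusterShade", 3),
                    ("ClusterTendency", 2)):
        f[name] = sum((i + 1 + j + 1 - mux - muy) ** e * p[i, j]
                      for i in range(Ng) for j in range(Ng))
    f["Contrast"] = sum((i - j) ** 2 * p[i, j]
                        for i in range(Ng) for j in range(Ng))
    f["Correlation"] = ((f["Autocorrelation"] - mux * muy) / (sigx * sigy)
                        if sigx > 0 and sigy > 0 else np.nan)
    f["DifferenceAverage"] = da
    f["DifferenceEntropy"] = _ent(pdiff)
    f["DifferenceVariance"] = sum((k - da) ** 2 * pdiff[k] for k in range(Ng))
    f["Id"] = sum(p[i, j] / (1 + abs(i - j)) for i in range(Ng) for j in range(Ng))
    f["Idm"] = sum(p[i, j] / (1 + (i - j) ** 2) for i in range(Ng) for j in range(Ng))
    f["Idmn"] = sum(p[i, j] / (1 + (i - j) ** 2 / Ng ** 2)
                    for i in range(Ng) for j in range(Ng))
    f["Idn"] = sum(p[i, j] / (1 + abs(i - j) / Ng)
                   for i in range(Ng) for j in range(Ng))
    f["Imc1"] = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else np.nan
    f["Imc2"] = math.sqrt(max(0.0, 1.0 - math.exp(-2 * (hxy2 - hxy))))
    f["InverseVariance"] = sum(p[i, j] / (i - j) ** 2
                               for i in range(Ng) for j in range(Ng) if i != j)
    f["JointAverage"] = mux
    f["JointEnergy"] = sum(p[i, j] ** 2 for i in range(Ng) for j in range(Ng))
    f["JointEntropy"] = hxy
    rows = [i for i in range(Ng) if px[i] > 0]
    if len(rows) < 2:
        f["MCC"] = np.nan
    else:
        Q = np.zeros((len(rows), len(rows)))
        for a, i in enumerate(rows):
            for b, j in enumerate(rows):
                Q[a, b] = sum(p[i, k] * p[j, k] / (px[i] * py[k])
                              for k in rows if py[k] > 0)
        ev = sorted(np.real(np.linalg.eigvals(Q)), reverse=True)
        f["MCC"] = math.sqrt(max(ev[1], 0.0))
    f["MaximumProbability"] = p.max()
    f["SumAverage"] = sum((k + 2) * psum[k] for k in range(2 * Ng - 1))
    f["SumEntropy"] = _ent(psum)
    f["SumSquares"] = sum((i + 1 - mux) ** 2 * p[i, j]
                          for i in range(Ng) for j in range(Ng))
    return f


def glrlm_features_naive(P, Np):
    Ng, maxlen = P.shape
    Nr = P.sum()
    p = P / Nr
    mu_i = sum((i + 1) * p[i, j] for i in range(Ng) for j in range(maxlen))
    mu_j = sum((j + 1) * p[i, j] for i in range(Ng) for j in range(maxlen))
    pg = [P[i, :].sum() for i in range(Ng)]
    pr = [P[:, j].sum() for j in range(maxlen)]
    S = lambda w: sum(w(i + 1, j + 1) * P[i, j]
                      for i in range(Ng) for j in range(maxlen))
    f = {}
    f["ShortRunEmphasis"] = S(lambda i, j: 1 / j ** 2) / Nr
    f["LongRunEmphasis"] = S(lambda i, j: j ** 2) / Nr
    f["GrayLevelNonUniformity"] = sum(g ** 2 for g in pg) / Nr
    f["GrayLevelNonUniformityNormalized"] = sum(g ** 2 for g in pg) / Nr ** 2
    f["RunLengthNonUniformity"] = sum(r ** 2 for r in pr) / Nr
    f["RunLengthNonUniformityNormalized"] = sum(r ** 2 for r in pr) / Nr ** 2
    f["RunPercentage"] = Nr / Np
    f["GrayLevelVariance"] = sum((i + 1 - mu_i) ** 2 * p[i, j]
                                 for i in range(Ng) for j in range(maxlen))
    f["RunVariance"] = sum((j + 1 - mu_j) ** 2 * p[i, j]
                           for i in range(Ng) for j in range(maxlen))
    f["RunEntropy"] = _ent(p.ravel())
    f["LowGrayLevelRunEmphasis"] = S(lambda i, j: 1 / i ** 2) / Nr
    f["HighGrayLevelRunEmphasis"] = S(lambda i, j: i ** 2) / Nr
    f["ShortRunLowGrayLevelEmphasis"] = S(lambda i, j: 1 / (i ** 2 * j ** 2)) / Nr
    f["ShortRunHighGrayLevelEmphasis"] = S(lambda i, j: i ** 2 / j ** 2) / Nr
    f["LongRunLowGrayLevelEmphasis"] = S(lambda i, j: j ** 2 / i ** 2) / Nr
    f["LongRunHighGrayLevelEmphasis"] = S(lambda i, j: i ** 2 * j ** 2) / Nr
    return f


def glszm_features_naive(P, Nz, Np):
    Ng, maxsize = P.shape
    p = P / Nz
    mu_i = sum((i + 1) * p[i, j] for i in range(Ng) for j in range(maxsize))
    mu_j = sum((j + 1) * p[i, j] for i in range(Ng) for j in range(maxsize))
    pg = [P[i, :].sum() for i in range(Ng)]
    ps = [P[:, j].sum() for j in range(maxsize)]
    S = lambda w: sum(w(i + 1, j + 1) * P[i, j]
                      for i in range(Ng) for j in range(maxsize))
    f = {}
    f["SmallAreaEmphasis"] = S(lambda i, j: 1 / j ** 2) / Nz
    f["LargeAreaEmphasis"] = S(lambda i, j: j ** 2) / Nz
    f["GrayLevelNonUniformity"] = sum(g ** 2 for g in pg) / Nz
    f["GrayLevelNonUniformityNormalized"] = sum(g ** 2 for g in pg) / Nz ** 2
    f["SizeZoneNonUniformity"] = sum(s ** 2 for s in ps) / Nz
    f["SizeZoneNonUniformityNormalized"] = sum(s ** 2 for s in ps) / Nz ** 2
    f["ZonePercentage"] = Nz / Np
    f["GrayLevelVariance"] = sum((i + 1 - mu_i) ** 2 * p[i, j]
                                 for i in range(Ng) for j in range(maxsize))
    f["ZoneVariance"] = sum((j + 1 - mu_j) ** 2 * p[i, j]
                            for i in range(Ng) for j in range(maxsize))
    f["ZoneEntropy"] = _ent(p.ravel())
    f["LowGrayLevelZoneEmphasis"] = S(lambda i, j: 1 / i ** 2) / Nz
    f["HighGrayLevelZoneEmphasis"] = S(lambda i, j: i ** 2) / Nz
    f["SmallAreaLowGrayLevelEmphasis"] = S(lambda i, j: 1 / (i ** 2 * j ** 2)) / Nz
    f["SmallAreaHighGrayLevelEmphasis"] = S(lambda i, j: i ** 2 / j ** 2) / Nz
    f["LargeAreaLowGrayLevelEmphasis"] = S(lambda i, j: j ** 2 / i ** 2) / Nz
    f["LargeAreaHighGrayLevelEmphasis"] = S(lambda i, j: i ** 2 * j ** 2) / Nz
    return f


def gldm_features_naive(P):
    Ng, ncol = P.shape
    Nz = P.sum()
    p = P / Nz
    # column j corresponds to dependence + 1
    mu_i = sum((i + 1) * p[i, j] for i in range(Ng) for j in range(ncol))
    mu_j = sum((j + 1) * p[i, j] for i in range(Ng) for j in range(ncol))
    pg = [P[i, :].sum() for i in range(Ng)]
    pdd = [P[:, j].sum() for j in range(ncol)]
    S = lambda w: sum(w(i + 1, j + 1) * P[i, j]
                      for i in range(Ng) for j in range(ncol))
    f = {}
    f["SmallDependenceEmphasis"] = S(lambda i, j: 1 / j ** 2) / Nz
    f["LargeDependenceEmphasis"] = S(lambda i, j: j ** 2) / Nz
    f["GrayLevelNonUniformity"] = sum(g ** 2 for g in pg) / Nz
    f["DependenceNonUniformity"] = sum(d ** 2 for d in pdd) / Nz
    f["GrayLevelVariance"] = sum((i + 1 - mu_i) ** 2 * p[i, j]
                                 for i in range(Ng) for j in range(ncol))
    f["DependenceVariance"] = sum((j + 1 - mu_j) ** 2 * p[i, j]
                                  for i in range(Ng) for j in range(ncol))
    f["DependenceEntropy"] = _ent(p.ravel())
    f["LowGrayLevelEmphasis"] = S(lambda i, j: 1 / i ** 2) / Nz
    f["HighGrayLevelEmphasis"] = S(lambda i, j: i ** 2) / Nz
    f["SmallDependenceLowGrayLevelEmphasis"] = S(lambda i, j: 1 / (i ** 2 * j ** 2)) / Nz
    f["SmallDependenceHighGrayLevelEmphasis"] = S(lambda i, j: i ** 2 / j ** 2) / Nz
    f["LargeDependenceLowGrayLevelEmphasis"] = S(lambda i, j: j ** 2 / i ** 2) / Nz
    f["LargeDependenceHighGrayLevelEmphasis"] = S(lambda i, j: i ** 2 * j ** 2) / Nz
    return f


def md_loop(lam1, lam2, lam3):
    """Per-voxel scalar-loop mean diffusivity."""
    out = np.zeros_like(np.asarray(lam1, dtype=float))
    it = np.ndindex(out.shape)
    for p in it:
        out[p] = (lam1[p] + lam2[p] + lam3[p]) / 3.0
    return out


def fa_loop(lam1, lam2, lam3):
    """Per-voxel scalar-loop fractional anisotropy (sorted, clamped)."""
    out = np.zeros(np.asarray(lam1, dtype=float).shape)
    for p in np.ndindex(out.shape):
        lams = sorted((max(lam1[p], 0), max(lam2[p], 0), max(lam3[p], 0)),
                      reverse=True)
        md = sum(lams) / 3.0
        den = sum(l * l for l in lams)
        if den == 0:
            out[p] = 0.0
            continue
        num = sum((l - md) ** 2 for l in lams)
        out[p] = min(1.0, math.sqrt(1.5) * math.sqrt(num) / math.sqrt(den))
    return out


def auc_pairs(scores, labels):
    """AUC by exhaustive concordant-pair counting, ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    c = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                c += 1.0
            elif a == b:
                c += 0.5
    return c / (len(pos) * len(neg))
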