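"""Bank of derived image forms feeding texture-feature extraction.

The default manifest has 25 forms — original, exponential, logarithm, the
eight subbands of a one-level 3-D Haar decomposition, twelve slice-wise
Gabor responses (angular bandwidth beta in {30, 60, 90} degrees crossed
with in-plane orientation theta in {0, 45, 90, 135} degrees), and two
Laplacian-of-Gaussian responses (sigma 1 and 3 mm) — so that the 92-feature
class registry yields 2300 features per map.

Descriptor strings are canonical and stable, e.g. ``Gabor.Beta.90.Theta.135``,
``wavelet.LHL``, ``LoG.Sigma.1.0``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pywt
from scipy import ndimage, signal
from skimage.filters import gabor_kernel

from .core import BrainMask, ScalarMap, TransformedVolume

WAVELET_SUBBANDS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")
GABOR_BETAS = (30.0, 60.0, 90.0)
GABOR_THETAS = (0.0, 45.0, 90.0, 135.0)
LOG_SIGMAS_MM = (1.0, 3.0)
DEFAULT_GABOR_WAVELENGTH_VOX = 4.0


@dataclass(frozen=True)
class TransformDescriptor:
    name: str  # original | exponential | logarithm | wavelet | gabor | log_sigma
    params: Tuple[Tuple[str, object], ...] = ()

    @property
    def p(self) -> Dict[str, object]:
        return dict(self.params)

    @property
    def canonical(self) -> str:
        if self.name == "wavelet":
            return f"wavelet.{self.p['subband']}"
        if self.name == "gabor":
            return f"Gabor.Beta.{self.p['beta_deg']:g}.Theta.{self.p['theta_deg']:g}"
        if self.name == "log_sigma":
            return f"LoG.Sigma.{self.p['sigma_mm']:.1f}"
        return self.name

    def __str__(self) -> str:
        return self.canonical


def wavelet_descriptor(subband: str) -> TransformDescriptor:
    if subband not in WAVELET_SUBBANDS:
        raise ValueError(f"unknown wavelet subband {subband!r}; valid: {WAVELET_SUBBANDS}")
    return TransformDescriptor("wavelet", (("subband", subband),))


def gabor_descriptor(beta_deg: float, theta_deg: float) -> TransformDescriptor:
    return TransformDescriptor(
        "gabor", (("beta_deg", float(beta_deg)), ("theta_deg", float(theta_deg)))
    )


def log_descriptor(sigma_mm: float) -> TransformDescriptor:
    return TransformDescriptor("log_sigma", (("sigma_mm", float(sigma_mm)),))


def parse_descriptor(s: str) -> TransformDescriptor:
    """Inverse of :attr:`TransformDescriptor.canonical`."""
    if s in ("original", "exponential", "logarithm"):
        return TransformDescriptor(s)
    if s.startswith("wavelet."):
        return wavelet_descriptor(s.split(".", 1)[1])
    if s.startswith("Gabor.Beta."):
        parts = s.split(".")
        try:
            beta = float(parts[2])
            assert parts[3] == "Theta"
            theta = float(parts[4])
        except (IndexError, ValueError, AssertionError):
            raise ValueError(f"malformed Gabor descriptor {s!r}") from None
        return gabor_descriptor(beta, theta)
    if s.startswith("LoG.Sigma."):
        return log_descriptor(float(s[len("LoG.Sigma."):]))
    raise ValueError(
        f"unknown transform descriptor {s!r}; valid forms: original, exponential, "
        f"logarithm, wavelet.<subband>, Gabor.Beta.<b>.Theta.<t>, LoG.Sigma.<s>"
    )


def default_manifest() -> List[TransformDescriptor]:
    """The 25-form default transform bank (25 x 92 = 2300 features per map)."""
    out = [TransformDescriptor("original"),
           TransformDescriptor("exponential"),
           TransformDescriptor("logarithm")]
    out += [wavelet_descriptor(sb) for sb in WAVELET_SUBBANDS]
    out += [gabor_descriptor(b, t) for b in GABOR_BETAS for t in GABOR_THETAS]
    out += [log_descriptor(s) for s in LOG_SIGMAS_MM]
    return out


# ---------------------------------------------------------------------------
# individual transforms


def _monotone_remap(data: np.ndarray, mask: np.ndarray, kind: str) -> np.ndarray:
    """Shared exponential/logarithm remap of the masked intensity range.

    With u = x - min and r = max - min over the mask:
      exponential: exp(u * ln(r+1)/r) - 1 + min
      logarithm:   ln(u + 1) * r/ln(r+1) + min
    Both are monotone, preserve the masked min and range, and are exact
    inverses of each other.
    """
    vals = data[mask]
    mn = float(vals.min())
    r = float(vals.max()) - mn
    out = np.zeros_like(data)
    if r == 0.0:
        out[mask] = vals
        return out
    u = np.clip(data[mask] - mn, 0.0, None)
    c = np.log1p(r) / r
    if kind == "exponential":
        out[mask] = np.expm1(u * c) + mn
    else:
        out[mask] = np.log1p(u) / c + mn
    return out


def _haar_subband(data: np.ndarray, mask: np.ndarray, subband: str):
    """One-level orthonormal 3-D Haar subband on the mask bounding box.

    The box is padded with zeros to even dimensions; the subband is kept at
    decimated resolution with the mask downsampled by strict majority
    (>= 5 of 8 voxels per 2x2x2 block).
    """
    idx = np.nonzero(mask)
    lo = [int(i.min()) for i in idx]
    hi = [int(i.max()) + 1 for i in idx]
    box = tuple(slice(l, h) for l, h in zip(lo, hi))
    sub = data[box]
    msk = mask[box]
    pad = [(0, (-sub.shape[a]) % 2) for a in range(3)]
    sub = np.pad(sub, pad)
    msk = np.pad(msk, pad)
    key = "".join("a" if c == "L" else "d" for c in subband)
    coeffs = pywt.dwtn(sub, "haar", axes=(0, 1, 2))
    band = coeffs[key]
    blocks = msk.reshape(msk.shape[0] // 2, 2, msk.shape[1] // 2, 2,
                         msk.shape[2] // 2, 2)
    dmask = blocks.sum(axis=(1, 3, 5)) >= 5
    return band, dmask


def _gabor_kernel_2d(beta_deg: float, theta_deg: float,
                     wavelength_vox: float) -> np.ndarray:
    """Complex 2-D Gabor kernel.

    ``theta_deg`` is the in-plane orientation; ``beta_deg`` is read as the
    filter's half-response angular bandwidth, which sets the envelope width
    perpendicular to the carrier via
    sigma_perp = sqrt(ln 2 / 2) * lambda / (pi * tan(beta/2)).
    The envelope along the carrier is fixed at 0.56 * lambda (one octave).
    """
    lam = float(wavelength_vox)
    sigma_x = 0.56 * lam
    sigma_y = np.sqrt(np.log(2) / 2.0) * lam / (np.pi * np.tan(np.deg2rad(beta_deg) / 2))
    return gabor_kernel(frequency=1.0 / lam, theta=np.deg2rad(theta_deg),
                        sigma_x=sigma_x, sigma_y=sigma_y)


def _gabor_response(data: np.ndarray, beta_deg: float, theta_deg: float,
                    wavelength_vox: float) -> np.ndarray:
    kern = _gabor_kernel_2d(beta_deg, theta_deg, wavelength_vox)
    # slice-wise axial filtering: convolve the whole volume with a (kx, ky, 1)
    # kernel so each z-slice is filtered independently
    k3 = kern[:, :, None]
    resp = signal.fftconvolve(data.astype(complex), k3, mode="same")
    return np.abs(resp)


def apply_transform(map_: ScalarMap, mask: BrainMask, d: TransformDescriptor,
                    gabor_wavelength_vox: float = DEFAULT_GABOR_WAVELENGTH_VOX
                    ) -> TransformedVolume:
    """Compute one derived image form of a masked scalar map."""
    if map_.shape != mask.shape:
        raise ValueError("map and mask must share a grid")
    data = map_.data
    m = mask.data
    spacing = map_.spacing

    if d.name == "original":
        out, om, osp = data.copy(), m, spacing
    elif d.name in ("exponential", "logarithm"):
        out, om, osp = _monotone_remap(data, m, d.name), m, spacing
    elif d.name == "wavelet":
        band, dmask = _haar_subband(data, m, d.p["subband"])
        out, om = band, dmask
        osp = tuple(2 * s for s in spacing)
    elif d.name == "gabor":
        out = _gabor_response(data, d.p["beta_deg"], d.p["theta_deg"],
                              gabor_wavelength_vox)
        om, osp = m, spacing
    elif d.name == "log_sigma":
        sigma_vox = [d.p["sigma_mm"] / s for s in spacing]
        out = ndimage.gaussian_laplace(data, sigma=sigma_vox)
        om, osp = m, spacing
    else:
        raise ValueError(f"unknown transform {d.name!r}")

    return TransformedVolume(out, om, descriptor=d, source_kind=map_.kind,
                             spacing=osp)
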