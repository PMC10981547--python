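"""Device-independent color math for tongue colorimetry.

Implements the standard sRGB -> CIE XYZ -> CIE L*a*b* conversion chain and the
complete CIEDE2000 color-difference formula (the CIE's 2000 revision of the
Lab color-difference metric, including the G rescaling of a*, the primed
chroma/hue quantities, the hue-mean wraparound rules, the weighting functions
S_L, S_C, S_H and the chroma-hue rotation term R_T).

All hue arithmetic is carried out in degrees, matching the form in which the
CIEDE2000 formula is published; the well-known edge cases (hue means across
the 0/360 discontinuity, achromatic inputs) follow the published
implementation notes for the formula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "RGBColor",
    "LabColor",
    "ChromaHue",
    "ParametricCoefficients",
    "ColorDifferenceResult",
    "WHITE_POINTS",
    "rgb_to_lab",
    "lab_to_rgb",
    "chroma_hue",
    "ciede2000",
    "delta_e_ab",
]


class RGBColor(NamedTuple):
    """An sRGB triple with channels in [0, 1] (8-bit values divided by 255)."""

    r: float
    g: float
    b: float


class LabColor(NamedTuple):
    """A CIE L*a*b* triple.

    L: lightness in [0, 100]; a: red(+)/green(-) axis; b: yellow(+)/blue(-)
    axis. The chromatic axes are unbounded in principle but stay within
    roughly +/-128 for colors realizable in sRGB.
    """

    L: float
    a: float
    b: float


class ChromaHue(NamedTuple):
    """Chroma C = sqrt(a^2 + b^2) and hue angle h in degrees, in [0, 360)."""

    C: float
    h: float


@dataclass(frozen=True)
class ParametricCoefficients:
    """Parametric weights kL, kC, kH of CIEDE2000 (all 1 by default)."""

    kL: float = 1.0
    kC: float = 1.0
    kH: float = 1.0

    def __post_init__(self) -> None:
        if not (self.kL > 0 and self.kC > 0 and self.kH > 0):
            raise ValueError("parametric coefficients kL, kC, kH must be positive")


@dataclass(frozen=True)
class ColorDifferenceResult:
    """CIEDE2000 distance plus every intermediate term for one pair of colors.

    Signed differences are sample minus reference. ``dH_prime`` is the signed
    hue-difference term 2*sqrt(C1'*C2')*sin(dh'/2), not the raw angle.
    """

    dE00: float
    dL_prime: float
    dC_prime: float
    dH_prime: float
    S_L: float
    S_C: float
    S_H: float
    R_T: float
    G: float
    T: float

    def rounded(self) -> "ColorDifferenceResult":
        """Report-style rounding: dE00 to 1 decimal, components to 2."""
        return ColorDifferenceResult(
            dE00=round(self.dE00, 1),
            dL_prime=round(self.dL_prime, 2),
            dC_prime=round(self.dC_prime, 2),
            dH_prime=round(self.dH_prime, 2),
            S_L=self.S_L,
            S_C=self.S_C,
            S_H=self.S_H,
            R_T=self.R_T,
            G=self.G,
            T=self.T,
        )


# sRGB (IEC 61966-2-1) linear-RGB -> XYZ matrix, D65 primaries.
_RGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
_XYZ_TO_RGB = np.linalg.inv(_RGB_TO_XYZ)

#: Reference-white XYZ (Y normalized to 1) for the supported illuminants,
#: 2-degree standard observer. D65 is taken as the matrix image of RGB
#: (1,1,1) so sRGB white maps exactly to L* = 100, a* = b* = 0.
WHITE_POINTS: dict[str, tuple[float, float, float]] = {
    "D65": tuple(_RGB_TO_XYZ.sum(axis=1)),
    "D50": (0.96422, 1.00000, 0.82521),
}

_EPS = (6.0 / 29.0) ** 3  # CIE Lab linearity threshold
_KAPPA = (29.0 / 3.0) ** 3


def _srgb_decompand(c: np.ndarray) -> np.ndarray:
    return np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)


def _srgb_compand(c: np.ndarray) -> np.ndarray:
    c = np.clip(c, 0.0, None)
    return np.where(c <= 0.0031308, 12.92 * c, 1.055 * c ** (1.0 / 2.4) - 0.055)


def _lab_f(t: np.ndarray) -> np.ndarray:
    return np.where(t > _EPS, np.cbrt(t), (_KAPPA * t + 16.0) / 116.0)


def _lab_f_inv(ft: np.ndarray) -> np.ndarray:
    ft3 = ft**3
    return np.where(ft3 > _EPS, ft3, (116.0 * ft - 16.0) / _KAPPA)


def rgb_to_lab(rgb, white_point: str = "D65"):
    """Convert sRGB to CIE L*a*b*.

    Parameters
    ----------
    rgb
        An ``RGBColor``, a length-3 sequence, or an array of shape (..., 3)
        with channels in [0, 1] (sRGB-companded, as read from 8/16-bit files
        after division by the full-scale value).
    white_point
        Reference white used for the XYZ normalization; one of
        ``WHITE_POINTS``. Default D65, 2-degree observer, the native white of
        sRGB.

    Returns
    -------
    ``LabColor`` for a single triple, else an array of shape (..., 3).

    Raises
    ------
    ValueError
        If any channel falls outside [0, 1] or the white point is unknown.
    """
    if white_point not in WHITE_POINTS:
        raise ValueError(
            f"unknown white point {white_point!r}; supported: {sorted(WHITE_POINTS)}"
        )
    arr = np.asarray(rgb, dtype=float)
    scalar = arr.ndim == 1
    if arr.shape[-1] != 3:
        raise ValueError("rgb input must have 3 channels on the last axis")
    if np.any(arr < 0.0) or np.any(arr > 1.0):
        raise ValueError("rgb channels must lie in [0, 1]")
    xyz = _srgb_decompand(arr) @ _RGB_TO_XYZ.T
    wp = np.array(WHITE_POINTS[white_point])
    f = _lab_f(xyz / wp)
    L = 116.0 * f[..., 1] - 16.0
    a = 500.0 * (f[..., 0] - f[..., 1])
    b = 200.0 * (f[..., 1] - f[..., 2])
    out = np.stack([L, a, b], axis=-1)
    if scalar:
        return LabColor(*out)
    return out


def lab_to_rgb(lab, white_point: str = "D65", clip: bool = False):
    """Convert CIE L*a*b* back to sRGB (inverse of :func:`rgb_to_lab`).

    With ``clip=False`` (default) an out-of-gamut color raises ``ValueError``;
    with ``clip=True`` linear-RGB values are clipped into [0, 1] first.
    """
    if white_point not in WHITE_POINTS:
        raise ValueError(
            f"unknown white point {white_point!r}; supported: {sorted(WHITE_POINTS)}"
        )
    arr = np.asarray(lab, dtype=float)
    scalar = arr.ndim == 1
    if arr.shape[-1] != 3:
        raise ValueError("lab input must have 3 channels on the last axis")
    L, a, b = arr[..., 0], arr[..., 1], arr[..., 2]
    fy = (L + 16.0) / 116.0
    fx = fy + a / 500.0
    fz = fy - b / 200.0
    wp = np.array(WHITE_POINTS[white_point])
    xyz = np.stack([_lab_f_inv(fx), _lab_f_inv(fy), _lab_f_inv(fz)], axis=-1) * wp
    lin = xyz @ _XYZ_TO_RGB.T
    if clip:
        lin = np.clip(lin, 0.0, 1.0)
    elif np.any(lin < -1e-9) or np.any(lin > 1.0 + 1e-9):
        raise ValueError("Lab color falls outside the sRGB gamut")
    out = _srgb_compand(np.clip(lin, 0.0, 1.0))
    if scalar:
        return RGBColor(*out)
    return out


def chroma_hue(color: LabColor) -> ChromaHue:
    """Chroma and hue angle of a Lab color.

    C = sqrt(a^2 + b^2); h = atan2(b, a) in degrees mapped to [0, 360),
    defined as 0 for achromatic colors (a = b = 0).
    """
    L, a, b = color
    C = math.hypot(a, b)
    if C == 0.0:
        return ChromaHue(0.0, 0.0)
    h = math.degrees(math.atan2(b, a)) % 360.0
    if h >= 360.0:  # -tiny % 360 can round to exactly 360
        h = 0.0
    return ChromaHue(C, h)


_25_POW7 = 25.0**7


def ciede2000(
    reference: LabColor,
    sample: LabColor,
    k: ParametricCoefficients = ParametricCoefficients(),
) -> ColorDifferenceResult:
    """CIEDE2000 color difference between two Lab colors.

    ``reference`` and ``sample`` order fixes the sign convention of the
    returned components: dL', dC', dH' are sample minus reference (in the
    position-comparison pipeline the sitting color is the reference, so the
    signed terms read supine minus sitting). The distance itself is symmetric.
    """
    L1, a1, b1 = float(reference[0]), float(reference[1]), float(reference[2])
    L2, a2, b2 = float(sample[0]), float(sample[1]), float(sample[2])

    C1_ab = math.hypot(a1, b1)
    C2_ab = math.hypot(a2, b2)
    C_ab_mean = 0.5 * (C1_ab + C2_ab)
    c7 = C_ab_mean**7
    G = 0.5 * (1.0 - math.sqrt(c7 / (c7 + _25_POW7)))

    a1p = (1.0 + G) * a1
    a2p = (1.0 + G) * a2
    C1p = math.hypot(a1p, b1)
    C2p = math.hypot(a2p, b2)

    h1p = 0.0 if C1p == 0.0 else math.degrees(math.atan2(b1, a1p)) % 360.0
    h2p = 0.0 if C2p == 0.0 else math.degrees(math.atan2(b2, a2p)) % 360.0

    dLp = L2 - L1
    dCp = C2p - C1p

    if C1p * C2p == 0.0:
        dhp = 0.0
    else:
        dhp = h2p - h1p
        if dhp > 180.0:
            dhp -= 360.0
        elif dhp < -180.0:
            dhp += 360.0
    dHp = 2.0 * math.sqrt(C1p * C2p) * math.sin(math.radians(dhp) / 2.0)

    Lp_mean = 0.5 * (L1 + L2)
    Cp_mean = 0.5 * (C1p + C2p)

    if C1p * C2p == 0.0:
        hp_mean = h1p + h2p
    else:
        hsum = h1p + h2p
        if abs(h1p - h2p) <= 180.0:
            hp_mean = 0.5 * hsum
        elif hsum < 360.0:
            hp_mean = 0.5 * (hsum + 360.0)
        else:
            hp_mean = 0.5 * (hsum - 360.0)

    T = (
        1.0
        - 0.17 * math.cos(math.radians(hp_mean - 30.0))
        + 0.24 * math.cos(math.radians(2.0 * hp_mean))
        + 0.32 * math.cos(math.radians(3.0 * hp_mean + 6.0))
        - 0.20 * math.cos(math.radians(4.0 * hp_mean - 63.0))
    )
    d_theta = 30.0 * math.exp(-(((hp_mean - 275.0) / 25.0) ** 2))
    cp7 = Cp_mean**7
    R_C = 2.0 * math.sqrt(cp7 / (cp7 + _25_POW7))
    R_T = -math.sin(math.radians(2.0 * d_theta)) * R_C

    Lm50sq = (Lp_mean - 50.0) ** 2
    S_L = 1.0 + 0.015 * Lm50sq / math.sqrt(20.0 + Lm50sq)
    S_C = 1.0 + 0.045 * Cp_mean
    S_H = 1.0 + 0.015 * Cp_mean * T

    tL = dLp / (k.kL * S_L)
    tC = dCp / (k.kC * S_C)
    tH = dHp / (k.kH * S_H)
    dE00 = math.sqrt(tL * tL + tC * tC + tH * tH + R_T * tC * tH)

    return ColorDifferenceResult(
        dE00=dE00,
        dL_prime=dLp,
        dC_prime=dCp,
        dH_prime=dHp,
        S_L=S_L,
        S_C=S_C,
        S_H=S_H,
        R_T=R_T,
        G=G,
        T=T,
    )


def delta_e_ab(reference: LabColor, sample: LabColor) -> float:
    """Plain 1976 CIELAB Euclidean distance (comparison helper only)."""
    return math.dist(tuple(reference), tuple(sample))
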