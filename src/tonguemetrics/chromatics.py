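"""Chromatic indexes of a tongue region: RGB, HIS, CIE L*a*b*, YCbCr.

Twelve indexes are reported per region: the mean channel intensities R, G, B;
hue H (degrees), brightness I and saturation S from the HSI model; CIELAB
L*, a*, b* (sRGB, D65 white point); and full-range BT.601 luma/chroma Y, Cb,
Cr.  By default a region is summarised by converting its *mean* RGB triple
(aggregate-then-convert) — circular quantities like hue have no well-defined
arithmetic mean over pixels — but a per-pixel-then-average mode is available
for the HSI indexes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage import color as _skcolor

__all__ = [
    "ChromaticProfile",
    "rgb_to_his",
    "rgb_to_lab",
    "rgb_to_ycbcr",
    "profile_region",
]


@dataclass(frozen=True)
class ChromaticProfile:
    """The 12 chromatic indexes of one region.

    Ranges: ``r, g, b, i, y, cb, cr, l_star`` in [0, 255]; ``h`` in degrees
    [0, 360); ``s`` in [0, 1]; ``a_star``/``b_star`` sign-carrying opponent
    axes.  L* is scaled by 255/100 so that lightness shares the 8-bit range of
    the other indexes.
    """

    r: float
    g: float
    b: float
    h: float
    i: float
    s: float
    l_star: float
    a_star: float
    b_star: float
    y: float
    cb: float
    cr: float
    region_label: str
    n_pixels: int

    def __post_init__(self) -> None:
        if self.n_pixels < 1:
            raise ValueError("profile requires at least one pixel")
        if not (0.0 <= self.h < 360.0):
            raise ValueError(f"hue out of range: {self.h}")
        if not (0.0 <= self.s <= 1.0 + 1e-9):
            raise ValueError(f"saturation out of range: {self.s}")

    def as_dict(self) -> dict[str, float]:
        return {
            "H": self.h, "I": self.i, "S": self.s,
            "R": self.r, "G": self.g, "B": self.b,
            "L_star": self.l_star, "a_star": self.a_star, "b_star": self.b_star,
            "Y": self.y, "Cb": self.cb, "Cr": self.cr,
        }


def rgb_to_his(r: float, g: float, b: float) -> tuple[float, float, float]:
    """Convert an RGB triple (0–255) to (H degrees, I 0–255, S 0–1).

    The HSI model:

        I = (R + G + B) / 3
        S = 1 − 3·min(R, G, B) / (R + G + B)
        H = arccos( ½[(R−G) + (R−B)] / √[(R−G)² + (R−B)(G−B)] ),
            reflected to 360° − H when B > G.

    Achromatic pixels (R = G = B, including black) return S = 0 and H = 0 by
    convention.
    """
    r, g, b = float(r), float(g), float(b)
    total = r + g + b
    i = total / 3.0
    if total == 0.0:
        return 0.0, 0.0, 0.0
    s = 1.0 - 3.0 * min(r, g, b) / total
    num = 0.5 * ((r - g) + (r - b))
    den = math.sqrt((r - g) ** 2 + (r - b) * (g - b))
    if den == 0.0:
        h = 0.0
    else:
        h = math.degrees(math.acos(max(-1.0, min(1.0, num / den))))
        if b > g:
            h = 360.0 - h
    if h >= 360.0:
        h -= 360.0
    return h, i, max(0.0, s)


def rgb_to_lab(
    r: float, g: float, b: float, l_scale: str = "255"
) -> tuple[float, float, float]:
    """sRGB (0–255) to CIELAB under D65, via XYZ.

    ``l_scale="255"`` (default) rescales L* by 255/100 onto the 8-bit range;
    ``"100"`` keeps the canonical 0–100 lightness.  a* and b* are returned
    unshifted (sign-carrying).
    """
    rgb = np.array([[[r, g, b]]], dtype=float) / 255.0
    l_val, a_val, b_val = _skcolor.rgb2lab(rgb)[0, 0]
    if l_scale == "255":
        l_val = l_val * 255.0 / 100.0
    elif l_scale != "100":
        raise ValueError(f"unknown l_scale {l_scale!r}")
    return float(l_val), float(a_val), float(b_val)


def rgb_to_ycbcr(
    r: float, g: float, b: float, variant: str = "full"
) -> tuple[float, float, float]:
    """RGB (0–255) to BT.601 YCbCr.

    ``variant="full"`` (default) is the full-range (JPEG) transform with
    128-centred chroma, outputs clipped to [0, 255]; ``"studio"`` applies the
    16–235/240 studio swing.
    """
    r, g, b = float(r), float(g), float(b)
    y = 0.299 * r + 0.587 * g + 0.114 * b
    if variant == "full":
        cb = 128.0 - 0.168736 * r - 0.331264 * g + 0.5 * b
        cr = 128.0 + 0.5 * r - 0.418688 * g - 0.081312 * b
    elif variant == "studio":
        y = 16.0 + y * 219.0 / 255.0
        cb = 128.0 + (-0.168736 * r - 0.331264 * g + 0.5 * b) * 224.0 / 255.0
        cr = 128.0 + (0.5 * r - 0.418688 * g - 0.081312 * b) * 224.0 / 255.0
    else:
        raise ValueError(f"unknown variant {variant!r}")
    clip = lambda v: max(0.0, min(255.0, v))
    return clip(y), clip(cb), clip(cr)


def profile_region(
    image,
    mask: np.ndarray,
    region_label: str = "",
    his_mode: str = "mean-rgb",
    l_scale: str = "255",
    ycbcr_variant: str = "full",
) -> ChromaticProfile:
    """Chromatic profile of the pixels selected by a boolean mask.

    R, G, B are per-channel means over the region.  With the default
    ``his_mode="mean-rgb"`` every derived index is computed from that mean
    triple; ``his_mode="per-pixel"`` instead converts each pixel to HSI and
    averages H, I, S arithmetically (sensitivity-analysis mode — hue averages
    are ill-defined near the 0/360 wrap).
    """
    pixels = np.asarray(getattr(image, "pixels", image), dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError("expected an HxWx3 RGB image")
    if mask.shape != pixels.shape[:2]:
        raise ValueError("mask shape does not match image shape")
    if not mask.any():
        raise ValueError("empty region mask")
    region = pixels[mask]
    r_mean, g_mean, b_mean = region.mean(axis=0)

    if his_mode == "mean-rgb":
        h, i, s = rgb_to_his(r_mean, g_mean, b_mean)
    elif his_mode == "per-pixel":
        his = np.array([rgb_to_his(*px) for px in region])
        h, i, s = his.mean(axis=0)
    else:
        raise ValueError(f"unknown his_mode {his_mode!r}")

    l_star, a_star, b_star = rgb_to_lab(r_mean, g_mean, b_mean, l_scale=l_scale)
    y, cb, cr = rgb_to_ycbcr(r_mean, g_mean, b_mean, variant=ycbcr_variant)
    return ChromaticProfile(
        r=float(r_mean), g=float(g_mean), b=float(b_mean),
        h=float(h), i=float(i), s=float(s),
        l_star=l_star, a_star=a_star, b_star=b_star,
        y=y, cb=cb, cr=cr,
        region_label=region_label,
        n_pixels=int(mask.sum()),
    )
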