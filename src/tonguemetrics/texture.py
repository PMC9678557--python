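"""Gray-level difference texture statistics.

Texture of a tongue region is summarised by the histogram of absolute gray
differences at a fixed pixel offset (Δi, Δj).  For an image f and offset
(Δi, Δj), the difference image is ``g(i,j) = f(i,j) - f(i+Δi, j+Δj)``; hg is
the normalized histogram of |g| over gray levels 0..m-1, and the four
statistics are

    MEAN = (1/m) Σ_i i·hg(i)
    CON  = Σ_i i²·hg(i)            (contrast)
    ASM  = Σ_i hg(i)²              (angular second moment / energy)
    ENT  = −Σ_i hg(i)·log₂ hg(i)   (entropy, bits; 0·log 0 := 0)

Pixel pairs contribute only when both endpoints lie inside the region mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "TextureProfile",
    "FOUR_OFFSETS",
    "gray_difference_histogram",
    "texture_features",
    "texture_profile",
    "texture_oracle",
]

#: the four standard unit offsets for the direction-averaged option
FOUR_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))

_BT601 = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class TextureProfile:
    """Gray-difference histogram and its four summary statistics.

    ``mean``/``con``/``asm``/``ent`` are ``None`` until
    :func:`texture_features` has been applied.
    """

    hg: np.ndarray
    m: int
    delta: tuple[tuple[int, int], ...]
    n_pairs: int
    region_label: str = ""
    mean: float | None = None
    con: float | None = None
    asm: float | None = None
    ent: float | None = None


def _to_gray(pixels: np.ndarray, m: int, gray_mode: str) -> np.ndarray:
    """Quantize an image to integer gray levels 0..m-1.

    ``gray_mode='bt601'`` uses the BT.601 luma weights; ``'mean'`` averages the
    channels.  Rounding is numpy's round-half-to-even.
    """
    pixels = np.asarray(pixels, dtype=float)
    if pixels.ndim == 3:
        if gray_mode == "bt601":
            gray = pixels @ _BT601
        elif gray_mode == "mean":
            gray = pixels.mean(axis=2)
        else:
            raise ValueError(f"unknown gray_mode {gray_mode!r}")
    elif pixels.ndim == 2:
        gray = pixels
    else:
        raise ValueError("expected an HxW or HxWx3 array")
    if m != 256:
        gray = gray * (m - 1) / 255.0
    return np.clip(np.round(gray), 0, m - 1).astype(np.int64)


def _normalize_offsets(delta) -> tuple[tuple[int, int], ...]:
    if delta == "average4":
        return FOUR_OFFSETS
    if isinstance(delta[0], (int, np.integer)):
        return (tuple(int(v) for v in delta),)
    return tuple(tuple(int(v) for v in d) for d in delta)


def gray_difference_histogram(
    pixels: np.ndarray,
    mask: np.ndarray,
    delta=(1, 1),
    m: int = 256,
    gray_mode: str = "bt601",
    region_label: str = "",
) -> TextureProfile:
    """Histogram of absolute gray differences over all valid in-mask pixel pairs.

    Parameters
    ----------
    pixels
        HxWx3 RGB (converted to gray per ``gray_mode``) or an HxW gray array.
    mask
        Boolean region mask; a pair contributes only when both (i, j) and
        (i+Δi, j+Δj) are inside it.
    delta
        A single ``(Δi, Δj)`` offset, a sequence of offsets, or ``"average4"``
        to pool the four unit offsets (0,1), (1,0), (1,1), (1,−1).

    Raises
    ------
    ValueError
        If the mask is empty or admits no valid pixel pair ("degenerate
        region").
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty region mask")
    gray = _to_gray(getattr(pixels, "pixels", pixels), m, gray_mode)
    if gray.shape != mask.shape:
        raise ValueError("mask shape does not match image shape")
    offsets = _normalize_offsets(delta)

    counts = np.zeros(m, dtype=np.int64)
    h, w = gray.shape
    for di, dj in offsets:
        # slice views of the anchor and the offset endpoint
        i0, i1 = max(0, -di), min(h, h - di)
        j0, j1 = max(0, -dj), min(w, w - dj)
        if i0 >= i1 or j0 >= j1:
            continue
        a = np.s_[i0:i1, j0:j1]
        b = np.s_[i0 + di : i1 + di, j0 + dj : j1 + dj]
        valid = mask[a] & mask[b]
        diffs = np.abs(gray[a][valid] - gray[b][valid])
        counts += np.bincount(diffs, minlength=m)
    n_pairs = int(counts.sum())
    if n_pairs == 0:
        raise ValueError("degenerate region: no valid pixel pair for the given offset")
    hg = counts / n_pairs
    return TextureProfile(hg=hg, m=m, delta=offsets, n_pairs=n_pairs, region_label=region_label)


def texture_features(profile: TextureProfile) -> TextureProfile:
    """Fill in MEAN, CON, ASM and ENT from a profile's histogram."""
    hg = np.asarray(profile.hg, dtype=float)
    if abs(hg.sum() - 1.0) > 1e-9 or np.any(hg < 0):
        raise ValueError("hg is not a normalized histogram")
    i = np.arange(len(hg), dtype=float)
    mean = float(i @ hg / profile.m)
    con = float((i**2) @ hg)
    asm = float(hg @ hg)
    nz = hg[hg > 0]
    ent = float(-(nz @ np.log2(nz)))
    return replace(profile, mean=mean, con=con, asm=asm, ent=max(ent, 0.0))


def texture_profile(
    pixels: np.ndarray,
    mask: np.ndarray,
    delta=(1, 1),
    m: int = 256,
    gray_mode: str = "bt601",
    region_label: str = "",
) -> TextureProfile:
    """Histogram plus statistics in one call."""
    return texture_features(
        gray_difference_histogram(pixels, mask, delta, m, gray_mode, region_label)
    )


def texture_oracle(
    pixels: np.ndarray,
    mask: np.ndarray,
    delta=(1, 1),
    m: int = 256,
    gray_mode: str = "bt601",
) -> TextureProfile:
    """Brute-force reference: explicit double loops over every pixel pair.

    Intended for validation on small regions (bounding box at most 64x64);
    deliberately unvectorized so it shares no code path with
    :func:`gray_difference_histogram`.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty region mask")
    rows, cols = np.nonzero(mask)
    if rows.max() - rows.min() >= 64 or cols.max() - cols.min() >= 64:
        raise ValueError("oracle restricted to regions within a 64x64 bounding box")
    gray = _to_gray(getattr(pixels, "pixels", pixels), m, gray_mode)
    offsets = _normalize_offsets(delta)
    h, w = gray.shape
    counts = [0] * m
    n_pairs = 0
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            for di, dj in offsets:
                i2, j2 = i + di, j + dj
                if 0 <= i2 < h and 0 <= j2 < w and mask[i2, j2]:
                    counts[abs(int(gray[i, j]) - int(gray[i2, j2]))] += 1
                    n_pairs += 1
    if n_pairs == 0:
        raise ValueError("degenerate region: no valid pixel pair for the given offset")
    mean = con = asm = ent = 0.0
    for level in range(m):
        p = counts[level] / n_pairs
        mean += level * p / m
        con += level * level * p
        asm += p * p
        if p > 0:
            ent -= p * math.log2(p)
    return TextureProfile(
        hg=np.array(counts, dtype=float) / n_pairs,
        m=m,
        delta=offsets,
        n_pairs=n_pairs,
        mean=mean,
        con=con,
        asm=asm,
        ent=ent,
    )
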