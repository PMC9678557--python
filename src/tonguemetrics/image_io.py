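"""Image loading, tongue segmentation, and body/coating splitting.

A tongue photograph is decomposed into two pixel sets — the tongue *body*
(the tissue surface) and the tongue *coating* (the deposit layer) — which are
profiled separately downstream.  Segmentation is deliberately simple:
threshold on brightness/saturation/redness, keep the largest connected
component, close small holes.  Ground-truth masks (e.g. from the synthetic
generator, or hand-drawn) can always be supplied instead, so feature
extraction never depends on segmentation quality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError
from skimage import measure, morphology

__all__ = [
    "TongueImage",
    "RegionMasks",
    "SegmentationConfig",
    "SplitConfig",
    "load_image",
    "save_image",
    "load_mask",
    "save_mask",
    "segment_tongue",
    "split_body_coating",
]


@dataclass(frozen=True)
class TongueImage:
    """8-bit RGB raster with provenance metadata."""

    pixels: np.ndarray
    source_path: str = ""
    color_space_tag: str = "sRGB-8bit"

    def __post_init__(self) -> None:
        px = self.pixels
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("pixels must be an HxWx3 array")
        if px.dtype != np.uint8:
            raise ValueError("pixels must be 8-bit (uint8)")
        if px.shape[0] < 16 or px.shape[1] < 16:
            raise ValueError("image must be at least 16x16")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class RegionMasks:
    """Boolean tongue/body/coating masks sharing the image shape.

    Invariant (checked by :meth:`validate_partition`): body and coating are
    disjoint and their union is the tongue mask.
    """

    tongue: np.ndarray
    body: np.ndarray
    coating: np.ndarray

    def validate_partition(self) -> None:
        if np.any(self.body & self.coating):
            raise ValueError("body and coating masks overlap")
        if not np.array_equal(self.body | self.coating, self.tongue):
            raise ValueError("body and coating do not partition the tongue mask")


@dataclass(frozen=True)
class SegmentationConfig:
    """Thresholds for isolating the tongue from the background.

    A pixel is a tongue candidate when its HSI brightness, saturation and red
    channel all meet their minima; the defaults assume a dark capture
    background, selecting on brightness alone.
    """

    min_intensity: float = 60.0
    min_saturation: float = 0.0
    min_redness: float = 0.0
    closing_radius: int = 2


@dataclass(frozen=True)
class SplitConfig:
    """Rule for assigning tongue pixels to the coating.

    Coatings are paler than the body tissue: a pixel is coating when its
    saturation falls below ``max_saturation`` and its brightness exceeds
    ``min_intensity``.
    """

    max_saturation: float = 0.18
    min_intensity: float = 120.0


def load_image(path: str | Path) -> TongueImage:
    """Load a raster image as 8-bit RGB.

    Grayscale inputs are promoted by channel replication; an alpha channel is
    discarded.  A truncated or unreadable file raises ``OSError`` naming the
    path, with no partial result.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            if im.mode != "RGB":
                im = im.convert("RGB")
            pixels = np.asarray(im, dtype=np.uint8)
    except UnidentifiedImageError as exc:
        raise OSError(f"cannot decode image file: {path}") from exc
    except OSError as exc:
        raise OSError(f"cannot read image file: {path}") from exc
    if pixels.size == 0:
        raise ValueError(f"zero-area image: {path}")
    return TongueImage(pixels=pixels, source_path=str(path))


def save_image(image: TongueImage, path: str | Path) -> None:
    """Write as PNG (lossless) or JPEG depending on the suffix."""
    Image.fromarray(image.pixels, mode="RGB").save(path)


def load_mask(path: str | Path) -> np.ndarray:
    """Read a single-channel 0/255 PNG as a boolean mask."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return arr >= 128


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as a single-channel 0/255 PNG."""
    arr = np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def _his_planes(pixels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-pixel brightness I and saturation S."""
    px = pixels.astype(float)
    total = px.sum(axis=2)
    i = total / 3.0
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(total > 0, 1.0 - 3.0 * px.min(axis=2) / np.where(total > 0, total, 1.0), 0.0)
    return i, s


def segment_tongue(image: TongueImage, config: SegmentationConfig | None = None) -> RegionMasks:
    """Isolate the tongue as the largest connected component of candidate pixels.

    Candidates satisfy the brightness/saturation/redness thresholds of
    ``config``; the component is then morphologically closed.  Body and
    coating masks in the returned object are empty — use
    :func:`split_body_coating` next.  Raises when no pixel passes
    ("no tongue region").
    """
    cfg = config or SegmentationConfig()
    px = image.pixels.astype(float)
    i, s = _his_planes(image.pixels)
    candidate = (
        (i >= cfg.min_intensity)
        & (s >= cfg.min_saturation)
        & (px[:, :, 0] >= cfg.min_redness)
    )
    if not candidate.any():
        raise ValueError("no tongue region: no pixel passes the segmentation criterion")
    labels = measure.label(candidate, connectivity=2)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    tongue = labels == largest
    if cfg.closing_radius > 0:
        tongue = morphology.closing(tongue, morphology.disk(cfg.closing_radius))
    empty = np.zeros_like(tongue)
    return RegionMasks(tongue=tongue, body=empty, coating=empty.copy())


def split_body_coating(
    image: TongueImage,
    tongue: np.ndarray,
    config: SplitConfig | None = None,
    body_mask: np.ndarray | None = None,
    coating_mask: np.ndarray | None = None,
) -> RegionMasks:
    """Partition the tongue mask into body and coating pixels.

    The default rule marks a pixel as coating when S < ``max_saturation`` and
    I > ``min_intensity`` (coatings are whiter and paler than the body).
    Supplying ``body_mask``/``coating_mask`` bypasses the rule entirely;
    external masks are intersected with the tongue mask and coating takes
    precedence on overlap.
    """
    tongue = np.asarray(tongue, dtype=bool)
    if not tongue.any():
        raise ValueError("empty tongue mask")
    if coating_mask is not None or body_mask is not None:
        coating = (np.asarray(coating_mask, dtype=bool) & tongue) if coating_mask is not None else np.zeros_like(tongue)
        body = tongue & ~coating
    else:
        cfg = config or SplitConfig()
        i, s = _his_planes(image.pixels)
        coating = tongue & (s < cfg.max_saturation) & (i > cfg.min_intensity)
        body = tongue & ~coating
    masks = RegionMasks(tongue=tongue, body=body, coating=coating)
    masks.validate_partition()
    return masks
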