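"""Per-image feature extraction: chromatic + texture block for each region."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .chromatics import profile_region
from .image_io import (
    RegionMasks,
    SegmentationConfig,
    SplitConfig,
    TongueImage,
    load_image,
    load_mask,
    segment_tongue,
    split_body_coating,
)
from .texture import texture_profile

__all__ = ["CHROMATIC_INDEXES", "TEXTURE_INDEXES", "extract_features", "extract_from_paths", "feature_frame"]

CHROMATIC_INDEXES = ("H", "I", "S", "R", "G", "B", "L_star", "a_star", "b_star", "Y", "Cb", "Cr")
TEXTURE_INDEXES = ("MEAN", "CON", "ASM", "ENT")


def extract_features(
    image: TongueImage,
    masks: RegionMasks | None = None,
    delta=(1, 1),
    m: int = 256,
    his_mode: str = "mean-rgb",
    segmentation: SegmentationConfig | None = None,
    split: SplitConfig | None = None,
) -> dict[str, dict[str, float]]:
    """The 12 chromatic indexes plus the 4 texture statistics per region.

    When ``masks`` is ``None`` the image is segmented and split with the given
    configs; supplying ground-truth masks bypasses segmentation entirely.
    Returns ``{"body": {...}, "coating": {...}}``; a region absent from the
    image (e.g. no coating) is omitted.
    """
    if masks is None:
        seg = segment_tongue(image, segmentation)
        masks = split_body_coating(image, seg.tongue, split)
    out: dict[str, dict[str, float]] = {}
    for label in ("body", "coating"):
        mask = getattr(masks, label)
        if not mask.any():
            continue
        block = profile_region(image, mask, region_label=label, his_mode=his_mode).as_dict()
        tex = texture_profile(image.pixels, mask, delta=delta, m=m, region_label=label)
        block.update({"MEAN": tex.mean, "CON": tex.con, "ASM": tex.asm, "ENT": tex.ent})
        out[label] = block
    return out


def extract_from_paths(
    image_path: str | Path,
    body_mask_path: str | Path | None = None,
    coating_mask_path: str | Path | None = None,
    **kwargs,
) -> dict[str, dict[str, float]]:
    """File-based variant used by the command-line ``extract`` subcommand."""
    image = load_image(image_path)
    masks = None
    if body_mask_path is not None and coating_mask_path is not None:
        body = load_mask(body_mask_path)
        coating = load_mask(coating_mask_path)
        masks = RegionMasks(tongue=body | coating, body=body, coating=coating)
    return extract_features(image, masks=masks, **kwargs)


def feature_frame(per_subject: dict[str, dict[str, dict[str, float]]]) -> pd.DataFrame:
    """Flatten ``{subject_id: {region: {index: value}}}`` to one row per
    subject x region, columns exactly the 12 chromatic + 4 texture indexes."""
    rows = []
    for sid, regions in per_subject.items():
        for region, block in regions.items():
            row = {"subject_id": sid, "region": region}
            row.update({k: block[k] for k in CHROMATIC_INDEXES + TEXTURE_INDEXES})
            rows.append(row)
    return pd.DataFrame(rows)


def save_features_json(features: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(features, indent=2, sort_keys=True))
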