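"""Per-subject cohort records: clinical tongue features plus blood markers.

The categorical vocabulary is the nine-feature clinical grading of a tongue
examination: shape, body color, coating color, coating thickness, coating
texture (greasy/normal), and four yes/no signs.  Blood markers are the
immune-inflammatory panel (WBC, PLT, CRP, IL-2, IL-6, TGF-β).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "SubjectRecord",
    "CATEGORY_VOCAB",
    "BINARY_FEATURES",
    "ORDINAL_FEATURES",
    "MARKERS",
    "GROUPS",
    "cohort_frame",
    "records_from_frame",
    "load_cohort_csv",
    "save_cohort_csv",
]

GROUPS = ("GLM", "control")

#: allowed categories per feature; ordinal features are listed lowest-first
CATEGORY_VOCAB: dict[str, tuple[str, ...]] = {
    "tongue_shape": ("small_thin", "moderate", "fat"),
    "body_color": ("light_red", "red", "dark_red"),
    "coating_color": ("none", "white", "yellow"),
    "coating_thick": ("thin", "thick"),
    "coating_greasy": ("normal", "greasy"),
    "prick": ("no", "yes"),
    "tooth_marked": ("no", "yes"),
    "sublingual_vessel": ("no", "yes"),
    "ecchymosis": ("no", "yes"),
}

#: three-level mutually exclusive features, compared by rank-sum on their codes
ORDINAL_FEATURES = ("tongue_shape", "body_color", "coating_color")
#: two-level features, compared by the chi-squared test
BINARY_FEATURES = (
    "coating_thick", "coating_greasy", "prick", "tooth_marked",
    "sublingual_vessel", "ecchymosis",
)

MARKERS = ("wbc", "plt", "crp", "il2", "il6", "tgfb")

_COLUMNS = (
    ["subject_id", "group", "age"]
    + list(ORDINAL_FEATURES)
    + list(BINARY_FEATURES)
    + list(MARKERS)
    + ["image_path"]
)


@dataclass
class SubjectRecord:
    """One subject: group label, age, tongue features, blood markers."""

    subject_id: str
    group: str
    age: float
    tongue_shape: str
    body_color: str
    coating_color: str
    coating_thick: str
    coating_greasy: str
    prick: str
    tooth_marked: str
    sublingual_vessel: str
    ecchymosis: str
    wbc: float
    plt: float
    crp: float
    il2: float
    il6: float
    tgfb: float
    image_path: str = ""
    #: synthetic standardized indexes (copula-induced), keyed by index name
    induced_indexes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        for feat, vocab in CATEGORY_VOCAB.items():
            val = getattr(self, feat)
            if val not in vocab:
                raise ValueError(f"{feat}={val!r} not in vocabulary {vocab}")
        for m in MARKERS:
            if getattr(self, m) <= 0:
                raise ValueError(f"marker {m} must be positive")


def cohort_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """Tabulate records; induced index columns are appended when present."""
    rows = []
    for r in records:
        row = {c: getattr(r, c) for c in _COLUMNS}
        row.update(r.induced_indexes)
        rows.append(row)
    return pd.DataFrame(rows)


def records_from_frame(df: pd.DataFrame) -> list[SubjectRecord]:
    """Validate a cohort table row by row; raises naming any bad column."""
    missing = [c for c in _COLUMNS if c != "image_path" and c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing required column(s): {missing}")
    extra = [c for c in df.columns if c not in _COLUMNS]
    records = []
    for _, row in df.iterrows():
        records.append(
            SubjectRecord(
                **{c: row[c] for c in _COLUMNS if c in df.columns},
                induced_indexes={c: float(row[c]) for c in extra},
            )
        )
    return records


def save_cohort_csv(records: list[SubjectRecord], path: str | Path) -> None:
    cohort_frame(records).to_csv(path, index=False)


def load_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV, returning the table."""
    df = pd.read_csv(path)
    records_from_frame(df)  # validation only
    return df
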