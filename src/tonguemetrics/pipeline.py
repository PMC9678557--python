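"""Case-control analysis of a tongue cohort, statsmodels-style.

:class:`CaseControlAnalysis` is the model object: build it from a cohort table
(and optionally a per-subject image feature table), call :meth:`fit`, and get a
:class:`CaseControlResults` carrying five report blocks:

* ``demographics`` — per-variable group comparison: median (min–max) or n (%)
  with the matching test (t for age, Mann–Whitney for markers, chi-squared for
  binary features, rank-sum on ordinal codes for three-level features);
* ``univariate`` / ``multivariate`` — logistic odds ratios with 95% Wald
  intervals for the binary tongue-feature encodings;
* ``roc`` — AUC per binary feature (and the greasy+thick combined score);
* ``image_comparison`` — per region x index group comparison of the image
  features;
* ``correlations`` — Spearman grid of image indexes against blood markers in
  the case group, with the p < 0.05 subset broken out.

No multiplicity correction is applied anywhere (alpha is fixed at 0.05),
mirroring the single-screen design this reimplements; treat the grids as
descriptive.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .features import CHROMATIC_INDEXES, TEXTURE_INDEXES, extract_features, feature_frame
from .image_io import SegmentationConfig, SplitConfig, load_image, load_mask, RegionMasks
from .records import (
    BINARY_FEATURES,
    CATEGORY_VOCAB,
    MARKERS,
    ORDINAL_FEATURES,
    cohort_frame,
    load_cohort_csv,
)
from .stats import (
    ContingencyTable2x2,
    chi_square_2x2,
    logistic_fit,
    logistic_univariate_2x2,
    mann_whitney_u,
    roc_auc,
    roc_auc_binary,
    spearman,
    two_sample_t_data,
)

__all__ = [
    "FEATURE_ENCODINGS",
    "CaseControlAnalysis",
    "CaseControlResults",
    "PipelineConfig",
    "run_pipeline",
    "summarize_cohort",
    "feature_association",
    "compare_image_features",
    "correlate_features_markers",
]

#: binary encodings of tongue features used for logistic regression / ROC;
#: cases are coded 1, the named category is the exposure
FEATURE_ENCODINGS: dict[str, tuple[str, str]] = {
    "yellow_coating": ("coating_color", "yellow"),
    "white_coating": ("coating_color", "white"),
    "greasy_coating": ("coating_greasy", "greasy"),
    "thick_coating": ("coating_thick", "thick"),
    "fat_tongue": ("tongue_shape", "fat"),
    "tooth_marked_tongue": ("tooth_marked", "yes"),
}

_SCHEMA_COLS = (
    {"subject_id", "group", "age"} | set(CATEGORY_VOCAB) | set(MARKERS) | {"image_path"}
)


def _split_groups(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    glm = df[df["group"] == "GLM"]
    ctrl = df[df["group"] == "control"]
    if len(glm) == 0 or len(ctrl) == 0:
        raise ValueError("both groups (GLM and control) must be present")
    return glm, ctrl


def _median_range(x: pd.Series) -> str:
    return f"{x.median():.2f} ({x.min():.2f}–{x.max():.2f})"


def summarize_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Demographics block: one row per variable (or per category level).

    Continuous markers get median (min–max) and a Mann–Whitney p; age gets a
    pooled t test; binary features n (%) and chi-squared; three-level features
    n (%) per level and a rank-sum p on their ordinal codes.  Degenerate
    variables (a zero margin, e.g. a sign absent from both groups) report no
    p-value.
    """
    for col in ("group", "age", *CATEGORY_VOCAB, *MARKERS):
        if col not in cohort.columns:
            raise ValueError(f"cohort table missing required column: {col!r}")
    glm, ctrl = _split_groups(cohort)
    rows = []

    t_res = two_sample_t_data(glm["age"], ctrl["age"])
    rows.append(
        {
            "variable": "age",
            "category": "",
            "glm": f"{glm['age'].mean():.2f} ± {glm['age'].std(ddof=1):.2f}",
            "control": f"{ctrl['age'].mean():.2f} ± {ctrl['age'].std(ddof=1):.2f}",
            "test": t_res.method,
            "p_value": t_res.p_value,
        }
    )
    for m in MARKERS:
        res = mann_whitney_u(glm[m].to_numpy(), ctrl[m].to_numpy())
        rows.append(
            {
                "variable": m,
                "category": "",
                "glm": _median_range(glm[m]),
                "control": _median_range(ctrl[m]),
                "test": res.method,
                "p_value": res.p_value,
            }
        )

    for feat in ORDINAL_FEATURES:
        vocab = CATEGORY_VOCAB[feat]
        codes = {c: k for k, c in enumerate(vocab)}
        x = glm[feat].map(codes).to_numpy()
        y = ctrl[feat].map(codes).to_numpy()
        try:
            res = mann_whitney_u(x, y)
            p, method = res.p_value, "rank-sum(ordinal)"
        except ValueError:
            p, method = np.nan, "not-testable"
        for cat in vocab:
            a, b = int((glm[feat] == cat).sum()), int((ctrl[feat] == cat).sum())
            rows.append(
                {
                    "variable": feat,
                    "category": cat,
                    "glm": f"{a} ({100 * a / len(glm):.2f}%)",
                    "control": f"{b} ({100 * b / len(ctrl):.2f}%)",
                    "test": method,
                    "p_value": p,
                }
            )
    for feat in BINARY_FEATURES:
        positive = CATEGORY_VOCAB[feat][1]
        a, b = int((glm[feat] == positive).sum()), int((ctrl[feat] == positive).sum())
        table = ContingencyTable2x2.from_counts(a, len(glm), b, len(ctrl))
        try:
            res = chi_square_2x2(table)
            p, method = res.p_value, res.method
        except ValueError:  # zero margin, e.g. the sign occurs in neither group
            p, method = np.nan, "not-testable"
        rows.append(
            {
                "variable": feat,
                "category": positive,
                "glm": f"{a} ({100 * a / len(glm):.2f}%)",
                "control": f"{b} ({100 * b / len(ctrl):.2f}%)",
                "test": method,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


def feature_association(
    cohort: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Logistic odds ratios and ROC for the binary tongue-feature encodings.

    Returns ``(univariate, multivariate, roc)`` tables.  The multivariate fit
    includes exactly the features with univariate p < ``alpha``.  Features with
    a zero cell are reported with a ``separation`` flag, never dropped
    silently.
    """
    glm, ctrl = _split_groups(cohort)
    uni_rows, tables = [], {}
    for name, (col, cat) in FEATURE_ENCODINGS.items():
        a, b = int((glm[col] == cat).sum()), int((ctrl[col] == cat).sum())
        table = ContingencyTable2x2.from_counts(a, len(glm), b, len(ctrl))
        tables[name] = table
        try:
            fit = logistic_univariate_2x2(table)
            uni_rows.append(
                {
                    "feature": name,
                    "or": fit.odds_ratios[0],
                    "ci_low": fit.ci_low[0],
                    "ci_high": fit.ci_high[0],
                    "p_value": fit.p_values[0],
                    "flag": "",
                }
            )
        except ValueError:
            uni_rows.append(
                {"feature": name, "or": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                 "p_value": np.nan, "flag": "separation"}
            )
    univariate = pd.DataFrame(uni_rows)

    selected = univariate.loc[univariate["p_value"] < alpha, "feature"].tolist()
    multi_rows = []
    if selected:
        y = (cohort["group"] == "GLM").to_numpy(dtype=float)
        X = np.column_stack(
            [np.ones(len(cohort))]
            + [
                (cohort[FEATURE_ENCODINGS[f][0]] == FEATURE_ENCODINGS[f][1]).to_numpy(dtype=float)
                for f in selected
            ]
        )
        fit = logistic_fit(y, X, names=["intercept", *selected])
        for j, f in enumerate(selected, start=1):
            multi_rows.append(
                {
                    "feature": f,
                    "or": fit.odds_ratios[j],
                    "ci_low": fit.ci_low[j],
                    "ci_high": fit.ci_high[j],
                    "p_value": fit.p_values[j],
                    "flag": "" if fit.converged else "non-converged",
                }
            )
    multivariate = pd.DataFrame(
        multi_rows, columns=["feature", "or", "ci_low", "ci_high", "p_value", "flag"]
    )

    roc_rows = []
    for name, table in tables.items():
        if min(table.margins[:2]) == 0:  # exposure absent or universal
            continue
        res = roc_auc_binary(table.a, table.a + table.c, table.b, table.b + table.d)
        roc_rows.append(
            {"marker": name, "auc": res.auc, "ci_low": res.ci_low,
             "ci_high": res.ci_high, "p_value": res.p_value}
        )
    greasy_col, greasy_cat = FEATURE_ENCODINGS["greasy_coating"]
    thick_col, thick_cat = FEATURE_ENCODINGS["thick_coating"]
    score = (
        (cohort[greasy_col] == greasy_cat).astype(float)
        + (cohort[thick_col] == thick_cat).astype(float)
    )
    if score.nunique() > 1:
        res = roc_auc(score.to_numpy(), (cohort["group"] == "GLM").astype(int).to_numpy())
        roc_rows.append(
            {"marker": "greasy+thick", "auc": res.auc, "ci_low": res.ci_low,
             "ci_high": res.ci_high, "p_value": res.p_value}
        )
    return univariate, multivariate, pd.DataFrame(roc_rows)


def compare_image_features(
    feature_table: pd.DataFrame, groups: pd.DataFrame | pd.Series
) -> pd.DataFrame:
    """Per region x index group comparison of image features (Mann–Whitney).

    ``groups`` maps subject_id to group (a Series indexed by subject_id or a
    frame with those columns).  Subjects missing a region are excluded from
    that region's rows; the exclusion count is reported per row.
    """
    if isinstance(groups, pd.DataFrame):
        groups = groups.set_index("subject_id")["group"]
    merged = feature_table.merge(
        groups.rename("group"), left_on="subject_id", right_index=True, how="inner"
    )
    n_subjects = groups.size
    rows = []
    indexes = [c for c in CHROMATIC_INDEXES + TEXTURE_INDEXES if c in merged.columns]
    for region, sub in merged.groupby("region", sort=True):
        glm, ctrl = _split_groups(sub)
        for idx in indexes:
            try:
                p = mann_whitney_u(glm[idx].to_numpy(), ctrl[idx].to_numpy()).p_value
            except ValueError:
                p = np.nan
            rows.append(
                {
                    "region": region,
                    "index": idx,
                    "glm": _median_range(glm[idx]),
                    "control": _median_range(ctrl[idx]),
                    "glm_median": glm[idx].median(),
                    "control_median": ctrl[idx].median(),
                    "p_value": p,
                    "n_excluded": int(n_subjects - len(sub)),
                }
            )
    return pd.DataFrame(rows)


def correlate_features_markers(
    cohort: pd.DataFrame,
    feature_table: pd.DataFrame | None = None,
    group: str = "GLM",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Spearman grid of image indexes against blood markers within one group.

    Besides the per-region indexes from ``feature_table``, any extra cohort
    columns (e.g. copula-induced synthetic indexes) enter as region
    ``"induced"``.  Returns ``(full_grid, significant_subset, skipped)`` where
    ``skipped`` logs constant feature vectors.
    """
    sub = cohort[cohort["group"] == group].set_index("subject_id")
    series: dict[tuple[str, str], pd.Series] = {}
    if feature_table is not None:
        ft = feature_table[feature_table["subject_id"].isin(sub.index)]
        for region, block in ft.groupby("region"):
            block = block.set_index("subject_id")
            for idx in CHROMATIC_INDEXES + TEXTURE_INDEXES:
                if idx in block.columns:
                    series[(str(region), idx)] = block[idx]
    for col in cohort.columns:
        if col not in _SCHEMA_COLS:
            series[("induced", col)] = sub[col]

    rows, skipped = [], []
    for (region, idx), values in series.items():
        for m in MARKERS:
            paired = pd.concat([values, sub[m]], axis=1, join="inner").dropna()
            if len(paired) < 3:
                skipped.append(f"{region}/{idx} x {m}: fewer than 3 pairs")
                continue
            try:
                res = spearman(paired.iloc[:, 0].to_numpy(), paired.iloc[:, 1].to_numpy())
            except ValueError as exc:
                skipped.append(f"{region}/{idx} x {m}: {exc}")
                continue
            rows.append(
                {"region": region, "index": idx, "marker": m,
                 "r": res.statistic, "p_value": res.p_value, "n": len(paired)}
            )
    full = pd.DataFrame(rows, columns=["region", "index", "marker", "r", "p_value", "n"])
    significant = full[full["p_value"] < alpha].reset_index(drop=True)
    return full, significant, skipped


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------


class CaseControlAnalysis:
    """Case-control tongue analysis model.

    Parameters
    ----------
    cohort
        Per-subject table (see :mod:`tonguemetrics.records` for the schema).
    feature_table
        Optional per subject x region image feature table
        (:func:`tonguemetrics.features.feature_frame` layout).
    alpha
        Significance level used for univariate selection and the correlation
        filter.
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        feature_table: pd.DataFrame | None = None,
        alpha: float = 0.05,
    ):
        if "group" not in cohort.columns:
            raise ValueError("cohort table missing required column: 'group'")
        self.cohort = cohort.reset_index(drop=True)
        self.feature_table = feature_table
        self.alpha = alpha

    @classmethod
    def from_dataframe(cls, cohort: pd.DataFrame, **kwargs) -> "CaseControlAnalysis":
        return cls(cohort, **kwargs)

    @classmethod
    def from_records(cls, records, **kwargs) -> "CaseControlAnalysis":
        return cls(cohort_frame(records), **kwargs)

    @classmethod
    def from_csv(
        cls, cohort_csv: str | Path, features_csv: str | Path | None = None, **kwargs
    ) -> "CaseControlAnalysis":
        feature_table = pd.read_csv(features_csv) if features_csv else None
        return cls(load_cohort_csv(cohort_csv), feature_table=feature_table, **kwargs)

    def fit(self) -> "CaseControlResults":
        """Run every applicable block; a failing block is isolated and its
        error recorded rather than aborting the whole report."""
        blocks: dict[str, object] = {}
        errors: dict[str, str] = {}

        def _run(name, fn):
            try:
                blocks[name] = fn()
            except Exception as exc:  # noqa: BLE001 - isolation is the point
                errors[name] = f"{type(exc).__name__}: {exc}"

        _run("demographics", lambda: summarize_cohort(self.cohort))
        _run("associations", lambda: feature_association(self.cohort, alpha=self.alpha))
        if self.feature_table is not None or any(
            c not in _SCHEMA_COLS for c in self.cohort.columns
        ):
            _run(
                "image_comparison",
                lambda: compare_image_features(
                    self.feature_table, self.cohort[["subject_id", "group"]]
                )
                if self.feature_table is not None
                else pd.DataFrame(),
            )
            _run(
                "correlations",
                lambda: correlate_features_markers(
                    self.cohort, self.feature_table, alpha=self.alpha
                ),
            )
        uni, multi, roc = blocks.get("associations", (None, None, None))
        corr = blocks.get("correlations", (None, None, []))
        return CaseControlResults(
            model=self,
            demographics=blocks.get("demographics"),
            univariate=uni,
            multivariate=multi,
            roc=roc,
            image_comparison=blocks.get("image_comparison"),
            correlations_full=corr[0],
            correlations=corr[1],
            skipped_correlations=corr[2],
            errors=errors,
        )


@dataclass
class CaseControlResults:
    """Fitted report blocks; see :class:`CaseControlAnalysis`."""

    model: CaseControlAnalysis
    demographics: pd.DataFrame | None
    univariate: pd.DataFrame | None
    multivariate: pd.DataFrame | None
    roc: pd.DataFrame | None
    image_comparison: pd.DataFrame | None
    correlations_full: pd.DataFrame | None
    correlations: pd.DataFrame | None
    skipped_correlations: list[str] = field(default_factory=list)
    errors: dict[str, str] = field(default_factory=dict)

    def summary(self) -> str:
        """Plain-text report of every block that was produced."""
        out = ["Case-control tongue analysis", "=" * 32]
        n = self.model.cohort.groupby("group").size().to_dict()
        out.append(f"subjects: {n}")
        for title, df in (
            ("Demographics", self.demographics),
            ("Univariate logistic (OR, 95% CI)", self.univariate),
            ("Multivariate logistic (OR, 95% CI)", self.multivariate),
            ("ROC / AUC", self.roc),
            ("Image features by group", self.image_comparison),
            ("Significant Spearman correlations (cases)", self.correlations),
        ):
            if df is None or len(df) == 0:
                continue
            out += ["", title, "-" * len(title), df.to_string(index=False)]
        if self.errors:
            out += ["", "Blocks not produced:"]
            out += [f"  {k}: {v}" for k, v in self.errors.items()]
        return "\n".join(out)

    def save(self, out_dir: str | Path, seed: int | None = None, settings: dict | None = None) -> None:
        """Write per-block CSVs, a JSON report, and a run log (versions, seed,
        settings in force)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        names = {
            "demographics": self.demographics,
            "univariate": self.univariate,
            "multivariate": self.multivariate,
            "roc": self.roc,
            "image_comparison": self.image_comparison,
            "correlations_full": self.correlations_full,
            "correlations_significant": self.correlations,
        }
        produced = []
        for name, df in names.items():
            if df is not None:
                df.to_csv(out / f"{name}.csv", index=False)
                produced.append(name)
        report = {
            "blocks_produced": produced,
            "errors": self.errors,
            "skipped_correlations": self.skipped_correlations,
        }
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        import scipy

        log = {
            "package": {"tonguemetrics": _pkg_version},
            "versions": {
                "python": platform.python_version(),
                "numpy": np.__version__,
                "scipy": scipy.__version__,
                "pandas": pd.__version__,
            },
            "seed": seed,
            "alpha": self.model.alpha,
            "settings": settings or {},
        }
        (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))

    def plot_roc(self, ax=None):
        """Bar-free ROC summary plot: one step curve per binary marker."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        if self.roc is not None:
            cohort = self.model.cohort
            labels = (cohort["group"] == "GLM").astype(int).to_numpy()
            for _, row in self.roc.iterrows():
                name = row["marker"]
                if name in FEATURE_ENCODINGS:
                    col, cat = FEATURE_ENCODINGS[name]
                    score = (cohort[col] == cat).to_numpy(dtype=float)
                elif name == "greasy+thick":
                    score = sum(
                        (cohort[FEATURE_ENCODINGS[f][0]] == FEATURE_ENCODINGS[f][1]).to_numpy(dtype=float)
                        for f in ("greasy_coating", "thick_coating")
                    )
                else:
                    continue
                fpr, tpr = _roc_points(score, labels)
                ax.plot(fpr, tpr, drawstyle="steps-post", label=f"{name} (AUC={row['auc']:.3f})")
        ax.plot([0, 1], [0, 1], "k:", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend(loc="lower right", fontsize=8)
        return ax


def _roc_points(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    thresholds = np.r_[np.inf, np.unique(scores)[::-1]]
    fpr = [( (scores >= t) & (labels == 0) ).sum() / max((labels == 0).sum(), 1) for t in thresholds]
    tpr = [( (scores >= t) & (labels == 1) ).sum() / max((labels == 1).sum(), 1) for t in thresholds]
    return np.array(fpr), np.array(tpr)


# ---------------------------------------------------------------------------
# file-based orchestration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """End-to-end run configuration (YAML-serializable)."""

    cohort_csv: str
    out_dir: str
    features_csv: str | None = None
    image_dir: str | None = None
    seed: int = 0
    alpha: float = 0.05
    delta: tuple[int, int] = (1, 1)
    m: int = 256
    his_mode: str = "mean-rgb"
    min_intensity: float = 60.0
    closing_radius: int = 2
    split_max_saturation: float = 0.18
    split_min_intensity: float = 120.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "delta" in data:
            data["delta"] = tuple(data["delta"])
        return cls(**data)


def _features_from_images(cohort: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    image_dir = Path(config.image_dir)
    seg = SegmentationConfig(min_intensity=config.min_intensity, closing_radius=config.closing_radius)
    split = SplitConfig(max_saturation=config.split_max_saturation, min_intensity=config.split_min_intensity)
    per_subject = {}
    for _, row in cohort.iterrows():
        sid = row["subject_id"]
        declared = row.get("image_path", "")
        declared = "" if pd.isna(declared) else str(declared).strip()
        path = Path(declared) if declared else image_dir / f"{sid}.png"
        if not path.exists():
            continue
        image = load_image(path)
        masks = None
        body_p, coat_p = image_dir / f"{sid}_body.png", image_dir / f"{sid}_coating.png"
        if body_p.exists() and coat_p.exists():
            body, coating = load_mask(body_p), load_mask(coat_p)
            masks = RegionMasks(tongue=body | coating, body=body, coating=coating)
        per_subject[sid] = extract_features(
            image, masks=masks, delta=config.delta, m=config.m,
            his_mode=config.his_mode, segmentation=seg, split=split,
        )
    return feature_frame(per_subject)


def run_pipeline(config: PipelineConfig | str | Path) -> CaseControlResults:
    """Cohort CSV (+ optional image directory) to a full written report.

    Deterministic given the config: rerunning writes byte-identical CSVs.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    cohort = load_cohort_csv(config.cohort_csv)
    feature_table = None
    if config.features_csv:
        feature_table = pd.read_csv(config.features_csv)
    elif config.image_dir:
        feature_table = _features_from_images(cohort, config)
        if len(feature_table) == 0:
            feature_table = None
    model = CaseControlAnalysis(cohort, feature_table=feature_table, alpha=config.alpha)
    results = model.fit()
    settings = {
        "his_aggregation": config.his_mode,
        "texture_delta": list(config.delta),
        "texture_levels": config.m,
        "ycbcr": "bt601-full-range",
        "lab_l_scale": "255",
        "yates_correction": False,
        "multiple_testing": "none",
    }
    results.save(config.out_dir, seed=config.seed, settings=settings)
    return results
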