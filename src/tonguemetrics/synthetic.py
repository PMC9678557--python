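"""Synthetic tongue images and case-control cohorts with known ground truth.

The generators exist so every downstream stage — segmentation, chromatic and
texture profiling, the statistical pipeline — is testable without clinical
data.  Images are an elliptical tongue on a dark background with a contiguous
pale coating patch, additive Gaussian pixel noise and an optional sinusoidal
luminance modulation (controllable texture).  Cohorts draw the nine
categorical tongue features from per-group probabilities matching the study's
observed proportions (40 cases / 40 controls) and the blood markers from
right-skewed log-normal distributions whose medians equal the printed group
medians, truncated to the printed min–max envelopes.

Every generator is a pure function of its spec: same spec and seed give
bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as _sps

from .image_io import RegionMasks, TongueImage
from .records import (
    BINARY_FEATURES,
    CATEGORY_VOCAB,
    MARKERS,
    ORDINAL_FEATURES,
    SubjectRecord,
)

__all__ = [
    "ImageSpec",
    "MarkerEnvelope",
    "CohortSpec",
    "generate_tongue_image",
    "generate_cohort",
    "reference_cohort",
    "default_image_spec",
    "GLM_CATEGORY_PROBS",
    "CONTROL_CATEGORY_PROBS",
    "GLM_MARKERS",
    "CONTROL_MARKERS",
]

_BACKGROUND = (18, 14, 14)


@dataclass(frozen=True)
class ImageSpec:
    """Parameters of one synthetic tongue image.

    ``coating_fraction`` is the proportion of tongue pixels assigned to the
    coating patch; ``noise_sd`` the per-channel SD of i.i.d. additive Gaussian
    noise (gray levels); ``texture_period`` the spatial period in pixels of a
    sinusoidal luminance modulation (``None`` or ``inf`` disables it).
    """

    width: int = 256
    height: int = 256
    body_color: tuple[int, int, int] = (172, 96, 88)
    coating_color: tuple[int, int, int] = (196, 186, 172)
    coating_fraction: float = 0.35
    noise_sd: float = 4.0
    texture_period: float | None = 16.0
    texture_amplitude: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 16 or self.height < 16:
            raise ValueError("width/height must be at least 16 pixels")
        for name in ("body_color", "coating_color"):
            col = getattr(self, name)
            if len(col) != 3 or any(not (0 <= v <= 255) for v in col):
                raise ValueError(f"{name} must be an RGB triplet in [0, 255]")
        if not (0.0 <= self.coating_fraction <= 1.0):
            raise ValueError("coating_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.texture_period is not None and not math.isinf(self.texture_period):
            if self.texture_period <= 0:
                raise ValueError("texture_period must be positive")


def generate_tongue_image(spec: ImageSpec) -> tuple[TongueImage, RegionMasks]:
    """Render a synthetic tongue image and its ground-truth region masks.

    The tongue is an axis-aligned ellipse; the coating is the contiguous
    inner patch (anterior-shifted elliptical level set) covering exactly
    ``round(coating_fraction · |tongue|)`` tongue pixels.
    """
    h, w = spec.height, spec.width
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    ax, ay = 0.42 * w, 0.46 * h
    tongue = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0

    n_tongue = int(tongue.sum())
    k = int(round(spec.coating_fraction * n_tongue))
    coating = np.zeros_like(tongue)
    if k > 0:
        # anterior-shifted elliptical distance; its level sets are contiguous
        d = ((xx - cx) / ax) ** 2 + ((yy - (cy - 0.12 * h)) / (0.8 * ay)) ** 2
        idx = np.nonzero(tongue)
        order = np.argsort(d[idx], kind="stable")[:k]
        coating[idx[0][order], idx[1][order]] = True
    body = tongue & ~coating

    img = np.empty((h, w, 3), dtype=float)
    img[:] = _BACKGROUND
    img[body] = spec.body_color
    img[coating] = spec.coating_color

    period = spec.texture_period
    if period is not None and not math.isinf(period):
        wave = spec.texture_amplitude * np.sin(2.0 * np.pi * (xx + yy) / period)
        img[tongue] += wave[tongue][:, None]
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)

    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)
    image = TongueImage(pixels=pixels, source_path=f"synthetic:seed={spec.seed}")
    return image, RegionMasks(tongue=tongue, body=body, coating=coating)


def default_image_spec(group: str, seed: int = 0, **overrides) -> ImageSpec:
    """Per-group image spec: cases get brighter, paler coating and body colors."""
    if group == "GLM":
        base = dict(body_color=(182, 118, 108), coating_color=(205, 196, 184))
    elif group == "control":
        base = dict(body_color=(168, 92, 84), coating_color=(182, 165, 150))
    else:
        raise ValueError(f"unknown group {group!r}")
    base.update(overrides)
    return ImageSpec(seed=seed, **base)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MarkerEnvelope:
    """Log-normal marker distribution pinned to a printed median and range.

    ``mu = ln(median)``; ``sigma`` places the printed min/max at the 1/(2n)
    and 1−1/(2n) quantiles of an n=40 sample.  Sampling inverts the CDF on the
    truncated interval, so draws stay inside [minimum, maximum] without point
    masses at the bounds.
    """

    median: float
    minimum: float
    maximum: float
    n_ref: int = 40

    def __post_init__(self) -> None:
        if not (0 < self.minimum <= self.median <= self.maximum):
            raise ValueError("require 0 < minimum <= median <= maximum")

    @property
    def mu(self) -> float:
        return math.log(self.median)

    @property
    def sigma(self) -> float:
        if self.maximum == self.minimum:
            return 1e-12
        z = _sps.norm.ppf(1.0 - 1.0 / (2.0 * self.n_ref))
        return math.log(self.maximum / self.minimum) / (2.0 * z)

    def from_uniform(self, u: np.ndarray) -> np.ndarray:
        """Truncated inverse-CDF transform of uniforms in (0, 1)."""
        lo = _sps.norm.cdf((math.log(self.minimum) - self.mu) / self.sigma)
        hi = _sps.norm.cdf((math.log(self.maximum) - self.mu) / self.sigma)
        return np.exp(self.mu + self.sigma * _sps.norm.ppf(lo + np.asarray(u) * (hi - lo)))


GLM_CATEGORY_PROBS: dict[str, dict[str, float]] = {
    "tongue_shape": {"small_thin": 0.0, "moderate": 0.675, "fat": 0.325},
    "body_color": {"light_red": 1.0, "red": 0.0, "dark_red": 0.0},
    "coating_color": {"none": 0.15, "white": 0.80, "yellow": 0.05},
    "coating_thick": {"thin": 0.15, "thick": 0.85},
    "coating_greasy": {"normal": 0.05, "greasy": 0.95},
    "prick": {"no": 1.0, "yes": 0.0},
    "tooth_marked": {"no": 0.625, "yes": 0.375},
    "sublingual_vessel": {"no": 0.625, "yes": 0.375},
    "ecchymosis": {"no": 1.0, "yes": 0.0},
}

CONTROL_CATEGORY_PROBS: dict[str, dict[str, float]] = {
    "tongue_shape": {"small_thin": 0.225, "moderate": 0.625, "fat": 0.15},
    "body_color": {"light_red": 0.725, "red": 0.275, "dark_red": 0.0},
    "coating_color": {"none": 0.70, "white": 0.175, "yellow": 0.125},
    "coating_thick": {"thin": 0.875, "thick": 0.125},
    "coating_greasy": {"normal": 0.85, "greasy": 0.15},
    "prick": {"no": 1.0, "yes": 0.0},
    "tooth_marked": {"no": 0.85, "yes": 0.15},
    "sublingual_vessel": {"no": 1.0, "yes": 0.0},
    "ecchymosis": {"no": 1.0, "yes": 0.0},
}

GLM_MARKERS: dict[str, MarkerEnvelope] = {
    "wbc": MarkerEnvelope(8.85, 4.70, 21.14),
    "plt": MarkerEnvelope(291.50, 121.00, 552.00),
    "crp": MarkerEnvelope(6.73, 0.50, 85.63),
    "il2": MarkerEnvelope(112.80, 8.50, 262.70),
    "il6": MarkerEnvelope(3.15, 2.00, 26.40),
    "tgfb": MarkerEnvelope(430.00, 51.70, 1169.90),
}

CONTROL_MARKERS: dict[str, MarkerEnvelope] = {
    "wbc": MarkerEnvelope(7.42, 6.19, 8.67),
    "plt": MarkerEnvelope(205.00, 108.00, 292.00),
    "crp": MarkerEnvelope(2.69, 1.73, 3.88),
    "il2": MarkerEnvelope(60.64, 46.07, 76.05),
    "il6": MarkerEnvelope(2.98, 1.61, 4.66),
    "tgfb": MarkerEnvelope(186.08, 148.10, 222.48),
}

#: age mean/SD per group (years), truncated to the 18–70 inclusion window
_AGE_PARAMS = {"GLM": (34.10, 11.03), "control": (33.13, 8.47)}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic case-control cohort.

    ``category_probs[group][feature]`` maps each category to its probability
    (mutually exclusive features must sum to 1 per group).  ``marker_params``
    holds per-group :class:`MarkerEnvelope` objects.  ``correlation_targets``
    maps ``(marker, index_name)`` to a Spearman coefficient to induce between
    that marker and a synthetic standardized index column, via a Gaussian
    copula.
    """

    n_glm: int = 40
    n_control: int = 40
    category_probs: dict[str, dict[str, dict[str, float]]] = field(
        default_factory=lambda: {"GLM": GLM_CATEGORY_PROBS, "control": CONTROL_CATEGORY_PROBS}
    )
    marker_params: dict[str, dict[str, MarkerEnvelope]] = field(
        default_factory=lambda: {"GLM": GLM_MARKERS, "control": CONTROL_MARKERS}
    )
    correlation_targets: dict[tuple[str, str], float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_glm < 0 or self.n_control < 0:
            raise ValueError("group sizes must be non-negative")
        for group, feats in self.category_probs.items():
            for feat, probs in feats.items():
                vocab = CATEGORY_VOCAB[feat]
                if set(probs) != set(vocab):
                    raise ValueError(f"{group}/{feat}: categories must be exactly {vocab}")
                if any(not (0.0 <= p <= 1.0) for p in probs.values()):
                    raise ValueError(f"{group}/{feat}: probabilities must lie in [0, 1]")
                if abs(sum(probs.values()) - 1.0) > 1e-9:
                    raise ValueError(f"{group}/{feat}: probabilities must sum to 1")
        for (marker, _), rho in self.correlation_targets.items():
            if marker not in MARKERS:
                raise ValueError(f"unknown marker {marker!r} in correlation_targets")
            if not (-1.0 < rho < 1.0):
                raise ValueError("correlation targets must lie in (-1, 1)")


def generate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Draw a reproducible cohort of ``n_glm + n_control`` subject records."""
    rng = np.random.default_rng(spec.seed)
    records: list[SubjectRecord] = []
    for group, n, prefix in (("GLM", spec.n_glm, "G"), ("control", spec.n_control, "C")):
        probs = spec.category_probs[group]
        envelopes = spec.marker_params[group]
        mean_age, sd_age = _AGE_PARAMS[group]
        # truncated-normal ages within the 18-70 inclusion window
        lo = _sps.norm.cdf((18 - mean_age) / sd_age)
        hi = _sps.norm.cdf((70 - mean_age) / sd_age)
        ages = mean_age + sd_age * _sps.norm.ppf(lo + rng.random(n) * (hi - lo))

        cats = {
            feat: rng.choice(
                CATEGORY_VOCAB[feat],
                size=n,
                p=[probs[feat][c] for c in CATEGORY_VOCAB[feat]],
            )
            for feat in CATEGORY_VOCAB
        }
        latents = {m: rng.standard_normal(n) for m in MARKERS}
        markers = {m: envelopes[m].from_uniform(_sps.norm.cdf(latents[m])) for m in MARKERS}

        induced = {}
        for (marker, index_name), rho in spec.correlation_targets.items():
            # Gaussian copula: latent Pearson r giving Spearman rho
            r = 2.0 * math.sin(math.pi * rho / 6.0)
            induced[index_name] = r * latents[marker] + math.sqrt(1.0 - r * r) * rng.standard_normal(n)

        for i in range(n):
            records.append(
                SubjectRecord(
                    subject_id=f"{prefix}{i + 1:03d}",
                    group=group,
                    age=float(ages[i]),
                    **{feat: str(cats[feat][i]) for feat in CATEGORY_VOCAB},
                    **{m: float(markers[m][i]) for m in MARKERS},
                    induced_indexes={k: float(v[i]) for k, v in induced.items()},
                )
            )
    return records


def _exact_counts_column(vocab: tuple[str, ...], counts: dict[str, int], n: int, offset: int) -> list[str]:
    values: list[str] = []
    for cat in vocab:
        values.extend([cat] * counts.get(cat, 0))
    if len(values) != n:
        raise ValueError("category counts do not sum to the group size")
    return values[offset % n :] + values[: offset % n]


_REFERENCE_COUNTS = {
    "GLM": {
        "tongue_shape": {"small_thin": 0, "moderate": 27, "fat": 13},
        "body_color": {"light_red": 40, "red": 0, "dark_red": 0},
        "coating_color": {"none": 6, "white": 32, "yellow": 2},
        "coating_thick": {"thin": 6, "thick": 34},
        "coating_greasy": {"normal": 2, "greasy": 38},
        "prick": {"no": 40, "yes": 0},
        "tooth_marked": {"no": 25, "yes": 15},
        "sublingual_vessel": {"no": 25, "yes": 15},
        "ecchymosis": {"no": 40, "yes": 0},
    },
    "control": {
        "tongue_shape": {"small_thin": 9, "moderate": 25, "fat": 6},
        "body_color": {"light_red": 29, "red": 11, "dark_red": 0},
        "coating_color": {"none": 28, "white": 7, "yellow": 5},
        "coating_thick": {"thin": 35, "thick": 5},
        "coating_greasy": {"normal": 34, "greasy": 6},
        "prick": {"no": 40, "yes": 0},
        "tooth_marked": {"no": 34, "yes": 6},
        "sublingual_vessel": {"no": 40, "yes": 0},
        "ecchymosis": {"no": 40, "yes": 0},
    },
}


def reference_cohort() -> list[SubjectRecord]:
    """Deterministic 40+40 cohort whose categorical marginals equal the study's
    observed counts exactly.

    The joint structure across features is arbitrary (each column is rotated by
    a different offset); only the per-feature marginals are meaningful.  Marker
    values follow the group envelopes on a deterministic quantile grid, so the
    sample medians sit at the envelope medians.
    """
    records: list[SubjectRecord] = []
    for group, prefix in (("GLM", "G"), ("control", "C")):
        n = 40
        counts = _REFERENCE_COUNTS[group]
        cols = {
            feat: _exact_counts_column(CATEGORY_VOCAB[feat], counts[feat], n, offset=7 * k)
            for k, feat in enumerate(CATEGORY_VOCAB)
        }
        envelopes = (GLM_MARKERS if group == "GLM" else CONTROL_MARKERS)
        grid = (np.arange(n) + 0.5) / n
        markers = {
            m: env.from_uniform(np.roll(grid, 3 * k))
            for k, (m, env) in enumerate(envelopes.items())
        }
        mean_age, sd_age = _AGE_PARAMS[group]
        ages = np.clip(mean_age + sd_age * _sps.norm.ppf(grid), 18, 70)
        for i in range(n):
            records.append(
                SubjectRecord(
                    subject_id=f"{prefix}{i + 1:03d}",
                    group=group,
                    age=float(ages[i]),
                    **{feat: cols[feat][i] for feat in CATEGORY_VOCAB},
                    **{m: float(markers[m][i]) for m in MARKERS},
                )
            )
    return records
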