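"""Synthetic image and cohort generators: determinism, marginals, copula."""

import numpy as np
import pytest

from tonguemetrics.records import CATEGORY_VOCAB, cohort_frame
from tonguemetrics.stats import spearman
from tonguemetrics.synthetic import (
    CONTROL_CATEGORY_PROBS,
    GLM_CATEGORY_PROBS,
    CohortSpec,
    ImageSpec,
    MarkerEnvelope,
    generate_cohort,
    generate_tongue_image,
    reference_cohort,
)


class TestImageGenerator:
    def test_noiseless_tongue_is_constant_body_color(self):
        spec = ImageSpec(noise_sd=0.0, texture_period=None, coating_fraction=0.0, seed=1)
        img, masks = generate_tongue_image(spec)
        assert not masks.coating.any()
        region = img.pixels[masks.tongue]
        assert np.array_equal(region, np.tile(spec.body_color, (len(region), 1)))

    def test_coating_fraction_exact_to_rounding(self):
        spec = ImageSpec(width=256, height=256, coating_fraction=0.5, seed=0)
        _, masks = generate_tongue_image(spec)
        n_tongue = masks.tongue.sum()
        assert abs(masks.coating.sum() - 0.5 * n_tongue) <= 1.0

    def test_seed_contract(self):
        spec = ImageSpec(seed=7)
        img1, _ = generate_tongue_image(spec)
        img2, _ = generate_tongue_image(spec)
        assert np.array_equal(img1.pixels, img2.pixels)
        img3, _ = generate_tongue_image(ImageSpec(seed=8))
        assert not np.array_equal(img1.pixels, img3.pixels)

    @pytest.mark.parametrize("seed", range(5))
    def test_masks_partition_fuzz(self, seed, rng):
        spec = ImageSpec(
            width=int(rng.integers(32, 128)),
            height=int(rng.integers(32, 128)),
            coating_fraction=float(rng.random()),
            seed=seed,
        )
        _, masks = generate_tongue_image(spec)
        masks.validate_partition()
        assert masks.tongue.any()

    @pytest.mark.parametrize(
        "field, value",
        [
            ("coating_fraction", 1.5),
            ("width", 4),
            ("noise_sd", -1.0),
            ("body_color", (300, 0, 0)),
            ("texture_period", -2.0),
        ],
    )
    def test_invalid_spec_names_field(self, field, value):
        with pytest.raises(ValueError, match=field.split("_")[0]):
            ImageSpec(**{field: value})


class TestCohortGenerator:
    def test_seed_determinism(self):
        spec = CohortSpec(seed=11)
        a = cohort_frame(generate_cohort(spec))
        b = cohort_frame(generate_cohort(spec))
        assert a.equals(b)

    def test_large_sample_marginal_fidelity(self):
        """Each simulated categorical proportion sits within 3 binomial SEs."""
        n = 4000
        df = cohort_frame(generate_cohort(CohortSpec(n_glm=n, n_control=n, seed=2)))
        for group, probs in (("GLM", GLM_CATEGORY_PROBS), ("control", CONTROL_CATEGORY_PROBS)):
            sub = df[df["group"] == group]
            for feat, cat_probs in probs.items():
                for cat, p in cat_probs.items():
                    obs = (sub[feat] == cat).mean()
                    se = np.sqrt(max(p * (1 - p), 1e-12) / n)
                    assert abs(obs - p) <= max(3 * se, 2e-3), (group, feat, cat)

    def test_greasy_proportion_near_observed_rate(self):
        df = cohort_frame(generate_cohort(CohortSpec(n_glm=4000, n_control=4000, seed=9)))
        frac = (df.loc[df["group"] == "GLM", "coating_greasy"] == "greasy").mean()
        assert frac == pytest.approx(0.95, abs=0.02)

    def test_zero_probability_category_absent(self):
        probs = {
            "GLM": {**GLM_CATEGORY_PROBS, "coating_greasy": {"normal": 1.0, "greasy": 0.0}},
            "control": {**CONTROL_CATEGORY_PROBS, "coating_greasy": {"normal": 1.0, "greasy": 0.0}},
        }
        df = cohort_frame(generate_cohort(CohortSpec(category_probs=probs, seed=0)))
        assert (df["coating_greasy"] == "greasy").sum() == 0

    def test_bad_probability_vector_rejected(self):
        probs = {
            "GLM": {**GLM_CATEGORY_PROBS, "coating_color": {"none": 0.5, "white": 0.9, "yellow": 0.1}},
            "control": CONTROL_CATEGORY_PROBS,
        }
        with pytest.raises(ValueError, match="sum to 1"):
            CohortSpec(category_probs=probs)

    def test_markers_respect_printed_envelopes(self):
        df = cohort_frame(generate_cohort(CohortSpec(n_glm=500, n_control=500, seed=4)))
        glm = df[df["group"] == "GLM"]
        assert glm["wbc"].between(4.70, 21.14).all()
        assert glm["wbc"].median() == pytest.approx(8.85, rel=0.1)

    def test_copula_induces_target_spearman(self):
        spec = CohortSpec(
            n_glm=5000, n_control=0, seed=6,
            correlation_targets={("wbc", "coating_CON"): -0.32},
        )
        df = cohort_frame(generate_cohort(spec))
        r = spearman(df["wbc"].to_numpy(), df["coating_CON"].to_numpy()).statistic
        assert r == pytest.approx(-0.32, abs=0.05)

    def test_marker_envelope_validation(self):
        with pytest.raises(ValueError):
            MarkerEnvelope(median=5.0, minimum=6.0, maximum=10.0)


class TestReferenceCohort:
    def test_exact_observed_counts(self):
        df = cohort_frame(reference_cohort())
        glm = df[df["group"] == "GLM"]
        ctrl = df[df["group"] == "control"]
        assert (glm["coating_greasy"] == "greasy").sum() == 38
        assert (ctrl["coating_greasy"] == "greasy").sum() == 6
        assert (glm["coating_thick"] == "thick").sum() == 34
        assert (glm["coating_color"] == "white").sum() == 32
        assert (ctrl["body_color"] == "red").sum() == 11
        assert (glm["tooth_marked"] == "yes").sum() == 15

    def test_deterministic_and_vocabulary_clean(self):
        a, b = cohort_frame(reference_cohort()), cohort_frame(reference_cohort())
        assert a.equals(b)
        for feat, vocab in CATEGORY_VOCAB.items():
            assert set(a[feat]) <= set(vocab)
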