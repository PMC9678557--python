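# Methods

`tonguemetrics` reimplements, as a tested pipeline, the quantitative analysis
of tongue photographs used in case-control studies of granulomatous lobular
mastitis (GLM): per-region chromatic indexes, gray-difference texture
statistics, and the accompanying case-control statistics. This note records
the models, the parameter choices, and the places where the design was
genuinely open.

## Region model

A tongue image is decomposed into two disjoint pixel sets, the tongue **body**
(tissue surface) and the tongue **coating** (deposit layer); every feature is
computed per region. Segmentation (threshold on HSI brightness/saturation and
redness, largest connected component, morphological closing with a radius-2
disk) and the body/coating rule (coating ⇔ S < 0.18 and I > 120; coatings are
paler and brighter than the body) are deliberately simple, configurable
heuristics: clinical systems do this step with proprietary algorithms or
manual review, and nothing downstream depends on it — external masks can be
supplied everywhere, and all exact-value tests run with ground-truth masks.

## Chromatic indexes

Twelve indexes per region: mean channel intensities R, G, B; HSI hue
H ∈ [0°, 360°), brightness I = (R+G+B)/3, saturation
S = 1 − 3·min(R,G,B)/(R+G+B), with
H = arccos(½[(R−G)+(R−B)] / √[(R−G)² + (R−B)(G−B)]) reflected to 360° − H when
B > G and H = S = 0 for achromatic pixels; CIELAB L\*, a\*, b\* via the
standard sRGB → XYZ (D65) → Lab chain (delegated to scikit-image, pinned in
tests against an independent closed-form implementation); and full-range
BT.601 YCbCr (Y = 0.299R + 0.587G + 0.114B, chroma 128-centred, clipped to
[0, 255]).

Scaling conventions: L\* is reported on a 0–255 scale (×255/100) so lightness
shares the 8-bit range of the other indexes — reference report tables show L\*
values well above 100, impossible on the canonical scale; a\*/b\* are left
unshifted and sign-carrying (reference tables contain negative b\*). Both are
config options (`l_scale`, `ycbcr variant`), as is studio-swing YCbCr; the
full-range form was adopted because the source conventions are unverifiable.

A region is summarised **aggregate-then-convert**: the indexes are computed
from the region's mean RGB triple. Per-pixel-then-average is ill-defined for
hue (circular wrap) and is offered only as a sensitivity mode for H, I, S
(`his_mode="per-pixel"`); the two modes coincide on constant regions, which is
where the exact-value tests live.

## Gray-difference texture

For gray image f (BT.601 luma, rounded half-to-even to integers 0…m−1,
m = 256 by default) and offset (Δi, Δj), the difference
g(i,j) = f(i,j) − f(i+Δi, j+Δj) is accumulated over every pixel pair whose two
endpoints both lie in the region mask; hg is the normalized histogram of |g|.
Absolute differences are used (the standard convention; signed differences
would double the support and halve ASM). The four statistics:

* MEAN = (1/m) Σ i·hg(i) — scaled mean difference (the 1/m factor puts MEAN on
  the ~0.02–0.03 scale seen in practice);
* CON = Σ i²·hg(i) — contrast;
* ASM = Σ hg(i)² — angular second moment (energy), in (0, 1];
* ENT = −Σ hg(i)·log₂ hg(i) — entropy in bits (0·log 0 := 0; base
  configurable, default 2).

Default offset Δ = (1, 1); a pooled four-offset option
((0,1), (1,0), (1,1), (1,−1)) averages over directions by pooling pairs. A
deliberately unvectorized double-loop oracle (`texture_oracle`) recomputes all
four statistics for regions up to 64×64; the fast path must match it to a
relative 1e-12 (CON is O(10³), so agreement is asserted relatively — summation
order costs a few ulps).

## Statistics

All procedures are first-principles implementations; scipy supplies only the
χ², t and normal tail functions, and scipy/statsmodels serve as independent
cross-checks in the tests.

* **Pearson χ² (2×2)** — n(ad−bc)²/((a+b)(c+d)(a+c)(b+d)); Yates correction
  off by default (the reference contingency p-values match the uncorrected
  statistic analytically) and available by flag. Zero margins raise.
* **Univariate logistic (binary exposure)** — the saturated-model MLE:
  OR = ad/(bc), SE(log OR) = √(1/a+1/b+1/c+1/d), 95% Wald interval with
  z = 1.959964 (the full normal quantile; rounding z to 1.96 breaks agreement
  with the reference intervals at the printed precision). A zero cell raises
  a separation error by default; `haldane=True` applies the +0.5 correction.
* **Multivariate logistic** — Newton–Raphson/IRLS on the Bernoulli
  log-likelihood; convergence at max|score| < 1e-8 or 50 iterations; Wald SEs
  from the inverse observed information; diverging coefficients
  (|β| > 30 ⇒ separation) flag the fit non-converged rather than raising.
* **Mann–Whitney U** — midrank ties; exact two-sided p by full enumeration of
  rank assignments when n₁+n₂ ≤ 12 and no ties (p = 2·min tail, capped at 1),
  otherwise normal approximation with tie and continuity corrections.
* **Two-sample t** — pooled variance, df = n₁+n₂−2; both a summary-statistic
  form (for published mean ± SD inputs) and a raw-data form.
* **Spearman** — Pearson correlation of midranks; p via the t approximation
  with df = n−2; constant vectors raise ("zero rank variance").
* **ROC/AUC** — rank-based (midranks); for a binary marker this equals
  (sensitivity + specificity)/2. 95% CI by Hanley–McNeil; p two-sided against
  AUC = 0.5 using the same SE (reference software computes this null SE
  differently, so AUC values — not their p-values — are the comparable
  quantities).

No multiple-testing correction is applied anywhere, matching the single-screen
design this mirrors (α = 0.05 throughout); the correlation grids should be
read as descriptive. This is a deliberate limitation.

### Known non-reproducibilities

From printed 2×2 counts, the thick-coating univariate OR is 39.667 and
tooth-marked 3.4; published tables print 39.997 and 3.778 (and yellow 0.179 /
fat 0.367 fit no obvious coding). These cells, the three-level ordinal
p-values (the ordinal coding used is unrecoverable), multivariate ORs (joint
feature distribution unpublished) and all raw-data medians/p-values are
reported by the pipeline but never treated as exact targets.

## Synthetic data

**Images.** An axis-aligned ellipse (semi-axes 0.42·W, 0.46·H) on a dark
background (RGB 18, 14, 14); the coating is the contiguous anterior-shifted
elliptical level set covering exactly round(coating_fraction·|tongue|) tongue
pixels, so the fraction is recovered to one pixel of rounding. Texture is a
sinusoidal luminance modulation (default period 16 px, amplitude 12 gray
levels) plus i.i.d. Gaussian noise (default SD 4), clipped to [0, 255].
Default colors: body (172, 96, 88) — a desaturated red, S ≈ 0.26 — and coating
(196, 186, 172) — pale, S ≈ 0.07, I ≈ 185 — separable by the default split
rule with a wide margin. The geometry is *not* photorealistic: no specular
highlights, papillae, pose or illumination variation, so passing tests show
correctness of the measurement chain, not robustness to clinical capture
conditions.

**Cohorts.** Default group sizes 40 + 40. Categorical features are drawn
independently per feature from the observed per-group proportions of the
study this emulates (e.g. greasy coating 95% vs 15%); the joint distribution
across features is not published, so only marginals are matched — which is
also why multivariate odds ratios cannot be reproduced by construction.
Blood markers are log-normal (right-skewed, positive, matching the published
median-and-range summaries): μ = ln(median), and σ solves for the printed
min/max sitting at the 1/(2n) and 1−1/(2n) quantiles of an n = 40 sample.
Sampling inverts the CDF on the truncated [min, max] interval —
distributionally identical to resample-until-inside, with no point mass at
the bounds (truncation shifts the median by ≲1%). Ages are truncated normal
on the 18–70 inclusion window.

**Correlation induction.** A Spearman target ρ between a marker and an index
is induced with a Gaussian copula: the latent Pearson correlation is
2·sin(πρ/6), and the induced index is emitted as a standardized synthetic
column (`induced_indexes`). Induction is within-group — pooling groups with
different marker locations attenuates the pooled rank correlation, by design.

**Reference cohort.** `reference_cohort()` is a deterministic 40 + 40 cohort
whose categorical counts equal the observed study counts exactly (each
feature column rotated by a different offset to keep the joint structure
arbitrary), with markers on a deterministic quantile grid of the group
envelopes. It drives the golden-value pipeline tests and the acceptance
script's contingency block.

## Pipeline shape

The orchestration is exposed statsmodels-style: `CaseControlAnalysis`
(constructed `from_dataframe`/`from_records`/`from_csv`) with `fit()`
returning `CaseControlResults` carrying the report blocks
(demographics, univariate/multivariate logistic, ROC, per-region image
comparison, Spearman grids), `summary()`, `save()` and `plot_roc()`. Blocks
fail independently: an error in one is recorded in `results.errors` and the
rest are still produced. `run_pipeline` / the `tonguemetrics` CLI are thin
file-based wrappers; reruns with the same config write byte-identical CSVs.

## Problem sizes and numerical choices

The verification suite uses: 100 random 16×16 masked images for texture-oracle
equivalence (relative 1e-12); all no-tie Mann–Whitney cases with n₁+n₂ ≤ 10
against full enumeration; logistic recovery of β = (−1, 1.5) at n = 5000
(±0.1); copula Spearman −0.32 averaged over 500 case groups of n = 40
(±0.04); 10,000 null 2×2 simulations for type-I calibration (expected in
[0.03, 0.07] at α = 0.05; the univariate-logistic rate is computed with the
Haldane correction so zero-cell draws are scoreable); and 200 no-difference
cohorts for the feature-screen false-positive rate. These sizes were chosen
so each check has comfortable statistical resolution while the whole suite
runs in seconds.

Degenerate inputs are contracts, not silent fallbacks: empty masks, all-zero
margins, constant rank vectors, one-class outcomes and unnormalized
histograms all raise with messages naming the problem; a clinically absent
sign (zero in both groups) yields an untestable row with a missing p-value
rather than an error.
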