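# Methods

## Study design and synthetic data

The pipeline analyzes a repeated standardized-exercise design: `n_horses`
horses (default 12) each perform `n_re` daily exercise repetitions
(RE 1…6); around every repetition, blood is sampled and the thoracolumbar
region imaged twice — BS 0 at rest before and BS 1 immediately after
exercise — giving 12 × 6 × 2 = 144 thermograms and blood panels.

Because no raw study of this kind is publicly deposited, the
`synthetic` module generates full studies with the statistical structure
the analysis is designed to detect. Three ingredients matter:

**Latent exercise load.** For each (horse, RE) a latent cumulative load
`L = re + λ·ε`, `ε ~ N(0,1)`, `λ = 3.2·noise_sd` (RE units) is drawn
once and shared by every coupled quantity. The coupled biomarkers (WBC,
CPK, AST by default) at BS 1 follow `intercept + slope·L` plus a small
independent residual, and the thermal-heterogeneity driver (below) also
follows `L`. This shared-latent construction is what makes the
biomarker and feature trends *parallel up to independent noise* — the
exact structure the slope-parallelism test is meant to recover — while
keeping their marginal SDs realistic. The canonical per-RE slopes and
SDs are set to the magnitudes reported for equine repeated-exercise
panels (CPK rising from ~202 to ~294 U/L between the first and sixth
post-exercise samples with SD ≈ 70 U/L; WBC 8.0 → 10.2 ×10⁹/L; AST
238 → 309 U/L). Acute markers (RBC, HGB, HCT, LAC) jump between BS 0
and BS 1 within every RE but carry no across-RE trend; LAC is floored
at the 1.0 mmol/L assay detection limit. All values are positive.

**Temperature fields.** The baseline surface is `baseline_temp`
(default 26 °C, a resting dorsal surface in a thermoneutral indoor
hall) plus a per-horse offset and smooth spatial noise, all scaled by
`noise_sd` so that `noise_sd = 0` yields an exactly constant baseline.
At BS 1 each muscle ROI (withers, left/right back muscles — the spine
ROI receives nothing) gains one broad warm blob of amplitude
`re_warming` (default 2 °C — the order of post-exercise dorsal warming
reported for horses) with σ = 0.5 of the ROI extent, plus
`round(3 + 4·cumulative_slope·L)` small warm sub-blobs (σ ≈ 6% of the
ROI, amplitude `0.2·re_warming + 0.8·cumulative_slope` °C). The broad
blob produces the BS 0 → BS 1 warming; the sub-blob *count*, rising
with `L`, makes the ROI's spatial temperature variance — and hence any
variance-family texture feature of a channel monotone in temperature —
grow linearly across REs. The blob geometry was chosen so that the
trend carried by the sub-blobs dominates the image-to-image jitter of
the broad blob; a flatter, larger main blob contributes warming but
little variance noise. Fields are clamped to the camera range
10.0–50.0 °C.

**Reproducibility.** A single `SeedSequence` drives per-horse offsets,
the latent loads, and one child generator per imaging event; a study
bundle is bit-identical for a fixed seed.

What the generator does **not** emulate: anatomically realistic horse
silhouettes or muscle units, physiological thermoregulation dynamics,
ambient drift, camera vignetting, or motion artifacts. Passing tests
therefore demonstrate that the pipeline recovers the engineered
coupling under controlled conditions, not that real thermograms carry
the same signal.

## Palette rendering and inversion

Thermograms are rendered by clipping temperature to the camera range,
mapping linearly to a palette fraction, and interpolating a 7-point
rainbow (blue–cyan–green–yellow–orange–red–white) per RGB channel with
8-bit rounding; an 8-point variant with a magenta band at medium-high
temperatures is selectable. Inversion is nearest-point lookup against a
densely sampled palette curve (8192 samples), with runs of identical
quantized colors represented by their central temperature and exact
endpoint colors forced to the range endpoints; off-curve colors snap to
the nearest curve point rather than failing. The worst-case round-trip
error is half the widest constant-color run (≈ 0.04 °C on the default
palette over 10–50 °C); `palette.inversion_tolerance` computes the
bound. Warmth monotonicity holds in the sense that blue dominance
(B > R), once lost at the cold end, never returns; red-minus-blue is
strictly non-decreasing below the white-hot top band (the magenta
variant is inherently non-monotone in red-minus-blue since magenta has
R = B).

## Color models and normalization

An 8-bit RGB thermogram is decomposed into 12 components: R, G, B; the
BT.601 luma `Y = 0.299R + 0.587G + 0.114B` with U, V chrominance; Y
with I, Q (the YIQ rows have balanced positive/negative coefficient
sums); and hexcone H, S, B with B = max(R, G, B). Chrominance planes
are signed and mapped affinely so the achromatic value lands at
mid-gray (127.5); hue is linearized from [0°, 360°) onto the gray
range, i.e. treated as an ordinary channel rather than circularly —
moment features of H therefore depend on the hue origin, a documented
simplification. Each component is analyzed un-normalized and after one
ROI-based normalization (default min–max; μ±3σ and 1st–99th-percentile
bounds selectable), giving 24 channel variants per image.

Normalization maps onto 1-based gray levels [1, 2ⁿ]:
`I_out = clamp(round(2ⁿ·(I − MIN)/(MAX − MIN)) + 1, 1, 2ⁿ)` with values
clipped to [MIN, MAX] first and round-half-up rounding (the unclamped
formula reaches 2ⁿ+1 exactly at the upper bound; clamping preserves the
stated bit depth). A degenerate range (constant plane under min–max)
yields an all-1 plane flagged degenerate — this genuinely occurs for
saturated channels (e.g. green ≡ 255 in the green→yellow palette band)
and is handled, not hidden. The default bit depth is 8 for the
histogram, gradient, autoregressive, Gabor and HOG families; channels
are requantized by uniform binning to 6 bits for the run-length and
co-occurrence families so matrices stay dense on small ROIs
(configurable).

## The 88 texture features

Names and conventions follow the QMazda lineage. Per channel variant
and ROI:

* **HS (14)** — population moments of the ROI gray histogram (mean,
  variance, skewness μ₃/σ³, excess kurtosis μ₄/σ⁴ − 3, defined as 0 for
  constant ROIs); percentiles as the smallest gray level whose CDF
  reaches q; `HistArea` = ROI pixel count; `HistDomn01/10` = histogram
  mode position at bin widths 1 and 10 (bin lower edge, smallest level
  on ties); `HistMaxm01/10` = the corresponding maximal bin count / ROI
  area. The Domn/Maxm semantics are an interpretation of
  under-documented names; widths and normalization are config-exposed.
* **GM (6)** — central-difference gradient magnitude √(Gx²+Gy²) over
  the ROI interior (1-pixel erosion, cross element, image border
  excluded); the same four moments, plus the fraction of interior
  pixels with non-zero magnitude.
* **AM (5)** — least-squares fit of each pixel on its causal neighbors
  (left, top-left, top, top-right), eligible when all four lie in the
  ROI; rank-deficient designs take the minimum-norm solution (so a
  constant ROI gives θ = (¼,¼,¼,¼)); `sigma` is the RMS residual.
* **GT (24)** — complex Gabor kernels at wavelengths λ ∈
  {4,6,8,12,16,24} px, σ = λ/2 (the names encode both: Gab4H2…Gab24Z12),
  orientations H = 0°, V = 90°, N = 45°, Z = 135° (the orientation is
  the direction of the carrier wave vector), truncated at ±3σ and
  DC-corrected to zero mean; the feature is the mean response magnitude
  over ROI pixels whose kernel support lies fully inside the frame.
  Wavelengths with no supported pixel record NaN; if even λ = 4 (13 px
  support) fits nowhere the ROI is too small and the family errors.
* **HOG (8)** — unsigned gradient orientations in [0°, 180°) in eight
  22.5° bins, magnitude-weighted, normalized to sum 1 (all-zero for a
  zero-gradient ROI).
* **GRLM (7)** — maximal equal-gray runs along 0°, 45°, 90°, 135°
  (runs break at ROI boundaries); with N_r total runs and N_p ROI
  pixels: short/long-run emphases Σp/ℓ²/N_r and Σp·ℓ²/N_r, gray-level
  and run-length non-uniformities, `Fraction` = N_r/N_p, and the
  M-prefixed moments = base feature / N_r (dimensionless in run count);
  features are averaged over the four directions.
* **GLCM/GLCH (12 + 12)** — co-occurrence counts over ordered in-ROI
  pixel pairs at 4 directions × distances 1–9; the symmetric variant
  uses C + Cᵀ, the asymmetric (GLCH) uses C. Per matrix: `Area` (raw
  pair count, the only size-like reading of the name), angular second
  moment, contrast, correlation (defined 0 when a marginal SD is 0),
  sum of squares, inverse difference moment, and the sum/difference
  marginal statistics (SumAverg/SumEntrp/SumVarnc, Entropy,
  DifVarnc/DifEntrp) with 0·log 0 ≡ 0; `SumVarnc` centers on `SumAverg`
  (the modern convention; the historical formulation's use of the sum
  entropy there is treated as a typo). Entropies use the natural log by
  default (base 2 selectable). The 12-vector is the mean over all
  offsets with at least one valid pair; per-offset output is available
  behind a flag. Averaging over offsets is forced by the feature
  count: exactly 12 GLCM and 12 GLCH features fit in the 88-feature
  vector only if the 36 offsets pool.

Feature names in output tables are family-qualified
(`HS.HistVariance`, `GLCM.SumOfSqs`, …) under model-qualified channel
labels (`RGB.R` un-normalized, `RGB.r` normalized), reproducing the
field's `R.HS.Variance`-style annotations. A family that cannot be
computed records NaN for all its features — never a partial vector.

Every family is verified against an independent brute-force oracle
(naive pair/run enumeration, direct window sums, direct moment loops)
to 1e-9 relative tolerance on random low-bit-depth rasters. The matrix,
histogram, gradient, AR and HOG families are checked on 12×12 rasters;
Gabor magnitudes need a 13-pixel kernel support, so they are checked at
the smallest feasible sizes (18×18 for λ = 4, 80×80 for all
wavelengths).

## Conventional measures

`Tmax` (maximum) and `Taver` (arithmetic mean) per ROI, from the float
temperature raster when present, else from palette inversion of the
rendered image. Rows join the feature table under channel `IRT`. No
emissivity or ambient correction is modeled — the camera applies those
upstream.

## Statistics

**Routing.** Shapiro–Wilk at α = 0.05 routes each series to the
Gaussian or non-Gaussian branch; constant samples are non-Gaussian by
definition.

**BS comparisons.** Paired t-test (p = 1 for identical pairs) or
Wilcoxon matched pairs (zero differences dropped, mid-rank ties;
all-zero differences are an error on this route), two-sided.

**RE comparisons.** Repeated-measures one-way ANOVA with the
Geisser–Greenhouse ε (double-centered covariance estimator, clipped to
[1/(k−1), 1]) correcting both F degrees of freedom, Tukey post hoc on
the studentized range with the RM error term; or Friedman with Dunn's
Bonferroni-adjusted rank post hoc. Identical conditions short-circuit
to p = 1 (guarded with a relative tolerance against floating-point
residue).

**Slope parallelism.** For a biomarker series and a feature series over
x = RE (1…6) at BS 1, horses pooled as replicates: separate OLS lines
(full model) vs common-slope model — extra-sum-of-squares F with
(1, n−4) df for slope equality; if p > α, the pooled slope is the
common-slope estimate (algebraically the Sxx-weighted mean of the group
slopes — asserted to 1e-9 in tests) and intercept equality is tested
against the single-line model with (1, n−3) df; the non-zero-slope test
is the t-test on the pooled slope (or, when slopes differ, the weaker
of the per-group tests). `related = (p_slope_equal > α) and
(p_slope_nonzero < α)`, α = 0.05 for all three tests. Exact fits are
guarded by relative thresholds so identical series give F = 0, p = 1
rather than 0/0.

**Scale alignment.** A biomarker (U/L) and a texture feature (arbitrary
units) are not commensurate, so by default each feature series is
affinely rescaled to the biomarker's sample mean and SD before slope
comparison; after this matching, slope equality is equivalent to equal
correlation with the RE axis, which is exactly what the shared-latent
generator makes true for coupled pairs. A `raw` mode compares
unstandardized slopes for users who want the direct comparison. No
multiple-testing correction is applied across the 2112 pairs (per-pair
p < 0.05 semantics); a Benjamini–Hochberg option on the non-zero-slope
p-values is available and off by default.

## Numerical and design choices

* Rounding in the normalization formula is round-half-up; images are
  row-major, origin top-left, 0-based pixel indexing.
* Gray levels are 1-based everywhere ([1, 2ⁿ]), matching the
  normalization formula's range; co-occurrence indices use the gray
  levels themselves, so sum-marginal statistics live on [2, 2L].
* The ROI layout is four deterministic rectangles scaled to the frame
  (withers; thoracic spine; left/right back muscles), disjoint and
  non-empty for any frame ≥ 8×8.
* Simulation experiments run at 60×80 px — every ROI keeps hundreds of
  pixels and a full study renders in under a second — and the
  biomarker-only calibration uses 16×16 frames since it never reads
  the images.
* The parameter-recovery experiment uses the low-noise coupled
  scenario (`noise_sd = 0.2`) the recovery property is stated for; the
  type-I-error experiment draws both series from one linear model, for
  which the slope-equality F-test is exact.

## Known limitations

Two behaviors of the selection procedure on synthetic data deserve
emphasis. First, the generator drives every color channel through one
temperature field, so all channels monotone in temperature over a
warmed ROI co-vary and the synthetic selection matrix is far denser
than a real study's (where sensor physics, palette bands and biology
decouple the channels). Second, the parallelism criterion treats
*failure to reject* slope equality as evidence of relatedness; when a
feature series is noisy the equality test loses power and an uncoupled
feature can be flagged whenever the pooled slope inherits significance
from the biomarker's trend. Under the full null (no biomarker trend)
the false-positive rate stays near the nominal level because the pooled
slope is itself null; the parameter-recovery experiment accordingly
uses the low-noise scenario, where the equality test has the power to
reject the uncoupled control.

* Real pseudo-color thermograms from FLIR software include overlays,
  emissivity/ambient corrections and proprietary radiometric encoding;
  this pipeline assumes clean palette renderings or float rasters.
* Hue is not treated circularly; H-channel moment features depend on
  the hue origin.
* Horses are pooled as replicates in the regressions; no mixed-effects
  modeling of horse as a random effect.
* Exact QMazda definitions of `HistDomn/HistMaxm` and the M-prefixed
  run-length moments are not published; the interpretations above are
  config-exposed.
* The printed regression slopes of the original study (e.g. 11.639 for
  CPK vs red-channel variance) depend on its unpublished raw data and
  are not reproduction targets; the pipeline's checkable quantities are
  the enumeration counts, oracle equivalences, test calibration and
  synthetic-recovery rates that `scripts/acceptance.py` recomputes.
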