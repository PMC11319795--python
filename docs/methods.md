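# Methods

This note documents the models, conventions and numerical choices behind
`echosway`, and what the synthetic-data tests do and do not establish about
real data.

## Ultrasound quantification

**Echo-intensity.** EI is the arithmetic mean of 8-bit pixel values whose
centers lie inside (or on the boundary of) the muscle cross-section polygon
— even-odd membership, 0-based (row, col) coordinates with rows growing
downward. Boundary inclusion makes membership deterministic and independent
of vertex orientation. A polygon enclosing no pixel centers is an error,
never a silent zero.

**Thicknesses.** SAT and MT are vertical distances between tissue-interface
depths on the image's central scan line (skin → superficial aponeurosis,
superficial → deep boundary), multiplied by the pixel spacing (default
0.01 cm/px — synthetic images carry this metadata; real images must supply
their own calibration). A zero thickness (coincident interfaces) is allowed.

**GLCM.** Co-occurrence counts are taken over ordered pixel pairs at a
one-pixel offset (configurable) in the four axis directions; each
directional matrix is normalized to sum 1 and the reported features come
from the element-wise mean over directions. Because opposite directions are
transposes, the four-direction average equals the symmetrized matrix. Gray
levels default to the full 256 (no requantization of 8-bit input). Entropy
uses the natural logarithm by default (the base is configurable and
recorded); with 256 levels, typical muscle ROIs give natural-log entropies
in the 6–8 range. Feature identities on degenerate input: a constant ROI
yields ASM = IDM = 1, Contrast = Entropy = 0, and an *undefined* correlation
(returned as NaN — the marginal SDs are zero and no silent division
happens).

**Correlation variants.** The default `standard` correlation is the
covariance of the averaged matrix normalized by the marginal SDs (range
[−1, 1]). A `plugin_compatible` variant divides the covariance by the
*variance* product instead; with gray-level SDs of a few tens this yields
values of order 10⁻³, matching the magnitudes reported by a widely used
ImageJ texture plugin. The variant exists for comparability with studies
that used that plugin; its absolute scale is not meaningful and we make no
promise of matching any specific plugin build.

**Replicates.** Per-image records are averaged element-wise (typically 3
images per site); an undefined correlation in one replicate propagates via
`nanmean` rather than poisoning the average.

## Posturography

COP is reconstructed with the plate surface as moment origin:
COP_ML = −My/Fz, COP_AP = Mx/Fz, in mm. Samples with |Fz| ≤ 50 N are
rejected (not quiet stance). The COP series — not the raw moments — is
band-pass filtered 0.1–10 Hz with a 4th-order Butterworth applied
forward–backward (zero phase, reflective padding); filtering the assembled
COP matches the processing description this pipeline follows. Stability is
the per-axis sample SD (ddof = 1) of the filtered COP at native sampling
rate, optionally divided by body height (mm of sway per m). Sway summaries
are computed per recording; repeated blocks of the same subject × condition
are averaged (order-invariant) before group statistics. The axis/sign
convention is documented rather than critical: an SD is invariant to sign
and offset, and the band-pass removes any DC ambiguity.

## Group statistics

- **t-tests** are pooled-variance Student tests (df = n₁+n₂−2), available
  both from raw samples and from printed mean ± SD summaries; the two paths
  agree exactly by construction. Cohen's d uses the pooled SD and is
  reported as a magnitude.
- **Fisher's exact test** is the standard two-sided sum of hypergeometric
  probabilities no larger than the observed table's.
- **ICC** is the two-way random-effects, absolute-agreement, single-measure
  form (ICC(2,1)) with the F-based 95% CI, computed via pingouin and
  cross-checked in tests against the mean-squares closed form. Absolute
  agreement is the conservative reading for test–retest of single images;
  it is shift-invariant but not scale-invariant, and the form is recorded in
  the result.
- **ANOVA** is a two-way fixed-effects condition × group model with
  interaction on per-subject condition means; η² is classical
  (SS_effect/SS_total), and post-hoc condition comparisons are Student
  t-tests with Bonferroni-multiplied p. Degrees of freedom follow the actual
  table. Constant input returns F = 0, p = 1 for every effect rather than
  0/0 noise.

## ROC classification

Empirical (non-parametric) curves over all distinct thresholds; the
trapezoidal AUC equals the tie-corrected rank-sum estimate on every input
(both are implemented and asserted equal). Score orientation per ultrasound
parameter is fixed *a priori* from the expected direction of the ageing
effect (higher EI/Entropy/Contrast → older; higher MT/SAT/ASM/IDM/
Correlation → younger), so no data-driven flipping inflates AUCs; SAT's
orientation (lower SAT predicting older) follows the direction of the
published group difference at the thigh. Paired AUC comparisons use the
DeLong placement-value covariance with a two-sided normal z-test — the
standard paired empirical-ROC comparison, which accounts for the
correlation between two measures on the same subjects. Identical or
co-monotone score vectors give z = 0, p = 1.

## Regularized CCA

Preprocessing per column, in order: z-score → clamp |z| > 2.5 to ±2.5
(winsorization to the stated bounds — the self-consistent reading of
"replace outliers with the minimum/maximum value") → residualize on age by
least squares → re-standardize. Age correction is applied within the
analyzed group.

The first canonical pair solves
(Sxx+λxI)⁻¹ Sxy (Syy+λyI)⁻¹ Syx via a symmetric eigenproblem
(A^{-1/2} Sxy B⁻¹ Syx A^{-1/2}); weights are unit-norm, r = corr(Xwx, Ywy)
is reported in [0, 1] by flipping wy, and the wx sign is anchored so the MT
weight is positive (largest-magnitude weight otherwise). Only the first
pair is extracted.

**λ selection.** The grid is 13 points log-spaced 10⁻³–10³ on the
standardized scale, shared by both blocks. Each (λx, λy) pair is scored by
leave-one-out cross-validation: fit on n−1 subjects (centering within the
fold), project the held-out subject, and take the Pearson correlation of
the n held-out score pairs. Per-fold weight pairs are sign-aligned to the
full-data solution at the same penalties before scoring, since the global
sign of a canonical pair is arbitrary and unaligned folds add pure noise to
the score. The default selection applies the one-standard-error rule: among
pairs whose score is within one SE (≈ (1−r²)/√(n−3)) of the best, the most
regularized pair wins. At the study's sample sizes the held-out correlation
rarely separates penalties beyond its own noise, and the literal argmax
degenerates to a coin flip that lands on under-regularized fits a large
fraction of the time; the one-SE rule is the standard cross-validation
response to exactly this situation. `tie_rule="argmax"` restores the
literal maximizer.

**Inference.** Rows of the ultrasound block are permuted (sway untouched)
and r is recomputed with the *fixed* selected penalties;
perm_p = (1 + #{r_perm ≥ r_obs})/(n_perm + 1), deterministic given the
seed. Re-selecting λ inside every permutation is available behind a flag
but is computationally disproportionate and changes the null only
marginally. Calibration measured on null cohorts (n = 34, 200 permutations,
500 runs): rejection rate 0.048 at α = 0.05. On cohorts with a planted
coupling of 0.5 (n = 32, 200 runs): median |r̂ − 0.5| = 0.145,
power 0.63. In-sample canonical correlations at these dimensions are
upward-biased even at heavy regularization (directions adapt to Sxy); the
reported r̂ should be read with that bias in mind.

**Pooling.** pooled_usᵢ = meanⱼ sign(wxⱼ)·Xᵢⱼ and pooled_swayᵢ = the mean
standardized sway across the four conditions; their Pearson r (with
two-sided p) is the interpretable follow-up, labelled with the conventional
strength bins (0.20/0.40/0.60/0.80 boundaries).

## Synthetic data

**Cohorts.** A Gaussian copula over latent factors: eight ultrasound
variables and four condition sway SDs are jointly multivariate normal on a
latent scale and mapped to their marginals. Marginal means/SDs default to
the published young/old group summaries (thigh site); strongly skewed
features (those whose mean − 2.5 SD is negative, e.g. ASM) use
moment-matched lognormals, and latent correlations involving lognormal
variables are divided by the attenuation factor σ/√(e^σ²−1) so
post-transform Pearson correlations land on target (exact for
lognormal-normal pairs, first-order for lognormal-lognormal pairs). The
within-group correlation among ultrasound variables defaults to identity —
an explicit *assumption*, not an estimate: no within-group correlations are
published. Cross-covariances are rank-1 along the muscle-quality signs and
scaled so that the correlation between the sign-corrected mean of the
standardized ultrasound variables and the mean standardized sway equals
`coupling_rho` (default 0.53 young, 0 old, emulating the reported
group-specific association). The quality factor loads only on the five
variables the association analysis uses (MT, EI, ASM, IDM, Entropy) — with
identity within-block correlation this makes the population first canonical
correlation equal `coupling_rho`, so parameter-recovery tests are
well-posed; SAT, Contrast and Correlation are simulated but uncoupled,
mirroring their weak discriminative role. Demographics: ages uniform over
the recruitment ranges (19–31, 65–85 — only ranges and means are published;
uniform avoids out-of-range draws), fixed female counts (15/32, 18/34),
heights and weights normal at the published group values. Per-condition
sway means are package defaults chosen to order EOhard < EChard < EOfoam <
ECfoam in both groups with the old/young gap largest (~57%) on foam with
eyes closed; SDs default to 25% of the mean.

**Images.** Layered: dark gel, bright skin band, darker subcutaneous fat,
bright superficial aponeurosis, muscle texture, bright deep boundary. The
muscle field is mean + a zero-mean texture (fine speckle of SD 12 gray
levels at the phenotype's correlation length, coarse clutter of SD
`heterogeneity_scale` at a 6-px correlation length, plus a fine clutter
term) passed through a tanh soft limiter scaled to keep pixels strictly
inside [0, 255]; hard clipping would pile mass on gray level 0 at strong
heterogeneity and spuriously *raise* textural uniformity. The muscle-region
mean is corrected to within ±2 gray levels of the phenotype target. Young
and old default phenotypes (mean 32 vs 56, clutter 6 vs 20, speckle
correlation 2.0 vs 1.2 px) reproduce the published direction of all five
texture effects. Note a hard feasibility limit: around mean 32 an 8-bit
image cannot carry symmetric SD-40 texture without floor effects, so
extreme heterogeneity at low mean confounds ASM regardless of construction.
The generator returns the ground-truth landmarks and ROIs used to draw the
image; it does not simulate beam physics, attenuation, or focal effects —
passing texture tests here shows the measurement chain is correct, not that
the generator matches real speckle statistics.

**Force plates.** The latent COP per axis is Gaussian noise spectrally
confined (FFT brick wall) to an inner sub-band [2.5·low, 0.6·high] of the
analysis band and rescaled to the target SD, then converted to moments by
inverting the COP equations around a constant vertical load. Confining the
power inside the analysis band means the pipeline's own Butterworth passes
the signal with gain ≈ 1, so the planted SD is recovered end-to-end to
within 0.1% (noise shaped by the same filter the analysis reapplies loses
~5% SD on the second pass); real quiet-stance COP power likewise
concentrates well below 10 Hz.

## Problem sizes

Default test and acceptance runs use: 100,000 subjects per group for the
binormal AUC checks; 200 random ≤ 8×8 images for the texture oracle; 10–20
seeds of 300-s, 100-Hz recordings for sway recovery; 500 null and 200
planted cohorts with 200 permutations each (coarse 3-point λ sub-grid) for
CCA calibration; reduced image geometry (200×160) for per-seed texture
ordering. These sizes put Monte-Carlo noise well inside the asserted
tolerances while keeping the default suite fast.

## Known limitations

- The plugin-compatible GLCM correlation reproduces a magnitude scale, not
  a pinned formula; cross-study comparison of that variant is qualitative.
- In-sample regularized canonical correlations at n ≈ 30 with p = 5, q = 4
  are upward-biased; the permutation p-value, not r̂ itself, carries the
  inference.
- The cohort generator's identity within-block correlation understates the
  collinearity of real texture features; planted-coupling recovery under
  strong collinearity is exercised only via the configurable `us_corr`.
- Block-averaged ANOVA assumes both blocks present for every subject;
  missing trials change the error df from the balanced value.
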