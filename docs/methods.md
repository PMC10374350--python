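# Methods

This note records what each stage of `polypcadx` computes, the assumptions
behind it, the defaults and why they were chosen, and what the synthetic
experiments do and do not demonstrate.

## Synthetic NBI-like imaging

The generator emulates the *structure* of narrow-band-imaging stills of
diminutive colorectal polyps, not their photorealistic appearance. An image
(default 512×512, 8-bit RGB) is a mucosa-like background — teal base color,
low-frequency mottle (σ = 40 px), fine grain (σ = 1.5 px), mild vignette —
plus, unless `polyp_class="none"`, one soft-edged ellipse (semi-major axis =
`polyp_radius`, axis ratio 0.7–1.0, random orientation) carrying a
class-specific texture:

| class | pattern | default parameters |
|---|---|---|
| adenoma | warped oriented stripes (tubular pit pattern) | wavelength 9 px, amplitude 26, orientation warp 3 |
| SSL | dense dark round pits (open-pit pattern) | 3·10⁻³ pits/px², σ 2.6 px, amplitude 45 |
| hyperplastic | sparse faint dots on a pale smooth surface | grid spacing 15 px, σ 1.4 px, amplitude 30 |

plus a class-specific mean color shift (adenomas browner, serrated lesions
paler). The three textures are parametrically distinct by construction;
`TextureParams.contrast` scales all amplitudes and is the difficulty dial.
All intensity computations package-wide use Rec. 601 luminance, and
identical spec + seed yields bit-identical pixels.

Degradations reproduce the failure modes the pipeline must reject: whole-
image Gaussian blur; a saturated specular disk sized to cover a requested
fraction of the lesion box; an absent lesion. The highlight is drawn before
the blur (the highlight is part of the scene, so defocus smears it too;
its core remains saturated).

A synthetic *study* draws per-colonoscopy polyp counts from a negative
binomial matched to mean 0.74 and SD 1.23 (overdispersed, as the printed SD
exceeds the mean; size parameter μ²/(σ²−μ) ≈ 0.71), histology from the
73/10/17 mix, a rectosigmoid fraction of 0.29, sizes 1–5 mm skewed small,
and three capture recipes per polyp with independent degradations (8 % blur
at σ ∈ [2.5, 4.5], 5 % overexposure at fraction ∈ [0.3, 0.7], 2 % absent
lesion — chosen so that most first captures are diagnostic, as observed
clinically). Images are rasterized lazily so distributional checks at
10⁴ patients cost nothing.

What passing tests on this generator show: that the pipeline's *mechanics* —
localization geometry, gating logic, BoVW separability, protocol accounting,
statistics — are correct under controlled, separable conditions. What they
do not show: clinical performance. Real NBI data have inter-polyp texture
overlap, illumination and pose variation, and label noise that the generator
deliberately omits; the clinical accuracies of a deployed system are
therefore reproduced here only from its published confusion counts, never
from synthetic pixels.

## Localization

The production-grade neural detector is replaced by a deterministic
classical detector honoring the same contract (one box + confidence):

1. texture energy = Gaussian-pooled (σ = 10 px) magnitude of the luminance
   high-pass (σ = 3 px), and chroma contrast = pooled |R−G| deviation from
   its median;
2. both maps are robust-z-scored (median/MAD) with *floors* on the scale
   (0.2 for energy, 1.0 for chroma, in 8-bit units) so a near-constant map —
   whose MAD is one quantization step — cannot produce unbounded z-scores;
3. saliency z = z_energy + 0.6·z_chroma is thresholded at z > 2.5; the
   largest connected component is the candidate;
4. Gaussian pooling dilates the true extent, so the component is eroded by a
   disk of radius 0.6·σ_pool·√(2 ln(z₀.₈/2.5)) — the distance at which a
   pooled plateau of interior level z₀.₈ decays to the threshold — before
   the tight box is taken (on the default fixtures this yields median
   IoU ≈ 0.85 against generator ground truth);
5. confidence = logistic((contrast·fill·size − 3.0)/0.7), where contrast is
   the component's mean z, fill its areal fraction of the box, and size a
   saturating area term. Components under 400 px² report an empty box with
   the confidence of the rejected candidate.

The acceptance threshold defaults to 0.50. The published system reports only
that a localization confidence of 8.5 % was rejected; the actual operating
point is not public, so 0.50 is this package's own choice — any plug-in
detector and threshold can be configured. On the default synthetic
distribution the calibration places clean polyps near confidence 1.0 and
polyp-free frames below 0.1, so the gate is far from both populations.

## Quality gate

Sharpness is the variance of the 3×3 Laplacian of the in-box luminance:
zero for constant patches, invariant to global intensity offsets, strictly
decreasing under Gaussian blur. The pass threshold (3.8) is the geometric
midpoint between the 5th percentile of undegraded and the 95th percentile of
σ ≥ 3-blurred fixtures (`scripts/calibrate_quality.py`, fixed seed); at that
value both populations separate completely. Overexposure is the fraction of
in-box pixels with luminance ≥ 250/255, bounded at 0.2 by default. The
published thresholds are not public; these are calibrated, documented
defaults, and every violated criterion is listed in the report.

## Bag-of-Visual-Words characterization

Descriptors are upright, fixed-scale gridSIFT: 16-px patches every 8 px
wherever a whole patch fits the box; per patch, gradient magnitudes are
binned into 8 orientations over a 4×4 cell grid (128-d), L2-normalized,
clipped at 0.2 and renormalized (the standard SIFT illumination
normalization; constant patches give the zero vector). The vocabulary is
seeded k-means (mini-batch above 20 000 pooled descriptors, pool subsampled
to 10⁵), default k = 256 — a standard BoVW scale that trains in seconds on a
single CPU. Encoding assigns each descriptor to its nearest center (ties to
the lowest index) and L1-normalizes the histogram.

The classifier is an L2-penalized multinomial logistic model (C = 10,
LBFGS): it directly produces the calibrated class posteriors that the
0.33/0.50 tier thresholds require. The *prediction score* is the maximum
posterior; ties in the top class break by the fixed order (adenoma, SSL,
hyperplastic), putting neoplastic classes first. Since a 3-class posterior
has maximum ≥ 1/3 ≥ 0.33, the tier "none" is unreachable — diagnosis
failures can only arise at localization or quality gating; the test suite
asserts this as a property.

Cross-validation splits at the polyp level (all captures of a polyp share a
fold), stratified per class so every class appears in every training fold;
this is required because lesion-level leakage across folds would flatter
any image-level classifier.

## Decision protocol

A deterministic finite-state machine per polyp: each capture is green
(tier high — finalize immediately with that diagnosis), orange (tier low —
may continue) or red (localization/quality failure — may continue), with a
hard stop after three captures. On stop without a green, the orange capture
with the highest prediction score wins (earliest on ties — a reproducibility
convention, as score ties are otherwise unordered); with no scored capture
the session is a failure. The stop after three images is modeled as
mandatory, which bounds the machine. The test suite checks the machine
exhaustively against a brute-force transition table over all outcome
sequences of length ≤ 3. Success rate = non-failures / sessions, with an
exact Clopper–Pearson CI, reported with the 1/2/3-images-needed
distribution.

## Diagnostic-accuracy statistics

Lesions whose histology is carcinoma, traditional serrated adenoma, normal
mucosa, inflammatory, or missing are excluded up front and tallied. The
binary analysis is neoplastic (adenoma + SSL) vs non-neoplastic
(hyperplastic); cross-calls between adenoma and SSL count as correct.
Records without a CADx prediction (protocol failures) are excluded from the
accuracy tables and surface only in the success rate — the two denominators
are intentionally different. An endoscopist "carcinoma" call counts as
neoplastic and "other" as non-neoplastic in the binary view; in the 3-class
view they map to adenoma and hyperplastic respectively.

Proportion CIs default to exact Clopper–Pearson, with Wald and Wilson as
options. Checking the published intervals of this design showed the Wald
interval reproduces the sensitivity/specificity/PPV/NPV intervals
digit-for-digit, while the accuracy interval matches none of the three
standard methods exactly (Clopper–Pearson is closest); the package keeps
the exact method as its default because it is conservative and never
degenerates at the boundaries. Undefined metrics (zero denominators) are
reported absent, never as 0.

McNemar's test uses χ² = (max(|b−c|−1, 0))²/(b+c) with 1 df (continuity
corrected); an exact two-sided binomial option is provided and recommended
below 25 discordant pairs, and `method="auto"` switches automatically. With
no discordant pairs p = 1. Exhaustive comparison with the exact binomial
over all splits with b+c ≤ 20 shows agreement within 0.012 for all totals
≥ 3; at total 2 the chi-square approximation is off by 0.0205 — an intrinsic
boundary property of the approximation at the smallest discordant total, not
an implementation artifact, and precisely why the exact option exists.

PPV/NPV comparisons use a patient-clustered bootstrap (patients resampled
with replacement, two-sided p from the doubled tail of the bootstrap
difference distribution, seeded), plus Fisher's exact test; a weighted
generalized score statistic for paired predictive values is not implemented
— its exact construction in the motivating design is not public, and the
clustered bootstrap is the primary inferential path here.

Surveillance-interval agreement evaluates a *configurable* ordered rule
table over per-patient findings (counts of neoplastic lesions by default) —
guideline rule sets differ by country and era, so the shipped default is a
simple illustrative table, not a clinical recommendation. Competence checks
(PIVI/SODA-style) are declarative thresholds over computed metrics.

Sample size for the paired design uses the Connor normal-approximation
formula (see README); with ψ = 0.20, δ = 0.10, α = 0.05, power 0.90 it gives
206 pairs, and round((206/0.74)·1.05) = 292 patients. The (1+dropout)
inflation (rather than division by 1−dropout) is this package's documented
convention; the alternative gives 293. The power simulation draws the
discordant split ((ψ+δ)/2, (ψ−δ)/2) per pair and applies the *uncorrected*
asymptotic test by default — the test underlying the formula — recovering
0.91 empirical power at n = 206 (the continuity-corrected variant gives
≈ 0.88, the usual conservatism of the correction).

## Problem sizes and numerical conventions

The end-to-end synthetic experiment trains on 300 polyps at the 73/10/17
mix and evaluates the three-image protocol on 200 held-out polyps — large
enough for stable estimates of the ≥ 0.90 accuracy, ≥ 0.95 success-rate and
≥ 0.5 median-IoU properties while keeping a full run on one CPU in a couple
of minutes. Boxes are 0-based, half-open, COCO-ordered (x, y, w, h);
class order is fixed as (adenoma, SSL, hyperplastic) everywhere; all
randomness flows through explicit integer seeds (NumPy `default_rng`), and
every CLI artifact embeds the config hash and seed.

## Known limitations

* The synthetic textures are fully separable by design; accuracy numbers on
  them say nothing about clinical accuracy (see above).
* The classical detector assumes one lesion per frame and relies on
  texture/chroma contrast; multi-polyp frames and video are out of scope.
* The logistic posteriors are calibrated only in the regularized-likelihood
  sense; no post-hoc calibration is applied before the tier thresholds.
* The surveillance rule table and competence thresholds are configuration,
  not clinical guidance.
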