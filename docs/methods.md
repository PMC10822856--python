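# Methods

This note documents the models implemented in `ksface`, the parameters
that matter, the numerical choices, and the limits of what the synthetic
test bed can establish.

## Landmark templates and reliability

Three fixed templates are used: 105 landmarks on frontal views, 73 on
lateral (profile) views and 41 on external-ear views.  Coordinates are
0-based pixels, origin top-left, y downward.  Both profile sides occur
in practice; all lateral configurations are reflected into a
right-profile convention (`x ↦ width − 1 − x`) before any morphometrics
so that left and right profiles share one shape space.  The templates'
*coordinates* shipped with the package are procedural face-like layouts
used only by the synthetic generator; the pipeline depends on point
counts and on which indices form each zone polygon, not on the layout.

Inter-rater agreement of manual landmark placement is summarized with
ICC(2,1): two-way random effects, absolute agreement, single
measurement.  The two raters are interchangeable annotators, which makes
the two-way random/absolute form the appropriate one; the unit of
analysis is every (photo, landmark, axis) coordinate pooled, giving a
single scalar per template.  Agreement above 0.9 is labelled
"excellent", following the usual reliability guideline; the label
thresholds (0.5/0.75/0.9) are reported alongside the coefficient.

## Geometric morphometrics

Photographs are uncalibrated, so centroid size is not a usable signal:
only shape is analysed.  Generalized Procrustes analysis centres each
configuration, scales it to unit centroid size (root summed squared
distance to the centroid) and rotates it onto the evolving mean by the
SVD solution of the orthogonal Procrustes problem with a determinant
correction — reflections are excluded, since a face must never be
mirror-matched.  The mean is recomputed, re-centred and renormalized to
unit size each iteration; iteration stops when the mean moves by less
than 1e-10 (Frobenius) or after 100 iterations.  GPA typically converges
in well under ten iterations; the residual Procrustes sum of squares is
non-increasing across iterations.

Held-out photos are aligned to the *fitted* mean by ordinary Procrustes
superimposition rather than re-running GPA, so validation data cannot
influence the shape space.

PCA is applied to the aligned coordinates directly, without projection
to Kendall tangent space: at the small Procrustes distances of within-
population face data the difference is negligible, and the direct form
keeps scores linear in the aligned coordinates.  The smallest number of
components whose cumulative explained variance reaches 0.99 is retained;
the last percent is treated as noise.  The three view templates are
incommensurable point sets and are superimposed in three separate GPAs
(frontal, lateral, ear); their PC scores are concatenated per photo
session.  Pooling the views into a single PCA was the open alternative;
separate-then-concatenate keeps each view's variance structure intact
and lets a session with a missing view carry missing geometric scores
for that view only.

## Zone textures

Fourteen zones are defined as polygons over template landmark indices:
11 frontal (right/left eyes, right/left eyebrows, glabella, forehead,
nasal tip, philtrum, right/left cheeks, chin) and 3 lateral
(pre-auricular region, eye, zygoma relief).  Each zone is cropped at its
polygon's bounding box, pixels outside the polygon are replaced by the
polygon-interior mean (zero-filling would manufacture high-contrast
boundary pairs), and the crop is resampled to a standard 64×64 patch so
that co-occurrence offsets are comparable across photos of different
resolutions.

Patches are equalized with CLAHE: 8×8 tile grid (8-pixel tiles on the
standard patch), clip limit 2.0 in multiples of the uniform histogram
bin height (clamped to at least one count per bin), 256 bins, bilinear
interpolation between tile mappings, output in [0, 255].  One deliberate
departure from the textbook algorithm: the clipped excess is
redistributed *proportionally* (the clipped histogram is renormalized)
rather than uniformly across bins.  Uniform redistribution adds a
value-proportional ramp to the mapping; on sparse tiles this breaks the
invariance to monotone illumination changes that motivates equalizing in
the first place.  With proportional redistribution the mapping is a pure
function of gray-level ranks, and a global gain/offset (e.g. ×1.3, +20)
leaves the downstream feature vector essentially unchanged; with a
single tile and a clip limit at or above the patch area the procedure
reduces exactly to global histogram equalization.

Equalized patches are quantized to 32 gray levels over [0, 255] and
summarized by symmetric, normalized gray-level co-occurrence matrices at
distance 1 pixel and angles 0°, 45°, 90°, 135° — Haralick's classical
setting.  Haralick's 14 statistics (energy, contrast, correlation,
variance, homogeneity, sum average, sum variance, sum entropy, entropy,
difference variance, difference entropy, the two information measures of
correlation, and the maximal correlation coefficient) are computed per
angle with base-2 logarithms and the convention 0·log 0 = 0; the mean
and range (max − min) over the four angles give 28 features per zone.
Correlation and the maximal correlation coefficient fall back to 0 when
a marginal standard deviation vanishes or the Q-matrix eigenproblem is
degenerate, so constant patches produce finite features.  The full
texture vector is 14 × 28 = 392 values (a printed source gives the
product as 394; 392 is the arithmetic).  A missing view contributes
missing-value markers for its zones, never zeros.

## Metadata stratification

Faces change with age, differ by sex, and vary across ancestry groups;
repeated photo sessions of one patient are correlated.  Each feature
column is therefore modelled as

    f_ij = α + age_ij·β₁ + male_i·β₂ + ethnicity_i·β₃ + age_ij·b_i + ε_ij

with treatment coding (references: female, Caucasian — the majority
levels), no interactions, a per-individual random slope on age
b_i ~ N(0, σ_b²) and independent residuals.  There is deliberately no
random intercept: the model contains exactly one random term, the
individual age slope (the alternative with an added random intercept is
noted as the ambiguity in the source description; the displayed equation
form is implemented).

Estimation is REML.  Because the random part is a scalar slope per
individual, each individual's marginal covariance is
σ²(I + λ a aᵀ) with a the individual's age vector and λ = σ_b²/σ², a
rank-one update with closed-form inverse and determinant.  The REML
criterion profiles to one dimension in log λ, optimized by a coarse grid
(33 points over e^±16) plus 40 golden-section refinement steps —
vectorized across feature columns, so hundreds of per-feature fits cost
fractions of a second.  This is an exact maximizer of the restricted
likelihood, cross-checked in the tests against statsmodels' general
MixedLM to ~0.1% on fixed effects and variance components.  Singular
fits (zero residual variance, collinear design) fall back to ordinary
least squares with σ_b² = 0 and are flagged unconverged.

Residuals subtract the fixed part plus the BLUP-predicted random-slope
contribution, `b̂_i = λ aᵀr / (1 + λ aᵀa)`, for individuals present at
fit time; individuals unseen at fit time get the population-level
prediction (zero random slope).  Models are fitted on the training set
only and applied to validation photos.  This matters for the science as
well as for leakage: a patient-constant diagnostic shift can be partly
absorbed by a fitted patient's BLUP slope (a slope mimics an offset when
the patient's ages cluster away from zero), but survives intact in
held-out patients — which is where classification performance is
measured.

## Classification

Three binary designs: №1 KS vs control, №2 KS1 vs KS2, №3 PTV vs PAV
within KS1 (variant classes derived from the patients' HGVS strings).
Validation splits are drawn uniformly at the patient level with all of a
patient's photos following the patient: design 1 holds out
round(0.1 · n_KS) KS patients and the same number of controls; design 2
holds out the same total from the genotyped patients, balanced between
KS1 and KS2; design 3 has no held-out split and is evaluated by grouped
cross-validation only.

The classifier is XGBoost with a tree booster and logistic loss;
learning rate 0.3, γ = 0, maximum depth 6.  The number of boosting
rounds is the only tuned quantity: five-fold cross-validation grouped by
patient (repeated photos never straddle a fold) scans up to 500 rounds
and the round count minimizing the mean validation misclassification
rate is refitted on all training photos.  Missing feature values are
handled natively by the trees.  Training is photo-level; reporting is
patient-level, aggregating a patient's photo probabilities by their mean
and thresholding at 0.5 — the aggregation rule and threshold are package
choices.

## Evaluation

Confusion matrices are reported with rows as predictions.  Accuracy
carries an exact 95% Clopper–Pearson interval (beta-quantile form,
cross-checked against brute-force binomial tail inversion) and a
one-sided exact binomial p-value against the no-information rate (the
largest reference-class prevalence).  F1 is reported for the
reference-first class of each design (control in №1, KS1 in №2).  AUC is
the empirical Mann–Whitney statistic with half credit for ties; its 95%
CI uses DeLong's structural-components variance.  Feature importance is
the booster's total gain, normalized; the shortest descending-gain
prefix whose cumulative share strictly exceeds 0.75 is retained for the
UMAP embedding (k = 15 neighbours, cosine metric, minimum embedded
distance 10⁻⁶, seeded and deterministic).

## Variant classification

HGVS protein notation rules when present: a premature stop without a
frameshift suffix is nonsense (including stops introduced by small
deletions), `fs` is frameshift, a single residue substitution is
missense.  A substitution-shaped protein string paired with an
indel-type cDNA is classified by the cDNA reading frame (net length
divisible by 3 → in-frame indel, else frameshift) — multi-residue
replacements print that way.  cDNA-only records use the intronic-offset
pattern (digits±digits) for splice sites and the frame rule for indels;
whole-exon loss text is a large deletion.  Rollups: PTV = {nonsense,
frameshift, splice site, large deletion}; PAV = {missense, in-frame
indel}; premature stop = nonsense ∪ frameshift.  Percentages are
integer-rounded half-away-from-zero and always recomputed from counts.

The packaged cohort table carries one record per genotyped patient (82
KMT2D, 23 KDM6A) over the unique printed HGVS strings, with
multiplicities chosen so the per-gene aggregate counts hold; the printed
per-row entries do not sum to the printed aggregates (the PAV remainder
is absorbed into missense multiplicities), so only aggregate shares are
meaningful.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes,
not faces: per-patient demographics (52% female; 92/5/3% Caucasian /
African-Caribbean / Asian; gamma(3, 2.4) ages ≈ mean 7.2, sd 4.2 years),
1–4 photo sessions per patient aging 1.5 years apart, and per session
landmarks = template + group displacement + age·(shared slope +
individual slope)·growth field + isotropic Gaussian noise, followed by a
random similarity transform (pose/zoom nuisance) — which GPA must undo.
Default cohort counts mirror a realistic case-control registry (527
controls, 82 KS1, 23 KS2, 2 KS of unknown gene); tests use smaller
counts, stated per test, to keep runtimes reasonable.

Displacement fields are unit-RMS direction fields scaled by the effect
sizes, in pixels on a 256-pixel face: KS vs control raises and arches
the eyebrows, stretches the palpebral fissures laterally and elongates
the ears (default 4 px); KS2 vs KS1 rounds the face, shortens the nose,
thickens the upper lip and elongates/rotates the ear with a reduced lobe
(default 2.5 px); landmark noise defaults to 1.5 px; the shared
allometric slope is 0.4 px/year with a 0.08 px/year random-slope spread.
Zone textures are band-limited Gaussian noise whose contrast rises (and
correlation length falls) in the eyebrow/eye zones for KS (+50%
contrast) and in the philtrum/nasal-tip zones for KS2 (+30%), echoing
eyebrow-texture differences being texture- rather than shape-borne.
KS patients are assigned variant records sampled from the packaged
cohort table, so the genotype designs run end to end.  Everything
derives from one seed; identical configs generate byte-identical
cohorts.

What passing synthetic tests shows: every stage implements its
contract, injected group structure of realistic geometry survives the
whole pipeline at the expected operating points (near-chance AUC at zero
effect, near-perfect AUC at 5× noise), and nothing leaks across the
patient-level split.  What it does not show: performance on real
photographs — real faces have correlated landmark errors, non-Gaussian
texture, pose/expression/occlusion effects and ancestry-specific
geometry that the generator does not model.

## Numerical choices and degenerate inputs

- GPA: tolerance 1e-10, max 100 iterations; zero-size configurations and
  collinear landmark sets are rejected at construction.
- PCA threshold comparisons use a 1e-12 slack so exact-boundary
  cumulative sums (e.g. 75 equal gains of 0.01) resolve as intended;
  the gain-prefix rule requires strictly exceeding 0.75.
- Mixed model: λ ∈ [e⁻¹⁶, e¹⁶] with λ < 1e-8 snapped to 0; residual
  variance floored at 1e-30; missing feature cells are dropped per
  column at fit time and propagate as missing residuals only at the
  same cells.
- Haralick: logs base 2, 0·log 0 = 0, fallbacks to 0 for correlation
  and MCC in degenerate matrices.
- Binomial CI endpoints at k = 0 and k = n are exact {0, 1}.
- All randomness flows from one seed via named substreams (split,
  booster, embedding); XGBoost runs single-threaded for bit
  reproducibility.

## Known limitations

- Automatic landmark placement is out of scope: landmarks are consumed
  from files; the ICC machinery checks raters, not detectors.
- The mixed model is linear in age; infant-to-adult facial growth is
  nonlinear, and residual age signal may remain at the extremes.
- The BLUP absorption effect above means training-set residuals
  understate patient-constant group differences; validation metrics are
  unaffected, but training-set visualizations (UMAP) partially are.
- GLCM parameters (32 levels, distance 1) and the CLAHE clip/tiling are
  field-standard defaults, not tuned values; texture features are not
  calibrated across cameras beyond what equalization provides.
- Design 3 is evaluated by cross-validation only and inherits the
  training-side BLUP caveat.
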