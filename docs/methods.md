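# Methods

This package re-implements, as a tested pipeline, the quantitative
measurement chain used to validate cardiac MR tissue markers against
histopathology in a small-animal anthracycline-cardiotoxicity setting:
pixel-wise T1/T2 relaxometry, left-ventricular (LV) segment geometry,
extracellular volume fraction (ECV), collagen quantification of stained
sections, and the cohort-level statistics. Because no imaging or histology
data from such studies are publicly deposited, every stage is validated on
synthetic data with known ground truth; this note records the models, the
defaults and why, and what the synthetic validation does and does not show.

## Relaxometry

**T1.** Saturation-recovery signals follow the three-parameter model
`M(TD) = A − B·exp(−TD/T1)`, with `M` the magnitude signal at saturation
delay `TD` (ms) and `A`, `B` scale factors (equal for ideal saturation
recovery; both are reported, the near-equality is not enforced). The fit
uses variable projection: `A` and `B` enter linearly, so the problem
reduces to a one-dimensional least-squares search over `T1` (60-point
log-spaced bracket on 1–10 000 ms, then golden-section refinement), with
the linear pair solved in closed form at each candidate. A bounded
nonlinear fallback (Levenberg-style trust region, analytic initialization
`A0 = max M`, `B0 = A0 − min M`, `T1_0` from the delay nearest 63%
recovery) handles the rare cases where the projected solution violates the
positivity constraints. Saturation recovery needs no polarity restoration,
so magnitude signals are fitted directly. Curves that *decrease* with
delay are flagged `converged=False` and carry a NaN sentinel — no
inpainting, and sentinel pixels are excluded from every ROI statistic.
Cine details of the acquisition (heartbeats, cardiac phases) are treated
as metadata; the fit consumes (signal, TD) pairs regardless of phase,
because no per-phase combination rule is defined for this design.

**T2.** Multi-echo spin-echo decay is modeled as `S(TE) = S0·exp(−TE/T2)`.
The default estimator is weighted log-linear least squares on positive
signals with weights ∝ signal², which undoes the log-transform's variance
distortion and costs a single closed-form solve; `refine=True` adds a
nonlinear polish, and non-positive samples (clipped magnitudes) fall back
to the nonlinear path. With only three echoes (16/26/36 ms) and a fast
10 ms species, the late echo carries little signal: we quote phantom SNR
at the *first echo* of the fastest-decaying region, and Monte-Carlo runs
at first-echo SNR 30 keep region-mean bias under 2%.

**Noise model.** Phantom noise is Gaussian by default (clipped at zero),
with a Rician option (magnitude of a complex Gaussian); at SNR ≥ 30 the
Gaussian approximation is standard. All noise is seeded.

## LV geometry and function

Contours are closed polygons in mm. The wall mask is decided at pixel
centers (point-in-polygon: inside epicardium, outside endocardium). The
partial-volume offset trims both borders toward mid-wall by 15% of the
*local* wall thickness measured along radial rays from the wall centroid
(720 rays); this assumes star-shaped borders, which short-axis LV contours
satisfy. Normal-vector offsetting was rejected as harder to test and no
more faithful at this resolution. Applying the offset twice is *not* the
same as doubling it (each pass trims a fraction of the current thickness);
this is documented and tested rather than "fixed".

Four segments (septal, anterior, lateral, inferior) are 90° angular
quadrants centered on a user-supplied septal direction — the quadrant
orientation convention is a configuration input, not detectable from the
data. The blood ROI must be < 5 mm², lie strictly inside the endocardial
border and avoid a papillary exclusion mask when given.

Volumes use summation of discs: `V = Σ area_endo · (thickness + gap)`,
the standard short-axis CMR rule. When phases are unlabeled, ED is the
phase with maximal total endocardial area and ES the minimal. Derived
quantities are identities: `SV = EDV − ESV`, `EF = 100·SV/EDV`,
`CO = SV·HR/1000`, and mass uses the conventional myocardial density of
1.05 g/ml.

## ECV

With `R1 = 1/T1`, the partition coefficient is
`λ = ΔR1_myo / ΔR1_blood` and `ECV = (1 − Hct)·λ`. Hematocrit is accepted
as a fraction or a percent (values > 1 are divided by 100, logged).
Aggregation order is: segment-mean T1 first, then ECV per segment, then
the global value as the *mean of segment ECVs* — the alternative
(ECV of pooled mean T1) differs in general and a counterexample fixture
asserts the implementation's choice. Non-positive blood ΔR1 (no contrast
effect in blood) is rejected as invalid contrast dynamics rather than
propagated.

## Histology quantification

Stained-section images are converted sRGB (D65) → CIE L\*a\*b\* and
clustered with k-means, k = 3 (collagen fiber / cardiac muscle /
background). The iteration budget of 100 is read as the per-restart Lloyd
cap; 10 seeded restarts keep the best within-cluster sum of squares, and
both knobs are configuration (`max_iterations`, `restarts`) so the
alternative reading — 100 restarts — is one argument away. Clusters are
named by a rule, not by order: background is the centroid with the highest
L\* (near-white slide), and of the remaining two, collagen is the one with
the higher a\* (picrosirius red renders collagen strongly red); this rule
is exercised across randomized plausible palettes. The fibrosis fraction
defaults to the *tissue* denominator, `100·collagen/(collagen+muscle)`,
since interstitial fibrosis is a proportion of tissue; a `total`
denominator switch reproduces the whole-image reading. Scanner ICC
profiles and stain deconvolution are out of scope.

Myocyte injury arrives as counts of vacuolated cells per 100 cells per
high-power field (HPF); the module averages 10 HPFs × 4 segments = 40 per
subject and warns on incomplete sampling — vacuole *detection* is manual
in this workflow and deliberately not modeled. Inflammation and edema are
ordinal 0–4 per segment (absent/minimal/mild/moderate/severe); the
subject aggregate is the segment mean (quarter-step values arise
naturally), while cohort summaries of ordinal scores use medians.

## Cohort statistics

Each variable passes a Shapiro–Wilk gate (α = 0.05, per group; any
rejection or a degenerate constant group routes nonparametric). Two groups
use a t-test — Welch by default, pooled optional for classical power
arithmetic — or Mann–Whitney; more use one-way ANOVA or Kruskal–Wallis
with pairwise post-hoc tests, Bonferroni-corrected by the number of pairs
actually tested. p-values are stored raw and rendered in the clinical
"<0.001" style.

Univariable analysis is simple OLS reporting Pearson R. Multiple
regression reports coefficients, SEs, p-values, `R²`, adjusted
`R² = 1 − (1−R²)(n−1)/(n−p−1)` (asserted on every fit), and per-predictor
VIF from auxiliary regressions (`VIF_j = 1/(1−R²_j)`; exactly 1 for
orthogonal predictors). Rank-deficient designs raise an explicit
multicollinearity error instead of a silent pseudo-inverse. Model
reduction drops the predictor with the smallest univariable |R| (ties drop
the later-listed one, logged). Missing data are handled complete-case per
analysis. Sample sizing inverts the exact noncentral-t power of the
two-sided two-sample t-test and inflates enrollment by the dropout
fraction (ceiling): 7 evaluable per group at 10% dropout enrolls 8, i.e.
40 across five treated groups.

## Synthetic data: what it emulates

The generators are pure functions of (spec, seed).

* **Phantoms** forward-simulate the exact fitting models per region with
  seeded noise, so noiseless round trips are exact by construction and
  noisy runs measure estimator bias/variance only.
* **Contour stacks** are regular polygons whose disc-summed volumes hit
  the requested EDV/ESV (polygon areas solved in closed form), with wall
  volume set to the control-group LV mass at density 1.05 g/ml.
* **Histology images** place class pixels at an exact truth collagen
  fraction of tissue (default background fraction 0.2) and color them from
  a picrosirius-like palette (collagen deep red, muscle pale yellow-pink,
  background near-white, channel SD 6).
* **Cohorts** use the included group sizes (5 controls; 6, 8, 8, 7, 7
  treated — enrollment-plus-deaths simulation is a config choice, not the
  default), draw the four histology covariates per group from truncated
  normals at the published group centers (SD defaults to range/4, the
  normal-range heuristic, since only ranges are published; bounds 0–100%
  for fractions, 0–4 for scores), and then generate native T1 and ECV from
  the published multivariable slopes (T1: 4.7 ms per % vacuolar change,
  21.0 per inflammation point, −1.7 per edema point about a 1148 ms
  control intercept; ECV: 0.17, 0.44, 0.60, −0.39 points per unit of
  vacuolar/fibrosis/inflammation/edema). Residual SDs are *calibrated
  analytically*, not hand-picked: closed-form truncated-normal moments
  give the covariate covariance, and the residual variance is solved so
  the implied univariable correlations equal the published anchors
  (T1~vacuolar R = 0.60, ECV~fibrosis R = 0.78). The calibrated SDs come
  out at ≈ 60 ms and ≈ 1.5 ECV points — the same order as the published
  within-group SDs, a useful consistency check. Off-anchor correlations
  (e.g. ECV~vacuolar ≈ 0.70) then follow from the model rather than being
  imposed.

**What passing does not show.** The synthetic cohort cannot reproduce the
real covariate covariance beyond its group structure (within-group
covariates are drawn independently, so collinearity like the published
VIF of 3.0 is only partially induced); phantom geometry is a half-plane or
annulus, not cardiac anatomy, and no motion, B1 or banding artifacts are
simulated; histology images have no texture, so k-means separability is
easier than on real slides. Recovery results therefore demonstrate the
*measurement chain's* correctness, not field performance on rat data.

## Problem sizes and numerics

Phantoms default to 32×32 (24×24 in the heaviest Monte-Carlo sweeps),
20 seeds for bias estimates, 2000 replicates for the null-calibration
check and 150 cohorts of ~500 for CI coverage — sizes chosen so the full
validation runs comfortably on a laptop core while keeping Monte-Carlo
error well below the tolerances tested. Solver tolerances: T1 golden
section to ~1e-7 of the bracket; fits accept noiseless recovery at 1e-6
relative. Degenerate inputs (constant signals, empty masks, ROIs without
valid pixels, equal contours) raise typed errors or return flagged
non-converged results rather than numbers.

## Known limitations

Bruker/DICOM ingestion, k-space reconstruction, motion/B1 correction,
MOLLI-family variants, late gadolinium enhancement, automated contour
detection, stain normalization, vacuole detection and inter-reader
modeling are all out of scope. Whether the original in-scanner T1 map
combined cardiac phases is unknown; this implementation is agnostic. The
fibrosis denominator (tissue vs whole image) is configurable because the
original convention is not stated.
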