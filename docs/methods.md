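# Methods and numerical conventions

This document records the statistical model behind each module, the
default parameters, and the rationale for every numerical choice that
is not forced by the mathematics.

## Data model

**Spectra.** A `SpectraSet` stores a strictly descending wavenumber
grid (cm⁻¹, FTIR convention) and an `(n_samples, n_wavenumbers)`
absorbance matrix. The grid may consist of several uniformly spaced
segments; segment boundaries are detected where the local spacing
deviates from the segment's leading spacing by more than 50%.
Replicate rows are named `<sample>_rep<N>` and averaged before
analysis.

**Clinical table.** Five parameters per subject: triglycerides (TGL,
mg/dL), HDL cholesterol (mg/dL), systolic and diastolic blood pressure
(SP/DP, mmHg), fasting glucose (GLU, mg/dL), plus optional `sex` and a
class label.

## MetS rule engine

NCEP-ATP-III risk factors, evaluated per subject:

| criterion | rule | note |
|---|---|---|
| triglycerides | TGL ≥ 150 | inclusive |
| HDL | HDL < 50 (female) / < 40 (male) | strict; unknown sex uses the male cut-off |
| blood pressure | SP > 130 **or** DP > 85 | one merged criterion |
| glucose | GLU > 110 | strict; a diabetes flag substitutes |

MetS is assigned when ≥ 3 criteria are met. Waist circumference, the
fifth canonical factor, is not measured in this data model, so the
count tops out at 4; the ≥3 threshold is still attainable and is the
decision rule used throughout. All cut-offs live in a frozen
`CriteriaThresholds` dataclass and can be overridden.

## Synthetic generator

Clinical parameters are drawn per class from truncated normals with
the class's reported (min, max, mean) and SD = (max − min)/4,
truncated to [min, max] (`scipy.stats.truncnorm`). Spectra are sums of
Gaussian bands on the default grid (2973–2700 and 1583–1050 cm⁻¹,
nominal spacing 806/836 cm⁻¹ ⇒ 554 + 284 = 838 points; see "Grid
arithmetic" below), plus a linear baseline (offset SD 0.01, slope SD
0.005), a multiplicative scatter factor (SD 0.05) and i.i.d. detector
noise (SD 0.002).

Band intensities are either **linked** to a clinical parameter
(intensity shifts with the subject's standardized parameter value —
TGL drives the 2860.22/2948.94 cm⁻¹ C–H bands, GLU the 1108.98/1133.09
cm⁻¹ bands, HDL negatively drives 1557.40/1562.22/1578.61 cm⁻¹) or
carry a **direct class effect** (mean shift = effect × band jitter).
`GeneratorConfig.strong_signal(effect=6.0)` places ten informative
bands at the package's reference wavenumbers with a between-class
shift of 6 within-class SDs — the configuration used by the acceptance
target. All draws descend from a single integer seed through
`numpy.random.SeedSequence`; derived seeds stay below 2³¹.

**Scope and limits.** The generator reproduces the *structure* of the
problem (class-conditional clinical chemistry, clinically linked
bands, realistic nuisance effects), not any real instrument. Absolute
classification rates on synthetic data characterize the pipeline, not
plasma spectroscopy.

## Preprocessing

Default plan: average replicates → Savitzky–Golay (window 9, order 2,
no derivative) → SNV → restrict to the two analysed regions.

- **Savitzky–Golay** runs per grid segment via
  `scipy.signal.savgol_filter(mode="interp")` (polynomial boundary
  handling, no padding) and requires uniform spacing within a segment
  (tolerance 1e-6 cm⁻¹). Derivatives are returned with respect to
  *increasing* wavenumber: the index-wise derivative on the descending
  grid is multiplied by (−1)^deriv.
- **SNV** centers and scales each spectrum to unit SD (ddof = 1);
  constant spectra raise an error naming the sample.
- **EMSC** regresses each spectrum on [1, reference, ν, ν²] with ν
  scaled to [0, 1] for conditioning, then removes the additive and
  polynomial terms and divides by the multiplicative coefficient
  (|b| < 1e-8 is an error).

## NIPALS PCA

Power iteration per component with deflation; convergence when the
relative score change drops below 1e-10 (max 500 iterations — a
warning, not an error, on non-convergence, which is expected when
adjacent eigenvalues nearly coincide). Loadings are sign-fixed so the
largest-magnitude loading is positive, making results deterministic.
Residual statistics use Σe²/(p − A) per sample and Σe²/(n − A − 1) per
variable — the classical SIMCA degree-of-freedom conventions.

## SELECT variable selection

At each step the variable with the largest Fisher weight
w = (m₁ − m₂)²/(s₁² + s₂²) (ddof = 1, ties to the lowest column index)
is selected, and every remaining variable is orthogonalized against it
(least squares with intercept). Selection stops at `k_max` (default
20), at the 3-training-objects-per-variable rule
⌊n/3⌋, or when the best weight falls below `weight_floor`.
Orthogonalization makes later weights measure *additional*
discriminating information, not information shared with earlier picks.

## LDA

Pooled within-class covariance with the n − g denominator, equal
priors by default (proportional optional). When the condition number
exceeds 1e10 a ridge ε = 1e-8 · trace(Σ)/p is added (recorded on the
model). Leave-one-out CV uses exact rank-one downdates of the class
mean and scatter — algebraically identical to refitting without the
held-out sample (verified against a naive-refit oracle in the tests)
but O(n) model updates instead of O(n) full refits. The two-class
canonical score is g₁ − g₂ with decision threshold 0; exact ties go to
the first class in sorted order ("MetS" < "noMetS").

## SIMCA

One PCA model per class after within-class autoscaling. With A
components on n training samples and p variables:

- class residual SD: s0² = ΣΣe²/((n − A − 1)(p − A))
- sample distance: d(x) = s(x)/s0 with s(x)² = Σe²/(p − A)
- acceptance: d(x)² ≤ F(1 − α; p − A, (n − A − 1)(p − A)), α = 0.05

`crit_distance = √F` gives the class boundary of a Cooman's plot.
Membership is four-way: one class, both, or none; *forced* assignment
takes the nearest model regardless of boundaries. Diagnostics:

- **Modelling power** MP_j = 1 − s_j(residual) (total per-variable SD
  is 1 after autoscaling), clipped at 0.
- **Discriminant power** DP_j = √((cross residuals)/(own residuals)),
  symmetric under class swap, ≈1 for non-discriminating variables.
- **Class distance**: the same ratio pooled over variables; exactly 1
  for a class against itself.
- **Augmented distance** (used for the optional augmented Cooman
  plot): √(½(d_res/crit)² + ½ d_score²), where d_score is the
  score-space Mahalanobis distance normalized by its own
  F(1 − α; A, n − A) limit, so the combined acceptance boundary sits
  at 1. This equal-weight quadrature combination is a design choice:
  it penalizes residual-space and score-space atypicality
  symmetrically without introducing tunable weights.

Model performance is summarized as training recognition, LOO
recognition (the left-out sample's own class model is refitted without
it), CV efficiency √(sensitivity × specificity), forced-model
efficiency, and the external-test forced-assignment rate.

## Pipeline

One stratified 95/10 split (largest-remainder per-class allocation)
feeds all four branches. Spectral branches mean-center with training
means. SIMCA defaults: A = 4 components for the five clinical
parameters, A = 3 for the ten spectral variables — large enough to
model the within-class structure, small enough to keep
(n − A − 1)(p − A) ≥ 1 degrees of freedom with the minority class's
~17 training samples. The spectral SIMCA branch truncates the
20-variable SELECT ranking to 10 by a greedy drop that maximizes
training recognition (ties drop the lowest-weight variable), keeping
the SIMCA variable count within the 3-objects-per-variable rule for
the minority class.

## Grid arithmetic

The two analysed regions span 273 and 533 cm⁻¹. With the nominal
spacing of 806/836 ≈ 0.9641 cm⁻¹ neither width is an integer multiple
of the spacing, so the generator uses n = round(width/spacing) + 1
points per region — 284 + 554 = 838 points with both region endpoints
on the grid — rather than forcing exact nominal spacing.

## Open design rationale

- **Blood pressure as one criterion** keeps the rule count consistent
  with the four-factor data model; counting SP and DP separately would
  change labels for subjects with isolated systolic/diastolic
  elevation.
- **Equal LDA priors** by default: the study design oversamples the
  minority class relative to prevalence, so empirical priors would
  encode the sampling scheme, not the population.
- **s0 and residual degrees of freedom** follow the classical
  (n − A − 1)(p − A) convention so that the F-test acceptance region
  attains its nominal coverage (verified by simulation in the tests:
  ~95% acceptance at α = 0.05).
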