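# Methods

`aortamech` implements an ex vivo aortic-wall mechanics analysis: raw
uniaxial tension records are converted to true stress–strain curves, the
stiffness and distensibility of each specimen are measured in its
physiologic loading window, fracture energy is computed from paired
notched/unnotched tests, serial CT diameters are turned into annualized
growth rates, and an ensemble variable-selection procedure feeds a pooled
random-intercept model of growth rate. Because no patient data ship with
the package, a synthetic-data module generates every input with known
ground truth; all quantitative claims below are the ones the test suite and
`scripts/acceptance.py` recompute.

## Tensile mechanics

A specimen is a rectangular strip with triplicate caliper reads of width,
thickness and gauge length averaged to `W0`, `T0`, `L0` (SI meters
internally; file formats use mm/N/mmHg). Engineering stress and strain are
`σ_e = F/A0` with `A0 = W0·T0` and `ε_e = D/L0`. Assuming the wall is
incompressible (constant volume `A·L = A0·L0`), true quantities follow as

    σ_t = σ_e (1 + ε_e),    ε_t = ln(1 + ε_e).

A warning (not an error) is raised when `L0 < 2·W0`, the minimum aspect
ratio for clean uniaxial loading between grips.

The physiologic window is defined by thin-walled Laplace stresses
`σ = r·p/(c·t)` at diastolic and systolic pressure, with direction factor
`c = 1` circumferentially and `c = 2` longitudinally, so circumferential
stress is exactly twice longitudinal at any pressure. Pressures default to
120/80 mmHg (the donor-control convention) and convert at
1 mmHg = 133.322 Pa. The radius is a single per-specimen scalar held
constant across the window; no diastole–systole distension correction is
applied.

Two window properties are reported per specimen:

* **mean elastic modulus** `E_M`: the secant slope
  `(σ_sys − σ_dia)/(ε_t(σ_sys) − ε_t(σ_dia))` on the true curve;
* **relative strain** `ε_rel = ε_t(σ_sys)/ε_t(σ_dia)`, a dimensionless
  distensibility index. Systolic over diastolic (values > 1 on monotone
  curves) is the default; the reciprocal convention is available via
  `convention="diastolic_over_systolic"` for sensitivity checks.

Strain at a prescribed stress is obtained by piecewise-linear
interpolation of `ε_t` against `σ_t`, taking the first upward crossing if
the record is locally non-monotone. No smoothing is applied: the secant
uses only two points, so derivative noise is irrelevant, while smoothing
would bias the crossing locations. Strains entering `E_M` and `ε_rel` are
true strains by default; `use_true=False` switches to engineering strain
for sensitivity checks. Records are used as measured — no preconditioning,
preload or zero-offset correction is assumed.

## Fracture energy

A pair of geometrically identical specimens is tested: one notched to half
its width (`0.5·W0`) and pulled until a crack starts — visible as the
initial kink of its force–deformation record at the critical displacement
`L_c` — and one intact. Fracture energy integrates the *intact* record
between the physiologic length `L_p` (an explicit input; either the
displacement at diastolic or systolic Laplace stress is defensible, and the
caller chooses) and `L_c`:

    Γ = ∫_{L_p}^{L_c} F dl / (W0·T0)        [J/m²]

by the trapezoid rule with interpolated endpoints — exact for
piecewise-linear records and second-order convergent on smooth ones. The
formula as written yields J/m²; toughness is conventionally reported as an
energy density, so the default normalization further divides by `L0`
(J/m³), with the formula-literal per-area value always available.
`L_c = L_p` is the degenerate zero-energy case; only `L_c < L_p` errors.

### Kink detection

Manual reading of the kink always wins when supplied. Automatic detection
is two-stage and deterministic:

1. **trigger** — a trailing least-squares slope over `window` points
   (default 5) is tracked along the record; the first point where it falls
   below `slope_drop_fraction` (default 0.5) of the running maximum flags
   crack initiation. The trigger only arms outside the toe of the curve
   (running-max slope ≥ 5% of the record's maximum, and force ≥ 5% of peak):
   on J-shaped tissue records the toe's slopes are indistinguishable from
   noise, and cracks cannot initiate at negligible load;
2. **refinement** — because the trailing window must straddle the kink
   before the ratio trips, the trigger lags the kink by up to a window. A
   segmented least-squares fit over a local region around the trigger
   (breakpoint scanned on an 8× sub-sample grid, so the estimate is
   continuous in displacement) supplies the returned `L_c`. Two segmented
   flavours are fit — broken-line, and segmented-quadratic whose curvature
   terms absorb smooth stress-stiffening on either side of the break — and
   BIC picks between them (`model="auto"`); forcing `model="linear"` gives
   the tightest localization when the record is known piecewise-linear.

If no point qualifies (straight record, or a notched specimen whose slope
never drops) a `NoKinkError` instructs the caller to supply `L_c`
manually. On piecewise-linear records with a planted kink sampled at ~36
points per record, detection at 2% peak-force noise recovers the kink
within one sample spacing in 100/100 seeds (`window=10`). At 1% peak-force
noise on strongly exponential records (`B = 10`) the toe-to-peak force
ratio is so extreme that localization degrades to a few sample spacings
and Γ errors of tens of percent are possible — wider windows help, but
genuinely noisy curved records are best handled with a manual `L_c`.

## Growth rates

Serial inner-to-inner diameters at a fixed patient-location are reduced to
one annualized rate using the earliest and latest scans (per-pair rates are
kept as an audit trail). Two data-quality rules apply: a raw change
strictly below 2 mm is attributed to measurement error and zeroed *before*
annualization (a change of exactly 2 mm counts as real), and records whose
first-to-last interval does not exceed 60 days are excluded with an
explicit reason. Rates divide by interval/365.25 days. Donor controls have
no serial imaging: their growth rate is fixed at 0 mm/y and their size is
looked up in a user-supplied normative table (age band × sex × BMI band →
diameter); no published normative table is bundled because those references
are external and version-dependent. The mapping from measurement landmarks
(annulus, sinus, sinotubular junction, mid-ascending) to analysis segments
is the caller's configuration, not hard-coded.

## Cohort statistics

The cohort table has one row per patient × segment (× direction), so rows
sharing a patient are correlated; every comparison is a linear mixed model
with a patient random intercept, fit by REML (statsmodels `MixedLM`), with
Wald normal-approximation CIs (`estimate ± 1.96·SE`) and two-tailed
p-values. Categorical terms are one-hot encoded against a reference level
(root for segment, donor/no-aneurysm for disease), and singular designs
raise an error naming the aliased columns. No multiplicity adjustment is
applied anywhere; α = 0.05 two-tailed.

### Multiple imputation

Missing predictor cells are filled by chained equations with predictive
mean matching: each incomplete column is regressed on all others
(ridge-stabilized least squares on the dummy-coded design), and every
missing cell receives the *observed* value of one of 5 donors whose
predicted means are nearest — so imputations are always values the column
actually took, categorical columns stay categorical, and no distributional
form is imposed. Matching is type-1 (donors predicted under the
least-squares fit, targets under a posterior draw of the coefficients) so
the m = 20 imputed tables carry proper between-imputation variability; 10
chained cycles are run. The analysis response stays in the imputation
model — excluding it attenuates imputed-predictor associations toward
zero. Identifier columns are excluded via `exclude`. All draws descend
from one `SeedSequence`, making the m tables bit-reproducible.

### Variable selection

On each completed table a LASSO with standardized candidates is fit and
the penalty chosen by 10-fold cross-validation. Folds are grouped by
patient and the penalty is the largest within one standard error of the
CV minimum (the `lambda.1se` convention): with ~8 correlated rows per
patient, row-level folds leak patients across the train/test split, the
CV-minimizing penalty stays near zero, and roughly half the pure-noise
candidates survive every fit — measured directly on the default synthetic
cohort, where CV-min with row folds admitted 5–7 of 10 decoys per seed
versus 0–1 under the grouped 1SE rule. The minimizing penalty remains
available (`penalty="min"`), and an explicit `alpha` (including 0 = OLS)
bypasses cross-validation.

A variable is finally selected when it is nonzero in ≥ 60% of the m
imputations *and* more than 80% of its nonzero coefficients share a sign
(computed among the imputations where it was selected — a zero coefficient
has no sign). A categorical counts as selected when any level is nonzero,
with the sign of its largest-magnitude level; selection is at variable,
not level, granularity. The rule is a pure function of the per-imputation
sets and invariant to imputation order.

### Pooled growth model and bootstrap selection

The selected variables (plus segment, per the analysis design; relative
strain and direction enter as separate terms, never interacted) are refit
per imputation as random-intercept models and combined by Rubin's rules:
pooled estimate = mean; pooled variance = W + (1 + 1/m)·B, where W is the
mean within-imputation variance and B the between-imputation variance — so
the pooled SE is never below the mean within SE. Histology–mechanics
associations use backward elimination by AIC inside 100 bootstrap
replicates; whole patients are resampled with replacement so the
within-patient correlation travels with the rows, and per-variable
selection frequencies are reported.

## Synthetic data

The tensile generator uses a Fung-type exponential true-stress law
`σ_t(ε_t) = (A/B)(e^{B·ε_t} − 1)` — the simplest law with the J-shaped
stiffening of arterial tissue — mapped back to force–displacement through
the exact inverse of the conversion pipeline, with additive Gaussian force
noise scaled to peak force. `B → 0` is the linear limit with modulus `A`.
Defaults (`A` = 50 kPa, `B` = 10, 5×2 mm section, 12 mm gauge) put
physiologic-window moduli in the 10²–10³ kPa range observed for thoracic
aorta. Closed-form
inversion `ε = (1/B)·ln(1 + B·σ/A)` provides the independent oracle for
window properties; notched pairs plant a kink by scaling the post-kink
slope and their Γ oracle uses adaptive quadrature of the analytic force.

The cohort generator draws 200 patients × 4 segments × 2 directions by
default. Growth rate is `Xβ + u_patient + ε` with sparse truth at
clinically plausible scales: intercept −8.88, radius
+0.40 mm/y per mm, relative strain +3.64 mm/y per unit, chronic dissection
+6.97 mm/y, segment offsets +1.34/+1.81/+2.45 mm/y (ascending/arch/
descending vs root); patient-intercept and residual SDs are 1.0 mm/y.
Mechanical covariates carry their own segment/direction/disease structure
(longitudinal offsets −166.8 kPa, −201.2 J/m³, −0.01; disease offsets
−431.7 J/m³ and +0.09 on toughness and relative strain; none on modulus)
so they behave like measured covariates rather than white noise, and ten
iid standard-normal decoys are appended. Missingness (default 20%, MCAR,
on the three measured mechanical columns) can instead be MAR conditioned
on segment, with root rows twice as likely missing — root specimens are
smaller and yield fewer tests. The truth record (β, patient intercepts,
missing mask, linear predictor) round-trips losslessly through JSON.

What the generator does *not* emulate: real tissue viscoelasticity and
strain-rate dependence, anatomical correlation between neighbouring
segments beyond the patient intercept, non-Gaussian measurement error, and
informative missingness driven by unobserved tissue quality. Passing
parameter-recovery tests on these synthetics therefore demonstrates that
the estimators are correctly implemented and calibrated under the stated
model, not that the model captures every feature of patient data.

## Numerical choices and problem sizes

Tolerances: exact identities are asserted to 1e−12 relative; interpolated
window properties to 0.1% on 200-point curves; the CI-coverage check uses
100 replicate cohorts of 30 patients and accepts 95 ± 5 percentage points;
selection power uses 10 replicate default cohorts. These sizes were chosen
so each recovery check is decisive (multiple SEs of headroom) at desk
scale. PMM imputation of a 1600-row cohort with m = 20 runs in ~1 s;
the full selection pipeline ~4 s per cohort.

Known limitations: the pooled relative-strain coefficient is mildly
attenuated (~15%) relative to its generating value because PMM with a
moderately predictive imputation model shrinks imputed-cell associations;
it stays well within 3 pooled SEs of truth at the default sizes. REML
variance estimates sit exactly at zero only when the between-group
variance is empirically zero; on finite noisy data they hover at a small
positive value, as expected. Wald inference ignores the finite-m
t-correction of Rubin's degrees of freedom, which is conservative only for
very small m.
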