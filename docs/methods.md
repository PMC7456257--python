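# Methods

This note records the models, the numerical choices and the open design
decisions behind `saplingcrown`, and what the synthetic-data tests do and
do not establish about field data.

## Crown geometry

Field measurements are taken per branch on felled saplings: `L` (m), the
distance along the trunk from the tip to the branch base; `BC` (cm), the
branch chord length; `VA` (degrees), the insertion angle; plus branch
length `BL`, diameter `BD` and azimuth (carried through but not modelled).
Derived per branch:

* outer crown radius `OCR = BC·sin(VA)` — the horizontal reach of the
  branch tip (m);
* depth of the branch tip `DINC = L − BC·cos(VA)` — the chord's projection
  onto the trunk subtracted from the base depth;
* relative depth `RDINC = DINC/CL ∈ [0,1]`, with `CL` the crown length.

Insertion angles above 90° (drooping lower branches; observed up to 160°)
give a negative projection and can push `RDINC` slightly above 1. The
retention policy is configurable (`drop`, `clip`, `fail`); the default is
`clip`, which keeps the sample size and snaps the relative depth into
[0,1]. Crown ratio is `CR = CL/HT` — the standard forestry definition,
adopted because the sources using this model family never spell the
formula out. Internally all lengths are metres and angles radians; the CSV
dialect keeps field units (cm chords, mm diameters, degree angles).

For candidate-model comparison only the largest-radius branch per whorl is
used (one whorl ≈ one growth year; the longest branch traces the envelope).
Largest is judged on derived `OCR` by default with a `BD` switch, ties
broken by larger `BD` then file order — `OCR` is the modelled quantity,
which is why it ranks first.

## Profile forms

Four forms are implemented (coefficients as ordered in the code):

* `power_exp_basic`: `OCR = a1·t^a2·e^(a3·t)`, `t = RDINC`;
* `power_exp_full`: `OCR = a1·DBH^a2·t^(a3+a4·CR)·e^(a5·t)`;
* `kozak_basic`: `OCR = c1·X^c2`, `X = (1−√(1−t))/(1−√p)`;
* `kozak_mod`: `OCR = c1·DBH^c2·B^(c5·(1−t))`,
  `B = (1−√(1−t))/(1−√(c3·CR^c4))`, value at `t=1` taken as the limit
  `c1·DBH^c2` (exponent 0).

For the power-exponential forms with negative exponential rate, the depth
of maximum radius has the closed form `t* = (a3 + a4·CR)/(−a5)` (from
`d/dt [t^b e^(ct)] = 0`), capped at 1; a nonnegative rate means the
profile is monotone to the crown base and `t* = 1` is returned with a
monotone flag. In crown-morphology usage this argmax depth is called the
*inflection point*; true second-derivative inflections are not computed.
Note the basic Kozak form's own claim — that its maximum sits at `t = p` —
is not algebraically consistent with the printed base (X is monotone in t);
the form is implemented exactly as printed and `p` is reported as its
nominal inflection parameter without correction.

Upper-crown volume is the rotational integral `V = π·CL·∫ r(t)² dt` by
composite Simpson on ≥ 2001 points; the default region is tip-to-inflection
(`[0, t*]`), exposed as a parameter because "upper crown" has no unique
definition. Quadrature at 2001 points agrees with 200001 points to 1e-8
relative on these smooth profiles.

## Ordinary least squares and fit statistics

Candidate forms are fitted by `scipy.optimize.least_squares` with
multi-start (default start `a1 = mean(OCR), a2 = 0.5, a3 = 1, a4 = −0.5,
a5 = −1`, matching the sign pattern of fitted coefficient tables in this
literature, plus 20 multiplicative U(0.5,2) perturbations, seeded).
Goodness of fit: `R² = 1 − SSE/SST`, `R²adj = 1 − (1−R²)(n−1)/(n−p)`, and
`RMSE = √(SSE/(n−1))`. The `n−1` RMSE denominator (rather than `n−p`)
follows the convention of the crown-profile literature this package
targets; it is deliberate and documented here because it differs from
common regression practice. Ranking: largest `R²adj`, ties by smaller
RMSE. Candidate comparison pools both strips (the published comparison is
phrased species-level, not per strip).

## Nonlinear quantile regression

The τ-quantile profile minimises `Σ ρ_τ(OCR_i − f(x_i; θ))`. The check
function is non-smooth, so the optimiser runs a continuation on the
log-sum-exp smoothing `ρ_τ^ε(u) = τ·u + ε·log(1+e^(−u/ε))` with ε
decreasing 1e-2 → 1e-6 (L-BFGS-B at each stage), then a Nelder–Mead
polish on the exact loss; starts are the OLS solution plus seeded
multiplicative perturbations. The reported loss is always the exact
pinball loss at the returned coefficients — the optimiser is treated as
conformant if it matches the reference interior-point solution's loss, not
its path. Grid fits (0.50 … 0.99 step 0.01, 50 levels) chain warm starts
from the previous level; per-level failures are recorded without aborting
the grid. Quantile crossing of the fitted curves is measured (fraction of
adjacent-level grid evaluations out of order) and reported, never silently
re-ordered.

## Boundary (frontier) estimation

The outermost profile of one sapling's branch-tip cloud `(RDINC_i, OCR_i)`
is the polynomial `φ_θ` of degree `p` minimising its integral over [0,1]
subject to `φ_θ(x_i) ≥ y_i` — a linear program (objective coefficients
`(b^{k+1}−a^{k+1})/(k+1)`), solved with HiGHS. Two implementation choices
matter:

* **Nonnegativity rows.** `φ(g_j) ≥ 0` is imposed on a 201-point support
  grid. Radii are physical lengths, and without these rows the LP is
  unbounded whenever the point cloud sits to one side of the support (a
  tilted envelope pivoting outside the cloud drives the area to −∞).
* **Post-solve lift.** Any residual solver infeasibility (≈1e-10) is
  absorbed by lifting the intercept, so the fitted polynomial envelopes
  every point exactly.

Degree selection fits `p = 0 … max_degree` (default 6 in the pipeline;
up to 20 supported) and minimises the slack-based criteria
`AIC(p) = log(Σ slack) + (p+1)/n` and `BIC(p) = log(Σ slack) +
log(n)(p+1)/(2n)`; AIC decides and disagreements resolve to the smaller
degree. Slack sums below 1e-9 are treated as exactly zero so that the
complexity penalty, not the logarithm of numerical noise, breaks ties
among exact envelopes. Degrees are capped at `n−1` points. Because the
polynomial envelopes the data only at the data points, a 201-point audit
reports between-point dips below binned data maxima and any negative
values.

## Quantile selection and strip summaries

Per sapling, every strip-level quantile curve is evaluated at the
sapling's own (DBH, CR) on the fine depth grid (10,000 even intervals,
10,001 points), clamped at zero radius, and compared to the sapling's
boundary curve by mean absolute distance. The closest quantile wins; ties
go to the larger quantile (the outermost curve is the object of interest).
Two strip-level summaries are reported because the aggregation rule is
genuinely ambiguous in this literature: the mean of per-sapling best
quantiles (rounded to the 0.01 grid) and the quantile minimising the
column mean of the distance matrix. Both appear in the outputs with the
discrepancy visible. Saplings with fewer than 4 measured branches are
skipped (a boundary through 2–3 points is uninformative).

## Morphology and growth comparison

Crown metrics are tabulated at fixed crown ratio (default 0.80, the
approximate sample mean) over DBH 0.5–5.0 cm step 0.1. Because the profile
scales as `DBH^a2` with different exponents per strip, the *absolute*
upper-crown volume difference between strips need not be monotone in DBH
(with the shipped reference coefficients it peaks near 3.5 cm); the
*relative* difference `(V_uncut − V_cut)/V_cut` is the size-standardised
contrast, decreases monotonically, and is the quantity the directional
tests check. Both are reported.

Annual branch-length growth (one sample branch per sapling) is compared
per year with Welch's two-sample t-test — chosen because unequal variances
between treatments are plausible and the comparison is a single planned
contrast per year; p-values are reported unadjusted with a Holm-adjusted
column alongside for transparency.

## Synthetic stands: what they emulate and what they do not

The generator reproduces the measurement *structure*: per-strip truncated
normal DBH (0.5–5 cm) and HT (>1.3 m) matching the field sample moments
(49 cut / 30 uncut saplings; DBH 2.46±0.99 vs 1.36±0.54 cm, …), crown
length `CR·HT` with CR truncated to (0,1], whorls every 0.20 m (giving
≈ 1200/690 branches, close to the field 1398/753), insertion angles from
truncated normals matching the per-strip VA moments, and branch radii
`OCR = r*·u` with `r*` the strip's true envelope radius and
`u ~ Beta(α, β)` on (0,1] — every observation on or below the envelope.
Chord and base distance are back-solved (`BC = OCR/sin(VA)`,
`L = RDINC·CL + BC·cos(VA)`) so the geometric derivation round-trips
exactly; where a drooping angle would imply `L < 0` near the tip the angle
is mirrored about 90°, which preserves the radius. The default envelope
truths are the shipped published coefficient rows; default noise
`Beta(4, 1)` puts the conditional 0.99-quantile at 99.7% of the envelope,
so a τ ≈ 0.99 fit should recover the envelope coefficients — the basis of
the end-to-end recovery test. Growth series share a common pre-treatment
mean (11.35 cm/yr, the average of the two near-equal field means) and
follow strip-specific means afterwards; the default trajectory has the
uncut strip ahead in the first two post-treatment years and the cut strip
ahead from the third, sd 2.5 cm/yr.

Not emulated: spatial competition and crown interlocking, light gradients,
within-whorl depth jitter, measurement error in angles and chords, and any
dependence of the depletion distribution on depth or tree size — the Beta
form is an assumption with tunable shape, not a field estimate. Passing
tests therefore establish that the estimators recover known structure
under the stated noise model, not that field data satisfy that model.

## Problem sizes and determinism

The shipped analysis and tests run at the field sample's own scale
(49 + 30 saplings, ≈ 1900 branches; 50-level quantile grids fit in well
under a minute) with the recovery checks on a 150-sapling strip. All
stochastic stages take explicit integer seeds (numpy `default_rng`);
identical configuration and seed reproduce byte-identical CSV outputs.

## Known limitations

* Quantile fits carry no standard errors or confidence bands; published
  coefficient standard errors are not a reproduction surface.
* The frontier is a single polynomial; spline/kernel/extreme-value
  boundary estimators are out of scope.
* The per-sapling selection evaluates strip-level fitted curves at each
  sapling's covariates; no per-sapling refitting is attempted.
* Branch azimuth is carried as data but unused (no crown-asymmetry
  analysis).
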