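# Methods

This package implements a dendrochronological analysis of drought response
in a forest-tree provenance trial: a common garden in the western boreal in
which seed sources (provenances) from across a species' range, planted in a
randomized complete block design, were exposed to two severe droughts
(1999 and 2002). Ring widths from increment cores provide a retrospective
annual growth record per tree; the analysis asks whether regional
populations differ in how much growth they keep during a drought
(resistance), how strongly they rebound (recovery), and whether they return
to pre-drought performance (resilience).

## Chronology assembly and cross-dating statistics

Each tree contributes two cores (north and south side), measured in a
Tucson/RWL or long-CSV record in millimetres. Cores are averaged
arithmetically per year; the analysis window is the span with complete
coverage, 1988–2017 by default (configurable). Cross-dating quality is
summarized by leave-one-out interseries correlations (each tree against
the mean of all others over the overlapping years) and the expressed
population signal

    EPS = n·r̄ / (n·r̄ + (1 − r̄)),

with n the number of series and r̄ the mean interseries correlation.
EPS is defined as 0 for r̄ ≤ 0 (no common signal). In natural stands 0.85
is the customary adequacy threshold; trees of identical age in a common
garden score far higher because environmental variation is shared.

## Common-spline detrending with reversed standardization

Ring width declines with tree age, so the age trend must be removed before
drought years can be compared with reference periods. Standard
dendrochronology fits one spline per tree, but in a common garden that
would absorb genuine population differences in growth trajectory. Here a
*single* cubic smoothing spline is fitted to the pooled z-scored data of
all trees (each tree standardized by its own window mean and sample SD,
n−1 denominator), subtracted in z-space, and the standardization is then
reversed:

    detrended(t) = (z(t) − f(t))·sd + mean = width(t) − f(t)·sd.

Detrended values therefore stay in millimetres and preserve between-tree
level differences — the absolute growth a provenance achieves is part of
the signal, not a nuisance.

The smoothing spline minimizes Σ w(y − f)² + λ∫f″² over natural cubic
splines with knots at every distinct year, solved with the Reinsch
(second-difference) formulation. The dimensionless stiffness (default 0.7,
a deliberately stiff setting so the spline tracks the age trend but not
year-to-year climate signal) maps to λ by

    λ = r · 256^(3·s − 1),

where r is a trace ratio of the B-spline cross-product and curvature-Gram
matrices computed on the year axis rescaled to [0, 1]. The ratio sums
interior basis functions only, reproducing the convention of the reference
smoother (`smooth.spline`); fitted curves agree with it to ~2·10⁻⁴ on a
30-year fixture and the solver agrees to ~10⁻⁶ at a fixed λ. Every pooled
(tree, year) point carries equal weight, so years with more surviving
trees weigh more; a point absent from a tree's record is simply absent.

## Lloret indices

With preD and postD the mean detrended growth over shared pre- (1993–1997)
and post-disturbance (2003–2007) windows and D_e the detrended growth in
event year e ∈ {1999, 2002}:

    resistance  Rt_e = D_e / preD
    recovery    Rc_e = postD / D_e
    resilience  Rs   = postD / preD

The two events were too close for full recovery in between, so one shared
pre and one shared post window serve both; this makes Rs = Rt_e·Rc_e an
exact identity per tree. Indices are ratio-scale (invariant to rescaling a
tree's series) and require positive preD and D_e; a non-positive value
(possible after detrending a near-zero ring) raises an error by default,
with an optional small positive floor for exploratory use.

### What the pipeline estimates, and a known bias

The synthetic generator injects droughts as multiplicative event-year
shocks m ∈ (0, 1] on the width. Two deterministic effects make the
pipeline's regional resistance estimate differ from m itself:

1. *Additive detrending of a multiplicative shock.* Perfect removal of the
   common trend gives D_e = width(e) − sd·f(e) ≈ m·trend(e) − (trend(e) −
   μ), so Rt ≈ 1 − (trend(e)/μ)(1 − m) with μ the window-mean trend. When
   the event falls where the trend is below its window mean (2002 here),
   Rt exceeds m by ≈ (1 − trend(e)/μ)(1 − m) — about +0.04 at the default
   trend parameters.
2. *Spline absorption.* The pooled spline is fitted through the event
   years, and even a stiff spline absorbs part of a dip shared by every
   tree (~0.05 z-units per event here), inflating detrended event growth.

Both effects are properties of the method itself (one spline for all
trees, fitted to all years, standardization reversed), not of this
implementation — the spline matches the reference smoother and the mixed
model matches `lme4` to numerical precision. Consequently the end-to-end
check that regional BLUEs recover the *injected multiplier* within 2 SE
fails by construction (measured deviation ≈ +0.045 at 1999 and ≈ +0.10 at
2002, uniform across regions, identical in a noise-free run); the
corresponding acceptance test is left failing with this explanation rather
than redefining the target. Stochastic recovery of the method's true
estimand (the noise-free pipeline output) is what the remaining tests
verify. Rankings and between-region contrasts are essentially unaffected,
because the bias is nearly constant across regions.

## Site water balance

Reference evapotranspiration uses Hargreaves–Samani,

    ET0 = 0.0023 · Ra · (Tmean + 17.8) · √(Tmax − Tmin)   [mm/day],

with extraterrestrial radiation Ra from standard solar geometry (solar
constant 0.0820 MJ m⁻² min⁻¹, 0.408 mm per MJ m⁻²; sunset-hour-angle
argument clamped to [−1, 1] so polar day/night degrade gracefully);
negative ET0 is clamped to 0. The daily climatic moisture deficit is
max(0, ET0 − precip) and annual CMD is its calendar-year sum. Missing days
are dropped and counted, never imputed.

Anomalies are departures from a day-of-year climatology (reference period
1961–1990 by default, smoothed with a 15-day circular running mean), and a
window's anomaly integral is the signed sum of daily departures —
capturing both the intensity and the duration of an event.

Note on scales: an annual CMD accumulated daily is substantially larger
than the monthly-water-balance CMD printed in climate-normal tables,
because every dry day contributes its full deficit even inside a wet
month. The synthetic site's daily-scale normal (~500 mm) is therefore not
comparable to a downscaled monthly normal (~150 mm) for a similar climate;
the generator's thinned-gamma precipitation, which concentrates rain in
fewer events than a real station record, widens the gap further. Monthly
bioclimatic summaries that *are* recomputable from monthly normals (MAT,
MWMT, MCMT, TD, MAP, MSP, AHM, SHM) are provided; PAS, degree-days and
frost-free period require downscaling machinery and arrive via the input
table.

## Mixed models

The trait model is the provenance-trial classic

    Y = μ + Region (fixed) + Prov(Region) + Block + Plot(Block) + e,

with independent random intercepts. Two named presets encode the sampling
designs: `plots` (25 trees per provenance in 5-tree row plots — full
model, used for height and DBH) and `cores` (one tree per provenance per
block — region fixed, block random, used for the drought indices, where
provenance and plot are confounded with tree).

Fitting is REML on the variance ratios γ_f = σ²_f/σ²_e (log scale), with
the residual variance profiled out and the Woodbury identity keeping all
linear algebra in the random-effect dimension. The gradient is analytic
(dF/dγ_f = tr(Z_f′PZ_f) − c‖Z_f′Py‖²); two spread-out starts plus a
Nelder-Mead polish guard against quasi-stationary points, and a plateau
within 10⁻⁵ of the optimum counts as converged. Components driven to the
lower bound are reported as 0 with a warning. Noiseless data short-circuit
to exact least squares. Region BLUEs are generalized least squares at the
REML estimates with model-based SEs; on one full-size trial the fit
matches `lme4` (−2·REML identical, BLUEs to 10⁻¹¹, variance components to
four decimals).

Survival is a binomial logit GLMM fitted by penalized quasi-likelihood:
iteratively reweighted working responses through the same REML machinery
with the binomial dispersion fixed at 1 (estimating a working-scale
dispersion lets spurious cluster variance absorb Bernoulli residual noise).
Estimates are reported on the probability scale with delta-method SEs, and
2-SE intervals are formed on the logit scale and back-transformed, giving
proper asymmetric intervals near 0/1. A region whose trees all share one
outcome has no finite estimate (complete separation); it is reported at
the boundary with an infinite SE and excluded from the letters rather than
silently penalized.

Pairwise region comparisons use the studentized-range criterion
(|diff|/SE > q(1−α; k, df)/√2) at family-wise α = 0.05, with containment
degrees of freedom (observations minus the rank of the combined
fixed-plus-used-random design); letter displays are sensitive to the df
choice, hence it is stated. Letters come from the insert-and-absorb
algorithm, ordered by estimate.

## Associations and ordination

Provenance trait means are correlated with origin climate normals by
Spearman's ρ (average ranks on ties). p-values: exact permutation
enumeration for n ≤ 10; for larger untied samples, a shared
million-permutation Monte-Carlo null per sample size (fixed internal
stream, add-one corrected, so p-values are reproducible and never zero) —
the t-approximation is anti-conservative at these n and measurably
inflates the family-wise error of the screen; it remains only as the
fallback under ties. Holm's step-down runs over the full trait × climate
matrix by default (more conservative than per-trait families; both
available). Measured family-wise error under a label-permutation null is
5–6% at nominal 5%.

The climate ordination is a PCA of the correlation matrix: variance
fractions from the eigenvalues, provenance scores, and loadings as
variable–PC correlations (eigenvector × √eigenvalue). Signs are fixed so
each PC's largest-magnitude loading is positive.

## Synthetic trial generator

The generator's defaults are the study conditions: 33 provenances in six
regions (4/9/9/3/4/4), five blocks, 5-tree row plots (825 trees), one tree
per provenance per block cored (165 trees, two cores each), years
1988–2017, and daily weather 1961–2017 at 55.28° N.

Ring widths follow

    width(t) = [A·e^(−(t−t₀)/τ) + c] · G_region · b_block · ε(t) · Π_e m^(d_e(t)),

with age-trend A = 2.5 mm, τ = 12 yr, asymptote c = 0.8 mm (ring widths of
1–3 mm, realistic for a mid-rotation boreal conifer), lognormal tree-year
noise (σ = 0.15), per-core lognormal noise (σ = 0.10; two-core averaging
halves its variance), lognormal block multipliers (σ = 0.05), and regional
drought multipliers m — defaults set to realistic field-scale regional
resistance values (0.44–0.69) so simulated effect sizes and SEs are
comparable in magnitude to real trials. d_e(t) = decay^(t−e) switches
the shock on in the event year and fades it geometrically (default decay
0.3, reflecting incomplete recovery between the two events; set 0 for
clean parameter-recovery experiments, since any carryover enters the
recovery windows by design). Noise is multiplicative because growth is
positive and right-skewed, and it makes variance arithmetic exact on the
log scale.

Traits follow the mixed-model generative structure with configurable
variance components (height defaults 3600/900/1600/14400 cm²; DBH scaled
by 0.13); survival is Bernoulli with regional probabilities (defaults
0.78–0.97) perturbed per provenance on the logit scale (σ = 0.3). Weather is a sinusoidal seasonal temperature cycle (annual mean
0.6 °C, amplitude 16.8 °C, daily noise 3 °C, mean diurnal range 10 °C)
with thinned-gamma precipitation calibrated to ~490 mm/yr peaking in
summer; drought windows scale precipitation down and shift temperature.
Provenance climate normals are drawn around realistic regional means and
SDs for the seven core variables (boreal-range climates spanning
continental-dry to maritime-wet), with the other six derived from simple
bioclimatic relationships so the table is internally consistent.

All draws come from one `numpy.random.default_rng` (PCG64) stream per
simulation call, so a fixed seed reproduces the trial bit for bit across
platforms.

What the generator does *not* emulate: measurement error from ring
detection, missing or locally absent rings, cross-dating mistakes, spatial
autocorrelation within the site, age-dependent noise, and a realistic
precipitation event structure. Passing tests demonstrate that the
implementation recovers known structure under the stated stochastic model,
not that field data of this kind will behave as cleanly.

## Problem sizes used in the checks

The automated checks simulate at the full trial scale (825 trees, 165
cored) with 100–200 replicates for the recovery simulations and 500
replicates for the family-wise-error null; the worked example in the
README uses a single full-scale trial. These sizes give Monte-Carlo
standard errors comfortably below the tolerances being asserted.

## Known limitations

- PQL is a first-order approximation; for heavier random-effect structure
  on binary data an adaptive-quadrature fit would be preferable.
- Containment df is one convention among several; letter displays near the
  significance boundary can differ from tools using Satterthwaite or
  Kenward–Roger df.
- The resistance estimand bias described above is inherent to additive
  common-spline detrending of multiplicative shocks; comparisons *between*
  regions are robust to it, absolute levels are not.
- The weather model's daily-scale CMD is not comparable to monthly-balance
  climate normals (see above).
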