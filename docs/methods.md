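# Methods

This note records what the package computes, the assumptions behind each
stage, the numerical choices that were genuinely open, and what the
synthetic test worlds do and do not establish about real data.

## Chronology from heterogeneous dates

Each archaeological context carries zero or more absolute dates
(radiocarbon, TL, ESR, OSL, U-series), each a central age in years BP with a
one-sigma error. Radiocarbon dates are calibrated by evaluating, on a
calendar-year grid, the Gaussian density of the measured radiocarbon age at
the curve mean with variance `error² + curve_error²`, then normalizing.
Non-radiocarbon dates become discretized normal densities. All per-date PDFs
are normalized *before* summation, so the context's summed distribution is
an equal-weight mixture: dates with narrow errors produce taller peaks and
thereby dominate the mode without any explicit weighting scheme.

Choices where convention was open:

- **Year grid**: 10-yr resolution over 0–160 ka. Finer than any plausible
  dating error in this period, coarse enough that a full PDF is 16k floats.
- **Confidence**: the summed distribution is renormalized to unit mass before
  the ±5000-yr window mass is measured, so confidence is comparable across
  contexts regardless of how many dates they carry.
- **Peak ties** break toward the older (larger BP) year and are flagged;
  deterministic, and conservative against leaking post-50-ka contexts into
  the analysis window.
- **Millennium rounding** is nearest-multiple with exact halves toward the
  older millennium, for the same reasons.
- **Deduplication** keys on (longitude, latitude, millennium) — the spatial
  location, not the locality label — keeping the first-seen record.
- Radiocarbon ages are assumed to be on the same BP scale as the curve; no
  reservoir or marine corrections are applied, and Bayesian stratigraphic
  (sequence) modelling is out of scope.

## The synthetic paleoworld

The generator exists so that every downstream stage can be tested against
known truth; it emulates the *structure* of millennial paleoclimate stacks,
not any particular climate simulation. Temperature is a latitudinal profile,
precipitation a west–east maritime gradient, productivity a saturating
function of both; each gets a sinusoidal forcing (default period 23 kyr,
amplitudes 5 °C / 180 mm — glacial-cycle scale swings) and a static smooth
spatial noise field. Sea cells follow a fixed bathymetry against a
forcing-driven sea level (warm = high stand); ice covers northern rows whose
noise-free temperature criterion falls below −8 °C, so cold-phase ice extent
dominates warm-phase extent by construction. Cells are 33.5 km squares on a
natively equal-area grid (1122.25 km² each), millennial slices default to
145→30 ka BP, and no map-projection machinery is involved — the equal-area
property of real inputs is a property of their preparation, not of these
algorithms.

The archaeological record is a thinned point process: uniform proposals over
land cells and slices, accepted with probability (true suitability ×
taphonomic survival × detection). The true niche is a product of Gaussian
terms per variable (defaults: optimum 8 °C with 4 °C tolerance, 900 mm with
250 mm tolerance). Survival decays with age and with northern latitude,
mimicking glacial scouring of old, high-latitude sites, so "niche recovered
despite preservation bias" is a testable claim. Dates get method-specific
Gaussian noise (radiocarbon measurements pass through the calibration curve
first).

What passing tests on these worlds shows: the estimators recover what they
claim to recover under the stated noise and bias processes, at realistic
sample sizes (order 10² presences against order 10³–10⁴ background points).
What they do not show: robustness to spatially correlated dating error,
research-intensity bias (clustered survey effort), non-Gaussian niches, or
climate fields with regime shifts — real-data conclusions still rest on the
usual domain caution.

## Maxent

The model is the standard presence–background Gibbs density. The fitted
objective (minimized) is

    −(1/n_p) Σ_presences η(x_i) + log( (1/n_b) Σ_background exp(η(x_j)) )
    + Σ_j λ_j |β_j| .

- **Features**: covariates are min–max scaled on the combined training
  sample; L is the scaled covariate, Q its square, H forward hinges
  `max(0, (z − k)/(1 − k))` at 15 evenly spaced knots per variable
  (configurable). Threshold/product/categorical features are out of scope.
  Feature values are not clamped outside the training range.
- **Regularization**: λ_j = RM × base(class, n_p) × sd_j(presences) / √n_p,
  with the published default base tables (linear 1.0/0.2/0.05 at 10/30/100
  presences, quadratic 1.3→0.05 at 0→100, hinge 0.5) interpolated in n_p.
- **Normalization set**: the presence samples are added to the background
  for Z, following the reference implementation's long-standing default.
  Besides fidelity, this guarantees the objective is bounded (coercive) even
  when a hinge feature perfectly separates presences from background.
- **Optimizer**: monotone accelerated proximal gradient (FISTA with an ISTA
  safeguard, backtracking line search), terminated on the lasso KKT
  conditions, followed by a damped-Newton polish on the identified active
  set with signs held fixed. The objective is nonincreasing across
  iterations by construction, and solutions match an independent
  bound-constrained optimizer to ~1e-8 on small instances.
- **Outputs**: raw (sums to 1 over the normalization set), logistic
  `e^H·raw / (1 + e^H·raw)` with H the training-background entropy (the
  default-prevalence-0.5 convention; a null model scores 0.5 everywhere),
  and cloglog `1 − exp(−e^H·raw)`.
- **AICc**: −2 lnL + 2K + 2K(K+1)/(n−K−1) with K the nonzero-coefficient
  count, n the presence count, and lnL the presence log-likelihood of the
  raw density normalized over the full background; undefined (NaN) when
  n ≤ K + 1.
- **Omission**: the test omission rate is measured against the
  10th-percentile training-presence threshold (or.10p), the common choice in
  tuning workflows; minimum-training-presence is available by flag and the
  rule used is recorded in the selection result.
- **Selection**: random presence folds (default 10) share one background;
  per candidate, AICc comes from the full-data fit and AUC/omission are fold
  means. Screens: ΔAICc < 2, then minimum mean omission, then maximum mean
  AUC; residual ties go to the lower RM, then the simpler feature class.
- **Variable contribution**: two surrogates are reported — permutation
  (mean AUC drop over 10 shuffles) and drop (training-gain loss when a
  variable's coefficients are zeroed), each normalized to 100%. The
  path-gain "percent contribution" of the reference GUI is not
  reconstructible from fitted coefficients; both surrogates are labelled as
  such.
- **Niche envelope**: per-variable intervals where the response curve
  (others at their training means) exceeds a cut (default 0.5), endpoints
  interpolated at the crossings, plus pairwise suitability surfaces.

## Smooths, stability screens and the AR1 trend model

One spline engine serves both the niche-stability screens and the trend
model: a natural cubic regression spline in the knot-value parameterization
(k = 3 knots at quantiles; the coefficients are the function values at the
knots) with the integrated-squared-second-derivative penalty, whose null
space is {constant, linear} — so infinite smoothing recovers the
least-squares line exactly. The penalty matrix is rescaled to the design's
magnitude so the smoothing parameter is dimensionless; it is then chosen by
REML (profiled Gaussian criterion, coarse grid plus bounded refinement).

Smooth-term p-values are Wald-type: the hypothesis "f is constant" is tested
through the contrasts of knot values, against a reference distribution with
fractional degrees of freedom equal to the smooth's effective df (F when the
scale is estimated, χ² when fixed). This is an approximation — penalized
p-values always are — and simulation at the package's scales puts its
empirical size at α = 0.05 between 0.05 and 0.07 (the test suite asserts the
documented [0.02, 0.10] band over 500 null series).

The trend model adds AR1 errors for the evenly spaced niche-area series:
iterate (a) a Prais–Winsten-whitened penalized fit and (b) the lag-1
autocorrelation of the working residuals, to a 1e-6 fixed point (max 50
iterations; ρ clipped to ±0.99). The default family is Poisson on
presence-cell counts via penalized IRLS (working response whitened and
weighted); a Gaussian family on log area is provided as a simpler fallback,
and the family is labelled in every output. The reported r² is the adjusted
r² of the final whitened working model. Simulations with latent AR1 ρ = 0.6
over 116 slices detect a one-log-unit decline in >90% of replicates with
mean ρ̂ ≈ 0.53 — the small downward bias is the usual price of estimating ρ
jointly with a flexible mean.

## Projection, thresholding, bookkeeping

Projection evaluates the selected model on every land cell of every slice;
sea/ice cells are missing. The optimal threshold maximizes TPR + TNR over
the observed training scores, ties breaking toward the lower threshold (so
separable scores threshold at the gap's lower edge); TSS and Cohen's κ are
reported at that cut. Presences that fall on cells masked at their assigned
millennium are excluded with a logged count, never snapped to valid cells.
Background cells are sampled uniformly without replacement within a slice
(replacement only by explicit flag); the same cell may recur across slices,
which are distinct environments by construction.

## Problem sizes

The bundled demonstration runs a 26×40 world, 116 slices, 160 contexts,
50 background points per millennium, the full 20-candidate tuning grid with
10 folds — about half a minute on one CPU. The package defaults keep the
study-scale settings (100 background points per millennium over 145–50 ka,
giving 9600; filters at 50–145 ka, ≤70°E, ≥35°N). Recovery and calibration
simulations use 100–500 replicates as noted above.

## Known limitations

- Calibration treats curve uncertainty as independent Gaussian at each
  calendar year; no curve-covariance or outlier handling.
- The Maxent AICc (coefficient-counting K) is a convention, not a
  likelihood-theory result; it is used only comparatively within a grid.
- The AR1 Poisson path is quasi-likelihood through and through; its p-values
  inherit both the penalized-Wald and the working-model approximations.
- The equal-area assumption is structural: real rasters must arrive already
  projected; there is no CRS handling.
- GeoTIFF export is not provided; stacks round-trip through classic NetCDF.
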